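"""Synthetic fixture generator with planted, machine-readable ground truth.

Everything downstream of read mapping is emulated: a small annotated
genome, a cohort of focal and reference individuals with Poisson per-site
coding depth (the simplest count model that reproduces the HIGH/MID/LOW
classes), planted gene losses (depth collapse to < 3 reads), planted
duplications (depth scaled by the extra-copy factor), planted pseudogenes
(substitutions plus deletions in a pairwise CDS alignment against the
intact ortholog), planted lineage-specific indels in per-gene protein
alignments, planted de novo genes (depth collapse in the reference
individuals, guaranteed expression), and per-tissue DE tables with a
controlled cross-tissue effect structure.

Losses are simulated as depth collapse rather than sequence removal
because the callers consume depth only. A fixed ``rng_seed`` fully
determines every output, byte for byte.
"""

from __future__ import annotations

import io
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io_formats
from .models import FOCAL, REFERENCE, DepthTrack, GeneModel

FOCAL_SPECIES = "hadal_snailfish"

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = np.array(
    [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in _STOPS]
)
_STOP_CODONS = np.array(sorted(_STOPS))
_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

_TISSUES = ("eye", "stomach", "heart", "liver", "muscle", "skin")

# rng stream tags, one per operation, so ops are independently deterministic
_TAG_GENOME, _TAG_DEPTH, _TAG_MSA, _TAG_EXPR, _TAG_CDSALN = 0, 1, 2, 3, 4


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class SimulationConfig:
    """The stated world for one fixture bundle.

    ``planted_duplications`` maps gene id to the depth scale factor (the
    focal copy count divided by the reference copy count; fractional values
    such as 14/3 model extra copies of a multi-copy family).
    ``planted_pseudogenes`` maps gene id to
    (number of substitutions, tuple of deletion lengths in nt).
    ``planted_indels`` maps gene id to a signed residue count: positive for
    a focal-specific insertion, negative for a deletion.
    """

    n_genes: int = 200
    gene_length_range: tuple[int, int] = (300, 1500)  # CDS bp, start..stop
    n_focal_individuals: int = 8
    n_reference_individuals: int = 5
    mean_depth: float | tuple[float, ...] = 30.0
    planted_losses: frozenset = frozenset()
    planted_duplications: Mapping[str, float] = field(default_factory=dict)
    planted_pseudogenes: Mapping[str, tuple[int, tuple[int, ...]]] = field(default_factory=dict)
    planted_indels: Mapping[str, int] = field(default_factory=dict)
    planted_denovo: frozenset = frozenset()
    n_msa_species: int = 10
    msa_background_substitution: float = 0.0
    n_tissues: int = 6
    planted_consistent_up: frozenset = frozenset()
    background_de_rate: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be positive")
        lo, hi = self.gene_length_range
        if lo < 9 or hi < lo:
            raise ConfigurationError("gene_length_range must satisfy 9 <= lo <= hi")
        if self.n_focal_individuals < 1:
            raise ConfigurationError("n_focal_individuals must be positive")
        if self.n_reference_individuals < 1:
            raise ConfigurationError("n_reference_individuals must be positive")
        means = self.mean_depths()
        if any(m <= 0 for m in means):
            raise ConfigurationError("mean_depth must be positive")
        if self.n_tissues < 2:
            raise ConfigurationError("n_tissues must be at least 2")
        if not 0 <= self.background_de_rate <= 1:
            raise ConfigurationError("background_de_rate must be in [0, 1]")
        if not 0 <= self.msa_background_substitution < 1:
            raise ConfigurationError("msa_background_substitution must be in [0, 1)")
        if self.n_msa_species < 4:
            raise ConfigurationError("n_msa_species must be at least 4")
        valid = set(self.gene_ids())
        planted_sets = {
            "planted_losses": set(self.planted_losses),
            "planted_duplications": set(self.planted_duplications),
            "planted_pseudogenes": set(self.planted_pseudogenes),
            "planted_indels": set(self.planted_indels),
            "planted_denovo": set(self.planted_denovo),
            "planted_consistent_up": set(self.planted_consistent_up),
        }
        seen: dict[str, str] = {}
        for field_name, ids in planted_sets.items():
            unknown = ids - valid
            if unknown:
                raise ConfigurationError(
                    f"{field_name}: gene ids not in the simulated annotation: {sorted(unknown)}"
                )
            for gid in ids:
                if gid in seen:
                    raise ConfigurationError(
                        f"{field_name}: gene {gid} already planted in {seen[gid]}"
                    )
                seen[gid] = field_name
        for gid, factor in self.planted_duplications.items():
            if factor <= 1:
                raise ConfigurationError(
                    f"planted_duplications: factor for {gid} must exceed 1"
                )
        for gid, delta in self.planted_indels.items():
            if delta == 0:
                raise ConfigurationError(f"planted_indels: zero-length indel for {gid}")

    def gene_ids(self) -> list[str]:
        return [f"g{i + 1:04d}" for i in range(self.n_genes)]

    def individuals(self) -> list[tuple[str, str]]:
        focal = [(f"HS{i + 1:02d}", FOCAL) for i in range(self.n_focal_individuals)]
        ref = [(f"TS{i + 1:02d}", REFERENCE) for i in range(self.n_reference_individuals)]
        return focal + ref

    def mean_depths(self) -> list[float]:
        n = self.n_focal_individuals + self.n_reference_individuals
        if isinstance(self.mean_depth, (int, float)):
            return [float(self.mean_depth)] * n
        means = [float(m) for m in self.mean_depth]
        if len(means) != n:
            raise ConfigurationError(
                f"mean_depth: expected {n} per-individual values, got {len(means)}"
            )
        return means

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "gene_length_range": list(self.gene_length_range),
            "n_focal_individuals": self.n_focal_individuals,
            "n_reference_individuals": self.n_reference_individuals,
            "mean_depth": self.mean_depth
            if isinstance(self.mean_depth, (int, float))
            else list(self.mean_depth),
            "planted_losses": sorted(self.planted_losses),
            "planted_duplications": dict(sorted(self.planted_duplications.items())),
            "planted_pseudogenes": {
                g: [n, list(dels)] for g, (n, dels) in sorted(self.planted_pseudogenes.items())
            },
            "planted_indels": dict(sorted(self.planted_indels.items())),
            "planted_denovo": sorted(self.planted_denovo),
            "n_msa_species": self.n_msa_species,
            "msa_background_substitution": self.msa_background_substitution,
            "n_tissues": self.n_tissues,
            "planted_consistent_up": sorted(self.planted_consistent_up),
            "background_de_rate": self.background_de_rate,
            "rng_seed": self.rng_seed,
        }


def _rng(cfg: SimulationConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, tag]))


# ---------------------------------------------------------------------------
# Truth table


def build_truth(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for gid in cfg.gene_ids():
        if gid in cfg.planted_losses:
            event, param = "loss", ""
        elif gid in cfg.planted_duplications:
            event, param = "duplication", f"factor={cfg.planted_duplications[gid]}"
        elif gid in cfg.planted_pseudogenes:
            n_sub, dels = cfg.planted_pseudogenes[gid]
            event = "pseudogene"
            param = f"substitutions={n_sub};deletions={','.join(map(str, dels)) or '-'}"
        elif gid in cfg.planted_indels:
            event, param = "indel_region", f"indel={cfg.planted_indels[gid]}"
        elif gid in cfg.planted_denovo:
            event, param = "de_novo", ""
        elif gid in cfg.planted_consistent_up:
            event, param = "consistent_up", ""
        else:
            event, param = "neutral", ""
        rows.append((gid, event, param))
    return pd.DataFrame(rows, columns=["gene_id", "event", "param"])


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


# ---------------------------------------------------------------------------
# Genome + annotation


@dataclass
class AnnotatedGenome:
    genome: dict[str, str]
    genes: list[GeneModel]
    cds: dict[str, str]  # spliced, strand-corrected CDS per gene
    truth: pd.DataFrame

    def fasta(self) -> str:
        return io_formats.fasta_string(self.genome)

    def gff3(self) -> str:
        return io_formats.gff3_string(
            self.genes, {c: len(s) for c, s in self.genome.items()}
        )


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(rng.choice(_NONSTOP_CODONS, size=n_codons - 2))
    return "ATG" + body + str(rng.choice(_STOP_CODONS))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def simulate_genome_annotation(cfg: SimulationConfig) -> AnnotatedGenome:
    """One contig of spaced genes, each a complete ATG..stop ORF.

    Genes have 1-3 CDS exons separated by short introns and a random
    strand. Minus-strand genes are stored reverse-complemented in the
    contig; their CDS intervals remain in ascending genome order.
    Planted de novo genes get compositionally skewed sequence so they
    share no k-mers with the rest of the genome (no outgroup homology).
    """
    rng = _rng(cfg, _TAG_GENOME)
    lo, hi = cfg.gene_length_range
    contig = "chr1"
    parts: list[str] = []
    genes: list[GeneModel] = []
    cds_map: dict[str, str] = {}
    cursor = 0

    def emit(seq: str) -> None:
        nonlocal cursor
        parts.append(seq)
        cursor += len(seq)

    emit(_random_seq(rng, int(rng.integers(100, 300))))
    for gid in cfg.gene_ids():
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        if gid in cfg.planted_denovo:
            # AT-rich ORF: virtually no 11-mer overlap with GC-balanced outgroups
            weights = np.array([0.45, 0.05, 0.05, 0.45])
            body_codons = []
            while len(body_codons) < n_codons - 2:
                codon = "".join(rng.choice(_BASES, size=3, p=weights))
                if codon not in _STOPS:
                    body_codons.append(codon)
            cds = "ATG" + "".join(body_codons) + str(rng.choice(_STOP_CODONS))
        else:
            cds = _random_cds(rng, n_codons)
        n_exons = int(rng.integers(1, 4))
        cds_len = len(cds)
        if n_exons > 1:
            cuts = np.sort(rng.choice(np.arange(1, cds_len), size=n_exons - 1, replace=False))
            bounds = [0, *cuts.tolist(), cds_len]
        else:
            bounds = [0, cds_len]
        exons = [cds[a:b] for a, b in zip(bounds, bounds[1:])]
        introns = [_random_seq(rng, int(rng.integers(50, 150))) for _ in range(n_exons - 1)]
        genic = exons[0]
        local_intervals = [(0, len(exons[0]))]
        for exon, intron in zip(exons[1:], introns):
            genic += intron
            start = len(genic)
            genic += exon
            local_intervals.append((start, len(genic)))
        strand = "+" if rng.random() < 0.5 else "-"
        glen = len(genic)
        if strand == "-":
            genic = _revcomp(genic)
            intervals = sorted((glen - e, glen - s) for s, e in local_intervals)
        else:
            intervals = local_intervals
        gene_start = cursor
        emit(genic)
        emit(_random_seq(rng, int(rng.integers(100, 300))))
        genes.append(
            GeneModel(
                gene_id=gid,
                contig=contig,
                strand=strand,
                cds_intervals=tuple((gene_start + s, gene_start + e) for s, e in intervals),
            )
        )
        cds_map[gid] = cds
    genome = {contig: "".join(parts)}
    return AnnotatedGenome(genome=genome, genes=genes, cds=cds_map, truth=build_truth(cfg))


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Depth cohort


def simulate_depth_cohort(
    cfg: SimulationConfig, annotated: AnnotatedGenome
) -> list[DepthTrack]:
    """Per-individual coding-site depth tracks with planted events.

    Neutral sites: Poisson around the individual's mean depth. Planted
    losses: focal depth collapsed to Poisson(0.3) capped at 2 (always LOW).
    Planted duplications: focal depth Poisson(mean x factor). Planted
    de novo genes: the same collapse, but in the reference individuals.
    """
    rng = _rng(cfg, _TAG_DEPTH)
    contig_len = {c: len(s) for c, s in annotated.genome.items()}
    tracks: list[DepthTrack] = []
    for (ind, label), mean in zip(cfg.individuals(), cfg.mean_depths()):
        arrays = {c: np.zeros(n, dtype=np.int64) for c, n in contig_len.items()}
        for gene in annotated.genes:
            pos = gene.coding_positions()
            gid = gene.gene_id
            if label == FOCAL and gid in cfg.planted_losses:
                depths = np.minimum(rng.poisson(0.3, size=pos.size), 2)
            elif label == FOCAL and gid in cfg.planted_duplications:
                depths = rng.poisson(mean * cfg.planted_duplications[gid], size=pos.size)
            elif label == REFERENCE and gid in cfg.planted_denovo:
                depths = np.minimum(rng.poisson(0.3, size=pos.size), 2)
            else:
                depths = rng.poisson(mean, size=pos.size)
            arrays[gene.contig][pos] = depths
        tracks.append(DepthTrack(individual_id=ind, species_label=label, depths=arrays))
    return tracks


# ---------------------------------------------------------------------------
# Protein alignments with planted indels

_CODON_TABLE = {}


def _translate(cds: str) -> str:
    from Bio.Seq import Seq

    protein = str(Seq(cds).translate())
    return protein[:-1] if protein.endswith("*") else protein


def simulate_protein_msa(
    cfg: SimulationConfig, annotated: AnnotatedGenome
) -> dict[str, dict[str, str]]:
    """Per-gene protein alignments: focal row plus identical background rows.

    The focal row carries the planted indel (if any); every row accrues
    background substitutions at ``msa_background_substitution`` per
    residue, sparing the planted region and its 5-column flanks so the
    planted signal stays embedded in conserved context.
    """
    rng = _rng(cfg, _TAG_MSA)
    species = [FOCAL_SPECIES] + [f"species_{i + 1:02d}" for i in range(cfg.n_msa_species)]
    flank = 5
    out: dict[str, dict[str, str]] = {}
    for gene in annotated.genes:
        gid = gene.gene_id
        base = _translate(annotated.cds[gid])
        L = len(base)
        delta = cfg.planted_indels.get(gid, 0)
        rows: dict[str, list[str]] = {}
        protected = np.zeros(L, dtype=bool)
        if delta < 0:  # focal-specific deletion
            dlen = -delta
            p = int(rng.integers(flank + 1, max(flank + 2, L - flank - dlen)))
            for name in species:
                row = list(base)
                if name == FOCAL_SPECIES:
                    row[p : p + dlen] = ["-"] * dlen
                rows[name] = row
            protected[max(0, p - flank) : min(L, p + dlen + flank)] = True
        elif delta > 0:  # focal-specific insertion
            ins = "".join(rng.choice(_AMINO_ACIDS, size=delta))
            p = int(rng.integers(flank + 1, max(flank + 2, L - flank)))
            for name in species:
                row = list(base[:p]) + (
                    list(ins) if name == FOCAL_SPECIES else ["-"] * delta
                ) + list(base[p:])
                rows[name] = row
            prot = np.zeros(L + delta, dtype=bool)
            prot[max(0, p - flank) : min(L + delta, p + delta + flank)] = True
            protected = prot
        else:
            for name in species:
                rows[name] = list(base)
        if cfg.msa_background_substitution > 0:
            width = len(next(iter(rows.values())))
            for name in species:
                row = rows[name]
                hit = rng.random(width) < cfg.msa_background_substitution
                for col in np.nonzero(hit)[0]:
                    if protected[col] or row[col] == "-":
                        continue
                    choices = [aa for aa in _AMINO_ACIDS if aa != row[col]]
                    row[col] = choices[int(rng.integers(len(choices)))]
        out[gid] = {name: "".join(row) for name, row in rows.items()}
    return out


# ---------------------------------------------------------------------------
# CDS alignments with planted pseudogene disruptions


def simulate_cds_alignments(
    cfg: SimulationConfig, annotated: AnnotatedGenome
) -> dict[str, tuple[str, str]]:
    """Pairwise (intact ortholog row, focal row) CDS alignments per gene.

    For planted pseudogenes the focal row carries the recipe's random
    substitutions and contiguous deletions (as gap runs). If a recipe has
    no frameshifting deletion, one substitution is spent turning a middle
    codon into TAA so the planted gene is disrupted by construction.
    """
    rng = _rng(cfg, _TAG_CDSALN)
    out: dict[str, tuple[str, str]] = {}
    for gene in annotated.genes:
        gid = gene.gene_id
        cds = annotated.cds[gid]
        if gid not in cfg.planted_pseudogenes:
            out[gid] = (cds, cds)
            continue
        n_sub, deletions = cfg.planted_pseudogenes[gid]
        focal = list(cds)
        n_codons = len(cds) // 3
        # deletions as gap runs, placed away from the ends and each other
        taken: list[tuple[int, int]] = []
        for dlen in deletions:
            for _ in range(100):
                start = int(rng.integers(3, max(4, len(cds) - 3 - dlen)))
                if all(start + dlen <= s or start >= e for s, e in taken):
                    taken.append((start, start + dlen))
                    break
        for start, end in taken:
            for pos in range(start, end):
                focal[pos] = "-"
        # without a frameshifting deletion, spend 3 substitutions turning an
        # undeleted middle codon into TAA so the gene is disrupted for sure
        forced: tuple[int, int] | None = None
        if not any((e - s) % 3 for s, e in taken):
            for mid in range(n_codons // 2, n_codons - 1):
                span = (3 * mid, 3 * mid + 3)
                if all(span[1] <= s or span[0] >= e for s, e in taken):
                    focal[span[0] : span[1]] = list("TAA")
                    forced = span
                    n_sub = max(0, n_sub - 3)
                    break
        # substitutions avoid start/stop codons, deletions, the forced stop
        blocked = taken + ([forced] if forced else [])
        interior = np.array(
            [
                p
                for p in range(3, len(cds) - 3)
                if all(not (s <= p < e) for s, e in blocked)
            ]
        )
        n_sub = min(n_sub, interior.size)
        for pos in rng.choice(interior, size=n_sub, replace=False):
            current = focal[pos]
            others = [b for b in "ACGT" if b != current]
            focal[pos] = others[int(rng.integers(3))]
        out[gid] = (cds, "".join(focal))
    return out


# ---------------------------------------------------------------------------
# Expression tables


def tissue_names(cfg: SimulationConfig) -> list[str]:
    names = list(_TISSUES[: cfg.n_tissues])
    while len(names) < cfg.n_tissues:
        names.append(f"tissue_{len(names) + 1:02d}")
    return names


def simulate_expression_tables(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], set[str]]:
    """(TPM matrix, per-tissue DE tables, truth set of consistent-up genes).

    Planted consistent genes satisfy log2FC >= 1 and adjusted p < 0.05 in
    every tissue; background genes are DE independently per tissue at
    ``background_de_rate`` (direction split evenly). Planted de novo genes
    are guaranteed a tissue with TPM >= 1; planted losses get TPM 0.
    """
    rng = _rng(cfg, _TAG_EXPR)
    genes = cfg.gene_ids()
    tissues = tissue_names(cfg)
    n = len(genes)

    tpm = pd.DataFrame(
        rng.lognormal(mean=1.0, sigma=1.5, size=(n, len(tissues))),
        index=pd.Index(genes, name="gene_id"),
        columns=tissues,
    )
    for gid in cfg.planted_losses:
        tpm.loc[gid] = 0.0
    for gid in cfg.planted_denovo:
        hot = tissues[int(rng.integers(len(tissues)))]
        tpm.loc[gid, hot] = float(rng.uniform(5, 50))

    de_tables: dict[str, pd.DataFrame] = {}
    planted = set(cfg.planted_consistent_up)
    for tissue in tissues:
        lfc = rng.uniform(-0.95, 0.95, size=n)
        padj = rng.uniform(0.051, 1.0, size=n)
        de_mask = rng.random(n) < cfg.background_de_rate
        signs = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        lfc = np.where(de_mask, signs * rng.uniform(1.0, 4.0, size=n), lfc)
        padj = np.where(de_mask, rng.uniform(1e-8, 0.049, size=n), padj)
        for gid in planted:
            i = genes.index(gid)
            lfc[i] = float(rng.uniform(1.0, 4.0))
            padj[i] = float(rng.uniform(1e-8, 0.04))
        de_tables[tissue] = pd.DataFrame(
            {"gene_id": genes, "log2fc": lfc, "padj": padj}
        )
    return tpm, de_tables, planted


# ---------------------------------------------------------------------------
# Fixture bundle on disk


def write_fixture_bundle(cfg: SimulationConfig, outdir) -> dict[str, object]:
    """Write the full fixture bundle and return the in-memory objects.

    Layout: genome.fa, annotation.gff3, truth.tsv, config.json,
    depth/<individual>.depth.tsv, msa/<gene>.afa, cds_aln/<gene>.afa,
    expression/tpm.tsv and expression/de_<tissue>.tsv.
    Identical config -> byte-identical bundle.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    annotated = simulate_genome_annotation(cfg)
    with open(os.path.join(outdir, "genome.fa"), "w") as fh:
        fh.write(annotated.fasta())
    with open(os.path.join(outdir, "annotation.gff3"), "w") as fh:
        fh.write(annotated.gff3())
    write_truth(annotated.truth, os.path.join(outdir, "truth.tsv"))
    with open(os.path.join(outdir, "config.json"), "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    tracks = simulate_depth_cohort(cfg, annotated)
    depth_dir = os.path.join(outdir, "depth")
    os.makedirs(depth_dir, exist_ok=True)
    positions = {
        contig: np.concatenate(
            [g.coding_positions() for g in annotated.genes if g.contig == contig]
        )
        for contig in annotated.genome
    }
    for track in tracks:
        path = os.path.join(depth_dir, f"{track.individual_id}.depth.tsv")
        with open(path, "w") as fh:
            fh.write(io_formats.depth_table_string(track, positions))

    msa = simulate_protein_msa(cfg, annotated)
    msa_dir = os.path.join(outdir, "msa")
    os.makedirs(msa_dir, exist_ok=True)
    for gid, rows in msa.items():
        with open(os.path.join(msa_dir, f"{gid}.afa"), "w") as fh:
            fh.write(io_formats.fasta_string(rows))

    cds_aln = simulate_cds_alignments(cfg, annotated)
    aln_dir = os.path.join(outdir, "cds_aln")
    os.makedirs(aln_dir, exist_ok=True)
    for gid, (orth, focal) in cds_aln.items():
        with open(os.path.join(aln_dir, f"{gid}.afa"), "w") as fh:
            fh.write(io_formats.fasta_string({"ortholog": orth, FOCAL_SPECIES: focal}))

    tpm, de_tables, consistent = simulate_expression_tables(cfg)
    expr_dir = os.path.join(outdir, "expression")
    os.makedirs(expr_dir, exist_ok=True)
    tpm.to_csv(os.path.join(expr_dir, "tpm.tsv"), sep="\t")
    for tissue, table in de_tables.items():
        table.to_csv(os.path.join(expr_dir, f"de_{tissue}.tsv"), sep="\t", index=False)

    return {
        "annotated": annotated,
        "tracks": tracks,
        "msa": msa,
        "cds_alignments": cds_aln,
        "tpm": tpm,
        "de_tables": de_tables,
        "consistent_truth": consistent,
    }
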