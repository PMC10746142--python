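"""Readers and writers for every external format the pipeline touches.

GFF3 is 1-based inclusive on disk and converted to the internal 0-based
half-open convention here, at the boundary, and nowhere else. All text
inputs may be gzip-compressed (detected by ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import hashlib
import io
import json
import logging
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import DepthTrack, GeneModel

logger = logging.getLogger(__name__)

GAP = "-"


def _open_text(path, mode: str = "rt"):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Sequences keyed by record id, uppercased."""
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def fasta_string(sequences: Mapping[str, str], width: int = 60) -> str:
    out = io.StringIO()
    for name, seq in sequences.items():
        out.write(f">{name}\n")
        for i in range(0, len(seq), width):
            out.write(seq[i : i + width] + "\n")
    return out.getvalue()


def extract_cds(genome: Mapping[str, str], gene: GeneModel) -> str:
    """Spliced CDS of a gene; reverse-complemented for minus-strand genes."""
    contig_seq = genome[gene.contig]
    spliced = "".join(contig_seq[s:e] for s, e in gene.cds_intervals)
    if gene.strand == "-":
        spliced = str(Seq(spliced).reverse_complement())
    return spliced


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path) -> list[GeneModel]:
    """Parse gene models from GFF3, collapsing multi-transcript genes.

    When a gene has several mRNAs the transcript with the longest summed
    CDS is kept. Overlapping CDS segments within one transcript are a
    validation error.
    """
    db = gffutils.create_db(
        os.fspath(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        best: tuple[int, list[tuple[int, int]]] | None = None
        for mrna in db.children(gene, featuretype="mRNA"):
            intervals = sorted(
                (cds.start - 1, cds.end) for cds in db.children(mrna, featuretype="CDS")
            )
            if not intervals:
                continue
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"{gene.id}/{mrna.id}: overlapping CDS intervals "
                        f"({s1 + 1}-{e1}) and ({s2 + 1}-{e2})"
                    )
            total = sum(e - s for s, e in intervals)
            if best is None or total > best[0]:
                best = (total, intervals)
        if best is None:
            continue
        genes.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                strand=gene.strand,
                cds_intervals=tuple(best[1]),
            )
        )
    return genes


def write_gff3(genes: Sequence[GeneModel], path, contig_lengths: Mapping[str, int] | None = None) -> None:
    with open(path, "w") as handle:
        handle.write(gff3_string(genes, contig_lengths))


def gff3_string(genes: Sequence[GeneModel], contig_lengths: Mapping[str, int] | None = None) -> str:
    """Serialize gene models as GFF3 (gene -> mRNA -> CDS), 1-based inclusive."""
    out = io.StringIO()
    out.write("##gff-version 3\n")
    if contig_lengths:
        for contig, length in contig_lengths.items():
            out.write(f"##sequence-region {contig} 1 {length}\n")
    for gene in genes:
        start, end = gene.span
        g, m = gene.gene_id, f"{gene.gene_id}.t1"
        out.write(
            f"{gene.contig}\thadalcomp\tgene\t{start + 1}\t{end}\t.\t{gene.strand}\t.\tID={g}\n"
        )
        out.write(
            f"{gene.contig}\thadalcomp\tmRNA\t{start + 1}\t{end}\t.\t{gene.strand}\t.\tID={m};Parent={g}\n"
        )
        intervals = list(gene.cds_intervals)
        # phase bookkeeping follows transcription order
        order = intervals if gene.strand == "+" else intervals[::-1]
        phases: dict[tuple[int, int], int] = {}
        acc = 0
        for s, e in order:
            phases[(s, e)] = (3 - acc % 3) % 3
            acc += e - s
        for s, e in intervals:
            out.write(
                f"{gene.contig}\thadalcomp\tCDS\t{s + 1}\t{e}\t.\t{gene.strand}\t{phases[(s, e)]}\t"
                f"ID={m}.cds;Parent={m}\n"
            )
    return out.getvalue()


# ---------------------------------------------------------------------------
# Depth tables (3-column TSV: contig, 1-based position, depth)


def read_depth_table(path, individual_id: str, species_label: str) -> DepthTrack:
    """Read a per-site depth table into a dense :class:`DepthTrack`.

    Malformed lines raise with the offending line number; negative depths
    are a validation error. An empty file yields an empty track (warning).
    """
    per_contig_pos: dict[str, list[int]] = {}
    per_contig_depth: dict[str, list[int]] = {}
    n_lines = 0
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            contig, pos_s, depth_s = parts
            try:
                pos = int(pos_s)
                depth = int(depth_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer position/depth") from exc
            if pos < 1:
                raise ValueError(f"{path}:{lineno}: position must be >= 1 (1-based)")
            if depth < 0:
                raise ValueError(f"{path}:{lineno}: negative depth {depth}")
            per_contig_pos.setdefault(contig, []).append(pos - 1)
            per_contig_depth.setdefault(contig, []).append(depth)
            n_lines += 1
    if n_lines == 0:
        logger.warning("depth table %s is empty", path)
    depths: dict[str, np.ndarray] = {}
    for contig, positions in per_contig_pos.items():
        pos_arr = np.asarray(positions, dtype=np.int64)
        arr = np.zeros(int(pos_arr.max()) + 1, dtype=np.int64)
        arr[pos_arr] = np.asarray(per_contig_depth[contig], dtype=np.int64)
        depths[contig] = arr
    return DepthTrack(individual_id=individual_id, species_label=species_label, depths=depths)


def write_depth_table(track: DepthTrack, path) -> None:
    """Write non-zero depth sites as a 3-column TSV (1-based positions)."""
    with _open_text(path, "wt") as handle:
        for contig in sorted(track.depths):
            arr = track.depths[contig]
            (nz,) = np.nonzero(arr)
            for pos in nz:
                handle.write(f"{contig}\t{pos + 1}\t{arr[pos]}\n")


def depth_table_string(track: DepthTrack, positions: Mapping[str, np.ndarray]) -> str:
    """Serialize given positions (including zeros) as depth TSV text."""
    out = io.StringIO()
    for contig in sorted(positions):
        pos = np.sort(np.asarray(positions[contig]))
        vals = track.depth_at(contig, pos)
        for p, d in zip(pos, vals):
            out.write(f"{contig}\t{p + 1}\t{d}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Alignments


@dataclass(frozen=True)
class MafRow:
    src: str  # species.contig
    start: int  # 0-based on the + strand of src when strand == '+'
    size: int
    strand: str
    src_size: int
    text: str

    @property
    def species(self) -> str:
        return self.src.split(".", 1)[0]

    @property
    def contig(self) -> str:
        parts = self.src.split(".", 1)
        return parts[1] if len(parts) > 1 else parts[0]


@dataclass(frozen=True)
class MafBlock:
    block_id: int
    rows: tuple[MafRow, ...]

    def row_for(self, species: str) -> MafRow | None:
        for row in self.rows:
            if row.species == species:
                return row
        return None


def read_maf(path) -> list[MafBlock]:
    """Parse MAF alignment blocks (species-prefixed ``src`` names)."""
    blocks: list[MafBlock] = []
    with _open_text(path) as handle:
        for i, msa in enumerate(AlignIO.parse(handle, "maf")):
            rows = []
            width = msa.get_alignment_length()
            for rec in msa:
                text = str(rec.seq).upper()
                if len(text) != width:
                    raise ValueError(f"MAF block {i}: row length mismatch for {rec.id}")
                ann = rec.annotations
                rows.append(
                    MafRow(
                        src=rec.id,
                        start=int(ann["start"]),
                        size=int(ann["size"]),
                        strand="+" if ann["strand"] in (1, "+") else "-",
                        src_size=int(ann["srcSize"]),
                        text=text,
                    )
                )
            blocks.append(MafBlock(block_id=i, rows=tuple(rows)))
    return blocks


def read_aligned_fasta(path) -> dict[str, str]:
    """Aligned FASTA: equal-length gapped rows keyed by sequence name."""
    rows = read_fasta(path)
    widths = {len(seq) for seq in rows.values()}
    if len(widths) > 1:
        raise ValueError(f"{path}: ragged alignment (row lengths {sorted(widths)})")
    return rows


def write_aligned_fasta(rows: Mapping[str, str], path) -> None:
    widths = {len(seq) for seq in rows.values()}
    if len(widths) > 1:
        raise ValueError("refusing to write ragged alignment")
    write_fasta(rows, path)


# ---------------------------------------------------------------------------
# Tabular results

PROVENANCE_PREFIX = "# hadalcomp"


def provenance_comment(seed: int | None = None, config_hash: str | None = None) -> str:
    from . import __version__

    parts = [f"{PROVENANCE_PREFIX} v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    return " ".join(parts)


def write_table(df: pd.DataFrame, path, seed: int | None = None, config_hash: str | None = None) -> None:
    """TSV with a leading provenance comment and a header line."""
    with _open_text(path, "wt") as handle:
        handle.write(provenance_comment(seed, config_hash) + "\n")
        df.to_csv(handle, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_tpm_table(path) -> pd.DataFrame:
    """Gene x tissue TPM matrix; first column is the gene id."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.set_index(df.columns[0])


def read_de_table(path) -> pd.DataFrame:
    """Per-tissue DE results with columns gene_id, log2fc, padj."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "log2fc", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing DE columns {sorted(missing)}")
    return df


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
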