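"""End-to-end orchestration over a simulated cohort.

``run_pipeline`` generates a fixture world from a single
:class:`~hadalcomp.simulate.SimulationConfig`, runs every caller in
dependency order, compares calls against the planted truth, and returns a
:class:`RunReport`. All stage outputs are pure functions of config + seed,
so identical configs reproduce identical reports.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import (
    copynum_caller,
    denovo_caller,
    depth_profiles,
    expression_consistency,
    indel_finder,
    io_formats,
    presence_caller,
    pseudogene_caller,
    simulate,
)
from .models import FOCAL, REFERENCE
from .simulate import FOCAL_SPECIES, SimulationConfig

ALL_STAGES = ("loss", "duplication", "pseudogene", "de_novo", "indel", "expression")


@dataclass
class StageMetrics:
    n_calls: int
    precision: float
    recall: float


@dataclass
class RunReport:
    seed: int
    config_hash: str
    parameters: dict
    counts: dict[str, int]
    metrics: dict[str, StageMetrics]
    tables: dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "parameters": self.parameters,
            "counts": self.counts,
            "metrics": {
                k: dataclasses.asdict(v) for k, v in sorted(self.metrics.items())
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _prf(called: set[str], truth: set[str]) -> StageMetrics:
    tp = len(called & truth)
    precision = tp / len(called) if called else 1.0
    recall = tp / len(truth) if truth else 1.0
    return StageMetrics(n_calls=len(called), precision=precision, recall=recall)


def run_pipeline(
    cfg: SimulationConfig,
    stages: Sequence[str] = ALL_STAGES,
    min_sls_fraction: float = presence_caller.DEFAULT_MIN_SLS_FRACTION,
    min_hcs_fraction: float = copynum_caller.DEFAULT_MIN_HCS_FRACTION,
    hcs_ratio: float = copynum_caller.DEFAULT_RATIO,
    deletion_depth: int = denovo_caller.DEFAULT_DELETION_DEPTH,
    n_permutations: int = 1000,
) -> RunReport:
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    params = {
        "min_sls_fraction": min_sls_fraction,
        "min_hcs_fraction": min_hcs_fraction,
        "hcs_ratio": hcs_ratio,
        "deletion_depth": deletion_depth,
        "n_permutations": n_permutations,
        "config": cfg.to_dict(),
    }
    chash = io_formats.config_hash(params)
    annotated = simulate.simulate_genome_annotation(cfg)
    tracks = simulate.simulate_depth_cohort(cfg, annotated)

    counts: dict[str, int] = {}
    metrics: dict[str, StageMetrics] = {}
    tables: dict[str, pd.DataFrame] = {"truth": annotated.truth}
    truth_by_event = {
        event: set(annotated.truth.loc[annotated.truth["event"] == event, "gene_id"])
        for event in annotated.truth["event"].unique()
    }

    # loss/duplication run against the reference-lineage annotation; a
    # focal-specific (de novo) gene has no locus there to be tested at
    ref_genes = [g for g in annotated.genes if g.gene_id not in cfg.planted_denovo]

    if "loss" in stages:
        matrix = depth_profiles.classify_sites(tracks, ref_genes)
        sls = presence_caller.call_sls(matrix)
        losses = presence_caller.call_gene_losses(sls, matrix, min_sls_fraction)
        called = {c.gene_id for c in losses if c.status == "candidate_loss"}
        counts["loss"] = len(called)
        metrics["loss"] = _prf(called, truth_by_event.get("loss", set()))
        tables["loss"] = presence_caller.losses_table(losses)

    if "duplication" in stages:
        comparisons = copynum_caller.call_hcs(tracks, ref_genes, ratio=hcs_ratio)
        dups = copynum_caller.call_duplications(comparisons, ref_genes, min_hcs_fraction)
        called = {c.gene_id for c in dups if c.status == "candidate_duplication"}
        counts["duplication"] = len(called)
        metrics["duplication"] = _prf(called, truth_by_event.get("duplication", set()))
        tables["duplication"] = copynum_caller.duplications_table(dups)

    if "pseudogene" in stages:
        cds_aln = simulate.simulate_cds_alignments(cfg, annotated)
        reports = [
            pseudogene_caller.detect_disruptions(gid, orth, focal)
            for gid, (orth, focal) in sorted(cds_aln.items())
        ]
        called = {r.gene_id for r in reports if r.verdict == "pseudogene_candidate"}
        counts["pseudogene"] = len(called)
        metrics["pseudogene"] = _prf(called, truth_by_event.get("pseudogene", set()))
        tables["pseudogene"] = pseudogene_caller.disruption_table(reports)

    tpm = de_tables = consistent_truth = None
    if "de_novo" in stages or "expression" in stages:
        tpm, de_tables, consistent_truth = simulate.simulate_expression_tables(cfg)

    if "de_novo" in stages:
        # the reference lineage carries every gene except the de novo ones
        outgroup = {
            "reference_lineage": "".join(
                annotated.cds[g.gene_id]
                for g in annotated.genes
                if g.gene_id not in cfg.planted_denovo
            )
        }
        reference_tracks = [t for t in tracks if t.species_label == REFERENCE]
        calls = denovo_caller.screen_de_novo(
            annotated.genes,
            reference_tracks,
            annotated.cds,
            outgroup,
            tpm,
            deletion_depth=deletion_depth,
        )
        called = {c.gene_id for c in calls if c.status == "candidate"}
        counts["de_novo"] = len(called)
        metrics["de_novo"] = _prf(called, truth_by_event.get("de_novo", set()))
        tables["de_novo"] = denovo_caller.de_novo_table(calls)

    if "indel" in stages:
        msa = simulate.simulate_protein_msa(cfg, annotated)
        regions = []
        for gid in sorted(msa):
            regions.extend(
                indel_finder.find_lineage_specific_regions(gid, msa[gid], FOCAL_SPECIES)
            )
        called = {r.gene_id for r in regions}
        counts["indel"] = len(called)
        metrics["indel"] = _prf(called, truth_by_event.get("indel_region", set()))
        tables["indel"] = indel_finder.regions_table(regions)

    if "expression" in stages:
        indicators = {
            tissue: expression_consistency.call_de(table)
            for tissue, table in de_tables.items()
        }
        consistent = expression_consistency.cross_tissue_consistent_genes(indicators, "up")
        matrix = expression_consistency.indicator_matrix(indicators)
        result = expression_consistency.independence_permutation_test(
            matrix, "up", n_permutations=n_permutations, seed=cfg.rng_seed
        )
        counts["expression"] = len(consistent)
        metrics["expression"] = _prf(set(consistent), consistent_truth)
        tables["expression"] = pd.DataFrame({"gene_id": consistent})
        params["independence_test"] = {
            "statistic": result.statistic,
            "p_value": result.p_value,
        }

    return RunReport(
        seed=cfg.rng_seed,
        config_hash=chash,
        parameters=params,
        counts=counts,
        metrics=metrics,
        tables=tables,
    )
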