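"""End-to-end orchestration: simulate -> signature -> deconvolve -> predict -> interpret.

A run executes the three reference modes (tiic+pbmc, tiic, pbmc) on one
shared Monte Carlo split list, so mode comparisons are paired by
construction, and writes every intermediate artifact plus a JSON manifest
(seeds, stage wall-clock, counts) into the run directory.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io
from .dmc import (
    REMap,
    call_dmcs,
    categorize_signature_dmcs,
    enrich_go,
    genes_for_cpgs,
    map_cpgs_to_res,
    marker_hypomethylation_test,
)
from .deconvolution import deconvolve_cohort
from .preprocess import intersect_universe
from .recurrence import compare_approaches, monte_carlo_splits, run_combination_search
from .signature import MODES, select_signature_cpgs
from .simulate import IMMUNE_TERMS, SimulationConfig, simulate_study

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a pipeline run (YAML-serializable)."""

    out_dir: str = "run"
    n_samples: int = 114
    seed: int = 0
    modes: tuple[str, ...] = MODES
    model_kind: str = "extra_trees"
    n_repeats: int = 100
    n_estimators: int = 100
    combination_sizes: tuple[int, ...] | None = (1, 2, 3)
    fdr_threshold: float = 0.05
    min_delta_beta: float = 0.2
    max_per_class: int = 200
    dmc_p_threshold: float = 0.001
    re_window_bp: int = 1250
    clinical_fields: tuple[str, ...] = ()
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "versions": {}}
    import methylstate

    manifest["versions"]["methylstate"] = methylstate.__version__

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.time()
                log.info("stage %s ...", name)
                return self

            def __exit__(self, *exc):
                manifest["stages"].setdefault(name, {})["seconds"] = round(
                    time.time() - self.t0, 3
                )

        return _Timer()

    with stage("simulate"):
        sim_cfg = SimulationConfig(**{"seed": config.seed, **config.simulation})
        genome, atlas, bulk, clinical, truth = simulate_study(
            sim_cfg, n_samples=config.n_samples
        )
        io.write_methylome(atlas, out / "atlas")
        io.write_methylome(bulk, out / "bulk")
        io.write_clinical(clinical, out / "clinical.tsv")
        io.write_bed(genome.re_intervals, out / "res.bed")
        io.write_re_targets(genome.re_targets, out / "re_targets.tsv")
        io.write_gmt(genome.gene_sets, out / "gene_sets.gmt")
        io.write_cpg_bed(atlas.cpg_ids, out / "cpgs.bed")
        io.write_ground_truth(truth, out / "ground_truth.json")
        manifest["stages"].setdefault("simulate", {}).update(
            {"n_cpgs": genome.n_cpgs, "n_samples": config.n_samples}
        )

    with stage("preprocess"):
        atlas, bulk = intersect_universe(atlas, bulk)

    signatures = {}
    proportions = {}
    with stage("signature+deconvolve"):
        for mode in config.modes:
            sig = select_signature_cpgs(
                atlas, mode=mode, fdr_threshold=config.fdr_threshold,
                min_delta_beta=config.min_delta_beta,
                max_per_class=config.max_per_class,
            )
            io.write_signature(sig, out / f"signature.{mode.replace('+', '_')}")
            table = deconvolve_cohort(bulk, sig)
            io.write_proportions(table, out / f"proportions.{mode.replace('+', '_')}.tsv")
            signatures[mode] = sig
            proportions[mode] = table

    reports = {}
    with stage("predict"):
        labels = clinical.recurrence
        splits = monte_carlo_splits(
            len(labels), labels, n_repeats=config.n_repeats, seed=config.seed
        )
        for mode, table in proportions.items():
            from .recurrence import enumerate_combinations

            combos = enumerate_combinations(
                table.class_labels,
                sizes=list(config.combination_sizes) if config.combination_sizes else None,
            )
            report = run_combination_search(
                table, clinical, combinations=combos, splits=splits,
                clinical_fields=config.clinical_fields,
                model_kind=config.model_kind, seed=config.seed,
                n_estimators=config.n_estimators,
            )
            reports[mode] = report
            tag = mode.replace("+", "_")
            report.ranking.to_csv(out / f"ranking.{tag}.tsv", sep="\t", index=False)
        comparisons = {}
        if "tiic+pbmc" in reports:
            best = reports["tiic+pbmc"]
            best_auc = best.auc_per_split[best.best_combination()]
            for mode in config.modes:
                if mode == "tiic+pbmc" or mode not in reports:
                    continue
                other = reports[mode]
                other_auc = other.auc_per_split[other.best_combination()]
                comparisons[f"tiic+pbmc_vs_{mode}"] = {
                    "mean_auc_combined": float(np.nanmean(best_auc)),
                    f"mean_auc_{mode}": float(np.nanmean(other_auc)),
                    "mannwhitney_p": compare_approaches(best_auc, other_auc),
                }
        io.write_json(comparisons, out / "mode_comparisons.json")
        manifest["stages"].setdefault("predict", {})["comparisons"] = comparisons

    with stage("dmc+enrich"):
        re_map = REMap.from_genome(genome)
        sig = signatures.get("tiic+pbmc") or next(iter(signatures.values()))
        categories = categorize_signature_dmcs(
            sig, atlas, p_threshold=config.dmc_p_threshold
        )
        io.write_json({k: sorted(v) for k, v in categories.items()},
                      out / "signature_dmc_categories.json")
        background = genes_for_cpgs(
            map_cpgs_to_res(list(atlas.cpg_ids), re_map, window_bp=config.re_window_bp)
        )
        target = genes_for_cpgs(
            map_cpgs_to_res(sorted(categories["TIIC-PBMC"]), re_map,
                            window_bp=config.re_window_bp)
        )
        enrichment = enrich_go(target, background, genome.gene_sets,
                               restrict_to=set(IMMUNE_TERMS))
        enrichment.to_csv(out / "enrichment.tiic_pbmc.tsv", sep="\t", index=False)
        dc_dmcs = call_dmcs(atlas, "TIIC-DC", "PBMC-DC",
                            p_threshold=config.dmc_p_threshold)
        dc_dmcs.to_csv(out / "dmcs.tiic_dc_vs_pbmc_dc.tsv", sep="\t", index=False)
        markers = marker_hypomethylation_test(dc_dmcs, re_map,
                                              window_bp=config.re_window_bp)
        io.write_json([dataclasses.asdict(m) for m in markers],
                      out / "dc_marker_tests.json")
        manifest["stages"].setdefault("dmc+enrich", {}).update(
            {"dmc_category_counts": {k: len(v) for k, v in categories.items()},
             "n_dc_dmcs": int(len(dc_dmcs))}
        )

    io.write_json(manifest, out / "manifest.json")
    return manifest
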