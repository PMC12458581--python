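"""End-to-end orchestration: synthesize (or load), call, classify, report.

``run_study`` wires the stages — simulation, differential calling, aging
signature derivation, trajectory classification, regulatory mapping with
concordance, enrichment networking, and cohort signature scoring — and
writes every intermediate table plus a machine-readable JSON report.  All
randomness flows from named seeds in the config, so identical config +
seeds reproduce the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .differential import Thresholds, call_degs, call_deps
from .enrichment import build_overlap_network, ora_collection
from .exceptions import ConfigError
from .io_formats import ExpressionMatrix
from .laasp_core import classify_trajectories, derive_signature, trajectory_frame
from .regulatory_map import (
    anchors_to_frames,
    assign_peaks,
    build_anchors,
    classify_concordance,
    linked_enhancer_stats,
    promoter_windows,
)
from .signature_scoring import (
    correlation_matrix,
    severity_association,
    signature_score,
    zscore_matrix,
)
from .synthetic_data import SimulationConfig, simulate_cohort, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(exposures=("vehicle", "TBT", "BPA.hi", "TCDD"))
    )
    thresholds: Thresholds = field(default_factory=Thresholds)
    flank: int = 3000
    max_gap: int = 0
    n_perm: int = 2000
    n_random_sets: int = 30
    random_set_size: int = 50
    ora_alpha: float = 0.05
    cohort_n_samples: int = 120
    cohort_effect: float = 1.0
    severity_levels: tuple[str, ...] = ("normal", "NAFLD", "NASH", "HCC")
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        sim_raw = raw.pop("simulation", {})
        thr_raw = raw.pop("thresholds", {})
        known_sim = {f.name for f in dataclasses.fields(SimulationConfig)}
        bad = set(sim_raw) - known_sim
        if bad:
            raise ConfigError(f"unknown simulation keys: {sorted(bad)}")
        for key in ("age_groups", "exposures", "marks"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown run-config keys: {sorted(bad)}")
        if "severity_levels" in raw:
            raw["severity_levels"] = tuple(raw["severity_levels"])
        return cls(simulation=SimulationConfig(**sim_raw),
                   thresholds=Thresholds(**thr_raw), **raw)


def _sample_ids(matrix: ExpressionMatrix, **criteria) -> list[str]:
    ids = matrix.sample_ids(**criteria)
    if len(ids) < 2:
        raise ConfigError(f"fewer than 2 samples match {criteria}")
    return ids


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def run_study(config: RunConfig) -> dict[str, Any]:
    """Run every stage on a synthetic study and return the report dict."""
    sim = config.simulation
    sim.validate()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage synth: simulating study (n_genes=%d)", sim.n_genes)
    bundle = simulate_study(sim)
    if outdir:
        bundle.write_dir(outdir / "synthetic")

    matrix = bundle.expression
    ages = sim.age_groups
    young, adult = ages[0], ages[-1]
    toxicants = [e for e in sim.exposures if e != "vehicle"]

    # ---- differential expression & signatures --------------------------
    logger.info("stage differential: aging contrast %s -> %s", young, adult)
    aging_diff = call_degs(
        matrix,
        _sample_ids(matrix, age=young, exposure="vehicle"),
        _sample_ids(matrix, age=adult, exposure="vehicle"),
        config.thresholds,
    )
    laasp_sig = derive_signature(aging_diff, "aging")
    exposure_diffs: dict[str, pd.DataFrame] = {}
    exposure_sigs = {}
    for exposure in toxicants:
        diff = call_degs(
            matrix,
            _sample_ids(matrix, age=adult, exposure="vehicle"),
            _sample_ids(matrix, age=adult, exposure=exposure),
            config.thresholds,
        )
        exposure_diffs[exposure] = diff
        exposure_sigs[exposure] = derive_signature(diff, exposure)

    # ---- trajectory classification -------------------------------------
    overlap_report = {}
    for exposure in toxicants:
        calls, summary = classify_trajectories(exposure_sigs[exposure], laasp_sig)
        n_cls = summary.n_attenuated + summary.n_accelerated
        overlap_report[exposure] = {
            "n_signature": summary.n_signature,
            "n_overlap": summary.n_overlap,
            "percent_of_signature": round(summary.percent, 4),
            "n_attenuated": summary.n_attenuated,
            "n_accelerated": summary.n_accelerated,
            "attenuated_share": round(summary.n_attenuated / n_cls, 6) if n_cls else None,
        }
        if outdir:
            trajectory_frame(calls).to_csv(
                outdir / f"trajectories_{exposure}.tsv", sep="\t", index=False
            )

    # ---- regulatory map -------------------------------------------------
    logger.info("stage regmap: promoters, anchors, peaks, concordance")
    promoters = promoter_windows(bundle.annotation, flank=config.flank)
    anchors = build_anchors(bundle.enhancers, max_gap=config.max_gap)
    chip_meta = next(iter(bundle.chip.values())).samples
    young_chip = [s for s in chip_meta.index if chip_meta.loc[s, "age"] == young]
    adult_chip = [s for s in chip_meta.index if chip_meta.loc[s, "age"] == adult]
    dep_frames = []
    for mark, wc in bundle.chip.items():
        deps = call_deps(wc, young_chip, adult_chip, config.thresholds)
        deps["mark"] = mark
        dep_frames.append(deps)
    all_deps = pd.concat(dep_frames, ignore_index=True)
    assignments = assign_peaks(all_deps, promoters, anchors)
    concordance = classify_concordance(assignments, aging_diff)
    enh_stats = linked_enhancer_stats(anchors, all_deps, sorted(laasp_sig.genes))
    if outdir:
        all_deps.to_csv(outdir / "deps.tsv", sep="\t", index=False)
        assignments.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
        concordance.records.to_csv(outdir / "concordance_records.tsv", sep="\t", index=False)
        bed, links = anchors_to_frames(anchors)
        bed.to_csv(outdir / "anchors.bed", sep="\t", index=False, header=False)
        links.to_csv(outdir / "anchor_links.tsv", sep="\t", index=False)

    # ---- enrichment network ---------------------------------------------
    logger.info("stage enrich: ORA + overlap network")
    universe = set(matrix.genes)
    rng = np.random.default_rng(config.seed + 101)
    gene_list = sorted(universe)
    collection: dict[str, set[str]] = {
        "AGING_UP_TRUTH": set(bundle.truth.aging_signature().up),
        "AGING_DOWN_TRUTH": set(bundle.truth.aging_signature().down),
    }
    for i in range(config.n_random_sets):
        members = rng.choice(len(gene_list), size=config.random_set_size, replace=False)
        collection[f"RANDOM_{i:03d}"] = {gene_list[j] for j in members}
    pathway_universe = set(collection)

    enriched: dict[str, dict[str, set[str]]] = {}
    for exposure in toxicants:
        sig = exposure_sigs[exposure]
        signed: dict[str, set[str]] = {"positive": set(), "negative": set()}
        for direction, hits in (("positive", sig.up), ("negative", sig.down)):
            if not hits:
                continue
            res = ora_collection(set(hits), collection, universe)
            signed[direction] = set(res.loc[res["q_value"] < config.ora_alpha, "set_name"])
        enriched[exposure] = signed

    network_report: dict[str, Any] = {"edges": []}
    if len(toxicants) >= 2:
        network = build_overlap_network(
            enriched, universe=pathway_universe, n_perm=config.n_perm, seed=config.seed + 202
        )
        for row in network.edges.to_dict(orient="records"):
            network_report["edges"].append(
                {k: (round(v, 6) if isinstance(v, float) else v) for k, v in sorted(row.items())}
            )
        if outdir:
            network.edges.to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
            network.nodes.to_csv(outdir / "network_nodes.tsv", sep="\t", index=False)

    # ---- cohort scoring --------------------------------------------------
    logger.info("stage score: cohort simulation + signature activity")
    cohort, states = simulate_cohort(
        laasp_sig,
        n_samples=config.cohort_n_samples,
        severity_levels=list(config.severity_levels),
        effect=config.cohort_effect,
        seed=config.seed + 303,
    )
    z = zscore_matrix(cohort.values)
    vectors = [signature_score(z, laasp_sig)]
    for exposure in toxicants:
        sig = exposure_sigs[exposure]
        if sig.genes & set(z.index):
            vectors.append(signature_score(z, sig))
    corr = correlation_matrix(vectors)
    severity = severity_association(vectors[0], states, list(config.severity_levels))
    if outdir:
        corr.to_csv(outdir / "score_correlations.tsv", sep="\t")
        pd.DataFrame({v.signature_name: v.scores for v in vectors}).to_csv(
            outdir / "signature_scores.tsv", sep="\t"
        )

    report: dict[str, Any] = {
        "seed": config.seed,
        "simulation_seed": sim.seed,
        "n_genes": sim.n_genes,
        "aging_signature": {"n_up": len(laasp_sig.up), "n_down": len(laasp_sig.down)},
        "exposure_overlap": overlap_report,
        "concordance": {
            "category_counts": dict(sorted(concordance.category_counts.items())),
            "n_genes": len(concordance.categories),
            "percent_concordant": round(concordance.percent_concordant.percent, 4),
        },
        "linked_enhancers": {
            "mean_all": round(enh_stats.mean_all, 4),
            "mean_hit": round(enh_stats.mean_hit, 4),
        },
        "network": network_report,
        "scoring": {
            "correlation": {
                a: {b: round(float(corr.loc[a, b]), 6) for b in corr.columns}
                for a in corr.index
            },
            "severity_association": {
                "r": round(severity.r, 6),
                "p_value": float(severity.p_value),
                "n": severity.n,
            },
        },
    }
    if outdir:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
    return report
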