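"""Synthetic multi-omic study generator with known ground truth.

Emulates a developmental-exposure aging study on one synthetic chromosome:
negative-binomial RNA counts with planted age effects (up/down plasticity
genes), exposure effects that reverse (attenuate) or reinforce (accelerate)
a chosen fraction of the age effects, histone-mark window counts whose
planted peaks are direction-concordant with expression at a configurable
rate, an enhancer catalog with book-ended intervals and many-to-one gene
links, and a human-like cohort whose expression tracks an ordinal disease
severity.  Every planted effect is recorded so downstream stages have a
recovery target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .differential import WindowCounts
from .exceptions import ConfigError
from .io_formats import (
    ExpressionMatrix,
    GeneAnnotation,
    GenomicInterval,
    write_bed,
    write_gene_annotation,
)
from .laasp_core import GeneSignature
from .regulatory_map import DEFAULT_POLARITY

ENHANCER_WIDTH = 600
SLOT_WIDTH = 2000
PEAK_LOG2FC = 2.0  # planted mark fold change (FC = 4), strong enough to call
WINDOW_BASE_RATE = 20.0  # expected fragments per window per sample


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the emulated design: two age groups (weaning and young
    adulthood), vehicle plus one toxicant arm, a minority of genes with a
    planted aging trajectory (more down than up), strong planted fold
    changes that clear the FDR<0.05 / FC>1.5 rule, ~8 catalog enhancers
    linked per gene, and mark changes concordant with expression 80% of
    the time.
    """

    n_genes: int = 2000
    samples_per_group: int = 5
    age_groups: tuple[str, ...] = ("wk3", "mo5")
    exposures: tuple[str, ...] = ("vehicle", "TBT")
    frac_age_up: float = 0.05
    frac_age_down: float = 0.15
    age_log2fc: float = 1.5
    exposure_log2fc: float = 1.5
    n_exposure_genes: int = 300
    frac_attenuated: float = 0.5
    frac_accelerated: float = 0.2
    nb_mean_log: float = 5.0
    nb_dispersion: float = 0.1
    n_enhancers_per_gene: int = 8
    adjacency_rate: float = 0.2
    concordance_rate: float = 0.8
    marks: tuple[str, ...] = ("H3K27ac", "H3K27me3")
    chrom: str = "chrS"
    gene_spacing: int = 10_000
    window_size: int = 500
    promoter_flank: int = 3000
    sex: str = "M"
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_age_up", "frac_age_down", "frac_attenuated",
                     "frac_accelerated", "adjacency_rate", "concordance_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.frac_age_up + self.frac_age_down > 1:
            raise ConfigError("frac_age_up + frac_age_down must be <= 1")
        if self.frac_attenuated + self.frac_accelerated > 1:
            raise ConfigError("frac_attenuated + frac_accelerated must be <= 1")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if self.samples_per_group < 2:
            raise ConfigError("samples_per_group must be >= 2 (tests need replicates)")
        if len(self.age_groups) < 2:
            raise ConfigError("need >= 2 ordered age groups")
        if "vehicle" not in self.exposures:
            raise ConfigError("exposures must include 'vehicle'")
        if self.n_genes < 1 or self.n_exposure_genes < 0:
            raise ConfigError("gene counts must be positive")
        unknown_marks = set(self.marks) - set(DEFAULT_POLARITY)
        if unknown_marks:
            raise ConfigError(f"marks without known polarity: {sorted(unknown_marks)}")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Planted effects: per-gene directions/classes and per-peak targets."""

    genes: pd.DataFrame  # index gene_id; aging_direction + per-exposure direction/class
    peaks: pd.DataFrame  # mark, chrom, start, end, direction, target_gene, region_class, concordant
    exposures: tuple[str, ...]

    def trajectory_class(self, exposure: str) -> pd.Series:
        return self.genes[f"{exposure}_class"]

    def aging_signature(self, name: str = "aging.truth") -> GeneSignature:
        up = frozenset(self.genes.index[self.genes["aging_direction"] == "up"])
        down = frozenset(self.genes.index[self.genes["aging_direction"] == "down"])
        return GeneSignature(name=name, up=up, down=down)

    def exposure_signature(self, exposure: str) -> GeneSignature:
        col = self.genes[f"{exposure}_direction"]
        return GeneSignature(
            name=f"{exposure}.truth",
            up=frozenset(self.genes.index[col == "up"]),
            down=frozenset(self.genes.index[col == "down"]),
        )

    def to_tsv(self, genes_path: str | Path, peaks_path: str | Path) -> None:
        self.genes.rename_axis("gene_id").to_csv(genes_path, sep="\t")
        self.peaks.to_csv(peaks_path, sep="\t", index=False)


@dataclass
class StudyBundle:
    config: SimulationConfig
    expression: ExpressionMatrix
    chip: dict[str, WindowCounts]
    annotation: list[GeneAnnotation]
    enhancers: list[tuple[GenomicInterval, frozenset[str]]]
    truth: GroundTruth

    def write_dir(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.expression.to_tsv(out / "counts.tsv", out / "samples.tsv")
        write_gene_annotation(self.annotation, out / "annotation.tsv")
        write_bed(
            [
                GenomicInterval(iv.chrom, iv.start, iv.end, name=f"enh{i:05d}")
                for i, (iv, _) in enumerate(self.enhancers)
            ],
            out / "enhancers.bed",
        )
        link_rows = [
            (f"enh{i:05d}", iv.chrom, iv.start, iv.end, gene)
            for i, (iv, genes) in enumerate(self.enhancers)
            for gene in sorted(genes)
        ]
        pd.DataFrame(
            link_rows, columns=["enhancer_id", "chrom", "start", "end", "gene_id"]
        ).to_csv(out / "enhancer_links.tsv", sep="\t", index=False)
        for mark, wc in self.chip.items():
            wc.counts.rename_axis("window_start").to_csv(out / f"chip_{mark}.tsv", sep="\t")
            if wc.samples is not None:
                wc.samples.rename_axis("sample_id").to_csv(out / "chip_samples.tsv", sep="\t")
        self.truth.to_tsv(out / "truth_genes.tsv", out / "truth_peaks.tsv")


def _gene_layout(config: SimulationConfig) -> list[GeneAnnotation]:
    half = config.gene_spacing // 2
    return [
        GeneAnnotation(
            gene_id=f"gene{i:05d}",
            chrom=config.chrom,
            tss=i * config.gene_spacing + half,
            strand="+" if i % 2 == 0 else "-",
        )
        for i in range(config.n_genes)
    ]


def simulate_enhancer_catalog(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[tuple[GenomicInterval, frozenset[str]]]:
    """Enhancer intervals with gene links, placed in non-overlapping slots.

    Per-gene link counts are Poisson(n_enhancers_per_gene); each enhancer
    links 1-3 genes; with probability ``adjacency_rate`` an enhancer unit
    is a book-ended pair (two abutting intervals sharing a slot) so anchor
    merging is exercised.  Slots guarantee that distinct units never touch.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    genes = [g.gene_id for g in _gene_layout(config)]
    link_counts = rng.poisson(config.n_enhancers_per_gene, size=len(genes))
    stubs = np.repeat(np.arange(len(genes)), link_counts)
    rng.shuffle(stubs)

    region_start = config.n_genes * config.gene_spacing + 10_000
    enhancers: list[tuple[GenomicInterval, frozenset[str]]] = []
    pos, slot = 0, 0

    def take_enhancer(start: int) -> None:
        nonlocal pos
        k = min(int(rng.integers(1, 4)), len(stubs) - pos)
        linked = frozenset(genes[i] for i in stubs[pos : pos + k])
        pos += k
        enhancers.append(
            (GenomicInterval(config.chrom, start, start + ENHANCER_WIDTH), linked)
        )

    while pos < len(stubs):
        slot_start = region_start + slot * SLOT_WIDTH
        pair = rng.random() < config.adjacency_rate
        take_enhancer(slot_start)
        if pair and pos < len(stubs):
            take_enhancer(slot_start + ENHANCER_WIDTH)
        slot += 1
    return enhancers


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2 (gamma-Poisson)."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def simulate_study(config: SimulationConfig) -> StudyBundle:
    """Generate the full study bundle; identical config + seed is reproducible."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    annotation = _gene_layout(config)
    gene_ids = [g.gene_id for g in annotation]
    n = config.n_genes

    # ---- planted aging directions --------------------------------------
    n_up = int(round(config.frac_age_up * n))
    n_down = int(round(config.frac_age_down * n))
    order = rng.permutation(n)
    aging_sign = np.zeros(n)
    aging_sign[order[:n_up]] = 1.0
    aging_sign[order[n_up : n_up + n_down]] = -1.0
    aging_dir = np.where(aging_sign > 0, "up", np.where(aging_sign < 0, "down", "none"))

    # ---- planted exposure effects --------------------------------------
    toxicants = [e for e in config.exposures if e != "vehicle"]
    laasp_idx = np.flatnonzero(aging_sign != 0)
    null_idx = np.flatnonzero(aging_sign == 0)
    n_exp = config.n_exposure_genes
    n_att = int(round(config.frac_attenuated * n_exp))
    n_acc = int(round(config.frac_accelerated * n_exp))
    n_only = n_exp - n_att - n_acc
    if n_att + n_acc > len(laasp_idx):
        raise ConfigError(
            f"exposure draws need {n_att + n_acc} plasticity genes, only {len(laasp_idx)} planted"
        )
    if n_only > len(null_idx):
        raise ConfigError("not enough null genes for exposure-only effects")

    exposure_sign = {e: np.zeros(n) for e in toxicants}
    truth_cols: dict[str, np.ndarray] = {}
    for exposure in toxicants:
        chosen = rng.choice(laasp_idx, size=n_att + n_acc, replace=False)
        att_idx, acc_idx = chosen[:n_att], chosen[n_att:]
        only_idx = rng.choice(null_idx, size=n_only, replace=False)
        sign = exposure_sign[exposure]
        sign[att_idx] = -aging_sign[att_idx]
        sign[acc_idx] = aging_sign[acc_idx]
        sign[only_idx] = rng.choice([-1.0, 1.0], size=n_only)
        cls = np.full(n, "null", dtype=object)
        cls[att_idx] = "attenuated"
        cls[acc_idx] = "accelerated"
        cls[only_idx] = "exposure_only"
        direction = np.where(sign > 0, "up", np.where(sign < 0, "down", "none"))
        truth_cols[f"{exposure}_direction"] = direction
        truth_cols[f"{exposure}_class"] = cls

    # ---- RNA counts ----------------------------------------------------
    base_mean = rng.lognormal(mean=config.nb_mean_log, sigma=1.0, size=n)
    n_ages = len(config.age_groups)
    sample_rows = []
    mu_cols = []
    for age_idx, age in enumerate(config.age_groups):
        age_frac = age_idx / (n_ages - 1)
        adult = age_idx == n_ages - 1
        for exposure in config.exposures:
            for rep in range(config.samples_per_group):
                sample_rows.append(
                    {
                        "sample_id": f"{age}_{exposure}_r{rep + 1}",
                        "age": age,
                        "exposure": exposure,
                        "sex": config.sex,
                    }
                )
                mu = base_mean * 2.0 ** (config.age_log2fc * age_frac * aging_sign)
                if adult and exposure != "vehicle":
                    mu = mu * 2.0 ** (config.exposure_log2fc * exposure_sign[exposure])
                mu_cols.append(mu * rng.lognormal(0.0, 0.2))
        # library factor drawn per sample above (scalar lognormal)
    mu_matrix = np.column_stack(mu_cols)
    counts = _nb_draw(rng, mu_matrix, config.nb_dispersion)
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    expression = ExpressionMatrix(
        values=pd.DataFrame(counts, index=gene_ids, columns=samples.index),
        samples=samples,
    )

    # ---- enhancer catalog ----------------------------------------------
    enhancers = simulate_enhancer_catalog(config, rng=rng)
    gene_to_enh: dict[str, list[int]] = {g: [] for g in gene_ids}
    for i, (_, linked) in enumerate(enhancers):
        for g in sorted(linked):  # sorted: frozenset order is hash-dependent
            gene_to_enh[g].append(i)

    # ---- ChIP window counts with planted peaks -------------------------
    region_start = config.n_genes * config.gene_spacing + 10_000
    n_slots = 0
    if enhancers:
        last_end = max(iv.end for iv, _ in enhancers)
        n_slots = (last_end - region_start) // SLOT_WIDTH + 1
    chrom_len = region_start + n_slots * SLOT_WIDTH + 10_000
    w = config.window_size
    n_windows = chrom_len // w
    starts = np.arange(n_windows) * w

    chip_samples = pd.DataFrame(
        [
            {"sample_id": f"chip_{age}_r{r + 1}", "age": age}
            for age in (config.age_groups[0], config.age_groups[-1])
            for r in range(config.samples_per_group)
        ]
    ).set_index("sample_id")
    young_cols = [s for s in chip_samples.index if chip_samples.loc[s, "age"] == config.age_groups[0]]
    adult_cols = [s for s in chip_samples.index if s not in young_cols]

    tss_by_gene = {g.gene_id: g.tss for g in annotation}
    chip: dict[str, WindowCounts] = {}
    peak_rows = []
    for mark in config.marks:
        active = DEFAULT_POLARITY[mark] == "active"
        # per-sample rate matrix, planted peaks modulate adult or young rates
        rate = np.full((n_windows, len(chip_samples)), WINDOW_BASE_RATE)
        adult_mask = np.array([s in adult_cols for s in chip_samples.index])
        for gi in laasp_idx:
            gene = gene_ids[gi]
            expr_dir = "up" if aging_sign[gi] > 0 else "down"
            u = rng.random()
            regions: list[str] = []
            if u < 0.4 or not gene_to_enh[gene]:
                regions = ["promoter"]
            elif u < 0.8:
                regions = ["enhancer"]
            else:
                regions = ["promoter", "enhancer"]
            for region in regions:
                concordant = bool(rng.random() < config.concordance_rate)
                mark_matches_expr = concordant if active else not concordant
                peak_dir = expr_dir if mark_matches_expr else ("down" if expr_dir == "up" else "up")
                if region == "promoter":
                    tss = tss_by_gene[gene]
                    lo, hi = max(0, tss - 750), tss + 750
                else:
                    iv, _ = enhancers[int(rng.choice(gene_to_enh[gene]))]
                    lo, hi = iv.start, iv.end
                w_lo, w_hi = lo // w, (hi - 1) // w + 1
                factor = 2.0 ** PEAK_LOG2FC
                cols = adult_mask if peak_dir == "up" else ~adult_mask
                rate[w_lo:w_hi][:, cols] *= factor
                peak_rows.append(
                    {
                        "mark": mark,
                        "chrom": config.chrom,
                        "start": int(w_lo * w),
                        "end": int(w_hi * w),
                        "direction": peak_dir,
                        "target_gene": gene,
                        "region_class": region,
                        "concordant": concordant,
                    }
                )
        lib = rng.lognormal(0.0, 0.1, size=len(chip_samples))
        counts_mark = rng.poisson(rate * lib[None, :])
        chip[mark] = WindowCounts(
            chrom=config.chrom,
            window_size=w,
            counts=pd.DataFrame(counts_mark, index=starts, columns=chip_samples.index),
            samples=chip_samples,
        )

    genes_df = pd.DataFrame({"aging_direction": aging_dir, **truth_cols}, index=gene_ids)
    truth = GroundTruth(
        genes=genes_df,
        peaks=pd.DataFrame(
            peak_rows,
            columns=["mark", "chrom", "start", "end", "direction",
                     "target_gene", "region_class", "concordant"],
        ),
        exposures=tuple(toxicants),
    )
    return StudyBundle(
        config=config,
        expression=expression,
        chip=chip,
        annotation=annotation,
        enhancers=enhancers,
        truth=truth,
    )


def simulate_cohort(
    signature: GeneSignature,
    n_samples: int,
    severity_levels: Sequence[str],
    effect: float,
    seed: int,
    n_background: int = 200,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Human-like cohort whose expression tracks an ordinal severity.

    Samples are assigned to severity levels in a balanced round-robin;
    expression of the signature's up genes rises (and down genes falls)
    linearly with the 0-based severity index, scaled by ``effect``, on top
    of unit-variance Gaussian noise.  ``n_background`` null genes are added
    so z-scoring has a realistic backdrop.
    """
    if len(signature) == 0:
        raise ConfigError("signature must be non-empty")
    if len(severity_levels) < 2:
        raise ConfigError("need >= 2 severity levels")
    rng = np.random.default_rng(seed)
    k = len(severity_levels)
    sev_idx = np.arange(n_samples) % k
    states = pd.Series(
        [severity_levels[i] for i in sev_idx],
        index=[f"s{i + 1:04d}" for i in range(n_samples)],
        name="state",
    )
    up, down = sorted(signature.up), sorted(signature.down)
    bg = [f"BG{i + 1:05d}" for i in range(n_background)]
    direction = np.concatenate(
        [np.ones(len(up)), -np.ones(len(down)), np.zeros(len(bg))]
    )
    genes = up + down + bg
    noise = rng.normal(0.0, 1.0, size=(len(genes), n_samples))
    values = noise + effect * direction[:, None] * sev_idx[None, :]
    samples = pd.DataFrame({"state": states})
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=states.index), samples=samples
    )
    return matrix, states
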