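"""Differential expression and differential peak calling stand-ins.

These are *declared* simplified substitutes for the heavyweight tools a
production study would run (an exact-test NB framework for genes; a
sliding-window scan for peaks).  They apply the same significance rule —
BH-adjusted FDR < alpha and linear fold change beyond min_fc — so every
downstream classification behaves identically, and their operating
characteristics (type-I control, power on planted effects) are verified by
simulation in the test suite.

Genes: CPM normalization, Welch t-test on log2(CPM + 0.5).
Peaks: library-size-normalized G-test on pooled window counts, BH across
windows, and merging of adjacent same-direction significant windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import jensenshannon
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, GenomicInterval

logger = logging.getLogger(__name__)

DIFF_COLUMNS = ["feature_id", "log2fc", "fold_change_linear", "p_value", "q_value", "direction"]


@dataclass(frozen=True)
class Thresholds:
    """Significance rule: FDR < alpha and linear fold change beyond min_fc."""

    alpha: float = 0.05
    min_fc: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.min_fc <= 1:
            raise ValueError(f"min_fc must be > 1, got {self.min_fc}")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def assign_directions(q: np.ndarray, fold_change: np.ndarray, thresholds: Thresholds) -> np.ndarray:
    """up iff q < alpha and FC > min_fc; down iff q < alpha and FC < 1/min_fc; else ns."""
    direction = np.full(q.shape, "ns", dtype=object)
    sig = q < thresholds.alpha
    direction[sig & (fold_change > thresholds.min_fc)] = "up"
    direction[sig & (fold_change < 1.0 / thresholds.min_fc)] = "down"
    return direction


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalization by column totals."""
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        raise ValueError("sample with zero total counts cannot be CPM-normalized")
    return counts.div(libsize, axis=1) * 1e6


def call_degs(
    matrix: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Differential genes for group_b vs group_a.

    Per gene: Welch two-sample t-test on log2(CPM + 0.5); BH FDR across
    genes; linear fold change = (mean CPM_b + 0.5) / (mean CPM_a + 0.5)
    (pseudo-count keeps the ratio finite and exactly inverts under a group
    swap).  Genes with zero counts everywhere are retained with p = 1.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    counts = matrix.values
    norm = cpm(counts[list(group_a) + list(group_b)])
    a = norm[list(group_a)].to_numpy(dtype=float)
    b = norm[list(group_b)].to_numpy(dtype=float)
    log_a, log_b = np.log2(a + 0.5), np.log2(b + 0.5)

    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(log_b, log_a, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    all_zero = (counts[list(group_a) + list(group_b)].sum(axis=1) == 0).to_numpy()
    p[all_zero] = 1.0

    fc = (b.mean(axis=1) + 0.5) / (a.mean(axis=1) + 0.5)
    q = bh_fdr(p)
    direction = assign_directions(q, fc, thresholds)
    direction[all_zero] = "ns"
    out = pd.DataFrame(
        {
            "feature_id": counts.index,
            "log2fc": np.log2(fc),
            "fold_change_linear": fc,
            "p_value": p,
            "q_value": q,
            "direction": direction,
        }
    )
    n_sig = int((out["direction"] != "ns").sum())
    logger.info("call_degs: %d/%d significant", n_sig, len(out))
    return out


@dataclass
class WindowCounts:
    """Tiled, non-overlapping window counts for one mark on one chromosome."""

    chrom: str
    window_size: int
    counts: pd.DataFrame  # index = window start (bp), columns = sample ids
    samples: pd.DataFrame | None = None  # optional metadata indexed by sample id

    def __post_init__(self) -> None:
        starts = np.asarray(self.counts.index, dtype=int)
        if len(starts) > 1 and np.any(np.diff(starts) < self.window_size):
            raise ValueError("windows must tile without overlap")


def call_deps(
    window_counts: WindowCounts,
    group_a: list[str],
    group_b: list[str],
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Differential peaks for group_b vs group_a from tiled window counts.

    Per window the pooled group counts are compared with a G-test against
    expectations proportional to pooled library sizes; BH FDR across tested
    windows; runs of strictly adjacent significant windows with the same
    direction merge into one peak interval carrying the extreme log2fc and
    the minimum q.  Windows empty in both groups are skipped.
    """
    counts = window_counts.counts
    w = window_counts.window_size
    a = counts[list(group_a)].sum(axis=1).to_numpy(dtype=float)
    b = counts[list(group_b)].sum(axis=1).to_numpy(dtype=float)
    lib_a = counts[list(group_a)].to_numpy().sum()
    lib_b = counts[list(group_b)].to_numpy().sum()
    if lib_a == 0 or lib_b == 0:
        raise ValueError("a group has zero total counts")

    tested = (a + b) > 0
    n_skipped = int((~tested).sum())
    if n_skipped:
        logger.info("call_deps: skipped %d empty windows", n_skipped)

    total = a + b
    frac_a = lib_a / (lib_a + lib_b)
    ea, eb = total * frac_a, total * (1 - frac_a)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = 2.0 * (
            np.where(a > 0, a * np.log(a / ea), 0.0)
            + np.where(b > 0, b * np.log(b / eb), 0.0)
        )
    p = stats.chi2.sf(g[tested], df=1)
    q = bh_fdr(p)
    fc = ((b[tested] + 0.5) / lib_b) / ((a[tested] + 0.5) / lib_a)
    direction = assign_directions(q, fc, thresholds)

    starts = np.asarray(counts.index, dtype=int)[tested]
    log2fc = np.log2(fc)

    # merge runs of strictly adjacent same-direction significant windows
    rows = []
    run: list[int] = []
    def flush(run_idx: list[int]) -> None:
        if not run_idx:
            return
        s, e = starts[run_idx[0]], starts[run_idx[-1]] + w
        lfc = log2fc[run_idx]
        extreme = lfc[np.argmax(np.abs(lfc))]
        rows.append(
            {
                "feature_id": f"{window_counts.chrom}:{s}-{e}",
                "chrom": window_counts.chrom,
                "start": int(s),
                "end": int(e),
                "log2fc": float(extreme),
                "fold_change_linear": float(2.0 ** extreme),
                "p_value": float(p[run_idx].min()),
                "q_value": float(q[run_idx].min()),
                "direction": direction[run_idx[0]],
                "n_windows": len(run_idx),
            }
        )

    for i in range(len(starts)):
        if direction[i] == "ns":
            flush(run)
            run = []
            continue
        if run and (starts[i] - starts[run[-1]] == w) and direction[i] == direction[run[-1]]:
            run.append(i)
        else:
            flush(run)
            run = [i]
    flush(run)

    out = pd.DataFrame(
        rows,
        columns=["feature_id", "chrom", "start", "end", "log2fc",
                 "fold_change_linear", "p_value", "q_value", "direction", "n_windows"],
    )
    logger.info("call_deps: %d peaks from %d tested windows", len(out), int(tested.sum()))
    return out


def deps_to_intervals(deps: pd.DataFrame) -> list[GenomicInterval]:
    """DEP table rows as BED-style intervals (score = -log10 q)."""
    out = []
    for r in deps.itertuples(index=False):
        score = float(-np.log10(max(r.q_value, 1e-300)))
        out.append(
            GenomicInterval(r.chrom, int(r.start), int(r.end),
                            strand=".", name=r.direction, score=score)
        )
    return out


def jsd_qc(signal_histogram, ideal_input_histogram) -> float:
    """Jensen-Shannon *distance* (sqrt of the base-2 divergence) in [0, 1].

    The standard coverage-histogram QC statistic: 0 for identical binned
    coverage fractions, 1 for disjoint support.
    """
    h1 = np.asarray(signal_histogram, dtype=float)
    h2 = np.asarray(ideal_input_histogram, dtype=float)
    if h1.shape != h2.shape:
        raise ValueError("histograms must have the same bin count")
    if np.any(h1 < 0) or np.any(h2 < 0):
        raise ValueError("histogram bins must be non-negative")
    for h in (h1, h2):
        if abs(h.sum() - 1.0) > 1e-9:
            raise ValueError("histograms must each sum to 1")
    return float(jensenshannon(h1, h2, base=2))
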