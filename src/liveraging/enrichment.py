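"""Gene-set enrichment: hypergeometric ORA, preranked GSEA, and the
permutation null for pathway-set overlap between exposures.

The overlap test asks whether two exposures' significantly enriched pathway
lists share more members than chance: the permutation null redraws each
list uniformly from the pathway universe, the resulting overlap counts are
fitted with a normal distribution, and the upper-tail survival of the
observed overlap is the p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_fdr


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OraResult:
    p_value: float
    fold_enrichment: float
    k: int  # hits in set
    n: int  # hits
    K: int  # set size within universe
    N: int  # universe size


def ora(hits: Set[str], gene_set: Set[str], universe: Set[str]) -> OraResult:
    """Upper-tail hypergeometric over-representation test, P(X >= k)."""
    if not universe:
        raise ValueError("universe must be non-empty")
    hits = set(hits)
    if not hits <= set(universe):
        raise ValueError("hits must be a subset of the universe")
    K = len(set(gene_set) & set(universe))
    N, n = len(universe), len(hits)
    k = len(hits & set(gene_set))
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    expected = n * K / N
    fe = (k / expected) if expected > 0 else float("nan")
    return OraResult(p_value=min(p, 1.0), fold_enrichment=fe, k=k, n=n, K=K, N=N)


def ora_collection(
    hits: Set[str], collection: Mapping[str, Set[str]], universe: Set[str]
) -> pd.DataFrame:
    """ORA over a gene-set collection with BH adjustment across sets."""
    rows = []
    for name in sorted(collection):
        r = ora(hits, collection[name], universe)
        rows.append((name, r.k, r.K, r.fold_enrichment, r.p_value))
    df = pd.DataFrame(rows, columns=["set_name", "k", "K", "fold_enrichment", "p_value"])
    df["q_value"] = bh_fdr(df["p_value"].to_numpy()) if len(df) else []
    return df


# ---------------------------------------------------------------------------
# Preranked GSEA
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentRecord:
    set_name: str
    es: float
    nes: float
    p_value: float
    direction: str  # "positive" | "negative"
    core_genes: frozenset[str]
    q_value: float | None = None
    n_perm: int = 0


def _running_sum(scores: np.ndarray, hit: np.ndarray, weight: float) -> np.ndarray:
    """Weighted KS-style running sum over a ranked list."""
    n = len(scores)
    n_hit = int(hit.sum())
    steps = np.zeros(n)
    w = np.abs(scores[hit]) ** weight
    denom = w.sum()
    if denom > 0:
        steps[hit] = w / denom
    if n > n_hit:
        steps[~hit] = -1.0 / (n - n_hit)
    return np.cumsum(steps)


def _es_from_running(running: np.ndarray) -> tuple[float, int]:
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), idx


def gsea_preranked(
    ranked: Sequence[str],
    scores: Sequence[float],
    gene_set: Set[str],
    set_name: str = "set",
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentRecord:
    """Preranked GSEA for one gene set.

    ES is the signed maximal deviation of the running sum (hit increments
    proportional to |score|^weight, miss decrements 1/(N-K)).  The null is
    built from ``n_perm`` random same-size gene sets; NES divides ES by the
    mean |null ES| of matching sign; p is the one-sided empirical tail with
    the +1 correction.  Core (leading-edge) genes run up to the extremum.
    Ties in scores keep the caller's input order (stable ranking).
    """
    genes = list(ranked)
    s = np.asarray(scores, dtype=float)
    if len(genes) != len(s):
        raise ValueError("ranked genes and scores must have equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    hit = np.array([g in gene_set for g in genes])
    K = int(hit.sum())
    if K == 0:
        raise ValueError(f"gene set {set_name!r} is disjoint from the ranked list")
    n = len(genes)
    if K == n:
        # degenerate: no misses; the running sum ends at +1 with no
        # depletion signal, define ES = 0
        return EnrichmentRecord(set_name, 0.0, 0.0, 1.0, "positive", frozenset(genes), n_perm=0)

    running = _running_sum(s, hit, weight)
    es, idx = _es_from_running(running)

    rng = np.random.default_rng(seed)
    null_es = np.empty(n_perm)
    positions = np.arange(n)
    for i in range(n_perm):
        null_hit = np.zeros(n, dtype=bool)
        null_hit[rng.choice(positions, size=K, replace=False)] = True
        null_es[i], _ = _es_from_running(_running_sum(s, null_hit, weight))

    same_sign = null_es >= 0 if es >= 0 else null_es < 0
    n_same = int(same_sign.sum())
    if n_same:
        mean_abs = float(np.abs(null_es[same_sign]).mean())
        nes = es / mean_abs if mean_abs > 0 else 0.0
        p = (1 + int((np.abs(null_es[same_sign]) >= abs(es)).sum())) / (1 + n_same)
    else:
        nes, p = 0.0, 1.0 / (1 + n_perm)

    if es >= 0:
        core = frozenset(g for g, h in zip(genes[: idx + 1], hit[: idx + 1]) if h)
        direction = "positive"
    else:
        core = frozenset(g for g, h in zip(genes[idx:], hit[idx:]) if h)
        direction = "negative"
    return EnrichmentRecord(set_name, es, float(nes), float(p), direction, core, n_perm=n_perm)


def gsea_collection(
    ranked: Sequence[str],
    scores: Sequence[float],
    collection: Mapping[str, Set[str]],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    fdr_method: str = "bh",
) -> list[EnrichmentRecord]:
    """Preranked GSEA over a collection with an FDR across sets.

    ``fdr_method="bh"`` adjusts the empirical p-values; ``"nes"`` is the
    classic NES-based empirical FDR (pooled sign-matched null NES).
    """
    records = []
    null_pool_pos: list[float] = []
    null_pool_neg: list[float] = []
    for i, name in enumerate(sorted(collection)):
        rec = gsea_preranked(
            ranked, scores, collection[name], set_name=name,
            weight=weight, n_perm=n_perm, seed=seed + i,
        )
        records.append(rec)
    if fdr_method == "bh":
        q = bh_fdr([r.p_value for r in records])
        for r, qv in zip(records, q):
            r.q_value = float(qv)
    elif fdr_method == "nes":
        # empirical: rebuild a pooled null of NES-like values by rescaling
        rng = np.random.default_rng(seed + 10_000)
        s = np.asarray(scores, dtype=float)
        n = len(s)
        for rec in records:
            K = len(set(collection[rec.set_name]) & set(ranked))
            null = np.empty(max(n_perm // 4, 50))
            for j in range(len(null)):
                hit = np.zeros(n, dtype=bool)
                hit[rng.choice(n, size=K, replace=False)] = True
                null[j], _ = _es_from_running(_running_sum(s, hit, weight))
            (null_pool_pos if rec.es >= 0 else null_pool_neg).extend(null[null >= 0] if rec.es >= 0 else null[null < 0])
        obs_nes = np.array([r.nes for r in records])
        for rec in records:
            pool = np.array(null_pool_pos if rec.nes >= 0 else null_pool_neg)
            if len(pool) == 0:
                rec.q_value = 1.0
                continue
            pool_mean = np.abs(pool).mean() or 1.0
            pool_nes = pool / pool_mean
            tail_null = float((np.abs(pool_nes) >= abs(rec.nes)).mean())
            same = obs_nes[np.sign(obs_nes) == np.sign(rec.nes or 1.0)]
            tail_obs = float((np.abs(same) >= abs(rec.nes)).mean()) or 1.0 / max(len(same), 1)
            rec.q_value = float(min(1.0, tail_null / tail_obs))
    else:
        raise ValueError(f"unknown fdr_method {fdr_method!r}")
    return records


# ---------------------------------------------------------------------------
# Pathway-overlap permutation test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapTestResult:
    observed: int
    perm_mean: float
    perm_sd: float
    z: float
    p_value: float
    n_perm: int
    degenerate: bool = False


def pathway_overlap_test(
    sig_a: Set[str],
    sig_b: Set[str],
    universe: Set[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> OverlapTestResult:
    """Normal-fit permutation test for over-sharing of enriched pathways.

    Each permutation conceptually redraws |sig_a| and |sig_b| pathways
    uniformly without replacement from the universe and records the
    intersection size; conditionally on either draw that count is exactly
    hypergeometric, so the permutation is realized as hypergeometric
    sampling (identical distribution, far faster).  A normal distribution
    is fitted to the permuted overlaps and the upper-tail survival of the
    observed overlap is returned.
    """
    universe = set(universe)
    sig_a, sig_b = set(sig_a), set(sig_b)
    if not (sig_a <= universe and sig_b <= universe):
        raise ValueError("signature pathway sets must be subsets of the universe")
    N, na, nb = len(universe), len(sig_a), len(sig_b)
    observed = len(sig_a & sig_b)
    rng = np.random.default_rng(seed)
    perms = rng.hypergeometric(ngood=na, nbad=N - na, nsample=nb, size=n_perm) if N else np.zeros(n_perm)
    mean, sd = float(perms.mean()), float(perms.std(ddof=1))
    if sd == 0:
        p = 1.0 if observed <= mean else float(np.nextafter(0, 1))
        return OverlapTestResult(observed, mean, 0.0, float("inf") if observed > mean else 0.0,
                                 p, n_perm, degenerate=True)
    z = (observed - mean) / sd
    return OverlapTestResult(observed, mean, sd, float(z), float(stats.norm.sf(z)), n_perm)


# ---------------------------------------------------------------------------
# Overlap network
# ---------------------------------------------------------------------------

@dataclass
class OverlapNetwork:
    nodes: pd.DataFrame  # exposure, direction, n_pathways
    edges: pd.DataFrame  # exposure_a, exposure_b, direction, weight [, z, p_value]
    tests: dict[tuple[str, str, str], OverlapTestResult] = field(default_factory=dict)


def build_overlap_network(
    enriched: Mapping[str, Mapping[str, Set[str]]],
    universe: Set[str] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> OverlapNetwork:
    """Network of shared same-direction enriched pathways between exposures.

    ``enriched`` maps exposure -> {"positive": set, "negative": set}.
    Node size is the exposure's pathway count per direction; an undirected
    edge appears for every pair sharing >= 1 pathway in the same direction.
    When a universe is supplied every pair (including weight-0 pairs) also
    gets an overlap permutation test.
    """
    if len(enriched) < 2:
        raise ValueError("need >= 2 exposures")
    node_rows, edge_rows = [], []
    tests: dict[tuple[str, str, str], OverlapTestResult] = {}
    exposures = sorted(enriched)
    pair_index = 0
    for direction in ("positive", "negative"):
        for exp in exposures:
            node_rows.append((exp, direction, len(enriched[exp].get(direction, set()))))
        for a, b in combinations(exposures, 2):
            pair_index += 1
            set_a = set(enriched[a].get(direction, set()))
            set_b = set(enriched[b].get(direction, set()))
            weight = len(set_a & set_b)
            row = {"exposure_a": a, "exposure_b": b, "direction": direction, "weight": weight}
            if universe is not None:
                res = pathway_overlap_test(set_a, set_b, universe, n_perm=n_perm,
                                           seed=seed + pair_index)
                tests[(a, b, direction)] = res
                row["z"] = res.z
                row["p_value"] = res.p_value
            if weight >= 1 or universe is not None:
                edge_rows.append(row)
    nodes = pd.DataFrame(node_rows, columns=["exposure", "direction", "n_pathways"])
    edges = pd.DataFrame(edge_rows)
    return OverlapNetwork(nodes=nodes, edges=edges, tests=tests)
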