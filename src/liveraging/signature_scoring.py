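"""Summed z-score signature activity over cohort transcriptomes.

Each gene is z-scored across samples; a sample's signature score adds the
z-scores of the signature's up genes and subtracts those of its down genes.
Scores are correlated between signatures (Pearson) or against an ordinal
disease-severity encoding.  Mouse signatures are carried into human cohorts
through a homolog map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .laasp_core import GeneSignature

logger = logging.getLogger(__name__)


@dataclass
class ScoreVector:
    scores: pd.Series  # sample_id -> score
    signature_name: str
    n_genes_used: int


@dataclass(frozen=True)
class AssociationResult:
    r: float
    p_value: float
    n: int
    degenerate: bool = False


def zscore_matrix(expression: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores across samples (population sd, divisor n).

    Zero-variance genes are set to z = 0 everywhere (and counted in the
    log); fewer than 2 samples is an error.
    """
    if expression.shape[1] < 2:
        raise ValueError("z-scoring requires >= 2 samples")
    values = expression.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        logger.info("zscore_matrix: %d zero-variance genes set to z=0", int(flat.sum()))
    sd[sd == 0] = 1.0
    z = (values - mean) / sd
    z[flat, :] = 0.0
    return pd.DataFrame(z, index=expression.index, columns=expression.columns)


def signature_score(z: pd.DataFrame, signature: GeneSignature) -> ScoreVector:
    """Summed z-score activity: sum over up genes minus sum over down genes.

    Signature genes absent from the matrix are skipped (reflected in
    ``n_genes_used``); a signature with no gene present is an error.
    """
    up = sorted(signature.up & set(z.index))
    down = sorted(signature.down & set(z.index))
    n_used = len(up) + len(down)
    if n_used == 0:
        raise ValueError(f"no gene of signature {signature.name!r} present in the matrix")
    n_missing = len(signature) - n_used
    if n_missing:
        logger.info("signature %r: %d genes absent from matrix", signature.name, n_missing)
    scores = z.loc[up].sum(axis=0) - z.loc[down].sum(axis=0)
    return ScoreVector(scores=scores, signature_name=signature.name, n_genes_used=n_used)


def score_correlation(scores_a: ScoreVector, scores_b: ScoreVector) -> AssociationResult:
    """Pearson correlation between two score vectors over shared samples."""
    joined = pd.concat([scores_a.scores, scores_b.scores], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 3:
        raise ValueError("need >= 3 shared samples for a correlation")
    a, b = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
    if np.std(a) == 0 or np.std(b) == 0:
        return AssociationResult(r=float("nan"), p_value=float("nan"), n=n, degenerate=True)
    r, p = stats.pearsonr(a, b)
    return AssociationResult(r=float(r), p_value=float(p), n=n)


@dataclass
class HomologReport:
    n_unmapped: int = 0
    conflicts: set[str] = field(default_factory=set)


def map_homologs(
    signature: GeneSignature, homolog_map: pd.DataFrame
) -> tuple[GeneSignature, HomologReport]:
    """Carry a mouse signature into human gene space.

    ``homolog_map`` has columns ``mouse`` and ``human`` with unique pairs;
    a mouse gene maps to all its human homologs, unmapped genes drop (and
    are counted), and a human gene receiving both directions is excluded
    with a conflict warning.
    """
    if homolog_map.duplicated(["mouse", "human"]).any():
        raise ValueError("homolog map contains duplicate (mouse, human) pairs")
    by_mouse: dict[str, list[str]] = {}
    for r in homolog_map.itertuples(index=False):
        by_mouse.setdefault(str(r.mouse), []).append(str(r.human))

    report = HomologReport()
    up, down = set(), set()
    for gene in signature.up:
        if gene in by_mouse:
            up.update(by_mouse[gene])
        else:
            report.n_unmapped += 1
    for gene in signature.down:
        if gene in by_mouse:
            down.update(by_mouse[gene])
        else:
            report.n_unmapped += 1
    report.conflicts = up & down
    if report.conflicts:
        logger.warning(
            "map_homologs: %d human genes received conflicting directions and were dropped",
            len(report.conflicts),
        )
    mapped = GeneSignature(
        name=f"{signature.name}.human",
        up=frozenset(up - report.conflicts),
        down=frozenset(down - report.conflicts),
    )
    return mapped, report


def severity_association(
    scores: ScoreVector, states: pd.Series, order: list[str]
) -> AssociationResult:
    """Pearson association of signature activity with ordinal disease severity.

    States are encoded 0..k-1 in the supplied order (unit spacing); an
    unseen state label is an error.
    """
    if len(order) < 2:
        raise ValueError("need >= 2 severity levels")
    encoding = {state: i for i, state in enumerate(order)}
    joined = pd.concat([scores.scores.rename("score"), states.rename("state")],
                       axis=1, join="inner").dropna()
    unknown = set(joined["state"]) - set(encoding)
    if unknown:
        raise ValueError(f"unseen severity labels: {sorted(unknown)}")
    encoded = joined["state"].map(encoding).to_numpy(dtype=float)
    n = len(joined)
    if n < 3:
        raise ValueError("need >= 3 samples")
    score_arr = joined["score"].to_numpy(dtype=float)
    if np.std(encoded) == 0 or np.std(score_arr) == 0:
        return AssociationResult(r=float("nan"), p_value=float("nan"), n=n, degenerate=True)
    r, p = stats.pearsonr(score_arr, encoded)
    return AssociationResult(r=float(r), p_value=float(p), n=n)


def correlation_matrix(score_vectors: list[ScoreVector]) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of signature activity scores."""
    names = [sv.signature_name for sv in score_vectors]
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i in range(len(score_vectors)):
        for j in range(i + 1, len(score_vectors)):
            res = score_correlation(score_vectors[i], score_vectors[j])
            mat.iloc[i, j] = mat.iloc[j, i] = res.r
    return mat
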