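"""Aging-plasticity signatures and trajectory attenuation/acceleration calls.

The central objects are *gene signatures* — named pairs of disjoint up/down
gene sets derived from differential tables — and the classification of each
gene shared between an exposure signature and the aging signature as
*attenuated* (exposure opposes the normal aging direction, so the gene
"remains low"/"remains high") or *accelerated* (same direction as aging).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class GeneSignature:
    """A named pair of disjoint up/down gene sets."""

    name: str
    up: frozenset[str] = frozenset()
    down: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.up = frozenset(self.up)
        self.down = frozenset(self.down)
        common = self.up & self.down
        if common:
            raise ValueError(
                f"signature {self.name!r}: up/down sets overlap ({sorted(common)[:5]})"
            )

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)

    def direction_of(self, gene: str) -> str:
        if gene in self.up:
            return "up"
        if gene in self.down:
            return "down"
        raise KeyError(gene)

    def flipped(self) -> "GeneSignature":
        """Swap up and down sets (used for anti-symmetry checks)."""
        return GeneSignature(name=f"{self.name}.flipped", up=self.down, down=self.up)

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, "up", self.name) for g in sorted(self.up)]
        rows += [(g, "down", self.name) for g in sorted(self.down)]
        return pd.DataFrame(rows, columns=["gene_id", "direction", "source"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str | None = None) -> "GeneSignature":
        name = name or (df["source"].iloc[0] if len(df) else "signature")
        return cls(
            name=name,
            up=frozenset(df.loc[df["direction"] == "up", "gene_id"]),
            down=frozenset(df.loc[df["direction"] == "down", "gene_id"]),
        )


@dataclass(frozen=True)
class OverlapFraction:
    """A percentage reported three ways.

    Published summaries mix rounding conventions (nearest integer for most
    counts, truncation for some), so both are carried alongside the raw
    value.
    """

    percent: float
    rounded: int
    floored: int


def overlap_fraction(n_overlap: int, n_total: int) -> OverlapFraction:
    """Percent of ``n_total`` covered by ``n_overlap``.

    ``rounded`` uses half-away-from-zero rounding; ``floored`` truncates.
    """
    if n_total <= 0:
        raise ValueError(f"n_total must be positive, got {n_total}")
    if not 0 <= n_overlap <= n_total:
        raise ValueError(f"n_overlap={n_overlap} outside [0, {n_total}]")
    pct = 100.0 * n_overlap / n_total
    return OverlapFraction(percent=pct, rounded=int(math.floor(pct + 0.5)), floored=int(math.floor(pct)))


@dataclass(frozen=True)
class TrajectoryCall:
    gene_id: str
    aging_direction: str
    exposure_direction: str
    trajectory_class: str  # "attenuated" | "accelerated"


@dataclass(frozen=True)
class OverlapSummary:
    n_signature: int
    n_overlap: int
    percent: float
    n_attenuated: int
    n_accelerated: int


def derive_signature(diff_table: pd.DataFrame, name: str) -> GeneSignature:
    """Build a signature from a differential table (ns rows excluded)."""
    up = frozenset(diff_table.loc[diff_table["direction"] == "up", "feature_id"])
    down = frozenset(diff_table.loc[diff_table["direction"] == "down", "feature_id"])
    if not up and not down:
        logger.warning("signature %r derived from table with no significant genes", name)
    return GeneSignature(name=name, up=up, down=down)


def sex_partition(
    sig_male: GeneSignature, sig_female: GeneSignature
) -> dict[str, frozenset[str]]:
    """Partition two sex-specific signatures into shared/sex-only/discordant sets.

    Returns seven disjoint sets whose union covers every gene in either
    signature; "shared" requires the same direction in both sexes,
    "discordant" is the same gene with opposite directions.
    """
    discordant = (sig_male.up & sig_female.down) | (sig_male.down & sig_female.up)
    return {
        "shared_up": sig_male.up & sig_female.up,
        "shared_down": sig_male.down & sig_female.down,
        "male_only_up": sig_male.up - sig_female.genes,
        "male_only_down": sig_male.down - sig_female.genes,
        "female_only_up": sig_female.up - sig_male.genes,
        "female_only_down": sig_female.down - sig_male.genes,
        "discordant": discordant,
    }


def composite_signature(
    sig_male: GeneSignature, sig_female: GeneSignature, name: str = "composite"
) -> GeneSignature:
    """Union of same-direction calls across sexes; discordant genes excluded."""
    parts = sex_partition(sig_male, sig_female)
    up = (sig_male.up | sig_female.up) - parts["discordant"]
    down = (sig_male.down | sig_female.down) - parts["discordant"]
    return GeneSignature(name=name, up=up, down=down)


def classify_trajectories(
    exposure_sig: GeneSignature, laasp_sig: GeneSignature
) -> tuple[list[TrajectoryCall], OverlapSummary]:
    """Classify each gene shared between an exposure and the aging signature.

    attenuated: the exposure pushes against the gene's normal aging
    direction (an aging-up gene stays low, an aging-down gene stays high);
    accelerated: same direction as aging.  The summary percent is the
    overlap as a share of the exposure signature.
    """
    shared = sorted(exposure_sig.genes & laasp_sig.genes)
    calls: list[TrajectoryCall] = []
    for gene in shared:
        aging = laasp_sig.direction_of(gene)
        expo = exposure_sig.direction_of(gene)
        cls = "attenuated" if aging != expo else "accelerated"
        calls.append(TrajectoryCall(gene, aging, expo, cls))
    n_att = sum(c.trajectory_class == "attenuated" for c in calls)
    n_sig = len(exposure_sig)
    summary = OverlapSummary(
        n_signature=n_sig,
        n_overlap=len(calls),
        percent=(100.0 * len(calls) / n_sig) if n_sig else 0.0,
        n_attenuated=n_att,
        n_accelerated=len(calls) - n_att,
    )
    return calls, summary


def trajectory_frame(calls: Iterable[TrajectoryCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.gene_id, c.aging_direction, c.exposure_direction, c.trajectory_class) for c in calls],
        columns=["gene_id", "aging_direction", "exposure_direction", "trajectory_class"],
    )


@dataclass
class VennCounts:
    """Exact region counts for an n-set Venn decomposition."""

    regions: dict[frozenset[str], int] = field(default_factory=dict)
    union_size: int = 0

    def count(self, *names: str) -> int:
        """Genes in exactly the named sets and no others."""
        return self.regions.get(frozenset(names), 0)


def core_overlap(
    core_sets: Mapping[str, Iterable[str]],
    cell_identity_core: Iterable[str] | None = None,
) -> VennCounts:
    """Venn-region counts across per-exposure core gene sets.

    Each exposure set is optionally intersected with a cell-identity core
    set first, then every non-empty region of the inclusion-exclusion
    decomposition is counted exactly (a gene contributes to the single
    region matching its exact membership pattern).
    """
    if len(core_sets) < 2:
        raise ValueError("need at least 2 named sets")
    sets = {k: set(v) for k, v in core_sets.items()}
    if cell_identity_core is not None:
        core = set(cell_identity_core)
        sets = {k: v & core for k, v in sets.items()}
    universe = set().union(*sets.values())
    result = VennCounts(union_size=len(universe))
    for gene in universe:
        member = frozenset(k for k, v in sets.items() if gene in v)
        result.regions[member] = result.regions.get(member, 0) + 1
    return result


def intersection_counts(core_sets: Mapping[str, Iterable[str]]) -> dict[frozenset[str], int]:
    """Plain (non-exclusive) intersection sizes for every pair and higher tuple."""
    sets = {k: set(v) for k, v in core_sets.items()}
    out: dict[frozenset[str], int] = {}
    names = sorted(sets)
    for r in range(2, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(sets[c] for c in combo))
            out[frozenset(combo)] = len(inter)
    return out
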