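"""Gene-set overlap summaries, enrichment significance, and group statistics.

Overlap (Venn) reports follow the conventions used when describing stabilized
fractions of decay sets: the percentage of set A covered by the overlap is
*truncated* (not rounded) to two decimals, e.g. 1224/1724 = 70.997…% is
reported as 70.99%. Overlap significance is the hypergeometric upper tail
P(X ≥ overlap) returned in log10 space, so enrichments far below
double-precision underflow remain representable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers with an optional statistical universe."""

    name: str
    members: frozenset[str]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if self.universe is not None:
            universe = frozenset(self.universe)
            object.__setattr__(self, "universe", universe)
            if not self.members <= universe:
                raise ValueError(
                    f"gene set {self.name!r} has members outside its universe")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class OverlapResult:
    """Sizes, truncated coverage percentage and enrichment of A ∩ B."""

    size_a: int
    size_b: int
    overlap: int
    only_a: int
    only_b: int
    pct_of_a: float | None
    log10_p: float | None = None
    test: str = "hypergeometric upper tail"

    def as_dict(self) -> dict:
        return {
            "size_a": self.size_a, "size_b": self.size_b,
            "overlap": self.overlap, "only_a": self.only_a,
            "only_b": self.only_b, "pct_of_a": self.pct_of_a,
            "log10_p": self.log10_p, "test": self.test,
        }


def truncated_percentage(part: int, whole: int) -> float | None:
    """100 × part/whole truncated to two decimals; None for an empty whole.

    Truncation, not rounding: 568/909 → 62.48, 1224/1724 → 70.99.
    Integer arithmetic keeps the truncation exact.
    """
    if whole == 0:
        return None
    if part < 0 or whole < 0:
        raise ValueError("counts must be non-negative")
    return (10000 * part // whole) / 100


def hypergeom_log10_sf(overlap: int, size_a: int, size_b: int,
                       universe: int) -> float:
    """log10 of the hypergeometric upper tail P(X ≥ overlap).

    X is the overlap of a fixed set of ``size_a`` with a uniformly random set
    of ``size_b`` drawn from ``universe`` genes. Computed by log-space
    summation of exact log-pmf terms, so results like −550 or −1700 are
    returned exactly where a probability would underflow. Symmetric in A/B.
    """
    if not (0 <= size_a <= universe and 0 <= size_b <= universe):
        raise ValueError("set sizes must lie within the universe")
    if overlap > min(size_a, size_b) or overlap < 0:
        raise ValueError("overlap inconsistent with set sizes")
    if overlap <= max(0, size_a + size_b - universe):
        return 0.0  # tail includes the whole support
    support = np.arange(overlap, min(size_a, size_b) + 1)
    log_terms = stats.hypergeom.logpmf(support, universe, size_a, size_b)
    return float(logsumexp(log_terms) / math.log(10))


def enrichment_pvalue(overlap: int, size_a: int, size_b: int,
                      universe: int) -> float:
    """Alias for :func:`hypergeom_log10_sf` (returns the log10 p-value)."""
    return hypergeom_log10_sf(overlap, size_a, size_b, universe)


def venn(a: GeneSet, b: GeneSet,
         universe: frozenset[str] | int | None = None) -> OverlapResult:
    """Exact two-set overlap with truncated percentage-of-A and enrichment p.

    The enrichment p-value is computed only when a universe is available
    (argument, or the universe attached to either set).
    """
    inter = a.members & b.members
    result = OverlapResult(
        size_a=len(a), size_b=len(b), overlap=len(inter),
        only_a=len(a.members - b.members), only_b=len(b.members - a.members),
        pct_of_a=truncated_percentage(len(inter), len(a)),
    )
    if universe is None:
        universe = a.universe or b.universe
    if universe is not None:
        n_universe = universe if isinstance(universe, int) else len(universe)
        result.log10_p = hypergeom_log10_sf(
            result.overlap, result.size_a, result.size_b, n_universe)
    return result


def replicate_correlation(values: pd.DataFrame,
                          sample_meta: pd.DataFrame,
                          group_cols: tuple[str, ...] = ("stage", "condition"),
                          ) -> pd.Series:
    """Mean pairwise Spearman correlation among replicates of each group.

    ``values`` is genes × samples; groups are defined by ``group_cols`` of the
    sample sheet. Groups with fewer than two replicates raise.
    """
    out = {}
    for key, group in sample_meta.groupby(list(group_cols), sort=False):
        samples = list(group.index)
        if len(samples) < 2:
            raise ValueError(f"group {key} has fewer than two replicates")
        corrs = []
        for s1, s2 in itertools.combinations(samples, 2):
            rho = stats.spearmanr(values[s1], values[s2]).statistic
            corrs.append(rho)
        out[key] = float(np.mean(corrs))
    return pd.Series(out, name="mean_spearman")


def significance_stars(p: float) -> str:
    """Asterisk convention: * P<0.05, ** P<0.01, *** P<0.001, n.s. otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def group_compare(values_a, values_b) -> tuple[float, float, str]:
    """Two-tailed unpaired equal-variance Student's t-test.

    Returns ``(t, p, stars)``. Two degenerate groups with equal means (zero
    pooled variance) return t = 0, p = 1 by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        return 0.0, 1.0, "n.s."
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), significance_stars(float(p))
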