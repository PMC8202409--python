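"""Alpha diversity, Bray–Curtis dissimilarity, divergence-to-median
heterogeneity, and unpaired rank-sum testing.

Conventions
-----------
* The Shannon index uses the natural logarithm by default (configurable
  base), so H ranges in [0, ln T] for T taxa.
* Beta diversity is Bray–Curtis on relative abundances,
  ``d(x, y) = sum |x_t - y_t| / sum (x_t + y_t)``, which lies in [0, 1]
  when columns are normalized.
* A sample's *divergence* is its Bray–Curtis dissimilarity to the
  per-taxon median profile of its group; the group mean divergence is a
  simple measure of community heterogeneity.  The median reference is not
  renormalized (the Bray–Curtis formula tolerates an unnormalized
  reference), so divergences are reproducible from the stated definition.
* Group comparisons here are between independent samples, so the unpaired
  Mann–Whitney rank-sum test is used: exact enumeration when both groups
  are small and tie-free, otherwise the normal approximation with tie and
  continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy.stats import mannwhitneyu
from skbio import DistanceMatrix

from .profiles import RelativeAbundanceTable, ProfileValidationError

__all__ = [
    "shannon",
    "shannon_index",
    "bray_curtis",
    "bray_curtis_pair",
    "divergence_to_median",
    "DivergenceResult",
    "rank_sum_test",
    "RankSumResult",
    "write_distance_matrix",
]


def shannon(rel_column: np.ndarray | pd.Series, base: float | None = None) -> float:
    """Shannon entropy H = -sum p log p of one relative-abundance column.

    Returns NaN for an all-zero column (undefined).  ``base=None`` means
    natural log (nats).
    """
    p = np.asarray(rel_column, dtype=float)
    if p.sum() <= 0:
        return float("nan")
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def shannon_index(rel_table: RelativeAbundanceTable, base: float | None = None) -> pd.Series:
    """Per-sample Shannon index; flagged zero-total samples come out NaN."""
    return rel_table.values.apply(lambda col: shannon(col.to_numpy(), base=base), axis=0)


def bray_curtis_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Bray–Curtis dissimilarity of two abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = (x + y).sum()
    if denom == 0:
        raise ProfileValidationError("Bray-Curtis undefined for two empty profiles")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis(rel_table: RelativeAbundanceTable) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarities among the usable samples.

    Flagged zero-total samples are excluded; fewer than two usable samples
    is an error.
    """
    usable = rel_table.nonzero()
    if usable.shape[1] < 2:
        raise ProfileValidationError("need at least 2 nonzero samples for beta diversity")
    condensed = pdist(usable.T.to_numpy(), metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(usable.columns))


@dataclass(frozen=True)
class DivergenceResult:
    """Per-sample divergence to the group median profile."""

    values: pd.Series  # index: sample_id
    groups: pd.Series  # index: sample_id

    def group_means(self) -> pd.Series:
        return self.values.groupby(self.groups).mean()


def divergence_to_median(
    rel_table: RelativeAbundanceTable,
    group_labels: pd.Series,
) -> DivergenceResult:
    """Divergence of each sample to its group's per-taxon median profile.

    ``group_labels`` is indexed by sample id; flagged zero-total samples
    are ignored.  Each group must retain at least one usable sample.
    """
    usable = rel_table.nonzero()
    labels = group_labels.loc[[s for s in usable.columns if s in group_labels.index]]
    labels = labels.dropna()
    if labels.empty:
        raise ProfileValidationError("no labelled usable samples")
    values: dict[str, float] = {}
    for group, members in labels.groupby(labels):
        cols = usable.loc[:, members.index]
        if cols.shape[1] == 0:
            raise ProfileValidationError(f"group {group!r} has no usable samples")
        reference = cols.median(axis=1).to_numpy()
        for sample in cols.columns:
            values[sample] = bray_curtis_pair(cols[sample].to_numpy(), reference)
    out = pd.Series(values).loc[labels.index]
    return DivergenceResult(out, labels)


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann–Whitney U of the first group
    p_value: float
    method: str  # "exact" or "asymptotic"
    alternative: str


def rank_sum_test(
    values_a,
    values_b,
    alternative: str = "two-sided",
    exact_cap: int = 12,
) -> RankSumResult:
    """Unpaired Mann–Whitney rank-sum test between two independent groups.

    The exact null distribution is enumerated when both groups have at
    most ``exact_cap`` observations and there are no ties; otherwise the
    normal approximation with tie and continuity corrections is used.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ProfileValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (a.size <= exact_cap) and (b.size <= exact_cap) and not has_ties
    res = mannwhitneyu(
        a,
        b,
        alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return RankSumResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="exact" if exact else "asymptotic",
        alternative=alternative,
    )


def write_distance_matrix(dist: DistanceMatrix, path) -> None:
    """Square TSV with sample ids as header row and first column."""
    df = pd.DataFrame(dist.data, index=dist.ids, columns=dist.ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")
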