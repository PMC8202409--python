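"""PERMANOVA and group-contrast summaries, implemented from first
principles.

PERMANOVA partitions the total sum of squared dissimilarities among a
set of samples into among-group and within-group components::

    SS_T = (1/N) * sum_{i<j} d_ij^2
    SS_W = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    SS_A = SS_T - SS_W
    pseudo-F = (SS_A / (a - 1)) / (SS_W / (N - a))

with ``a`` groups of sizes ``n_g`` and ``N`` samples in total.
Significance is assessed by permuting the group labels: the reported
p-value is ``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)``, so it is
never zero and is bounded below by ``1/(n_permutations + 1)``.  When the
number of distinct label assignments does not exceed the requested
permutation count, the full assignment set is enumerated instead and the
p-value is the exact fraction of assignments at least as extreme as the
observed one.

The module also provides the per-taxon group-separating coefficients
(signed differences of group mean relative abundances), fold changes of
mean relative abundance with a pseudo-count policy for empty
denominators, and an age-threshold scan that re-runs PERMANOVA over a
grid of young/old cutoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .profiles import RelativeAbundanceTable, ProfileValidationError

__all__ = [
    "PermanovaResult",
    "NotTestable",
    "permanova",
    "pairwise_permanova",
    "SeparatingCoefficients",
    "separating_coefficients",
    "FoldChange",
    "fold_change",
    "age_threshold_scan",
    "results_to_frame",
]

_F_TOL = 1e-12  # slack for >= comparisons between permuted and observed F


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int  # permutations drawn, or assignments enumerated
    seed: int | None
    group_sizes: dict[str, int]
    method: str  # "permutation" or "exact"

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.R2 <= 1.0 + 1e-9):
            raise ProfileValidationError(f"R2 out of range: {self.R2}")


@dataclass(frozen=True)
class NotTestable:
    """Marker for a contrast that cannot be tested (e.g. a group of one)."""

    reason: str
    group_sizes: dict[str, int]


def _sum_squares(d2: np.ndarray, codes: np.ndarray, sizes: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from a squared-distance matrix and int codes."""
    n = d2.shape[0]
    ss_t = d2.sum() / (2.0 * n)  # full matrix double-counts i<j pairs
    ss_w = 0.0
    for g, n_g in enumerate(sizes):
        idx = np.flatnonzero(codes == g)
        ss_w += d2[np.ix_(idx, idx)].sum() / (2.0 * n_g)
    return float(ss_t), float(ss_w)


def _pseudo_f(ss_t: float, ss_w: float, n: int, a: int) -> float:
    ss_a = ss_t - ss_w
    if ss_w <= 0.0:
        # degenerate: all within-group distances zero; any separation is infinite
        return float("inf") if ss_a > _F_TOL else 0.0
    return (ss_a / (a - 1)) / (ss_w / (n - a))


def _n_assignments(sizes: Sequence[int]) -> int:
    total = math.factorial(int(np.sum(sizes)))
    for s in sizes:
        total //= math.factorial(int(s))
    return total


def _assignments(n: int, sizes: Sequence[int]) -> Iterator[np.ndarray]:
    """All distinct label assignments (as int codes) of n items into groups
    of the given sizes."""

    def rec(remaining: tuple[int, ...], group: int, codes: np.ndarray):
        if group == len(sizes) - 1:
            codes = codes.copy()
            codes[list(remaining)] = group
            yield codes
            return
        for chosen in combinations(remaining, sizes[group]):
            nxt = codes.copy()
            nxt[list(chosen)] = group
            rest = tuple(i for i in remaining if i not in set(chosen))
            yield from rec(rest, group + 1, nxt)

    yield from rec(tuple(range(n)), 0, np.full(n, -1, dtype=np.intp))


def _batched_perm_f(
    d2: np.ndarray,
    codes: np.ndarray,
    sizes: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
    ss_t: float,
    chunk: int = 256,
) -> np.ndarray:
    """Pseudo-F for seeded random label permutations, computed in batches.

    For indicator rows ``x_g`` of a permuted labelling, the within-group
    pair sum is ``x_g' D2 x_g / 2``, evaluated for whole batches with one
    matmul per group.
    """
    n, a = d2.shape[0], len(sizes)
    fs = np.empty(n_permutations)
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        perm_codes = np.empty((m, n), dtype=np.intp)
        for i in range(m):
            perm_codes[i] = codes[rng.permutation(n)]
        ss_w = np.zeros(m)
        for g, n_g in enumerate(sizes):
            ind = (perm_codes == g).astype(float)
            ss_w += np.einsum("pi,pi->p", ind @ d2, ind) / (2.0 * n_g)
        ss_a = ss_t - ss_w
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_a / (a - 1)) / (ss_w / (n - a))
        f[ss_w <= 0.0] = np.where(ss_a[ss_w <= 0.0] > _F_TOL, np.inf, 0.0)
        fs[done : done + m] = f
        done += m
    return fs


def _validate_dist(dist: DistanceMatrix | np.ndarray) -> np.ndarray:
    if isinstance(dist, DistanceMatrix):
        return np.asarray(dist.data, dtype=float)
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ProfileValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ProfileValidationError("distance matrix must be symmetric")
    if np.abs(np.diag(d)).max(initial=0.0) > 1e-12:
        raise ProfileValidationError("distance matrix must have a zero diagonal")
    return d


def permanova(
    dist: DistanceMatrix | np.ndarray,
    labels: Sequence,
    n_permutations: int = 999,
    seed: int | None = 0,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    ``labels`` must be aligned with the distance-matrix sample order;
    every group needs at least two members and at least two groups are
    required.  ``seed`` drives the permutation stream and is recorded in
    the result.
    """
    d = _validate_dist(dist)
    labels = np.asarray(labels)
    if len(labels) != d.shape[0]:
        raise ProfileValidationError("labels must align with the distance matrix")
    groups, codes = np.unique(labels, return_inverse=True)
    sizes = np.bincount(codes)
    if len(groups) < 2:
        raise ProfileValidationError("need at least 2 groups")
    if sizes.min() < 2:
        small = groups[np.argmin(sizes)]
        raise ProfileValidationError(f"group {small!r} has fewer than 2 samples")
    n, a = d.shape[0], len(groups)
    d2 = d**2
    ss_t, ss_w = _sum_squares(d2, codes, sizes)
    f_obs = _pseudo_f(ss_t, ss_w, n, a)
    r2 = 0.0 if ss_t == 0 else (ss_t - ss_w) / ss_t

    total_assignments = _n_assignments(sizes)
    if total_assignments <= n_permutations:
        extreme = 0
        for assignment in _assignments(n, list(sizes)):
            ss_t_a, ss_w_a = _sum_squares(d2, assignment, sizes)
            if _pseudo_f(ss_t_a, ss_w_a, n, a) >= f_obs - _F_TOL:
                extreme += 1
        return PermanovaResult(
            pseudo_F=f_obs,
            R2=float(np.clip(r2, 0.0, 1.0)),
            p_value=extreme / total_assignments,
            n_permutations=total_assignments,
            seed=seed,
            group_sizes={str(g): int(s) for g, s in zip(groups, sizes)},
            method="exact",
        )

    rng = np.random.default_rng(seed)
    f_perm = _batched_perm_f(d2, codes, sizes, n_permutations, rng, ss_t)
    p = (1 + int(np.sum(f_perm >= f_obs - _F_TOL))) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_F=f_obs,
        R2=float(np.clip(r2, 0.0, 1.0)),
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
        group_sizes={str(g): int(s) for g, s in zip(groups, sizes)},
        method="permutation",
    )


def pairwise_permanova(
    dist: DistanceMatrix,
    labels: pd.Series | Sequence,
    n_permutations: int = 999,
    seed: int | None = 0,
) -> dict[tuple[str, str], PermanovaResult | NotTestable]:
    """PERMANOVA on every pair of groups, each on its own submatrix."""
    ids = list(dist.ids)
    labels = pd.Series(np.asarray(labels), index=ids)
    groups = sorted(labels.dropna().unique())
    if len(groups) < 2:
        raise ProfileValidationError("need at least 2 groups")
    out: dict[tuple[str, str], PermanovaResult | NotTestable] = {}
    for g1, g2 in combinations(groups, 2):
        members = labels[labels.isin([g1, g2])]
        sizes = members.value_counts().to_dict()
        if min(sizes.values()) < 2:
            out[(g1, g2)] = NotTestable(
                reason="group with fewer than 2 samples",
                group_sizes={str(k): int(v) for k, v in sizes.items()},
            )
            continue
        sub = dist.filter(list(members.index))
        out[(g1, g2)] = permanova(
            sub, members.loc[list(sub.ids)].to_numpy(), n_permutations, seed
        )
    return out


@dataclass(frozen=True)
class SeparatingCoefficients:
    """Signed per-taxon differences of group mean relative abundances.

    Positive coefficients mark taxa more abundant in the reference group.
    """

    coefficients: pd.Series  # index: taxon, sorted by |coef| descending
    reference_group: str
    other_group: str

    def top(self, k: int) -> pd.Series:
        return self.coefficients.iloc[:k]


def separating_coefficients(
    rel_table: RelativeAbundanceTable,
    binary_labels: pd.Series,
    reference: str | None = None,
) -> SeparatingCoefficients:
    """Mean-abundance contrast per taxon between exactly two groups."""
    usable = rel_table.nonzero()
    labels = binary_labels.loc[[s for s in usable.columns if s in binary_labels.index]].dropna()
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ProfileValidationError(f"expected exactly 2 groups, got {groups}")
    ref = reference if reference is not None else groups[0]
    if ref not in groups:
        raise ProfileValidationError(f"reference group {ref!r} not among {groups}")
    other = groups[1] if ref == groups[0] else groups[0]
    mean_ref = usable.loc[:, labels.index[labels == ref]].mean(axis=1)
    mean_other = usable.loc[:, labels.index[labels == other]].mean(axis=1)
    coef = (mean_ref - mean_other).sort_values(key=np.abs, ascending=False)
    return SeparatingCoefficients(coef, ref, other)


@dataclass(frozen=True)
class FoldChange:
    taxon: str
    ratio: float
    mean_group1: float
    mean_group2: float
    pseudo_count: float  # 0.0 when no pseudo-count was needed
    groups: tuple[str, str]


def fold_change(
    rel_table: RelativeAbundanceTable,
    group_labels: pd.Series,
    taxon: str,
    groups: tuple[str, str] | None = None,
) -> FoldChange:
    """Ratio of a taxon's mean relative abundance between two groups.

    A zero denominator triggers a pseudo-abundance of half the smallest
    nonzero relative abundance in the table, added to both means and
    recorded in the result.
    """
    usable = rel_table.nonzero()
    if taxon not in usable.index:
        raise ProfileValidationError(f"taxon {taxon!r} not in table")
    labels = group_labels.loc[[s for s in usable.columns if s in group_labels.index]].dropna()
    observed = sorted(labels.unique())
    if groups is None:
        if len(observed) != 2:
            raise ProfileValidationError(f"expected exactly 2 groups, got {observed}")
        groups = (observed[0], observed[1])
    g1, g2 = groups
    for g in groups:
        if g not in observed:
            raise ProfileValidationError(f"group {g!r} has no usable samples")
    m1 = float(usable.loc[taxon, labels.index[labels == g1]].mean())
    m2 = float(usable.loc[taxon, labels.index[labels == g2]].mean())
    pseudo = 0.0
    if m2 == 0.0:
        nonzero = usable.to_numpy()
        nonzero = nonzero[nonzero > 0]
        if nonzero.size == 0:
            raise ProfileValidationError("table has no nonzero abundances")
        pseudo = float(nonzero.min() / 2.0)
    ratio = (m1 + pseudo) / (m2 + pseudo)
    return FoldChange(taxon, float(ratio), m1, m2, pseudo, (g1, g2))


def age_threshold_scan(
    dist: DistanceMatrix,
    ages: pd.Series,
    thresholds: Iterable[float] = range(45, 71, 5),
    n_permutations: int = 999,
    seed: int | None = 0,
) -> dict[float, PermanovaResult | NotTestable]:
    """PERMANOVA of young (age <= tau) vs old (age > tau) over a grid of
    cutoffs; cutoffs leaving a group with fewer than 2 samples are
    reported as not testable."""
    ids = list(dist.ids)
    ages = pd.Series(ages).loc[ids]
    if ages.isna().any():
        missing = list(ages.index[ages.isna()])[:5]
        raise ProfileValidationError(f"samples without age: {missing}")
    out: dict[float, PermanovaResult | NotTestable] = {}
    any_testable = False
    for tau in thresholds:
        labels = np.where(ages.to_numpy() <= tau, "young", "old")
        sizes = pd.Series(labels).value_counts().to_dict()
        if len(sizes) < 2 or min(sizes.values()) < 2:
            out[float(tau)] = NotTestable(
                reason="degenerate young/old split",
                group_sizes={str(k): int(v) for k, v in sizes.items()},
            )
            continue
        any_testable = True
        out[float(tau)] = permanova(dist, labels, n_permutations, seed)
    if not any_testable:
        raise ProfileValidationError("no threshold yields two groups of size >= 2")
    return out


def results_to_frame(results: Mapping, factor: str) -> pd.DataFrame:
    """Flatten PERMANOVA results into the TSV layout (one row per test)."""
    rows = []
    for key, res in results.items():
        name = key if isinstance(key, str) else "|".join(str(k) for k in key) if isinstance(key, tuple) else str(key)
        if isinstance(res, NotTestable):
            rows.append(
                {"factor": factor, "groups": name, "pseudo_F": np.nan, "R2": np.nan,
                 "p_value": np.nan, "n_permutations": 0, "seed": np.nan,
                 "note": res.reason}
            )
        else:
            rows.append(
                {"factor": factor, "groups": name, "pseudo_F": res.pseudo_F,
                 "R2": res.R2, "p_value": res.p_value,
                 "n_permutations": res.n_permutations, "seed": res.seed,
                 "note": res.method}
            )
    return pd.DataFrame(rows)
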