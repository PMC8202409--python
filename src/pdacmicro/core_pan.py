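"""Core-microbiota detection, cross-dataset overlap, and pan-microbiome
accumulation with Heaps-law fitting.

Core microbiota are the genera detected above a relative-abundance
threshold (default 0.2%) in at least a prevalence fraction of samples
(default 20%).  The pan-microbiome is estimated from the accumulation
(collector's) curve: samples are added in random order, the cumulative
number of distinct genera is recorded, the procedure is repeated many
times, and the mean curve is fitted with the Heaps power law
``P(n) = kappa * n**gamma`` by least squares on the log-log scale.  A
positive fitted exponent means richness keeps growing with sample count
— an *open* pan-microbiome — while gamma near zero marks saturation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .profiles import RelativeAbundanceTable, TaxonProfileTable, ProfileValidationError

__all__ = [
    "CoreTaxaResult",
    "core_taxa",
    "core_per_dataset",
    "OverlapResult",
    "overlap_sets",
    "AccumulationCurve",
    "accumulation_curve",
    "HeapsFit",
    "fit_heaps",
    "PanEstimate",
    "pan_estimate",
]


@dataclass(frozen=True)
class CoreTaxaResult:
    detection_threshold: float
    prevalence_threshold: float
    core: tuple[str, ...]
    prevalence: pd.Series  # per-genus fraction of samples above detection

    @property
    def n_core(self) -> int:
        return len(self.core)


def core_taxa(
    rel_table: RelativeAbundanceTable,
    detection: float = 0.002,
    prevalence: float = 0.20,
    detection_inclusive: bool = False,
    prevalence_inclusive: bool = True,
) -> CoreTaxaResult:
    """Genera detected above ``detection`` relative abundance in at least
    a ``prevalence`` fraction of samples.

    Detection is a strict inequality (p > threshold) and prevalence an
    inclusive one (>= threshold) by default; both are configurable.
    """
    if not (0.0 <= detection < 1.0):
        raise ProfileValidationError("detection threshold must be in [0, 1)")
    if not (0.0 < prevalence <= 1.0):
        raise ProfileValidationError("prevalence threshold must be in (0, 1]")
    values = rel_table.values
    if values.shape[0] == 0 or values.shape[1] == 0:
        raise ProfileValidationError("empty table")
    detected = values >= detection if detection_inclusive else values > detection
    prev = detected.mean(axis=1)
    is_core = prev >= prevalence if prevalence_inclusive else prev > prevalence
    core = tuple(prev.index[is_core])
    return CoreTaxaResult(detection, prevalence, core, prev)


def core_per_dataset(
    rel_table: RelativeAbundanceTable,
    datasets: pd.Series,
    detection: float = 0.002,
    prevalence: float = 0.20,
) -> dict[str, CoreTaxaResult]:
    """Core taxa computed within each dataset's samples separately."""
    out: dict[str, CoreTaxaResult] = {}
    for name, members in datasets.groupby(datasets):
        ids = [s for s in members.index if s in rel_table.values.columns]
        out[str(name)] = core_taxa(rel_table.subset_samples(ids), detection, prevalence)
    return out


@dataclass(frozen=True)
class OverlapResult:
    """Partition of a union of named sets into membership regions."""

    sets: dict[str, frozenset]
    regions: dict[frozenset, frozenset]  # membership signature -> members
    intersection: frozenset
    union: frozenset
    shared_fraction: dict[str, float]  # |k-way intersection| / |set|


def overlap_sets(genus_sets: Mapping[str, Iterable]) -> OverlapResult:
    """Full membership partition, k-way intersection, and per-set shared
    fractions for a family of named genus sets."""
    if not genus_sets:
        raise ProfileValidationError("no sets given")
    sets = {str(k): frozenset(v) for k, v in genus_sets.items()}
    names = list(sets)
    union = frozenset().union(*sets.values())
    inter = frozenset.intersection(*sets.values())
    regions: dict[frozenset, set] = {}
    for item in union:
        signature = frozenset(n for n in names if item in sets[n])
        regions.setdefault(signature, set()).add(item)
    shared = {
        n: (len(inter) / len(s)) if len(s) else float("nan") for n, s in sets.items()
    }
    return OverlapResult(
        sets=sets,
        regions={sig: frozenset(m) for sig, m in regions.items()},
        intersection=inter,
        union=union,
        shared_fraction=shared,
    )


@dataclass(frozen=True)
class AccumulationCurve:
    """Replicate-wise cumulative richness as samples accrue in random order."""

    curves: np.ndarray  # (n_reps, n_samples) int
    seed: int
    sample_ids: tuple[str, ...]

    @property
    def n_reps(self) -> int:
        return self.curves.shape[0]

    @property
    def n_samples(self) -> int:
        return self.curves.shape[1]

    def mean_curve(self) -> np.ndarray:
        return self.curves.mean(axis=0)

    def sd_curve(self) -> np.ndarray:
        return self.curves.std(axis=0, ddof=0)


def accumulation_curve(
    table: TaxonProfileTable,
    n_reps: int = 1000,
    seed: int = 0,
) -> AccumulationCurve:
    """Collector's curve of cumulative genus richness.

    For each replicate the samples are shuffled uniformly at random and
    the cumulative number of genera with count > 0 is recorded.  The
    per-replicate computation places every genus at the position of its
    first occurrence under the permutation, so a replicate costs
    O(G * N) rather than a cumulative union per step.
    """
    if table.n_samples < 1:
        raise ProfileValidationError("need at least one sample")
    if n_reps < 1:
        raise ProfileValidationError("n_reps must be >= 1")
    presence = (table.counts.to_numpy() > 0)
    g, n = presence.shape
    # genera never observed can be dropped; they contribute nothing
    observed = presence.any(axis=1)
    presence = presence[observed]
    rng = np.random.default_rng(seed)
    curves = np.empty((n_reps, n), dtype=np.int64)
    pos = np.empty(n, dtype=np.int64)
    for r in range(n_reps):
        order = rng.permutation(n)
        pos[order] = np.arange(n)  # pos[s] = step at which sample s enters
        first = np.where(presence, pos[np.newaxis, :], n).min(axis=1)
        counts_at = np.bincount(first, minlength=n + 1)[:n]
        curves[r] = np.cumsum(counts_at)
    return AccumulationCurve(curves, seed, tuple(table.sample_ids))


@dataclass(frozen=True)
class HeapsFit:
    """Power-law fit P(n) = kappa * n**gamma of a mean accumulation curve."""

    kappa: float
    gamma: float
    r_squared: float

    def predict(self, n) -> np.ndarray | float:
        return self.kappa * np.asarray(n, dtype=float) ** self.gamma


def fit_heaps(mean_curve: np.ndarray) -> HeapsFit:
    """Least-squares fit of ``ln P = ln kappa + gamma ln n`` over
    n = 1..N; R² is computed on the log-log scale."""
    y = np.asarray(mean_curve, dtype=float)
    if y.size < 3:
        raise ProfileValidationError("curve must have at least 3 points")
    if (y <= 0).any():
        raise ProfileValidationError("curve values must be strictly positive")
    n = np.arange(1, y.size + 1, dtype=float)
    ln_n, ln_y = np.log(n), np.log(y)
    gamma, ln_kappa = np.polyfit(ln_n, ln_y, 1)
    fitted = ln_kappa + gamma * ln_n
    ss_res = float(((ln_y - fitted) ** 2).sum())
    ss_tot = float(((ln_y - ln_y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return HeapsFit(float(np.exp(ln_kappa)), float(gamma), r2)


@dataclass(frozen=True)
class PanEstimate:
    predicted_richness: float
    n_extrapolate: int
    is_open: bool
    open_margin: float
    fit: HeapsFit


def pan_estimate(
    fit: HeapsFit,
    n_extrapolate: int,
    observed_n: int,
    open_margin: float = 0.02,
) -> PanEstimate:
    """Extrapolated richness at ``n_extrapolate`` samples, plus an
    open/closed call (open iff gamma exceeds ``open_margin``).

    The extrapolation point is explicit: a "pan size" is only meaningful
    at a stated sample count when the community is open.
    """
    if n_extrapolate < observed_n:
        raise ProfileValidationError("cannot extrapolate below the observed sample count")
    return PanEstimate(
        predicted_richness=float(fit.predict(n_extrapolate)),
        n_extrapolate=int(n_extrapolate),
        is_open=bool(fit.gamma > open_margin),
        open_margin=open_margin,
        fit=fit,
    )
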