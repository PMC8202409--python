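"""Dirichlet-multinomial generator for genus-level tumor-microbiome
count tables.

The generator emulates the structure of a multi-cohort tissue RNA-Seq
microbiome study: several datasets whose compositional differences
dominate the variation, an open pool of thousands of genera with
power-law (rank-abundance) occurrence so per-sample richness is in the
hundreds while cumulative richness keeps growing sublinearly,
bacteria/virus/archaea domain structure, binary covariates (sex, age
group, sampling site, tissue source) with configurable location effects
and group-specific overdispersion, and a tail of zero-read and
sub-100-read samples.

Generative model
----------------
* pool weights ``w_g ∝ g**(-alpha)`` over ``G`` genera (Zipf-like
  rank-abundance);
* per dataset ``d``: base composition ``theta_d ~ Dirichlet(A * w)``
  where ``A`` (``dataset_effect``) sets how similar datasets are;
* per sample ``s`` in ``d``: composition
  ``p_s ~ Dirichlet((c / r_s) * theta_d * m_s)`` with sample
  concentration ``c``, dispersion ratio ``r_s`` (> 1 for designated
  heterogeneity groups, making those groups more divergent without
  shifting their mean), and multiplicative effect vector ``m_s`` that
  up-weights designated taxa in one level of a factor;
* counts ``~ Multinomial(R_s, p_s)`` with log-normal read depth ``R_s``;
* a designated set of samples is overridden to zero reads, and another
  to a uniform 1–99 reads, mimicking failed/low-yield libraries.

All randomness flows from the mandatory config seed, so a fixed seed
gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .profiles import (
    NONE_PHYLUM,
    ProfileValidationError,
    SampleMetadata,
    TaxonProfileTable,
    Taxonomy,
)

__all__ = ["SyntheticConfig", "GeneratedStudy", "generate", "generate_null_pair"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the generative model.

    Defaults mirror the four-cohort study design the package targets:
    dataset sizes 214/191/30/147, a 2,500-genus open pool, nine
    zero-read and 33 low-read samples, planted sampling-site and
    tissue-source effects, null sex and age location effects, and
    overdispersion for the male and old groups.
    """

    seed: int
    pool_size: int = 2500
    rank_abundance_exponent: float = 0.7
    dataset_sizes: tuple[int, ...] = (214, 191, 30, 147)
    dataset_effect: float = 500.0  # Dirichlet concentration of dataset bases
    sample_concentration: float = 200.0
    reads_mu: float = float(np.log(5e4))  # log-normal read depth, mean of log
    reads_sigma: float = 1.0
    zero_read_count: int = 9
    low_read_count: int = 33
    site_effect: float = 1.5  # log-fold shift on designated taxa
    source_effect: float = 2.5
    sex_effect: float = 0.0
    age_effect: float = 0.0
    n_effect_taxa: int = 20
    dispersion_ratio: float = 1.2  # >1: male/old groups are more divergent
    age_cutoff: float = 65.0
    domain_mixture: tuple[float, float, float] = (0.86, 0.12, 0.02)
    phylum_none_fraction: float = 0.05
    n_phyla: int = 30
    null_group_size: int = 10

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ProfileValidationError("seed is mandatory")
        if self.pool_size < 1 or any(s < 1 for s in self.dataset_sizes):
            raise ProfileValidationError("all sizes must be positive")
        if self.rank_abundance_exponent <= 0:
            raise ProfileValidationError("rank_abundance_exponent must be > 0")
        n_total = int(sum(self.dataset_sizes))
        if self.zero_read_count + self.low_read_count > n_total:
            raise ProfileValidationError(
                "more designated zero/low-read samples than samples"
            )
        if abs(sum(self.domain_mixture) - 1.0) > 1e-9:
            raise ProfileValidationError("domain_mixture must sum to 1")
        if self.dispersion_ratio <= 0:
            raise ProfileValidationError("dispersion_ratio must be > 0")

    @property
    def n_samples(self) -> int:
        return int(sum(self.dataset_sizes))


@dataclass(frozen=True)
class GeneratedStudy:
    table: TaxonProfileTable
    taxonomy: Taxonomy
    metadata: SampleMetadata
    ground_truth: dict


def _pool_weights(config: SyntheticConfig) -> np.ndarray:
    ranks = np.arange(1, config.pool_size + 1, dtype=float)
    w = ranks ** (-config.rank_abundance_exponent)
    return w / w.sum()


def _make_taxonomy(config: SyntheticConfig, rng: np.random.Generator) -> Taxonomy:
    g = config.pool_size
    domains = np.array(["bacteria", "virus", "archaea"])[
        rng.choice(3, size=g, p=list(config.domain_mixture))
    ]
    # phylum occupancy is itself long-tailed; a slice of genera carries no
    # phylum-level assignment at all
    phylum_w = 1.0 / np.arange(1, config.n_phyla + 1)
    phylum_w /= phylum_w.sum()
    phylum_idx = rng.choice(config.n_phyla, size=g, p=phylum_w)
    phyla = np.array([f"Phylum_{d[:3]}_{k:02d}" for d, k in zip(domains, phylum_idx)])
    none_mask = rng.random(g) < config.phylum_none_fraction
    phyla[none_mask] = NONE_PHYLUM
    genus_ids = [f"Genus_{i:04d}" for i in range(1, g + 1)]
    return Taxonomy(
        pd.DataFrame({"phylum": phyla, "domain": domains}, index=pd.Index(genus_ids))
    )


def _metadata_frame(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Cohort layout mirroring the four archetype datasets: a
    site-resolved cohort, a human-vs-PDX cohort, a small all-PDX cohort
    with sex labels, and a cohort with sex and age labels."""
    rows: list[dict] = []
    sample_counter = 1

    def add(dataset: str, **kw) -> None:
        nonlocal sample_counter
        rows.append(
            {
                "sample_id": f"S{sample_counter:04d}",
                "dataset": dataset,
                "sex": kw.get("sex", np.nan),
                "age": kw.get("age", np.nan),
                "sampling_site": kw.get("site", np.nan),
                "tissue_source": kw.get("source", np.nan),
            }
        )
        sample_counter += 1

    for d, size in enumerate(config.dataset_sizes):
        name = f"DS{d + 1}"
        if d == 0:
            # site-resolved cohort: stroma/epithelium/bulk ~ 128/71/15
            n_stroma = round(size * 128 / 214)
            n_epi = round(size * 71 / 214)
            n_bulk = size - n_stroma - n_epi
            for _ in range(n_stroma):
                add(name, site="stroma", source="human_tissue")
            for _ in range(n_epi):
                add(name, site="epithelium", source="human_tissue")
            for _ in range(n_bulk):
                add(name, site="bulk", source="human_tissue")
        elif d == 1:
            # mixed-source cohort: human tissue vs patient-derived xenograft
            n_pdx = round(size * 28 / 191)
            for _ in range(size - n_pdx):
                add(name, site="bulk", source="human_tissue")
            for _ in range(n_pdx):
                add(name, site="bulk", source="pdx")
        elif d == 2:
            # small all-PDX cohort with sex labels (~16 male / 14 female)
            n_male = round(size * 16 / 30)
            for i in range(size):
                add(name, site="bulk", source="pdx",
                    sex="male" if i < n_male else "female")
        elif d == 3:
            # cohort with sex and age at diagnosis (~79 male / 68 female)
            n_male = round(size * 79 / 147)
            ages = np.clip(np.round(rng.normal(65.0, 9.0, size)), 40, 85)
            for i in range(size):
                add(name, site="bulk", source="human_tissue",
                    sex="male" if i < n_male else "female", age=float(ages[i]))
        else:
            for _ in range(size):
                add(name, site="bulk", source="human_tissue")
    return pd.DataFrame(rows).set_index("sample_id")


def _pick_effect_taxa(
    rng: np.random.Generator, genus_ids: Sequence[str], n: int, exclude: set[str]
) -> list[str]:
    # plant effects among moderately abundant ranks so they are detectable
    # but do not dominate the community; tiny pools host fewer planted taxa
    candidates = [g for g in genus_ids[4:200] if g not in exclude]
    n = min(n, len(candidates))
    if n == 0:
        return []
    chosen = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in sorted(chosen)]


def generate(config: SyntheticConfig) -> GeneratedStudy:
    """Draw a full synthetic study: counts, taxonomy, metadata and a
    ground-truth record of every planted effect and seed."""
    rng = np.random.default_rng(config.seed)
    g = config.pool_size
    w = _pool_weights(config)
    taxonomy = _make_taxonomy(config, rng)
    genus_ids = list(taxonomy.table.index)
    meta = _metadata_frame(config, rng)
    n_total = len(meta)

    effect_taxa: dict[str, list[str]] = {}
    taken: set[str] = set()
    half = max(1, config.n_effect_taxa // 2)
    for key in ("site_up_epithelium", "site_up_stroma", "source_up_pdx",
                "source_up_human", "sex_up_male", "age_up_old"):
        effect_taxa[key] = _pick_effect_taxa(rng, genus_ids, half, taken)
        taken.update(effect_taxa[key])
    idx_of = {gid: i for i, gid in enumerate(genus_ids)}

    theta = {
        f"DS{d + 1}": rng.dirichlet(config.dataset_effect * w)
        for d in range(len(config.dataset_sizes))
    }

    reads = np.round(rng.lognormal(config.reads_mu, config.reads_sigma, n_total)).astype(
        np.int64
    )
    # designated failed / low-yield libraries
    flagged = rng.choice(n_total, size=config.zero_read_count + config.low_read_count,
                         replace=False)
    zero_idx = flagged[: config.zero_read_count]
    low_idx = flagged[config.zero_read_count:]
    reads[zero_idx] = 0
    reads[low_idx] = rng.integers(1, 100, size=len(low_idx))

    counts = np.zeros((g, n_total), dtype=np.int64)
    dispersed_samples: list[str] = []
    for j, (sample_id, row) in enumerate(meta.iterrows()):
        base = theta[row["dataset"]]
        m = np.ones(g)

        def bump(keys_effects):
            for key, eff in keys_effects:
                if eff > 0:
                    m[[idx_of[t] for t in effect_taxa[key]]] *= np.exp(eff)

        site = row["sampling_site"]
        if site == "epithelium":
            bump([("site_up_epithelium", config.site_effect)])
        elif site == "stroma":
            bump([("site_up_stroma", config.site_effect)])
        source = row["tissue_source"]
        if source == "pdx":
            bump([("source_up_pdx", config.source_effect)])
        elif source == "human_tissue":
            bump([("source_up_human", config.source_effect)])
        if row["sex"] == "male":
            bump([("sex_up_male", config.sex_effect)])
        age = row["age"]
        if pd.notna(age) and age > config.age_cutoff:
            bump([("age_up_old", config.age_effect)])

        conc = config.sample_concentration
        is_dispersed = (row["sex"] == "male") or (pd.notna(age) and age > config.age_cutoff)
        if is_dispersed and config.dispersion_ratio != 1.0:
            conc /= config.dispersion_ratio
            dispersed_samples.append(sample_id)

        alpha = conc * base * m
        gam = rng.gamma(np.maximum(alpha, 0.0))
        total = gam.sum()
        if total <= 0:  # pragma: no cover - head alphas keep this positive
            gam[:] = w
            total = 1.0
        p = gam / total
        if reads[j] > 0:
            counts[:, j] = rng.multinomial(reads[j], p)

    table = TaxonProfileTable(
        pd.DataFrame(counts, index=pd.Index(genus_ids), columns=meta.index)
    )
    metadata = SampleMetadata(meta)
    ground_truth = {
        "config": dataclasses.asdict(config),
        "effect_taxa": effect_taxa,
        "zero_read_samples": [meta.index[i] for i in sorted(zero_idx)],
        "low_read_samples": [meta.index[i] for i in sorted(low_idx)],
        "dispersed_samples": dispersed_samples,
        "reads_per_sample": {s: int(r) for s, r in zip(meta.index, reads)},
    }
    return GeneratedStudy(table, taxonomy, metadata, ground_truth)


def generate_null_pair(
    config: SyntheticConfig,
) -> tuple[TaxonProfileTable, pd.Series]:
    """Two equally sized groups drawn from one homogeneous population.

    Labels are assigned independently of composition, so any test of the
    group factor is a test under its null; used by the calibration
    suites for PERMANOVA and the rank-sum test.
    """
    rng = np.random.default_rng(config.seed)
    g = config.pool_size
    w = _pool_weights(config)
    theta = rng.dirichlet(config.dataset_effect * w)
    n = 2 * config.null_group_size
    reads = np.round(rng.lognormal(config.reads_mu, config.reads_sigma, n)).astype(np.int64)
    reads = np.maximum(reads, 1)
    counts = np.zeros((g, n), dtype=np.int64)
    for j in range(n):
        gam = rng.gamma(np.maximum(config.sample_concentration * theta, 0.0))
        counts[:, j] = rng.multinomial(reads[j], gam / gam.sum())
    sample_ids = [f"N{j:04d}" for j in range(1, n + 1)]
    genus_ids = [f"Genus_{i:04d}" for i in range(1, g + 1)]
    table = TaxonProfileTable(
        pd.DataFrame(counts, index=pd.Index(genus_ids), columns=sample_ids)
    )
    labels = pd.Series(
        ["a"] * config.null_group_size + ["b"] * config.null_group_size,
        index=sample_ids,
    )
    return table, labels
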