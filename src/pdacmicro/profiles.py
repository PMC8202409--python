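"""Data model and I/O for genus-level microbial count tables.

The universal input of the package is a trio of TSV files:

* ``counts.tsv`` — genera as rows, samples as columns, integer read counts
  (first column holds the genus label);
* ``taxonomy.tsv`` — columns ``genus``, ``phylum`` (empty string when the
  genus has no phylum assignment), ``domain``;
* ``metadata.tsv`` — columns ``sample_id``, ``dataset``, ``sex``, ``age``,
  ``sampling_site``, ``tissue_source`` (empty cells mean missing).

Counts are reads assigned per genus per sample, typically produced by a
taxonomic classifier run on tissue RNA-Seq and aggregated at the genus
level.  Everything downstream (diversity, PERMANOVA, core-microbiota and
pan-microbiome analyses) consumes the containers defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "NONE_PHYLUM",
    "DOMAINS",
    "TaxonProfileTable",
    "Taxonomy",
    "SampleMetadata",
    "RelativeAbundanceTable",
    "QCReport",
    "ProfileValidationError",
    "read_profile",
    "write_profile",
    "to_relative_abundance",
    "aggregate",
    "domain_proportions",
    "qc_filter",
    "top_n_collapse",
]

#: Sentinel label for genera with no phylum-level assignment.
NONE_PHYLUM = "None"

#: Admissible domain labels. Fungi are admitted for completeness although
#: the bundled generator emits bacteria/virus/archaea communities.
DOMAINS = frozenset({"bacteria", "virus", "archaea", "fungi"})

_SEXES = frozenset({"male", "female"})
_SITES = frozenset({"stroma", "epithelium", "bulk"})
_SOURCES = frozenset({"human_tissue", "pdx"})


class ProfileValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


def _check_unique(labels: Iterable[str], what: str) -> None:
    labels = pd.Index(labels)
    if labels.has_duplicates:
        dupes = labels[labels.duplicated()].unique().tolist()
        raise ProfileValidationError(f"duplicate {what} label(s): {dupes[:5]}")


@dataclass(frozen=True)
class TaxonProfileTable:
    """Genus-by-sample matrix of non-negative integer read counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            raise ProfileValidationError("counts must be a pandas DataFrame")
        _check_unique(self.counts.index, "genus")
        _check_unique(self.counts.columns, "sample")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ProfileValidationError("counts must be numeric")
        if values.size and (values < 0).any():
            bad = self.counts.columns[(values < 0).any(axis=0)][0]
            raise ProfileValidationError(f"negative count in sample {bad!r}")

    @property
    def genus_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genera(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        """Total assigned microbial reads per sample."""
        return self.counts.sum(axis=0)

    def richness(self) -> pd.Series:
        """Number of genera with at least one read, per sample."""
        return (self.counts > 0).sum(axis=0)

    def subset_samples(self, sample_ids: Iterable[str]) -> "TaxonProfileTable":
        return TaxonProfileTable(self.counts.loc[:, list(sample_ids)])


@dataclass(frozen=True)
class Taxonomy:
    """Genus → (phylum, domain) lineage map.

    ``phylum`` may be the :data:`NONE_PHYLUM` sentinel; ``domain`` must be
    one of :data:`DOMAINS` for every genus.
    """

    table: pd.DataFrame  # index: genus; columns: phylum, domain

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "genus")
        missing = {"phylum", "domain"} - set(self.table.columns)
        if missing:
            raise ProfileValidationError(f"taxonomy missing column(s): {sorted(missing)}")
        bad = set(self.table["domain"].unique()) - DOMAINS
        if bad:
            raise ProfileValidationError(f"unknown domain label(s): {sorted(bad)}")

    def phylum_of(self, genus: str) -> str:
        return str(self.table.loc[genus, "phylum"])

    def domain_of(self, genus: str) -> str:
        return str(self.table.loc[genus, "domain"])

    def level_labels(self, genera: Iterable[str], level: Literal["phylum", "domain"]) -> pd.Series:
        genera = list(genera)
        unknown = [g for g in genera if g not in self.table.index]
        if level == "phylum":
            labels = pd.Series(
                [self.table.loc[g, "phylum"] if g not in unknown else NONE_PHYLUM for g in genera],
                index=genera,
            )
        elif level == "domain":
            if unknown:
                raise ProfileValidationError(
                    f"genus with unresolvable domain: {unknown[:5]}"
                )
            labels = self.table.loc[genera, "domain"]
        else:
            raise ProfileValidationError(f"unknown aggregation level {level!r}")
        return labels


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample covariates: dataset, sex, age, sampling site, tissue source."""

    table: pd.DataFrame  # index: sample_id

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        required = {"dataset", "sex", "age", "sampling_site", "tissue_source"}
        missing = required - set(self.table.columns)
        if missing:
            raise ProfileValidationError(f"metadata missing column(s): {sorted(missing)}")
        for col, allowed in [
            ("sex", _SEXES),
            ("sampling_site", _SITES),
            ("tissue_source", _SOURCES),
        ]:
            values = self.table[col].dropna().unique()
            bad = set(values) - allowed
            if bad:
                raise ProfileValidationError(f"invalid {col} value(s): {sorted(bad)}")
        ages = pd.to_numeric(self.table["age"], errors="coerce")
        if (ages.dropna() < 0).any():
            raise ProfileValidationError("age must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def factor(self, name: str, samples: Iterable[str] | None = None) -> pd.Series:
        """Factor values for ``samples`` (all samples by default)."""
        col = self.table[name]
        if samples is not None:
            col = col.loc[list(samples)]
        return col

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(sample_ids)])


@dataclass(frozen=True)
class RelativeAbundanceTable:
    """Per-sample relative abundances; columns sum to 1 except flagged
    zero-total samples, whose columns are all-zero."""

    values: pd.DataFrame
    zero_total_samples: tuple[str, ...] = field(default_factory=tuple)

    @property
    def genus_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def nonzero(self) -> pd.DataFrame:
        """Columns for samples with nonzero totals only."""
        keep = [s for s in self.values.columns if s not in self.zero_total_samples]
        return self.values.loc[:, keep]

    def subset_samples(self, sample_ids: Iterable[str]) -> "RelativeAbundanceTable":
        ids = list(sample_ids)
        flagged = tuple(s for s in self.zero_total_samples if s in ids)
        return RelativeAbundanceTable(self.values.loc[:, ids], flagged)


@dataclass(frozen=True)
class QCReport:
    """Result of read-depth filtering."""

    kept: TaxonProfileTable
    zero_read_samples: tuple[str, ...]
    low_read_samples: tuple[str, ...]  # includes the zero-read samples
    min_reads: int


# ---------------------------------------------------------------------------
# I/O


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise ProfileValidationError(f"malformed TSV {path}: {exc}") from exc


def read_profile(
    counts_path: str | Path,
    taxonomy_path: str | Path,
    metadata_path: str | Path,
) -> tuple[TaxonProfileTable, Taxonomy, SampleMetadata]:
    """Read the counts/taxonomy/metadata TSV trio and cross-validate it.

    Genera present in the counts but absent from the taxonomy file are
    assigned ``phylum = None``; their domain cannot be resolved, so domain-
    level aggregation of such a table raises.  Samples present in the counts
    but absent from the metadata are an error.
    """
    raw = _read_tsv(counts_path, index_col=0)
    raw.index = raw.index.astype(str)
    values = raw.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        bad = raw.columns[[not np.issubdtype(raw[c].dtype, np.number) for c in raw.columns]]
        raise ProfileValidationError(f"non-numeric count cell(s) in column(s) {list(bad)[:3]}")
    if values.size and not np.allclose(values, np.round(values)):
        raise ProfileValidationError("counts must be integers")
    table = TaxonProfileTable(raw.astype(np.int64))

    tax_raw = _read_tsv(taxonomy_path, dtype=str, keep_default_na=False)
    for col in ("genus", "phylum", "domain"):
        if col not in tax_raw.columns:
            raise ProfileValidationError(f"taxonomy missing column {col!r}")
    tax_raw = tax_raw.set_index("genus")
    tax_raw["phylum"] = tax_raw["phylum"].replace("", NONE_PHYLUM)
    missing_genera = [g for g in table.genus_ids if g not in tax_raw.index]
    if missing_genera:
        # A genus can live without a phylum (sentinel) but not without a
        # domain, and the taxonomy file is the only source of domains.
        raise ProfileValidationError(
            f"genus missing from taxonomy (domain unresolvable): {missing_genera[:5]}"
        )
    taxonomy = Taxonomy(tax_raw[["phylum", "domain"]])

    meta_raw = _read_tsv(metadata_path, dtype=str, keep_default_na=False)
    if "sample_id" not in meta_raw.columns:
        raise ProfileValidationError("metadata missing column 'sample_id'")
    meta_raw = meta_raw.set_index("sample_id")
    for col in ("sex", "sampling_site", "tissue_source", "dataset"):
        meta_raw[col] = meta_raw[col].replace("", np.nan)
    meta_raw["age"] = pd.to_numeric(meta_raw["age"].replace("", np.nan), errors="raise")
    metadata = SampleMetadata(meta_raw)

    orphans = [s for s in table.sample_ids if s not in metadata.table.index]
    if orphans:
        raise ProfileValidationError(f"sample(s) missing from metadata: {orphans[:5]}")
    return table, taxonomy, metadata


def write_profile(
    table: TaxonProfileTable,
    taxonomy: Taxonomy,
    metadata: SampleMetadata,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the TSV trio to ``out_dir``; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "metadata": out / "metadata.tsv",
    }
    counts = table.counts.copy()
    counts.index.name = "genus"
    counts.to_csv(paths["counts"], sep="\t")
    tax = taxonomy.table.copy()
    tax["phylum"] = tax["phylum"].replace(NONE_PHYLUM, "")
    tax.index.name = "genus"
    tax.to_csv(paths["taxonomy"], sep="\t")
    meta = metadata.table.copy()
    meta.index.name = "sample_id"
    meta.to_csv(paths["metadata"], sep="\t", na_rep="")
    return paths


# ---------------------------------------------------------------------------
# Transforms


def to_relative_abundance(table: TaxonProfileTable) -> RelativeAbundanceTable:
    """Normalize each sample column to relative abundances.

    Zero-total samples yield all-zero columns and are flagged rather than
    raising; downstream analyses drop flagged samples.
    """
    totals = table.sample_totals()
    zero = tuple(totals.index[totals == 0])
    safe = totals.replace(0, 1)
    values = table.counts.div(safe, axis=1).astype(float)
    return RelativeAbundanceTable(values, zero)


def aggregate(
    table: TaxonProfileTable,
    taxonomy: Taxonomy,
    level: Literal["phylum", "domain"],
) -> TaxonProfileTable:
    """Sum genus counts up to the phylum or domain level.

    At the phylum level, genera without an assignment are retained under the
    ``None`` category.  Total counts per sample are conserved.
    """
    labels = taxonomy.level_labels(table.genus_ids, level)
    grouped = table.counts.groupby(labels.to_numpy()).sum()
    grouped.index = grouped.index.astype(str)
    return TaxonProfileTable(grouped.sort_index())


def domain_proportions(
    table: TaxonProfileTable,
    taxonomy: Taxonomy,
    metadata: SampleMetadata | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-sample proportion of bacterial/viral/archaeal reads.

    Zero-total samples are excluded.  When metadata is given, per-dataset
    means and standard deviations are returned alongside.
    """
    if table.n_samples == 0:
        raise ProfileValidationError("empty table")
    dom = aggregate(table, taxonomy, "domain")
    totals = dom.sample_totals()
    keep = totals[totals > 0].index
    if len(keep) == 0:
        raise ProfileValidationError("no sample with nonzero microbial reads")
    props = dom.counts.loc[:, keep].div(totals[keep], axis=1).T  # samples × domains
    summary = None
    if metadata is not None:
        datasets = metadata.factor("dataset", props.index)
        summary = props.groupby(datasets).agg(["mean", "std"])
    return props, summary


def qc_filter(table: TaxonProfileTable, min_reads: int = 100) -> QCReport:
    """Drop samples whose total microbial reads fall strictly below
    ``min_reads``; report zero-read and sub-threshold samples."""
    if min_reads < 0:
        raise ProfileValidationError("min_reads must be >= 0")
    totals = table.sample_totals()
    zero = tuple(totals.index[totals == 0])
    low = tuple(totals.index[totals < min_reads])
    kept = table.subset_samples(totals.index[totals >= min_reads])
    return QCReport(kept, zero, low, min_reads)


def top_n_collapse(
    rel_table: RelativeAbundanceTable,
    n: int,
    other_label: str = "Other",
) -> RelativeAbundanceTable:
    """Keep the ``n`` most abundant taxa (mean relative abundance over all
    samples; ties broken lexicographically) and pool the rest into an
    ``Other`` row.  Column sums are preserved."""
    if n < 1:
        raise ProfileValidationError("n must be >= 1")
    values = rel_table.values
    order = (
        values.mean(axis=1)
        .to_frame("mean")
        .assign(label=values.index)
        .sort_values(["mean", "label"], ascending=[False, True])
        .index
    )
    top = list(order[:n])
    rest = values.index.difference(top)
    out = values.loc[top].copy()
    out.loc[other_label] = values.loc[rest].sum(axis=0)
    return RelativeAbundanceTable(out, rel_table.zero_total_samples)
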