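"""Count-table I/O, abundance transforms, aggregation, and QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import rel_from_columns
from pdacmicro.profiles import (
    NONE_PHYLUM,
    ProfileValidationError,
    TaxonProfileTable,
    aggregate,
    domain_proportions,
    qc_filter,
    read_profile,
    to_relative_abundance,
    top_n_collapse,
    write_profile,
)


class TestReadWrite:
    def test_round_trip_preserves_everything(
        self, tiny_table, tiny_taxonomy, tiny_metadata, tmp_path
    ):
        paths = write_profile(tiny_table, tiny_taxonomy, tiny_metadata, tmp_path)
        table, taxonomy, metadata = read_profile(
            paths["counts"], paths["taxonomy"], paths["metadata"]
        )
        pd.testing.assert_frame_equal(
            table.counts, tiny_table.counts, check_dtype=False, check_names=False
        )
        assert taxonomy.phylum_of("Mimivirus") == NONE_PHYLUM
        assert taxonomy.domain_of("Bacteroides") == "bacteria"
        assert metadata.table.loc["s1", "sex"] == "male"
        assert metadata.table.loc["s3", "tissue_source"] == "pdx"
        assert np.isnan(metadata.table.loc["s3", "age"])

    def test_sample_missing_from_metadata_is_an_error(
        self, tiny_table, tiny_taxonomy, tiny_metadata, tmp_path
    ):
        paths = write_profile(tiny_table, tiny_taxonomy, tiny_metadata, tmp_path)
        meta = pd.read_csv(paths["metadata"], sep="\t")
        meta[meta.sample_id != "s2"].to_csv(paths["metadata"], sep="\t", index=False)
        with pytest.raises(ProfileValidationError, match="missing from metadata"):
            read_profile(paths["counts"], paths["taxonomy"], paths["metadata"])

    def test_negative_count_is_an_error(
        self, tiny_table, tiny_taxonomy, tiny_metadata, tmp_path
    ):
        paths = write_profile(tiny_table, tiny_taxonomy, tiny_metadata, tmp_path)
        text = paths["counts"].read_text().replace("\t2\t0\t5", "\t2\t0\t-4")
        paths["counts"].write_text(text)
        with pytest.raises(ProfileValidationError, match="negative"):
            read_profile(paths["counts"], paths["taxonomy"], paths["metadata"])

    def test_duplicate_genus_label_is_an_error(self):
        counts = pd.DataFrame([[1, 2], [3, 4]], index=["A", "A"], columns=["s1", "s2"])
        with pytest.raises(ProfileValidationError, match="duplicate genus"):
            TaxonProfileTable(counts)

    def test_genus_without_taxonomy_entry_is_an_error(
        self, tiny_table, tiny_taxonomy, tiny_metadata, tmp_path
    ):
        paths = write_profile(tiny_table, tiny_taxonomy, tiny_metadata, tmp_path)
        tax = pd.read_csv(paths["taxonomy"], sep="\t")
        tax[tax.genus != "Mimivirus"].to_csv(paths["taxonomy"], sep="\t", index=False)
        with pytest.raises(ProfileValidationError, match="missing from taxonomy"):
            read_profile(paths["counts"], paths["taxonomy"], paths["metadata"])


class TestRelativeAbundance:
    def test_columns_normalize_and_zero_columns_flag(self, tiny_table):
        rel = to_relative_abundance(tiny_table)
        assert rel.values["s1"].tolist() == [0.5, 0.25, 0.25]
        assert rel.values["s3"].tolist() == [1.0, 0.0, 0.0]
        assert rel.values["s2"].tolist() == [0.0, 0.0, 0.0]
        assert rel.zero_total_samples == ("s2",)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_nonzero_columns_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(8, 5)),
            index=[f"g{i}" for i in range(8)],
            columns=[f"s{i}" for i in range(5)],
        )
        rel = to_relative_abundance(TaxonProfileTable(counts))
        sums = rel.nonzero().sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestAggregate:
    def test_phylum_sum_keeps_none_category(self, tiny_table, tiny_taxonomy):
        phy = aggregate(tiny_table, tiny_taxonomy, "phylum")
        assert phy.counts.loc["Bacteroidetes", "s1"] == 3
        assert phy.counts.loc[NONE_PHYLUM, "s1"] == 1
        # totals conserved per sample at every level
        assert (phy.sample_totals() == tiny_table.sample_totals()).all()

    def test_domain_identity_when_single_domain(self):
        counts = pd.DataFrame({"s1": [4, 6]}, index=["A", "B"])
        tax = pd.DataFrame(
            {"phylum": ["P", "P"], "domain": ["bacteria", "bacteria"]},
            index=["A", "B"],
        )
        from pdacmicro.profiles import Taxonomy

        dom = aggregate(TaxonProfileTable(counts), Taxonomy(tax), "domain")
        assert dom.counts.loc["bacteria", "s1"] == 10

    def test_mixed_domain_proportions(self, tiny_table, tiny_taxonomy):
        counts = pd.DataFrame({"s1": [90, 9, 1]}, index=["A", "B", "C"])
        tax = pd.DataFrame(
            {"phylum": ["P", "Q", "R"], "domain": ["bacteria", "virus", "archaea"]},
            index=["A", "B", "C"],
        )
        from pdacmicro.profiles import Taxonomy

        props, _ = domain_proportions(TaxonProfileTable(counts), Taxonomy(tax))
        assert props.loc["s1", "bacteria"] == pytest.approx(0.90)
        assert props.loc["s1", "virus"] == pytest.approx(0.09)
        assert props.loc["s1", "archaea"] == pytest.approx(0.01)


class TestDomainProportions:
    def test_zero_total_sample_excluded_and_dataset_means(
        self, tiny_table, tiny_taxonomy, tiny_metadata
    ):
        props, summary = domain_proportions(tiny_table, tiny_taxonomy, tiny_metadata)
        assert "s2" not in props.index  # zero-read sample dropped
        assert props.loc["s3", "bacteria"] == pytest.approx(1.0)
        assert summary.loc["DS1", ("bacteria", "mean")] == pytest.approx(0.75 / 1)

    def test_archaea_only_sample(self):
        counts = pd.DataFrame({"s1": [7]}, index=["A"])
        from pdacmicro.profiles import Taxonomy

        tax = Taxonomy(pd.DataFrame({"phylum": ["P"], "domain": ["archaea"]}, index=["A"]))
        props, _ = domain_proportions(TaxonProfileTable(counts), tax)
        assert props.loc["s1", "archaea"] == pytest.approx(1.0)


class TestQCFilter:
    def test_threshold_logic_and_reports(self):
        counts = pd.DataFrame(
            [[0, 50, 1000]], index=["A"], columns=["s1", "s2", "s3"]
        )
        report = qc_filter(TaxonProfileTable(counts), min_reads=100)
        assert report.kept.sample_ids == ["s3"]
        assert report.zero_read_samples == ("s1",)
        assert set(report.low_read_samples) == {"s1", "s2"}

    def test_boundary_is_strictly_less_than(self):
        counts = pd.DataFrame([[99, 100]], index=["A"], columns=["s1", "s2"])
        report = qc_filter(TaxonProfileTable(counts), min_reads=100)
        assert report.kept.sample_ids == ["s2"]
        assert report.low_read_samples == ("s1",)

    def test_zero_threshold_keeps_all_and_filter_is_idempotent(self, tiny_table):
        report = qc_filter(tiny_table, min_reads=0)
        assert report.kept.sample_ids == tiny_table.sample_ids
        once = qc_filter(tiny_table, min_reads=100)
        twice = qc_filter(once.kept, min_reads=100)
        assert twice.kept.sample_ids == once.kept.sample_ids
        # kept + removed partitions the input
        removed = set(tiny_table.sample_ids) - set(once.kept.sample_ids)
        assert removed | set(once.kept.sample_ids) == set(tiny_table.sample_ids)


class TestTopNCollapse:
    def test_ranking_and_other_row(self):
        rel = rel_from_columns({"s1": [0.5, 0.3, 0.2], "s2": [0.6, 0.3, 0.1]})
        out = top_n_collapse(rel, 2)
        assert list(out.values.index) == ["t0", "t1", "Other"]
        assert out.values.loc["Other", "s1"] == pytest.approx(0.2)

    def test_n_at_least_taxa_count_gives_zero_other(self):
        rel = rel_from_columns({"s1": [0.5, 0.5]})
        out = top_n_collapse(rel, 5)
        assert (out.values.loc["Other"] == 0).all()

    @given(st.integers(0, 2**31 - 1), st.integers(1, 6))
    @settings(max_examples=25, deadline=None)
    def test_column_sums_preserved(self, seed, n):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(
            rng.integers(1, 30, size=(7, 4)),
            index=[f"g{i}" for i in range(7)],
            columns=[f"s{i}" for i in range(4)],
        )
        rel = to_relative_abundance(TaxonProfileTable(counts))
        out = top_n_collapse(rel, n)
        assert np.allclose(out.values.sum(axis=0), rel.values.sum(axis=0), atol=1e-12)
        assert out.values.shape[0] == min(n, 7) + 1

    def test_nonpositive_n_is_an_error(self, tiny_table):
        rel = to_relative_abundance(tiny_table)
        with pytest.raises(ProfileValidationError):
            top_n_collapse(rel, 0)
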