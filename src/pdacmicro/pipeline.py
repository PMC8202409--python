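"""End-to-end analysis pipeline: QC → domain proportions → overlap →
core microbiota → pan-microbiome → diversity → factor tests.

:func:`run_pipeline` drives every analysis stage over one counts/
taxonomy/metadata trio and writes a report directory of plain-text
artifacts.  The same function backs the command-line ``report``
subcommand, the numbered analysis drivers, and the acceptance script,
so every published number is reproducible from the recorded parameters
and seed in ``run.log``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_pan import (
    AccumulationCurve,
    CoreTaxaResult,
    HeapsFit,
    PanEstimate,
    accumulation_curve,
    core_per_dataset,
    core_taxa,
    fit_heaps,
    overlap_sets,
    pan_estimate,
)
from .diversity import (
    bray_curtis,
    divergence_to_median,
    rank_sum_test,
    shannon_index,
    write_distance_matrix,
)
from .group_tests import (
    NotTestable,
    age_threshold_scan,
    fold_change,
    pairwise_permanova,
    permanova,
    results_to_frame,
    separating_coefficients,
)
from .profiles import (
    QCReport,
    SampleMetadata,
    TaxonProfileTable,
    Taxonomy,
    aggregate,
    domain_proportions,
    qc_filter,
    to_relative_abundance,
    top_n_collapse,
)

__all__ = ["PipelineParams", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineParams:
    """All analysis thresholds in one place; defaults are the study's."""

    seed: int
    min_reads: int = 100
    detection: float = 0.002  # core detection, relative abundance (0.2%)
    prevalence: float = 0.20  # core prevalence fraction (20%)
    n_reps: int = 1000  # accumulation-curve replicates
    n_permutations: int = 999
    top_n: int = 10  # phylum stack depth in the collapsed view
    top_k_coefficients: int = 20
    n_extrapolate: int = 2000  # explicit pan extrapolation point
    age_thresholds: tuple[int, ...] = (45, 50, 55, 60, 65, 70)


@dataclass
class PipelineResult:
    qc: QCReport
    domain_per_sample: pd.DataFrame
    domain_per_dataset: pd.DataFrame | None
    overlap: object
    core_pooled: CoreTaxaResult
    core_by_dataset: dict[str, CoreTaxaResult]
    shared_core: frozenset
    accumulation: AccumulationCurve
    heaps: HeapsFit
    pan: PanEstimate
    shannon: pd.Series
    permanova_table: pd.DataFrame
    divergence_table: pd.DataFrame
    rank_tests: pd.DataFrame
    coefficients: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def _binary_factor_tests(rel, dist_cache, metadata, factor, params, log):
    """PERMANOVA of one categorical factor within each dataset that has
    at least two testable levels; returns rows for permanova.tsv."""
    frames = []
    meta = metadata.table
    for ds, members in meta.groupby("dataset"):
        labels = members[factor].dropna()
        labels = labels.loc[[s for s in labels.index if s in rel.nonzero().columns]]
        counts = labels.value_counts()
        if len(counts) < 2 or counts.min() < 2:
            continue
        dm = dist_cache(tuple(labels.index))
        if len(counts) == 2:
            res = {tuple(sorted(counts.index)): permanova(
                dm, labels.loc[list(dm.ids)].to_numpy(),
                params.n_permutations, params.seed)}
        else:
            res = pairwise_permanova(dm, labels.loc[list(dm.ids)],
                                     params.n_permutations, params.seed)
            res["|".join(sorted(counts.index))] = permanova(
                dm, labels.loc[list(dm.ids)].to_numpy(),
                params.n_permutations, params.seed)
        frame = results_to_frame(res, factor)
        frame.insert(1, "dataset", ds)
        frames.append(frame)
        log.append(f"PERMANOVA {factor} within {ds}: groups {counts.to_dict()}")
    return frames


def run_pipeline(
    table: TaxonProfileTable,
    taxonomy: Taxonomy,
    metadata: SampleMetadata,
    out_dir: str | Path,
    params: PipelineParams,
) -> PipelineResult:
    """Run every analysis stage and write the report directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"pdacmicro {__version__}",
        f"parameters: {dataclasses.asdict(params)}",
        f"input: {table.n_genera} genera x {table.n_samples} samples",
    ]
    rng_seed = params.seed

    # --- QC -----------------------------------------------------------
    qc = qc_filter(table, params.min_reads)
    totals = table.sample_totals()
    qc_frame = pd.DataFrame(
        {
            "sample_id": table.sample_ids,
            "total_reads": totals.to_numpy(),
            "status": [
                "zero" if s in qc.zero_read_samples
                else "low" if s in qc.low_read_samples
                else "kept"
                for s in table.sample_ids
            ],
        }
    )
    log.append(
        f"QC: {len(qc.zero_read_samples)} zero-read, "
        f"{len(qc.low_read_samples)} below {params.min_reads} reads, "
        f"{qc.kept.n_samples} kept"
    )
    kept = qc.kept
    kept_meta = metadata.subset(kept.sample_ids)
    rel = to_relative_abundance(kept)

    # --- domain proportions -------------------------------------------
    dom_sample, dom_dataset = domain_proportions(kept, taxonomy, kept_meta)

    # --- per-dataset genus sets and overlap ---------------------------
    datasets = kept_meta.factor("dataset")
    genus_sets = {
        str(ds): set(kept.counts.index[(kept.counts[m.index].sum(axis=1) > 0)])
        for ds, m in datasets.groupby(datasets)
    }
    overlap = overlap_sets(genus_sets)
    log.append(
        "richness per dataset: "
        + ", ".join(f"{k}={len(v)}" for k, v in overlap.sets.items())
        + f"; union={len(overlap.union)}; shared={len(overlap.intersection)}"
    )

    # --- core microbiota ----------------------------------------------
    core_pooled = core_taxa(rel, params.detection, params.prevalence)
    core_by_ds = core_per_dataset(rel, datasets, params.detection, params.prevalence)
    shared_core = frozenset.intersection(
        *[frozenset(c.core) for c in core_by_ds.values()]
    )
    log.append(
        f"core: pooled={core_pooled.n_core}, per-dataset="
        + ", ".join(f"{k}={v.n_core}" for k, v in core_by_ds.items())
        + f", shared={len(shared_core)}"
    )

    # --- pan-microbiome ------------------------------------------------
    acc = accumulation_curve(kept, params.n_reps, rng_seed)
    heaps = fit_heaps(acc.mean_curve())
    pan = pan_estimate(heaps, params.n_extrapolate, acc.n_samples)
    log.append(
        f"Heaps fit: P(n) = {heaps.kappa:.1f} * n^{heaps.gamma:.4f}, "
        f"R2={heaps.r_squared:.4f}; predicted richness at "
        f"{pan.n_extrapolate} samples = {pan.predicted_richness:.0f} "
        f"({'open' if pan.is_open else 'closed'} pan-microbiome)"
    )

    # --- diversity -----------------------------------------------------
    shannon = shannon_index(rel)

    # distance matrices are computed lazily per sample subset and reused
    _dm_cache: dict[tuple, object] = {}

    def dist_cache(sample_ids: tuple):
        if sample_ids not in _dm_cache:
            _dm_cache[sample_ids] = bray_curtis(rel.subset_samples(list(sample_ids)))
        return _dm_cache[sample_ids]

    # --- PERMANOVA: dataset factor, then per-dataset factors ----------
    usable_ids = tuple(rel.nonzero().columns)
    dm_all = dist_cache(usable_ids)
    ds_labels = datasets.loc[list(dm_all.ids)]
    perm_frames = [
        results_to_frame(
            {"|".join(sorted(ds_labels.unique())): permanova(
                dm_all, ds_labels.to_numpy(), params.n_permutations, rng_seed)},
            "dataset",
        ).assign(dataset="all")
    ]
    for factor in ("sex", "sampling_site", "tissue_source"):
        perm_frames += _binary_factor_tests(rel, dist_cache, kept_meta, factor, params, log)

    # age groups: binary at 65 plus a threshold scan where ages exist
    for ds, members in kept_meta.table.groupby("dataset"):
        ages = pd.to_numeric(members["age"], errors="coerce").dropna()
        ages = ages.loc[[s for s in ages.index if s in usable_ids]]
        if len(ages) < 4:
            continue
        dm = dist_cache(tuple(ages.index))
        scan = age_threshold_scan(
            dm, ages, params.age_thresholds, params.n_permutations, rng_seed
        )
        frame = results_to_frame(
            {f"age<=%g|age>%g" % (t, t): r for t, r in scan.items()}, "age_group"
        )
        frame.insert(1, "dataset", ds)
        perm_frames.append(frame)
        log.append(f"age-threshold scan within {ds}: thresholds {list(scan)}")
    permanova_table = pd.concat(perm_frames, ignore_index=True)

    # --- divergence heterogeneity + rank-sum tests --------------------
    div_rows, rank_rows = [], []
    for factor, labeller in [
        ("sex", lambda m: m["sex"]),
        ("age_group", lambda m: pd.Series(
            np.where(pd.to_numeric(m["age"], errors="coerce") > 65, "old", "young"),
            index=m.index,
        ).where(pd.to_numeric(m["age"], errors="coerce").notna())),
        ("sampling_site", lambda m: m["sampling_site"]),
        ("tissue_source", lambda m: m["tissue_source"]),
    ]:
        for ds, members in kept_meta.table.groupby("dataset"):
            labels = labeller(members).dropna()
            labels = labels.loc[[s for s in labels.index if s in usable_ids]]
            counts = labels.value_counts()
            if len(counts) < 2 or counts.min() < 2:
                continue
            div = divergence_to_median(rel.subset_samples(list(labels.index)), labels)
            for s in div.values.index:
                div_rows.append(
                    {"factor": factor, "dataset": ds, "sample_id": s,
                     "group": div.groups[s], "divergence": div.values[s]}
                )
            groups = sorted(counts.index)
            for g1, g2 in [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]:
                for quantity, values in [
                    ("divergence", div.values),
                    ("shannon", shannon.loc[labels.index]),
                ]:
                    res = rank_sum_test(
                        values[labels == g1].dropna(), values[labels == g2].dropna()
                    )
                    rank_rows.append(
                        {"factor": factor, "dataset": ds, "quantity": quantity,
                         "groups": f"{g1}|{g2}", "U": res.statistic,
                         "p_value": res.p_value, "method": res.method,
                         f"mean_{g1}": float(values[labels == g1].mean()),
                         f"mean_{g2}": float(values[labels == g2].mean())}
                    )
    divergence_table = pd.DataFrame(div_rows)
    rank_tests = pd.DataFrame(rank_rows)

    # --- separating coefficients and fold changes ---------------------
    coef_rows = []
    for factor in ("sampling_site", "tissue_source", "sex"):
        for ds, members in kept_meta.table.groupby("dataset"):
            labels = members[factor].dropna()
            labels = labels.loc[[s for s in labels.index if s in usable_ids]]
            counts = labels.value_counts()
            levels = sorted(counts.index[counts >= 2])
            for i, g1 in enumerate(levels):
                for g2 in levels[i + 1:]:
                    pair = labels[labels.isin([g1, g2])]
                    coefs = separating_coefficients(
                        rel.subset_samples(list(pair.index)), pair, reference=g1
                    )
                    for rank, (taxon, c) in enumerate(
                        coefs.top(params.top_k_coefficients).items(), start=1
                    ):
                        coef_rows.append(
                            {"factor": factor, "dataset": ds,
                             "groups": f"{g1}|{g2}", "rank": rank,
                             "taxon": taxon, "coefficient": c}
                        )
    coefficients = pd.DataFrame(coef_rows)

    # fold changes of the strongest source-separating taxa, including the
    # cross-dataset contrast between an all-PDX and an all-human cohort
    fold_rows = []
    if not coefficients.empty:
        src = coefficients[coefficients.factor == "tissue_source"]
        for (ds, pair), block in src.groupby(["dataset", "groups"]):
            g1, g2 = pair.split("|")
            members = kept_meta.table[kept_meta.table.dataset == ds]
            labels = members["tissue_source"].dropna()
            labels = labels.loc[[s for s in labels.index if s in usable_ids]]
            for taxon in block.sort_values("rank").taxon.head(5):
                fc = fold_change(rel.subset_samples(list(labels.index)),
                                 labels, taxon, groups=(g1, g2))
                fold_rows.append(
                    {"comparison": f"{ds}:{pair}", "taxon": taxon,
                     "ratio": fc.ratio, "mean_1": fc.mean_group1,
                     "mean_2": fc.mean_group2, "pseudo_count": fc.pseudo_count}
                )
        source_by_ds = kept_meta.table.groupby("dataset")["tissue_source"].agg(
            lambda s: s.dropna().unique().tolist()
        )
        pdx_ds = [d for d, v in source_by_ds.items() if v == ["pdx"]]
        human_ds = [d for d, v in source_by_ds.items() if v == ["human_tissue"]]
        if pdx_ds and human_ds and not src.empty:
            ds_labels_fc = kept_meta.table["dataset"]
            ds_labels_fc = ds_labels_fc[ds_labels_fc.isin([pdx_ds[0], human_ds[0]])]
            ds_labels_fc = ds_labels_fc.loc[
                [s for s in ds_labels_fc.index if s in usable_ids]
            ]
            for taxon in src.sort_values(["dataset", "rank"]).taxon.head(5):
                fc = fold_change(rel.subset_samples(list(ds_labels_fc.index)),
                                 ds_labels_fc, taxon,
                                 groups=(pdx_ds[0], human_ds[0]))
                fold_rows.append(
                    {"comparison": f"{pdx_ds[0]}(pdx) vs {human_ds[0]}(human)",
                     "taxon": taxon, "ratio": fc.ratio,
                     "mean_1": fc.mean_group1, "mean_2": fc.mean_group2,
                     "pseudo_count": fc.pseudo_count}
                )
    fold_changes = pd.DataFrame(fold_rows)

    # --- write artifacts -----------------------------------------------
    paths: dict[str, Path] = {}

    def save(name: str, frame: pd.DataFrame) -> None:
        paths[name] = out / name
        frame.to_csv(paths[name], sep="\t", index=False)

    save("qc_report.tsv", qc_frame)
    dom_out = dom_sample.reset_index(names="sample_id")
    dom_out.insert(1, "dataset", datasets.loc[dom_sample.index].to_numpy())
    save("domain_proportions.tsv", dom_out)

    paths["overlap.json"] = out / "overlap.json"
    paths["overlap.json"].write_text(json.dumps({
        "set_sizes": {k: len(v) for k, v in overlap.sets.items()},
        "union": len(overlap.union),
        "intersection": len(overlap.intersection),
        "shared_fraction": overlap.shared_fraction,
        "regions": {
            "+".join(sorted(sig)): len(m) for sig, m in overlap.regions.items()
        },
    }, indent=2, sort_keys=True))

    core_frame = pd.DataFrame({
        "genus": list(core_pooled.prevalence.index),
        "prevalence_pooled": core_pooled.prevalence.to_numpy(),
        "core_pooled": [g in set(core_pooled.core) for g in core_pooled.prevalence.index],
    })
    for ds, c in core_by_ds.items():
        core_frame[f"core_{ds}"] = [g in set(c.core) for g in core_frame["genus"]]
    core_frame["shared_core"] = [g in shared_core for g in core_frame["genus"]]
    save("core_taxa.tsv", core_frame[core_frame.prevalence_pooled > 0])

    n_axis = np.arange(1, acc.n_samples + 1)
    save("accumulation.tsv", pd.DataFrame({
        "n": n_axis,
        "mean_richness": acc.mean_curve(),
        "sd_richness": acc.sd_curve(),
        "fitted": heaps.predict(n_axis),
    }))
    paths["pan.json"] = out / "pan.json"
    paths["pan.json"].write_text(json.dumps({
        "kappa": heaps.kappa, "gamma": heaps.gamma, "r_squared": heaps.r_squared,
        "n_observed": acc.n_samples, "n_extrapolate": pan.n_extrapolate,
        "predicted_richness": pan.predicted_richness,
        "classification": "open" if pan.is_open else "closed",
        "open_margin": pan.open_margin, "n_reps": acc.n_reps, "seed": acc.seed,
    }, indent=2, sort_keys=True))

    save("diversity.tsv", pd.DataFrame({
        "sample_id": shannon.index,
        "dataset": datasets.loc[shannon.index].to_numpy(),
        "shannon": shannon.to_numpy(),
    }))
    save("permanova.tsv", permanova_table)
    save("divergence.tsv", divergence_table)
    save("rank_tests.tsv", rank_tests)
    save("coefficients.tsv", coefficients)
    save("fold_changes.tsv", fold_changes)

    # Fig-4-style stacked view: top-N phyla plus "Other", "None" retained
    phylum_rel = to_relative_abundance(aggregate(kept, taxonomy, "phylum"))
    collapsed = top_n_collapse(phylum_rel, params.top_n)
    phylum_out = collapsed.values.T.reset_index(names="sample_id")
    phylum_out.insert(1, "dataset", datasets.loc[collapsed.values.columns].to_numpy())
    save("phylum_top.tsv", phylum_out)
    write_distance_matrix(dm_all, out / "bray_curtis.tsv")
    paths["bray_curtis.tsv"] = out / "bray_curtis.tsv"

    paths["run.log"] = out / "run.log"
    paths["run.log"].write_text("\n".join(log) + "\n")

    return PipelineResult(
        qc=qc,
        domain_per_sample=dom_sample,
        domain_per_dataset=dom_dataset,
        overlap=overlap,
        core_pooled=core_pooled,
        core_by_dataset=core_by_ds,
        shared_core=shared_core,
        accumulation=acc,
        heaps=heaps,
        pan=pan,
        shannon=shannon,
        permanova_table=permanova_table,
        divergence_table=divergence_table,
        rank_tests=rank_tests,
        coefficients=coefficients,
        paths=paths,
    )
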