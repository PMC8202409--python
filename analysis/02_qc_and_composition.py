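"""QC the study and describe its compositional landscape.

Filters low-depth libraries, computes per-dataset bacteria/virus/archaea
proportions, the genus-level overlap across cohorts, and the top-phylum
stacked view; writes the tables under results/composition/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from pdacmicro.core_pan import overlap_sets
from pdacmicro.profiles import (
    aggregate,
    domain_proportions,
    qc_filter,
    read_profile,
    to_relative_abundance,
    top_n_collapse,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study", type=Path, default=Path("results/study"))
    parser.add_argument("--out", type=Path, default=Path("results/composition"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table, taxonomy, metadata = read_profile(
        args.study / "counts.tsv", args.study / "taxonomy.tsv",
        args.study / "metadata.tsv",
    )
    qc = qc_filter(table, 100)
    print(f"QC: {len(qc.zero_read_samples)} zero-read and "
          f"{len(qc.low_read_samples)} sub-100-read samples removed; "
          f"{qc.kept.n_samples} kept")
    kept = qc.kept

    per_sample, per_dataset = domain_proportions(
        kept, taxonomy, metadata.subset(kept.sample_ids)
    )
    per_dataset.to_csv(args.out / "domain_proportions_by_dataset.tsv", sep="\t")
    print("mean bacterial fraction by dataset:")
    print(per_dataset[("bacteria", "mean")].round(3).to_string())

    datasets = metadata.factor("dataset", kept.sample_ids)
    sets = {ds: set(kept.counts.index[kept.counts[m.index].sum(axis=1) > 0])
            for ds, m in datasets.groupby(datasets)}
    overlap = overlap_sets(sets)
    (args.out / "overlap.json").write_text(json.dumps({
        "set_sizes": {k: len(v) for k, v in overlap.sets.items()},
        "union": len(overlap.union),
        "shared": len(overlap.intersection),
        "shared_fraction": overlap.shared_fraction,
    }, indent=2, sort_keys=True))
    print(f"genera per dataset: "
          + ", ".join(f"{k}={len(v)}" for k, v in overlap.sets.items()))
    print(f"union {len(overlap.union)}, shared across all {len(overlap.intersection)}")

    phylum = top_n_collapse(to_relative_abundance(aggregate(kept, taxonomy, "phylum")), 10)
    phylum.values.T.to_csv(args.out / "phylum_top10.tsv", sep="\t")
    print(f"top-10 phylum table written; rows: {', '.join(phylum.values.index[:5])}, ...")


if __name__ == "__main__":
    main()
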