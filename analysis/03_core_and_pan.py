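"""Core microbiota and pan-microbiome estimation.

Applies the 0.2% detection / 20% prevalence core definition per cohort
and pooled, then estimates the pan-microbiome from 1,000 accumulation
replicates with a Heaps-law fit and an extrapolation to 2,000 samples.
Tables land under results/core_pan/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from pdacmicro.core_pan import (
    accumulation_curve,
    core_per_dataset,
    core_taxa,
    fit_heaps,
    pan_estimate,
)
from pdacmicro.profiles import qc_filter, read_profile, to_relative_abundance


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study", type=Path, default=Path("results/study"))
    parser.add_argument("--out", type=Path, default=Path("results/core_pan"))
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-extrapolate", type=int, default=2000)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table, _, metadata = read_profile(
        args.study / "counts.tsv", args.study / "taxonomy.tsv",
        args.study / "metadata.tsv",
    )
    kept = qc_filter(table, 100).kept
    rel = to_relative_abundance(kept)

    pooled = core_taxa(rel)
    by_ds = core_per_dataset(rel, metadata.factor("dataset", kept.sample_ids))
    shared = set.intersection(*[set(c.core) for c in by_ds.values()])
    pd.DataFrame({
        "genus": sorted(pooled.core),
        "prevalence": pooled.prevalence[sorted(pooled.core)].to_numpy(),
    }).to_csv(args.out / "core_pooled.tsv", sep="\t", index=False)
    print(f"core genera: pooled {pooled.n_core}; "
          + ", ".join(f"{k}={v.n_core}" for k, v in by_ds.items())
          + f"; shared across all cohorts {len(shared)}")

    acc = accumulation_curve(kept, n_reps=1000, seed=args.seed)
    fit = fit_heaps(acc.mean_curve())
    est = pan_estimate(fit, args.n_extrapolate, acc.n_samples)
    n = np.arange(1, acc.n_samples + 1)
    pd.DataFrame({
        "n": n, "mean_richness": acc.mean_curve(),
        "sd_richness": acc.sd_curve(), "fitted": fit.predict(n),
    }).to_csv(args.out / "accumulation.tsv", sep="\t", index=False)
    (args.out / "pan.json").write_text(json.dumps({
        "kappa": fit.kappa, "gamma": fit.gamma, "r_squared": fit.r_squared,
        "predicted_richness": est.predicted_richness,
        "n_extrapolate": est.n_extrapolate,
        "classification": "open" if est.is_open else "closed",
    }, indent=2, sort_keys=True))
    print(f"Heaps fit P(n) = {fit.kappa:.1f} * n^{fit.gamma:.3f} "
          f"(log-log R2 = {fit.r_squared:.3f})")
    print(f"pan-microbiome is {'open' if est.is_open else 'closed'}; predicted "
          f"richness at {est.n_extrapolate} samples: {est.predicted_richness:.0f}")


if __name__ == "__main__":
    main()
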