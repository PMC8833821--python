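"""Prognostic feature construction from the density table.

Turns raw Q_A into the cohort's prognostic features: percentile
categories (low / intermediate / high), two-level splits, inter-ROI
ratios dichotomized at the cohort median, the pooled entire-margin
density and the combined CD8/CD20 inner-margin group.  Reports the
fraction of patients with an immune-excluded phenotype (inner/outer
margin ratio < 0.1) per marker.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from immunomargin.scoring import score_cohort


def main(seed: int = 1, out: str = "results") -> None:
    run_dir = Path(out) / "run"
    density = pd.read_csv(run_dir / "density_table.csv")
    margin_counts = pd.read_csv(run_dir / "margin_counts.csv")
    features, cutpoints = score_cohort(density, margin_counts)
    features.to_csv(run_dir / "features.csv")
    (run_dir / "cutpoints.json").write_text(json.dumps(cutpoints, indent=2, default=float))

    print(f"built {features.shape[1]} features for {len(features)} patients")
    print("\nimmune-excluded phenotype (innM/outM Q_A ratio < 0.1):")
    for marker in ("CD3", "CD8", "CD20"):
        col = f"{marker}_immune_excluded"
        frac = features[col].mean()
        print(f"  {marker}: {frac:.0%} of patients")
    print("\nmedian cutpoints of the inner/outer margin ratios:")
    for marker in ("CD3", "CD8", "CD20"):
        med = cutpoints[f"{marker}_innM_over_outM_median_group"]["median"]
        print(f"  {marker} innM/outM median: {med:.3f}")
    groups = features["CD8_CD20_innM_group"].value_counts()
    print("\ncombined CD8/CD20 inner-margin groups:")
    print(groups.to_string())


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    main(args.seed, args.out)
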