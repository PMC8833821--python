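"""Simulate the synthetic study: tissue sections, detections, cohort.

Generates one tumor-bearing section (disc tumor in liver), a distant
non-tumor block, per-patient marker detections (CD3/CD8/CD20 centroid
tables) and a patient cohort with TTR/DFS/OS-generating outcomes, and
writes everything under the run directory for the downstream steps.
"""

import argparse
from pathlib import Path

from immunomargin import io as imio
from immunomargin.pipeline import RunConfig, synthesize_study


def main(seed: int = 1, out: str = "results/run") -> None:
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = RunConfig(n_patients=60, seed=seed)
    study = synthesize_study(config)

    imio.write_mask(out_dir / "section.tif", study["section"])
    imio.write_partition(out_dir, study["section"].partition, "section")
    part = study["section"].partition
    if part.nt_mask is not None:
        import numpy as np

        from immunomargin.geometry import LABEL_LIVER, TissueSection

        nt = TissueSection(
            labels=(part.nt_mask * LABEL_LIVER).astype(np.uint8),
            pixel_size_um=part.nt_pixel_size_um,
        )
        imio.write_mask(out_dir / "nt.tif", nt)
    study["cohort"].to_csv(out_dir / "cohort.csv", index=False)
    det_dir = out_dir / "detections"
    det_dir.mkdir(exist_ok=True)
    for pid, pts in study["detections"].items():
        imio.write_points(det_dir / f"{pid}.csv", pts)

    cohort = study["cohort"]
    print(f"simulated {config.n_patients} patients (seed {seed}) -> {out_dir}")
    print(
        f"  observed recurrences: {cohort['recurrence_months'].notna().sum()} "
        f"({cohort['recurrence_months'].notna().mean():.0%}), "
        f"deaths: {cohort['death_months'].notna().sum()} "
        f"({cohort['death_months'].notna().mean():.0%})"
    )
    n_pts = sum(len(p) for p in study["detections"].values())
    print(f"  cell profiles sampled across all patients/markers: {n_pts:,}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/run")
    args = ap.parse_args()
    main(args.seed, args.out)
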