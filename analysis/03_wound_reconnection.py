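"""Wound-healing series: LVD time course and reconnection day.

Simulates post-transection imaging for six animals with known reconnection
days, then runs the full imaging pipeline per day — averaged projection,
tubeness enhancement, segmentation, vascular density, and the two-node
connectivity test — and compares recovered reconnection days with truth.

Run from the repository root:  python analysis/03_wound_reconnection.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from nirflow.pumping import ROI
from nirflow.simulate import VesselGeometry, WoundSpec, simulate_wound_series
from nirflow.vasculature import (
    average_projection,
    compute_lvd,
    reconnection_day,
    segment,
)

SEED = 1
OUT = Path("results")

GEOM = VesselGeometry(
    centerline=((12.0, 12.0), (48.0, 40.0), (84.0, 84.0)),
    radius_px=2.5,
    image_shape=(96, 96),
)
ROI_A, ROI_B = ROI.circle(12, 12, 8), ROI.circle(84, 84, 8)
DAYS = list(range(1, 31, 3))
NORM_AREA_PX2 = 96.0 * 96.0  # uncalibrated: whole field as the ROI


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)
    lvd_rows, recon_rows = [], []
    for animal in range(6):
        truth_day = int(rng.integers(5, 25))
        spec = WoundSpec(
            node_roi_a=(12, 12, 8), node_roi_b=(84, 84, 8),
            truth_reconnection_day=truth_day, collateral_paths=2,
        )
        days = sorted(set(DAYS) | {truth_day})
        series = simulate_wound_series(spec, GEOM, days, seed=SEED * 100 + animal)
        masks = {}
        for day, (stack, _) in series.items():
            mask = segment(average_projection(stack))
            masks[day] = mask
            lvd = compute_lvd(mask, norm=NORM_AREA_PX2)
            lvd_rows.append({"animal": animal, "day": day,
                             "density": lvd.density})
        res = reconnection_day(masks, ROI_A, ROI_B)
        expected = min(d for d in days if d >= truth_day)
        recon_rows.append({
            "animal": animal,
            "truth_day": truth_day,
            "first_imaged_day_at_or_after_truth": expected,
            "recovered_day": res.reconnection_day,
            "exact": res.reconnection_day == expected,
        })

    lvd_df = pd.DataFrame(lvd_rows)
    recon_df = pd.DataFrame(recon_rows)
    lvd_df.to_csv(OUT / "lvd_timecourse.csv", index=False, float_format="%.6g")
    recon_df.to_csv(OUT / "reconnection_days.csv", index=False)

    print(recon_df.to_string(index=False))
    print(f"\nexact recovery: {recon_df.exact.sum()}/{len(recon_df)} animals")
    pre = lvd_df[lvd_df.day < 10].density.mean()
    post = lvd_df[lvd_df.day >= 20].density.mean()
    print(f"mean LVD early (day<10) {pre:.4f} vs late (day>=20) {post:.4f} "
          "(the restored segment spans only the small transection gap, so "
          "density changes little even as connectivity flips)")
    print(f"tables -> {OUT}/lvd_timecourse.csv, reconnection_days.csv")


if __name__ == "__main__":
    main()
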