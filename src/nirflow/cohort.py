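"""Cohort-level pumping-rate estimation.

Mirrors the baseline protocol: every animal is imaged on both flanks on two
days; each 3-minute trace is trough-counted and converted to pumps/min, the
four measurements are averaged per animal, and genotype summaries are taken
over animals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pumping import rate_from_trace


def estimate_cohort_rates(
    traces: dict,
    prominence_fraction: float = 0.15,
    min_separation_s: float = 2.0,
    smooth_s: float = 1.0,
    detrend_window_s: float = 0.0,
) -> pd.DataFrame:
    """Per-measurement rate estimates for a ``simulate_cohort`` trace dict.

    Returns a long table (genotype, animal, side, day, rate).
    """
    rows = []
    for (genotype, animal, side, day), (trace, _) in traces.items():
        res = rate_from_trace(
            trace,
            prominence_fraction=prominence_fraction,
            min_separation_s=min_separation_s,
            smooth_s=smooth_s,
            detrend_window_s=detrend_window_s,
        )
        rows.append(
            {
                "genotype": genotype,
                "animal": animal,
                "side": side,
                "day": day,
                "troughs": res.n_troughs,
                "frames": res.n_frames,
                "rate": res.rate,
            }
        )
    return pd.DataFrame(rows)


def animal_baselines(measurements: pd.DataFrame) -> pd.DataFrame:
    """Average the per-measurement rates within each animal (sides x days)."""
    return (
        measurements.groupby(["genotype", "animal"], sort=False)["rate"]
        .mean()
        .reset_index()
        .rename(columns={"rate": "baseline_rate"})
    )


def genotype_summary(baselines: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of animal baselines per genotype."""
    g = baselines.groupby("genotype", sort=False)["baseline_rate"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"count": "n"})


def cohort_mean(traces: dict) -> float:
    """Cohort mean pumping rate via the full per-trace pipeline."""
    per_animal = animal_baselines(estimate_cohort_rates(traces))
    return float(per_animal.baseline_rate.mean())
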