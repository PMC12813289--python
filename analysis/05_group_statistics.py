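"""Adaptive group comparisons of the estimated baseline pumping rates.

Reads the per-animal baselines of 02_pumping_rates.py (regenerating them
if absent), compares each transgenic genotype with WT through the
normality/variance decision tree, and runs the four-genotype omnibus
analysis with its post hoc matrix and compact letter display.

Run from the repository root:  python analysis/05_group_statistics.py
"""

from pathlib import Path

import pandas as pd

from nirflow import io
from nirflow.cohort import animal_baselines, estimate_cohort_rates
from nirflow.simulate import GENOTYPE_PRESETS, simulate_cohort
from nirflow.stats import GroupData, adaptive_multi_group, adaptive_two_group

SEED = 1
OUT = Path("results")


def _load_baselines() -> pd.DataFrame:
    path = OUT / "animal_baselines.csv"
    if path.exists():
        return pd.read_csv(path)
    traces, _ = simulate_cohort(
        list(GENOTYPE_PRESETS.values()), n_per_genotype=6, seed=SEED
    )
    return animal_baselines(estimate_cohort_rates(traces))


def main() -> None:
    OUT.mkdir(exist_ok=True)
    baselines = _load_baselines()
    groups = {
        g: GroupData(g, sub.baseline_rate.to_numpy())
        for g, sub in baselines.groupby("genotype", sort=False)
    }

    report = {"two_group_vs_WT": {}, "multi_group": None}
    for name in ("bGH", "GHA", "GHRKO"):
        trace, result = adaptive_two_group(groups[name], groups["WT"])
        report["two_group_vs_WT"][name] = {
            "selected_test": trace.selected_test,
            "normal": trace.normal,
            "equal_variance": trace.equal_variance,
            "statistic": result.statistic,
            "p_value": result.p_value,
            "significant": result.significant,
        }
        print(f"{name} vs WT: {trace.selected_test:>11s}  "
              f"p = {result.p_value:.4f}"
              f"{'  *' if result.significant else ''}")

    omni, post, cld = adaptive_multi_group(list(groups.values()))
    report["multi_group"] = {
        "omnibus_test": omni.test,
        "statistic": omni.statistic,
        "p_value": omni.p_value,
        "posthoc": None if post is None else {
            "method": post.method,
            "labels": list(post.labels),
            "p_values": post.p_values.tolist(),
        },
        "cld": None if cld is None else cld.letters,
    }
    print(f"\nomnibus {omni.test}: statistic = {omni.statistic:.3f}, "
          f"p = {omni.p_value:.2e}")
    if cld is not None:
        print("letter display:",
              ", ".join(f"{g}:{s}" for g, s in cld.letters.items()),
              "(groups sharing a letter are not significantly different)")

    io.write_json(OUT / "group_statistics.json", report)
    print(f"report -> {OUT}/group_statistics.json")


if __name__ == "__main__":
    main()
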