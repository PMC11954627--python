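#!/usr/bin/env python
"""Group-level inference: window ANOVA, permutation companion, pointwise contrasts.

Writes results/experiment/report/ (ANOVA tables, pointwise comparisons, group
curves, figures, report.json) and prints a compact summary per channel: the
two-way group x distance ANOVA over 0-20 um and the group contrast at the mucus
peak (11 um), formatted as group mean +/- SD with the Welch p.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, experiment_config

from mucoprofiler.pipeline import stage_stats


def main() -> None:
    cfg = experiment_config()
    report = stage_stats(cfg)
    for channel, res in report["channels"].items():
        anova = res["anova"]
        print(f"\n{channel} (window {cfg.window_um[0]:g}-{cfg.window_um[1]:g} um):")
        print(
            f"  group effect:       F = {anova['group']['F']:.1f}, "
            f"p = {anova['group']['p']:.3g} "
            f"(permutation p = {res['permutation']['p_permutation']:.3g})"
        )
        print(
            f"  interaction:        F = {anova['interaction']['F']:.1f}, "
            f"p = {anova['interaction']['p']:.3g}"
        )
        at11 = [p for p in res["pointwise"] if abs(p["distance_um"] - 11.0) < 1.0]
        if at11:
            parts = [f"{p['group']}: {p['mean']:.2f} ± {p['sd']:.2f}" for p in at11]
            print(f"  at 11 um (mean ± SD): {', '.join(parts)}, Welch p = {at11[0]['p']:.3g}")
    print(f"\nreport bundle written to {RESULTS / 'report'}")


if __name__ == "__main__":
    main()
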