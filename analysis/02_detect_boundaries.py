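#!/usr/bin/env python
"""Detect the epithelial boundary on every field and score it against ground truth.

Writes results/experiment/boundaries/ and prints the per-field mean absolute
boundary error (pixels) versus the generator's true boundary chain.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, experiment_config

from mucoprofiler.boundary import boundary_mae
from mucoprofiler.pipeline import stage_boundary, _manifest


def main() -> None:
    cfg = experiment_config()
    stage_boundary(cfg)
    rows = []
    for _, rec in _manifest(RESULTS).iterrows():
        detected = pd.read_csv(RESULTS / "boundaries" / f"{rec['image_id']}_chain.csv")
        truth = pd.read_csv(RESULTS / "truth" / f"{rec['image_id']}_boundary.csv")
        mae = boundary_mae(detected.to_numpy(), truth.to_numpy())
        rows.append({"image_id": rec["image_id"], "group": rec["group"], "mae_px": mae})
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "boundaries" / "accuracy.csv", index=False, float_format="%.10g")
    print(table.to_string(index=False))
    print(f"\nmean boundary error: {table['mae_px'].mean():.2f} px "
          f"({table['mae_px'].mean() * 0.5:.2f} um)")


if __name__ == "__main__":
    main()
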