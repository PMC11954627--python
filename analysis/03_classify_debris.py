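#!/usr/bin/env python
"""Classify autofluorescent debris on every field and score against ground truth.

Writes results/experiment/debris/ and prints object-level precision/recall of the
broadband/oversize/fragment classifier versus the generator's debris masks.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, experiment_config

from mucoprofiler.debris import evaluate_debris_detection
from mucoprofiler.pipeline import stage_debris, _manifest


def main() -> None:
    cfg = experiment_config()
    stage_debris(cfg)
    rows = []
    for _, rec in _manifest(RESULTS).iterrows():
        pred = tifffile.imread(RESULTS / "debris" / f"{rec['image_id']}_mask.tif") > 0
        true = tifffile.imread(RESULTS / "truth" / f"{rec['image_id']}_debris.tif") > 0
        precision, recall = evaluate_debris_detection(pred, true)
        _, n_objects = ndi.label(pred, structure=np.ones((3, 3), bool))
        rows.append(
            {"image_id": rec["image_id"], "n_debris_called": n_objects,
             "precision": precision, "recall": recall}
        )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "debris" / "accuracy.csv", index=False, float_format="%.10g")
    print(table.to_string(index=False))
    print(f"\nmean precision {table['precision'].mean():.3f}, "
          f"mean recall {table['recall'].mean():.3f}")


if __name__ == "__main__":
    main()
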