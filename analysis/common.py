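"""Shared configuration for the analysis scripts: the reference experiment.

Two genotype groups (WT vs R451C), 5 animals per group, one 512x512 field per
animal at 0.5 um/pixel, mucus amplitude ratio 3, 20 debris objects per field,
default confocal noise. All scripts operate on results/experiment/.
"""

from pathlib import Path

from mucoprofiler.pipeline import RunConfig
from mucoprofiler.scene import default_scene_config

RESULTS = Path(__file__).resolve().parent.parent / "results" / "experiment"
SEED = 1


def experiment_config() -> RunConfig:
    cfg = RunConfig(out_dir=str(RESULTS), seed=SEED, n_per_group=5, effect=3.0)
    cfg.scene = default_scene_config()
    cfg.scene.debris.count = 20
    cfg.at_um = [0.5, 11.0]
    cfg.permutations = 5000
    return cfg
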