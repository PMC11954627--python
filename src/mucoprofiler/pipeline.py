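"""End-to-end pipeline: simulate (or load) -> boundary -> debris -> profile -> stats.

Every stage persists its outputs in open formats (TIFF masks, tidy CSV, JSON)
under the run's output directory, so any stage can be rerun in isolation from the
persisted artifacts of the previous ones, and two runs with the same config and
seed produce byte-identical CSV/JSON outputs.

Layout of a run directory::

    images/<id>.tif             rendered scenes (synthetic runs)
    truth/<id>_*.{tif,csv}      generator ground truth (synthetic runs)
    manifest.csv                image id / animal / group / path
    boundaries/<id>_{mask.tif,chain.csv,meta.json}
    debris/<id>_{mask.tif,objects.csv}
    profiles/{profiles.csv,animal_profiles.csv}
    report/{report.json,anova_<ch>.csv,pointwise_<ch>.csv,curves_<ch>.csv,<ch>.png}
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .boundary import BoundaryParams, EpithelialBoundary, detect_boundary
from .config import scene_config_from_dict, scene_config_to_dict
from .debris import DebrisParams, classify_debris, segment_luminal_objects
from .errors import ConfigurationError, MucoprofilerError
from .image import MultichannelImage, read_image, write_image
from .profiles import (
    ProfileError,
    aggregate_by_animal,
    bin_profile,
    compute_distance_field,
    extract_window,
    find_peak,
    frame_to_profiles,
    normalize_profile,
    profiles_to_frame,
)
from .scene import SceneConfig, default_scene_config, make_group_experiment
from .stats import ProfileMatrix, compare_at_distance, permutation_group_test, two_way_anova

log = logging.getLogger("mucoprofiler")

STAGES = ("simulate", "boundary", "debris", "profile", "stats")

_CSV_KW = dict(index=False, float_format="%.10g")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; YAML-serialisable."""

    out_dir: str
    seed: int = 0
    # synthetic experiment (used when `images` is empty)
    scene: SceneConfig = field(default_factory=default_scene_config)
    n_per_group: int = 5
    effect: float = 3.0
    groups: tuple[str, str] = ("WT", "R451C")
    # real-image mode: list of {path, image_id, animal, group}
    images: list = field(default_factory=list)
    # channel roles
    dapi_channel: str = "DAPI"
    signal_channels: list = field(default_factory=lambda: ["MUC2", "EUB338"])
    segmentation_channels: list | None = None  # default: DAPI + non-mucus signals
    mucus_channel: str = "MUC2"
    # stage parameters
    boundary_params: BoundaryParams = field(default_factory=BoundaryParams)
    debris_params: DebrisParams = field(default_factory=DebrisParams)
    bin_um: float = 1.0
    range_um: tuple[float, float] = (0.0, 100.0)
    window_um: tuple[float, float] = (0.0, 20.0)
    at_um: list = field(default_factory=lambda: [0.5, 11.5])
    permutations: int = 2000
    make_figures: bool = True

    def validate(self) -> None:
        if not self.dapi_channel:
            raise ConfigurationError("dapi_channel: a DAPI channel name is required")
        if not self.signal_channels:
            raise ConfigurationError("signal_channels: need at least one")
        if self.images:
            for rec in self.images:
                if not Path(rec["path"]).exists():
                    raise ConfigurationError(f"images: {rec['path']} does not exist")
        else:
            self.scene.validate()
            if self.n_per_group < 1:
                raise ConfigurationError("n_per_group: must be >= 1")

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "scene": scene_config_to_dict(self.scene),
            "n_per_group": self.n_per_group,
            "effect": self.effect,
            "groups": list(self.groups),
            "images": list(self.images),
            "dapi_channel": self.dapi_channel,
            "signal_channels": list(self.signal_channels),
            "segmentation_channels": self.segmentation_channels,
            "mucus_channel": self.mucus_channel,
            "boundary_params": dataclasses.asdict(self.boundary_params),
            "debris_params": dataclasses.asdict(self.debris_params),
            "bin_um": self.bin_um,
            "range_um": list(self.range_um),
            "window_um": list(self.window_um),
            "at_um": list(self.at_um),
            "permutations": self.permutations,
            "make_figures": self.make_figures,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        return cls(
            out_dir=d["out_dir"],
            seed=d.get("seed", 0),
            scene=scene_config_from_dict(d["scene"]) if "scene" in d else default_scene_config(),
            n_per_group=d.get("n_per_group", 5),
            effect=d.get("effect", 3.0),
            groups=tuple(d.get("groups", ("WT", "R451C"))),
            images=list(d.get("images", [])),
            dapi_channel=d.get("dapi_channel", "DAPI"),
            signal_channels=list(d.get("signal_channels", ["MUC2", "EUB338"])),
            segmentation_channels=d.get("segmentation_channels"),
            mucus_channel=d.get("mucus_channel", "MUC2"),
            boundary_params=BoundaryParams(**d.get("boundary_params", {})),
            debris_params=DebrisParams(**d.get("debris_params", {})),
            bin_um=d.get("bin_um", 1.0),
            range_um=tuple(d.get("range_um", (0.0, 100.0))),
            window_um=tuple(d.get("window_um", (0.0, 20.0))),
            at_um=list(d.get("at_um", [0.5, 11.5])),
            permutations=d.get("permutations", 2000),
            make_figures=d.get("make_figures", True),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# small I/O helpers

def _write_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, mask.astype(np.uint8) * 255, photometric="minisblack")


def _read_mask(path) -> np.ndarray:
    return tifffile.imread(path) > 0


def _json_dump(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=2, default=str) + "\n")


def _load_boundary(out: Path, image_id: str) -> EpithelialBoundary:
    mask = _read_mask(out / "boundaries" / f"{image_id}_mask.tif")
    chain = pd.read_csv(out / "boundaries" / f"{image_id}_chain.csv")
    meta = json.loads((out / "boundaries" / f"{image_id}_meta.json").read_text())
    return EpithelialBoundary(
        tissue_mask=mask,
        boundary_coords=chain[["row", "col"]].to_numpy(dtype=np.intp),
        luminal_side=meta["luminal_side"],
        provenance=meta["provenance"],
    )


def _manifest(out: Path) -> pd.DataFrame:
    path = out / "manifest.csv"
    if not path.exists():
        raise MucoprofilerError("missing upstream artifact: manifest.csv (run 'simulate' first)")
    frame = pd.read_csv(path)
    # synthetic-run paths are stored relative to the run directory
    frame["path"] = [p if Path(p).is_absolute() else str(out / p) for p in frame["path"]]
    return frame


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: RunConfig) -> pd.DataFrame:
    """Render the synthetic experiment (or register real input images) and write
    the image manifest."""
    out = Path(cfg.out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    if cfg.images:
        for rec in cfg.images:
            rows.append(
                {
                    "image_id": rec.get("image_id", Path(rec["path"]).stem),
                    "animal": rec["animal"],
                    "group": rec["group"],
                    "path": rec["path"],
                }
            )
    else:
        (out / "truth").mkdir(exist_ok=True)
        records = make_group_experiment(
            cfg.scene, cfg.n_per_group, effect=cfg.effect, seed=cfg.seed, groups=cfg.groups
        )
        for r in records:
            path = out / "images" / f"{r.image_id}.tif"
            write_image(path, r.image)
            _write_mask(out / "truth" / f"{r.image_id}_tissue.tif", r.truth.tissue_mask)
            _write_mask(out / "truth" / f"{r.image_id}_debris.tif", r.truth.debris_mask)
            pd.DataFrame(r.truth.boundary_coords, columns=["row", "col"]).to_csv(
                out / "truth" / f"{r.image_id}_boundary.csv", **_CSV_KW
            )
            rows.append(
                {
                    "image_id": r.image_id,
                    "animal": r.animal,
                    "group": r.group,
                    "path": str(path.relative_to(out)),
                }
            )
        log.info("simulate: rendered %d scenes", len(records))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", **_CSV_KW)
    return manifest


def stage_boundary(cfg: RunConfig) -> None:
    """Detect the epithelial boundary on every image and persist mask + chain."""
    out = Path(cfg.out_dir)
    (out / "boundaries").mkdir(parents=True, exist_ok=True)
    for _, row in _manifest(out).iterrows():
        image = read_image(row["path"])
        try:
            b = detect_boundary(
                image.channel(cfg.dapi_channel), cfg.boundary_params, image.pixel_size
            )
        except MucoprofilerError as exc:
            raise MucoprofilerError(f"boundary stage failed on {row['image_id']}: {exc}") from exc
        _write_mask(out / "boundaries" / f"{row['image_id']}_mask.tif", b.tissue_mask)
        pd.DataFrame(b.boundary_coords, columns=["row", "col"]).to_csv(
            out / "boundaries" / f"{row['image_id']}_chain.csv", **_CSV_KW
        )
        _json_dump(
            out / "boundaries" / f"{row['image_id']}_meta.json",
            {
                "luminal_side": b.luminal_side,
                "provenance": b.provenance,
                "params": dataclasses.asdict(cfg.boundary_params),
            },
        )
        log.info("boundary: %s done (%d chain pixels)", row["image_id"], len(b.boundary_coords))


def stage_debris(cfg: RunConfig) -> None:
    """Segment and classify luminal debris on every image."""
    out = Path(cfg.out_dir)
    (out / "debris").mkdir(parents=True, exist_ok=True)
    for _, row in _manifest(out).iterrows():
        image = read_image(row["path"])
        b = _load_boundary(out, row["image_id"])
        seg_channels = cfg.segmentation_channels or [cfg.dapi_channel] + [
            c for c in cfg.signal_channels if c != cfg.mucus_channel
        ]
        try:
            labels, thresholds = segment_luminal_objects(
                image, b.tissue_mask, cfg.debris_params, channel_names=seg_channels
            )
            dm = classify_debris(labels, image, thresholds, cfg.debris_params, cfg.dapi_channel)
        except MucoprofilerError as exc:
            raise MucoprofilerError(f"debris stage failed on {row['image_id']}: {exc}") from exc
        _write_mask(out / "debris" / f"{row['image_id']}_mask.tif", dm.mask)
        dm.objects.to_csv(out / "debris" / f"{row['image_id']}_objects.csv", **_CSV_KW)
        log.info(
            "debris: %s done (%d objects, %d debris)",
            row["image_id"], len(dm.objects), int(dm.objects["debris"].sum()),
        )


def stage_profile(cfg: RunConfig) -> pd.DataFrame:
    """Distance-binned profiles per image and channel; per-animal aggregates."""
    out = Path(cfg.out_dir)
    (out / "profiles").mkdir(parents=True, exist_ok=True)
    per_image = []
    for _, row in _manifest(out).iterrows():
        image = read_image(row["path"])
        b = _load_boundary(out, row["image_id"])
        debris_mask = _read_mask(out / "debris" / f"{row['image_id']}_mask.tif")
        field_ = compute_distance_field(b, image.shape, image.pixel_size)
        for ch in cfg.signal_channels:
            try:
                raw = bin_profile(
                    image.channel(ch),
                    field_,
                    cfg.bin_um,
                    cfg.range_um,
                    exclude_mask=debris_mask,
                    channel_name=ch,
                    image_id=str(row["image_id"]),
                    animal=str(row["animal"]),
                    group=str(row["group"]),
                )
            except ProfileError as exc:
                raise MucoprofilerError(
                    f"profile stage failed on {row['image_id']}/{ch}: {exc}"
                ) from exc
            per_image.append(raw)
            per_image.append(normalize_profile(raw))
    frame = profiles_to_frame(per_image)
    frame.to_csv(out / "profiles" / "profiles.csv", **_CSV_KW)

    per_animal = []
    for ch in cfg.signal_channels:
        per_animal.extend(
            aggregate_by_animal(
                [p for p in per_image if p.normalized and p.channel == ch]
            )
        )
    animal_frame = profiles_to_frame(per_animal)
    animal_frame.to_csv(out / "profiles" / "animal_profiles.csv", **_CSV_KW)
    log.info("profile: %d image profiles, %d animal profiles", len(per_image), len(per_animal))
    return animal_frame


def _plot_curves(curves: pd.DataFrame, channel: str, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    for group, sub in curves.groupby("group"):
        ax.plot(sub["distance_um"], sub["mean"], label=str(group))
        ax.fill_between(
            sub["distance_um"], sub["mean"] - sub["sem"], sub["mean"] + sub["sem"], alpha=0.25
        )
    ax.set_xlabel("distance from epithelium (um)")
    ax.set_ylabel("normalized density")
    ax.set_title(channel)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def stage_stats(cfg: RunConfig) -> dict:
    """Window ANOVA (parametric + permutation), pointwise comparisons, report bundle."""
    out = Path(cfg.out_dir)
    report_dir = out / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    path = out / "profiles" / "animal_profiles.csv"
    if not path.exists():
        raise MucoprofilerError("missing upstream artifact: profiles/animal_profiles.csv")
    animal_frame = pd.read_csv(path)

    report: dict = {
        "provenance": {
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "version": __version__,
            "window_um": list(cfg.window_um),
            "bin_um": cfg.bin_um,
        },
        "channels": {},
    }
    for ch in cfg.signal_channels:
        profs = [p for p in frame_to_profiles(animal_frame) if p.channel == ch]
        if not profs:
            raise MucoprofilerError(f"missing upstream artifact: no profiles for channel {ch}")
        full_matrix = ProfileMatrix.from_profiles(profs, channel=ch)
        windowed = [extract_window(p, *cfg.window_um) for p in profs]
        matrix = ProfileMatrix.from_profiles(windowed, channel=ch)

        anova = two_way_anova(matrix)
        anova.reset_index(names="effect").to_csv(report_dir / f"anova_{ch}.csv", **_CSV_KW)
        perm = permutation_group_test(matrix, cfg.permutations, seed=cfg.seed)

        pointwise = []
        for d in cfg.at_um:
            c = compare_at_distance(full_matrix, d)
            for g, s in c.group_stats.items():
                pointwise.append(
                    {
                        "distance_um": d, "group": g, "mean": s["mean"], "sd": s["sd"],
                        "n": s["n"], "t": c.statistic, "p": c.p, "method": c.method,
                    }
                )
        pd.DataFrame(pointwise).to_csv(report_dir / f"pointwise_{ch}.csv", **_CSV_KW)

        curves = []
        for group in sorted(set(full_matrix.groups)):
            sub = full_matrix.values[full_matrix.groups == group]
            mean = np.nanmean(sub, axis=0)
            sem = np.nanstd(sub, axis=0, ddof=1) / np.sqrt(sub.shape[0])
            for j, d in enumerate(full_matrix.bin_centers):
                curves.append(
                    {"group": group, "distance_um": d, "mean": mean[j], "sem": sem[j]}
                )
        curves = pd.DataFrame(curves)
        curves.to_csv(report_dir / f"curves_{ch}.csv", **_CSV_KW)
        if cfg.make_figures:
            _plot_curves(curves, ch, report_dir / f"{ch}.png")

        peaks = {}
        for group in sorted(set(full_matrix.groups)):
            sub = full_matrix.values[full_matrix.groups == group]
            gmean = np.nanmean(sub, axis=0)
            k = int(np.nanargmax(gmean))
            peaks[group] = {
                "distance_um": float(full_matrix.bin_centers[k]),
                "value": float(gmean[k]),
            }
        report["channels"][ch] = {
            "anova": {
                eff: {k: (None if pd.isna(v) else float(v)) for k, v in anova.loc[eff].items()}
                for eff in anova.index
            },
            "permutation": perm,
            "pointwise": pointwise,
            "group_peaks": peaks,
        }
        log.info(
            "stats: %s group p=%.3g (permutation p=%.3g)",
            ch, report["channels"][ch]["anova"]["group"]["p"], perm["p_permutation"],
        )
    _json_dump(report_dir / "report.json", report)
    return report


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in order; returns the final report dict (if the
    stats stage ran) or an empty dict."""
    cfg.validate()
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages {sorted(unknown)}")
    Path(cfg.out_dir).mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(Path(cfg.out_dir) / "run_config.yaml")
    report: dict = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        log.info("=== stage %s ===", stage)
        if stage == "simulate":
            stage_simulate(cfg)
        elif stage == "boundary":
            stage_boundary(cfg)
        elif stage == "debris":
            stage_debris(cfg)
        elif stage == "profile":
            stage_profile(cfg)
        elif stage == "stats":
            report = stage_stats(cfg)
    return report
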