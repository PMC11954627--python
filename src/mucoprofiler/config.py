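"""YAML (de)serialisation of scene and run configurations."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .boundary import BoundaryParams
from .debris import DebrisParams
from .errors import ConfigurationError
from .scene import (
    BoundaryGeometry,
    ChannelModel,
    DebrisSimParams,
    IntensityFn,
    NoiseParams,
    NucleiParams,
    SceneConfig,
)

__all__ = [
    "scene_config_to_dict",
    "scene_config_from_dict",
    "load_scene_config",
    "save_scene_config",
]


def _intensity_to_dict(fn: IntensityFn | None):
    if fn is None:
        return None
    return {"kind": fn.kind, "params": dict(fn.params)}


def _intensity_from_dict(d) -> IntensityFn | None:
    if d is None:
        return None
    return IntensityFn(d["kind"], dict(d.get("params", {})))


def scene_config_to_dict(cfg: SceneConfig) -> dict:
    out = dataclasses.asdict(cfg)
    out["image_shape"] = list(cfg.image_shape)
    out["channels"] = []
    for ch in cfg.channels:
        d = dataclasses.asdict(ch)
        d["intensity_fn"] = _intensity_to_dict(ch.intensity_fn)
        d["background_fn"] = _intensity_to_dict(ch.background_fn)
        out["channels"].append(d)
    return out


def scene_config_from_dict(d: dict) -> SceneConfig:
    d = dict(d)
    try:
        channels = [
            ChannelModel(
                name=c["name"],
                kind=c["kind"],
                intensity_fn=_intensity_from_dict(c["intensity_fn"]),
                amplitude=c["amplitude"],
                background_fn=_intensity_from_dict(c.get("background_fn")),
                background_amplitude=c.get("background_amplitude", 0.0),
                puncta_intensity=c.get("puncta_intensity", 120.0),
                puncta_sigma_um=c.get("puncta_sigma_um", 0.75),
                allow_tissue_side=c.get("allow_tissue_side", False),
            )
            for c in d.get("channels", [])
        ]
        cfg = SceneConfig(
            image_shape=tuple(d.get("image_shape", (512, 512))),
            pixel_size=d.get("pixel_size", 0.5),
            boundary=BoundaryGeometry(**d.get("boundary", {})),
            nuclei=NucleiParams(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in d.get("nuclei", {}).items()
                }
            ),
            channels=channels,
            debris=DebrisSimParams(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in d.get("debris", {}).items()
                }
            ),
            noise=NoiseParams(**d.get("noise", {})),
            dapi_tissue_background=d.get("dapi_tissue_background", 30.0),
            seed=d.get("seed", 0),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"bad scene config: {exc}") from exc
    cfg.validate()
    return cfg


def save_scene_config(path, cfg: SceneConfig) -> None:
    Path(path).write_text(yaml.safe_dump(scene_config_to_dict(cfg), sort_keys=True))


def load_scene_config(path) -> SceneConfig:
    return scene_config_from_dict(yaml.safe_load(Path(path).read_text()))


def boundary_params_from_dict(d: dict | None) -> BoundaryParams:
    return BoundaryParams(**(d or {}))


def debris_params_from_dict(d: dict | None) -> DebrisParams:
    return DebrisParams(**(d or {}))
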