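"""YAML configuration loading.

A config file describes a setup and/or a comparison run, e.g.::

    collimator: {type: kes, slit_width: 6.0, opening_angle: 53.13, thickness: 40.0}
    camera: {n_slabs: 20, slab_pitch: 4.0, n_rows: 2}
    d1: 220.0
    d2: 176.0
    material: {density: 17.0, mu_linear: 0.70}
    run:
      energies: [100, 160, 230]
      camera_mode: full
      n_samples: 1000
      master_seed: 12345

Only the keys present are overridden; everything else keeps the prototype
defaults.
"""

from __future__ import annotations

from dataclasses import fields as dc_fields

import yaml

from .geometry import (
    CameraSpec,
    KESSpec,
    MPSSpec,
    MaterialProps,
    SetupGeometry,
    default_kes_setup,
    default_mps_setup,
)
from .pipeline import RunMatrixConfig
from .synthetic_data import BackgroundModel

__all__ = ["load_config", "setup_from_config", "run_config_from_dict"]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def _build(cls, data: dict, **extra):
    allowed = {f.name for f in dc_fields(cls)}
    kwargs = {k: v for k, v in dict(data, **extra).items() if k in allowed}
    return cls(**kwargs)


def setup_from_config(cfg: dict) -> SetupGeometry:
    """Build a SetupGeometry from a config dict (prototype defaults filled in)."""
    coll_cfg = dict(cfg.get("collimator", {}))
    ctype = coll_cfg.pop("type", "kes").lower()
    material = _build(MaterialProps, cfg.get("material", {}))
    base = default_kes_setup(material=material) if ctype == "kes" else default_mps_setup(material=material)

    collimator = _build(
        KESSpec if ctype == "kes" else MPSSpec, coll_cfg, material=material
    )
    camera = _build(CameraSpec, cfg.get("camera", {}))
    return SetupGeometry(
        collimator=collimator,
        camera=camera,
        d1=float(cfg.get("d1", base.d1)),
        d2=float(cfg.get("d2", base.d2)),
        fov_center=float(cfg.get("fov_center", 0.0)),
    )


def run_config_from_dict(cfg: dict) -> RunMatrixConfig:
    run = dict(cfg.get("run", cfg))
    bg = _build(BackgroundModel, cfg.get("background", {}))
    for key in ("energies", "collimators", "alignments", "n_protons_grid"):
        if key in run:
            run[key] = tuple(run[key])
    return _build(RunMatrixConfig, run, background=bg)
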