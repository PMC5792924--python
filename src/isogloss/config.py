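"""Structured (YAML) configuration for landscapes and parameters.

Recognized keys::

    sigma, gamma, beta, alpha, tau        # model parameters
    cell_size, shape, boundary_mode       # raster geometry
    cities:                                # list of city blocks
      - center: [x, y]
        omega: 10
        radius: 10
        background_radius: 50             # optional
    rho0                                   # background density level
    density_mode                           # with_hinterland | bare_gaussian | capped
    metropolitan:
      c: 1.0                               # core-radius factor
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .core import (
    CitySpec,
    MetropolitanField,
    ModelParams,
    PopulationRaster,
    build_city_density,
    metropolitan_field,
)

__all__ = ["load_config", "params_from_config", "landscape_from_config", "dump_config"]


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def params_from_config(cfg: dict[str, Any]) -> ModelParams:
    kw = {k: float(cfg[k]) for k in ("sigma", "gamma", "beta", "alpha", "tau") if k in cfg}
    return ModelParams(**kw)


def cities_from_config(cfg: dict[str, Any]) -> list[CitySpec]:
    out = []
    for c in cfg.get("cities", []):
        out.append(
            CitySpec(
                center=tuple(c["center"]),
                omega=float(c["omega"]),
                radius=float(c["radius"]),
                background_radius=(
                    float(c["background_radius"]) if "background_radius" in c else None
                ),
            )
        )
    return out


def landscape_from_config(
    cfg: dict[str, Any],
) -> tuple[PopulationRaster, MetropolitanField | None, ModelParams]:
    params = params_from_config(cfg)
    cities = cities_from_config(cfg)
    shape = tuple(cfg.get("shape", (101, 101)))
    raster = build_city_density(
        cities,
        shape=shape,  # type: ignore[arg-type]
        cell_size=float(cfg.get("cell_size", 1.0)),
        background=cfg.get("rho0"),
        mode=cfg.get("density_mode", "with_hinterland"),
        boundary_mode=cfg.get("boundary_mode", "closed"),
    )
    M = None
    metro = cfg.get("metropolitan")
    if metro is not None:
        M = metropolitan_field(raster, cities, float(metro.get("c", 1.0)))
    return raster, M, params


def dump_config(cfg: dict[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
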