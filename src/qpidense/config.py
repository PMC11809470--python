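"""Physical constants and run configuration.

Units are fixed package-wide and never inferred: OPD in nm, lengths in μm,
pressure in MPa, dry-mass density in mg/ml, refractive index dimensionless.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

__all__ = [
    "OpticalConstants",
    "DeformationCalibration",
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
]


@dataclass(frozen=True)
class OpticalConstants:
    """Refractive indices and the refractive increment used by every conversion.

    ``n_media``/``n_pdms``/``n_water`` come from Abbe refractometry of the
    culture medium, cured PDMS and distilled water at the growth temperature;
    ``alpha`` is the refractive increment of proteins and nucleic acids
    (ml/g), the slope of RI versus dry-mass concentration.
    """

    n_media: float = 1.336
    n_pdms: float = 1.405
    n_water: float = 1.332
    alpha: float = 0.190  # ml/g
    temperature_C: float = 30.0

    def __post_init__(self) -> None:
        if not (self.n_pdms > self.n_media > self.n_water > 1.0):
            raise ValueError(
                "refractive indices must satisfy n_pdms > n_media > n_water > 1; "
                f"got n_pdms={self.n_pdms}, n_media={self.n_media}, "
                f"n_water={self.n_water}"
            )
        if self.alpha <= 0:
            raise ValueError(f"refractive increment alpha must be > 0, got {self.alpha}")


@dataclass(frozen=True)
class DeformationCalibration:
    """Lateral PDMS wall deformation per unit growth-induced pressure.

    ``k`` (μm/MPa) converts the measured chamber-wall displacement into the
    growth-induced pressure exerted by the packed cells.
    """

    k: float = 8.2  # μm/MPa

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"deformation calibration k must be > 0, got {self.k}")


@dataclass
class RunConfig:
    """Everything a pipeline run needs: constants, scene sizes, flags, seed.

    The synthetic-scene parameters default to the study conditions of the
    experiment the pipeline emulates: an asynchronous plate population of 91
    cells with RI 1.384 ± 0.004 and height 3.94 ± 0.50 μm, and a 9.2 μm
    chamber series of 45 pressurised observations anchored at a true nominal
    osmotic pressure of 1.55 MPa.
    """

    constants: OpticalConstants = field(default_factory=OpticalConstants)
    deformation: DeformationCalibration = field(default_factory=DeformationCalibration)
    seed: int = 0

    # imaging geometry (the instrument's pixel size is not a physical constant
    # of the method, so it is configurable, never hard-coded downstream)
    pixel_size_um: float = 0.1
    noise_sd_nm: float = 10.0

    # plate scene
    n_cells: int = 91
    ri_mean: float = 1.384
    ri_sd: float = 0.004
    height_mean_um: float = 3.94
    height_sd_um: float = 0.50

    # chamber series
    pi_c0_true_mpa: float = 1.55
    chamber_height0_um: float = 9.2
    chamber_height_slope_um_per_mpa: float = 0.5
    gip_max_mpa: float = 0.6
    n_chamber_obs: int = 45
    n_gip_zero_obs: int = 3
    packing_fraction_gip0: float = 0.8

    # analysis flags
    density_baseline: str = "media"  # "media" or "water"
    exclude_gip_zero: bool = True
    ci_method: str = "bootstrap"  # "bootstrap" or "delta"
    n_boot: int = 2000
    min_region_area_px: int = 30

    # paths (optional; pipeline writes here when set)
    output_dir: str | None = None


def _as_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    return d


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_as_dict(cfg), sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    constants = OpticalConstants(**raw.pop("constants", {}))
    deformation = DeformationCalibration(**raw.pop("deformation", {}))
    known = {f.name for f in RunConfig.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return RunConfig(constants=constants, deformation=deformation, **raw)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the full configuration, for provenance records."""
    canonical = yaml.safe_dump(_as_dict(cfg), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def baseline_ri(cfg: RunConfig) -> float:
    """Resolve the density-conversion baseline named in the config."""
    if cfg.density_baseline == "media":
        return cfg.constants.n_media
    if cfg.density_baseline == "water":
        return cfg.constants.n_water
    raise ValueError(f"density_baseline must be 'media' or 'water', got {cfg.density_baseline!r}")
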