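"""Pipeline configuration with the study's printed defaults.

Every tunable analysis parameter has a default equal to the published
setting where one exists (camera pixel 129 nm, 70-ms exposure, 10-nm
reconstruction pixel, FWHM factor 2.35, DBSCAN ε/MinPts pairs 40/6 and
50/40, fixed 1/7 FRC threshold, 0.02 µm² s⁻¹ mobility split, 24 subunits,
degrees of labeling 0.7 ± 0.15 and 0.95 ± 0.05, histogram bins
75/100/100/1000).  Configs round-trip through YAML; CLI flags override
file values; all randomness flows from one root seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "PipelineConfig"]

DEFAULTS: dict = {
    "global": {
        "pixel_size_nm": 129.0,
        "exposure_ms": 70.0,
        "seed": 0,
        "output_dir": "smlmq_out",
    },
    "drift": {"min_presence": 0.9, "gather_radius_nm": 500.0, "smooth_window": 10},
    "nena": {"search_radius_nm": 500.0, "hist_range_nm": 200.0, "bin_nm": 2.0},
    "merge": {"max_gap_frames": 0},
    "render": {"pixel_nm": 10.0},
    "fire": {"threshold": 1.0 / 7.0, "image_scale": 2048},
    "filaments": {
        "thickness_px": None,  # use each polyline's own thickness
        "fwhm_factor": 2.35,
        "width_bin_nm": 75.0,
        "category_edges_nm": [0.0, 75.0, 150.0],
        "section_um": 10.0,
        "per_section": 15,
    },
    "clusters": {
        "lc3b": {"eps_nm": 50.0, "min_pts": 40, "hist_bin_nm": 100.0},
        "nanobody": {"eps_nm": 40.0, "min_pts": 6},
    },
    "stoich": {
        "n_subunits": 24,
        "dol_nanobody": 0.7,
        "dol_nanobody_sd": 0.15,
        "dol_snap": 0.95,
        "dol_snap_sd": 0.05,
        "calib_bin_ad": 100.0,
        "report_bin_ad": 1000.0,
        "blink_window": 100,
        "min_blinks": 2,
    },
    "tracking": {
        "dt_s": 0.04,
        "max_disp_nm": 500.0,
        "max_gap_frames": 1,
        "min_steps": 5,
        "n_fit_points": 4,
        "mobility_threshold": 0.02,
    },
}


def _deep_update(base: dict, override: dict) -> dict:
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


@dataclass
class PipelineConfig:
    params: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    @classmethod
    def load(cls, path: str | Path | None = None, overrides: dict | None = None):
        params = copy.deepcopy(DEFAULTS)
        if path is not None:
            with open(path) as fh:
                loaded = yaml.safe_load(fh) or {}
            _deep_update(params, loaded)
        if overrides:
            _deep_update(params, overrides)
        return cls(params)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.params, fh, sort_keys=True)

    def __getitem__(self, key: str):
        return self.params[key]

    @property
    def seed(self) -> int:
        return int(self.params["global"]["seed"])
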