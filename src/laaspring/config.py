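"""Run-wide configuration with the defaults used throughout the pipeline.

Every tunable of the mapping/simulation pipeline lives here as a flat,
serializable key set so a whole run can be reproduced from one YAML file.
Defaults follow the published protocol where one exists (HU thresholds,
parameter grids, rupture threshold, iteration count, fit window) and are
otherwise the package's documented choices (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Tuple

import yaml


@dataclass
class RunConfig:
    # HU thresholding
    hu_laa_threshold: float = -960.0      # pixels strictly below are LAA
    hu_high_threshold: float = -500.0     # pixels strictly above are high attenuation

    # network
    lattice_edge: float = 1.0             # honeycomb edge length, pixels
    prestress_ratio: float = 1.25         # initial length / rest length (> 1)
    tension_only: bool = False            # linear springs push back when compressed
    fixed_band: float = 1.0               # rim width (in lattice edges) of fixed nodes

    # equilibrium solver
    solver_method: str = "deterministic"  # "deterministic" | "anneal"
    force_tolerance: float = 1e-4         # residual net force, units k*lattice_edge
    anneal_sweeps: int = 500
    anneal_cooling: float = 0.995
    anneal_sigma: float = 0.1             # proposal std, units of lattice_edge
    anneal_t0_scale: float = 0.1          # T0 = scale * E_init / n_springs

    # CSAM
    csam_samples_min: int = 64            # minimum boundary sample count
    csam_theta0_grid: int = 360           # brute-force grid over [0, 2pi)
    csam_size_floor_px: int = 50          # clusters below bypass CSAM (NM behavior)

    # apparent-CT conversion
    binarize_fraction: float = 0.5        # of intact-network interior mean intensity
    render_smooth_sigma: float = 1.2      # px; smallest blur taming lattice moire

    # metrics
    dlocal_square_size: int = 10          # pixels per grid square (Eq.-10 partition)
    fit_range: Tuple[int, int] = (50, 1000)  # cluster-size window for exponent D

    # calibration experiment
    alpha_min: float = 0.5
    alpha_max: float = 1.0
    alpha_step: float = 0.02
    beta_min: float = 0.0
    beta_max: float = 0.3
    beta_step: float = 0.02
    size_ladder: Tuple[int, ...] = (50, 100, 200, 500, 1000, 2000, 5000)

    # progression
    force_fraction: float = 0.8           # rupture threshold, fraction of max force
    n_iterations: int = 10

    # randomness
    seed: int = 0

    def alpha_grid(self):
        import numpy as np
        n = int(round((self.alpha_max - self.alpha_min) / self.alpha_step)) + 1
        return np.round(np.linspace(self.alpha_min, self.alpha_max, n), 10)

    def beta_grid(self):
        import numpy as np
        n = int(round((self.beta_max - self.beta_min) / self.beta_step)) + 1
        return np.round(np.linspace(self.beta_min, self.beta_max, n), 10)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["fit_range"] = list(d["fit_range"])
        d["size_ladder"] = list(d["size_ladder"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        if "fit_range" in raw:
            raw["fit_range"] = tuple(raw["fit_range"])
        if "size_ladder" in raw:
            raw["size_ladder"] = tuple(raw["size_ladder"])
        return cls(**raw)


DEFAULT_CONFIG = RunConfig()
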