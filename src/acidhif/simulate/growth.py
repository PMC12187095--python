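"""Synthetic SRB-style growth plates drawn from the biphasic Hill model."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..survival import BiphasicHillParams, predict_growth


class DesignError(ValueError):
    pass


def default_ph_grid() -> np.ndarray:
    """The standard acid-sensitivity grid: pH 6.2 to 7.7 in 0.1 steps."""
    return np.round(np.arange(6.2, 7.7 + 1e-9, 0.1), 2)


DEFAULT_SURVIVAL_PARAMS = BiphasicHillParams(
    g_max=100.0, pk_up=6.6, n_up=2.0, pk_down=7.9, n_down=3.0
)


@dataclass(frozen=True)
class SurvivalSimSpec:
    """Plate simulation: truth curve, pH grid, replicates and noise.

    ``noise_sd`` is in percent-growth units (2 = 2% of maximal growth);
    ``absorbance_scale`` maps 100% growth to an SRB absorbance.
    """

    params: BiphasicHillParams = DEFAULT_SURVIVAL_PARAMS
    ph_grid: np.ndarray = field(default_factory=default_ph_grid)
    n_replicates: int = 3
    noise_sd: float = 2.0
    absorbance_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        grid = np.asarray(self.ph_grid, dtype=float)
        object.__setattr__(self, "ph_grid", grid)
        if np.any(grid < 5.0) or np.any(grid > 9.0):
            raise DesignError("ph_grid outside the physiological window [5, 9]")
        if len(np.unique(grid)) < 5:
            raise DesignError("need >= 5 distinct pH points (model has 5 parameters)")
        if self.n_replicates < 1 or self.noise_sd < 0:
            raise DesignError("n_replicates >= 1 and noise_sd >= 0 required")


def make_survival_plate(spec: SurvivalSimSpec) -> tuple[pd.DataFrame, BiphasicHillParams]:
    """Simulate an absorbance plate; returns (plate frame, truth params).

    absorbance = model prediction / 100 * scale + Gaussian noise.  The frame
    has columns ``replicate``, ``ph``, ``absorbance``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    pred = predict_growth(spec.params, spec.ph_grid)
    for rep in range(1, spec.n_replicates + 1):
        noise = rng.normal(0.0, spec.noise_sd, size=len(spec.ph_grid))
        absorb = (pred + noise) / 100.0 * spec.absorbance_scale
        rows.append(
            pd.DataFrame({"replicate": rep, "ph": spec.ph_grid, "absorbance": absorb})
        )
    return pd.concat(rows, ignore_index=True), spec.params
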