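"""Biphasic Hill-type modelling of growth versus medium pH.

Cell growth across a pH gradient typically rises through an acid-limited
flank and falls through an alkaline-limited flank.  The model used here is
the product of two Hill-type sigmoids in pH (equivalently, Hill functions of
[H+] with binding constants 10**-pk):

    G(pH) = g_max * S_up(pH) * S_down(pH)
    S_up(pH)   = 1 / (1 + 10**(n_up   * (pk_up  - pH)))
    S_down(pH) = 1 / (1 + 10**(n_down * (pH - pk_down)))

i.e. one activatory and one inhibitory interaction, each with a midpoint
(binding constant on the pH scale) and a Hill coefficient — four shape
parameters plus a maximum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares


class DegenerateInputError(ValueError):
    """Raised when input data carry no usable signal (e.g. all-zero plate)."""


class FitError(RuntimeError):
    """Raised when no optimisation start converges; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class BiphasicHillParams:
    """Parameters of the biphasic Hill-type survival model.

    g_max   : maximal growth (100 when fitting normalized data)
    pk_up   : midpoint pH of the rising, acid-limited flank
    n_up    : Hill coefficient of the rising flank (> 0)
    pk_down : midpoint pH of the falling, alkaline-limited flank
    n_down  : Hill coefficient of the falling flank (> 0)
    """

    g_max: float
    pk_up: float
    n_up: float
    pk_down: float
    n_down: float

    def __post_init__(self):
        if self.g_max <= 0:
            raise ValueError("g_max must be > 0")
        if self.n_up <= 0 or self.n_down <= 0:
            raise ValueError("Hill coefficients must be > 0")

    @property
    def shape_parameters(self) -> tuple[float, float, float, float]:
        """The four shape parameters, excluding the maximum."""
        return (self.pk_up, self.n_up, self.pk_down, self.n_down)


N_SHAPE_PARAMETERS = len(dataclasses.fields(BiphasicHillParams)) - 1


@dataclass
class FitResult:
    params: BiphasicHillParams
    stderr: dict[str, float]
    rss: float
    n_points: int
    converged: bool
    reduced_model: bool
    n_starts_converged: int

    @property
    def rmse(self) -> float:
        return float(np.sqrt(self.rss / self.n_points))


def predict_growth(params: BiphasicHillParams, ph) -> np.ndarray | float:
    """Evaluate the biphasic model at one pH or a grid of pH values."""
    ph = np.asarray(ph, dtype=float)
    s_up = 1.0 / (1.0 + 10.0 ** (params.n_up * (params.pk_up - ph)))
    s_down = 1.0 / (1.0 + 10.0 ** (params.n_down * (ph - params.pk_down)))
    out = params.g_max * s_up * s_down
    return out if out.ndim else float(out)


def normalize_growth(plate: pd.DataFrame) -> pd.DataFrame:
    """Normalize an absorbance plate to percent of per-replicate maximal growth.

    `plate` has columns ``replicate``, ``ph``, ``absorbance``.  For each
    replicate, a monotone piecewise-cubic interpolant (PCHIP) is passed
    through the replicate's mean absorbance at each pH; growth is expressed
    as a percentage of the interpolant's maximum over the pH range, so the
    peak of a smooth curve through the data defines 100%.  Raw points may
    slightly exceed 100% if the interpolant peak falls between grid points.

    Returns a tidy frame with columns ``replicate``, ``ph``, ``growth_pct``.
    """
    required = {"replicate", "ph", "absorbance"}
    if not required.issubset(plate.columns):
        raise ValueError(f"plate must have columns {sorted(required)}")
    out = []
    for rep, sub in plate.groupby("replicate"):
        means = sub.groupby("ph")["absorbance"].mean()
        if means.nunique() == 1 and np.isclose(means.iloc[0], 0.0):
            raise DegenerateInputError(f"replicate {rep!r}: all absorbances are zero")
        if len(means) < 3:
            raise ValueError(f"replicate {rep!r}: need >= 3 distinct pH points")
        ph_grid = means.index.to_numpy(dtype=float)
        if means.nunique() == 1:
            peak = float(means.iloc[0])
        else:
            interp = PchipInterpolator(ph_grid, means.to_numpy(dtype=float))
            fine = np.linspace(ph_grid[0], ph_grid[-1], 1001)
            peak = float(np.max(interp(fine)))
        if peak <= 0:
            raise DegenerateInputError(f"replicate {rep!r}: non-positive peak absorbance")
        res = sub[["replicate", "ph"]].copy()
        res["growth_pct"] = 100.0 * sub["absorbance"].to_numpy(dtype=float) / peak
        out.append(res)
    return pd.concat(out, ignore_index=True)


def _half_crossings(ph: np.ndarray, g: np.ndarray) -> tuple[float, float]:
    """Crude half-max pH on the rising and falling flanks (fit starts)."""
    order = np.argsort(ph)
    ph, g = ph[order], g[order]
    half = 0.5 * np.max(g)
    imax = int(np.argmax(g))
    rising = ph[0]
    for i in range(imax, 0, -1):
        if g[i - 1] <= half <= g[i]:
            t = (half - g[i - 1]) / (g[i] - g[i - 1] + 1e-12)
            rising = ph[i - 1] + t * (ph[i] - ph[i - 1])
            break
    falling = ph[-1]
    for i in range(imax, len(ph) - 1):
        if g[i] >= half >= g[i + 1]:
            t = (g[i] - half) / (g[i] - g[i + 1] + 1e-12)
            falling = ph[i] + t * (ph[i + 1] - ph[i])
            break
    return float(rising), float(falling)


PK_BOUNDS = (5.5, 8.5)
N_BOUNDS = (1e-3, 10.0)
HILL_STARTS = (1.0, 2.0, 4.0)


def fit_biphasic_hill(
    curve: pd.DataFrame,
    weights: np.ndarray | None = None,
    fix_gmax: float | None = None,
) -> FitResult:
    """Fit the 5-parameter biphasic model by multi-start weighted least squares.

    `curve` has columns ``ph`` and ``growth_pct`` (replicates stacked).
    Midpoint starts come from the half-max pH on each flank; Hill starts are
    {1, 2, 4} on each flank.  Converged starts are ranked by residual sum of
    squares, ties broken toward the smallest n_up + n_down.  If mean growth
    is strictly increasing over the grid the falling flank is unidentifiable:
    a reduced (rising-only) model is fitted and ``reduced_model`` is set.
    """
    ph = curve["ph"].to_numpy(dtype=float)
    g = curve["growth_pct"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ph)) or not np.all(np.isfinite(g)):
        raise ValueError("non-finite values in curve")
    if len(np.unique(ph)) < 5:
        raise ValueError("need >= 5 distinct pH points to fit 5 parameters")
    w = np.ones_like(g) if weights is None else np.asarray(weights, dtype=float)
    sw = np.sqrt(w)

    means = pd.DataFrame({"ph": ph, "g": g}).groupby("ph")["g"].mean()
    reduced = bool(np.all(np.diff(means.to_numpy()) > 0))
    pk_up0, pk_down0 = _half_crossings(ph, g)
    pk_up0 = float(np.clip(pk_up0, *PK_BOUNDS))
    pk_down0 = float(np.clip(pk_down0, *PK_BOUNDS))
    gmax0 = float(np.max(g)) if fix_gmax is None else float(fix_gmax)

    def model(theta: np.ndarray) -> np.ndarray:
        if reduced:
            gm, pku, nu = _unpack_reduced(theta)
            p = BiphasicHillParams(gm, pku, nu, 20.0, 1.0)  # falling flank off-scale
        else:
            gm, pku, nu, pkd, nd = _unpack_full(theta)
            p = BiphasicHillParams(gm, pku, nu, pkd, nd)
        return predict_growth(p, ph)

    def _unpack_full(theta):
        if fix_gmax is None:
            return theta[0], theta[1], theta[2], theta[3], theta[4]
        return fix_gmax, theta[0], theta[1], theta[2], theta[3]

    def _unpack_reduced(theta):
        if fix_gmax is None:
            return theta[0], theta[1], theta[2]
        return fix_gmax, theta[0], theta[1]

    def residuals(theta):
        return sw * (model(theta) - g)

    lo_g, hi_g = 1e-6, max(10.0 * gmax0, 1e3)
    if reduced:
        starts = [
            ([gmax0, pk_up0, nu] if fix_gmax is None else [pk_up0, nu])
            for nu in HILL_STARTS
        ]
        lower = ([lo_g] if fix_gmax is None else []) + [PK_BOUNDS[0], N_BOUNDS[0]]
        upper = ([hi_g] if fix_gmax is None else []) + [PK_BOUNDS[1], N_BOUNDS[1]]
        names = (["g_max"] if fix_gmax is None else []) + ["pk_up", "n_up"]
    else:
        starts = [
            ([gmax0, pk_up0, nu, pk_down0, nd] if fix_gmax is None else [pk_up0, nu, pk_down0, nd])
            for nu in HILL_STARTS
            for nd in HILL_STARTS
        ]
        lower = ([lo_g] if fix_gmax is None else []) + [PK_BOUNDS[0], N_BOUNDS[0], PK_BOUNDS[0], N_BOUNDS[0]]
        upper = ([hi_g] if fix_gmax is None else []) + [PK_BOUNDS[1], N_BOUNDS[1], PK_BOUNDS[1], N_BOUNDS[1]]
        names = (["g_max"] if fix_gmax is None else []) + ["pk_up", "n_up", "pk_down", "n_down"]

    best = None
    n_conv = 0
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lower, upper)
        try:
            sol = least_squares(residuals, x0, bounds=(lower, upper), method="trf")
        except Exception:
            continue
        if not sol.success:
            continue
        n_conv += 1
        rss = float(2.0 * sol.cost)
        n_sum = sum(v for nm, v in zip(names, sol.x) if nm.startswith("n_"))
        key = (round(rss, 9), n_sum)
        if best is None or key < best[0]:
            best = (key, sol, rss)
    if best is None:
        raise FitError(
            "no optimisation start converged",
            {"starts": len(starts), "pk_up0": pk_up0, "pk_down0": pk_down0},
        )
    _, sol, rss = best

    # standard errors from the Gauss-Newton covariance at the optimum
    dof = max(len(g) - len(sol.x), 1)
    s2 = rss / dof
    try:
        cov = s2 * np.linalg.pinv(sol.jac.T @ sol.jac)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(sol.x), np.nan)
    stderr = dict(zip(names, se))

    if reduced:
        gm, pku, nu = _unpack_reduced(sol.x)
        params = BiphasicHillParams(float(gm), float(pku), float(nu), float("inf"), 1.0)
        stderr.setdefault("pk_down", float("nan"))
        stderr.setdefault("n_down", float("nan"))
    else:
        gm, pku, nu, pkd, nd = _unpack_full(sol.x)
        params = BiphasicHillParams(float(gm), float(pku), float(nu), float(pkd), float(nd))
    if fix_gmax is not None:
        stderr["g_max"] = 0.0
    return FitResult(
        params=params,
        stderr=stderr,
        rss=rss,
        n_points=len(g),
        converged=True,
        reduced_model=reduced,
        n_starts_converged=n_conv,
    )
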