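"""Intravoxel incoherent motion (IVIM) biexponential model.

The IVIM model decomposes the diffusion-weighted MR signal of a voxel into a
slowly decaying tissue-water compartment and a fast pseudo-diffusion
compartment attributed to capillary microcirculation:

    S(b) = S0 * [ f * exp(-b * D*) + (1 - f) * exp(-b * D) ]

with ``D`` the pure diffusion coefficient (mm^2/s), ``D*`` the pseudo-diffusion
coefficient of the perfusion compartment (mm^2/s), and ``f`` the perfusion
fraction in [0, 1].  Because D* >> D, the perfusion term has essentially
decayed above a few hundred s/mm^2, which motivates the classic segmented
estimation strategy used here for initialization: a log-linear fit of the
high-b tail yields D and the tissue-compartment intercept, the intercept
deficit at b=0 yields f, and a one-dimensional search yields D*.  The
segmented estimate is then refined by bounded nonlinear least squares on all
b-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

__all__ = [
    "BValueScheme",
    "IVIMParams",
    "FitConfig",
    "IVIMMaps",
    "PAPER_BVALUES",
    "predict_signal",
    "fit_voxel",
    "fit_volume",
]

#: The nine-point diffusion-weighting scheme used throughout (s/mm^2), with
#: the per-b number of signal averages of the acquisition protocol.
PAPER_BVALUES = (0.0, 30.0, 50.0, 80.0, 120.0, 160.0, 200.0, 500.0, 1000.0)
PAPER_AVERAGES = (1, 2, 2, 2, 2, 2, 2, 2, 3)


@dataclass(frozen=True)
class BValueScheme:
    """Ordered diffusion-weighting scheme.

    Parameters
    ----------
    bvalues : sequence of float
        Strictly increasing b-values in s/mm^2; the first must be 0.
    n_averages : sequence of int, optional
        Number of signal averages per b-value (used by the phantom generator
        to scale the effective noise level per volume).
    """

    bvalues: tuple = PAPER_BVALUES
    n_averages: tuple | None = None

    def __post_init__(self):
        b = np.asarray(self.bvalues, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("bvalues must be a 1-D sequence of length >= 2")
        if b[0] != 0:
            raise ValueError("the first b-value must be 0")
        if np.any(np.diff(b) <= 0):
            raise ValueError("bvalues must be strictly increasing")
        object.__setattr__(self, "bvalues", tuple(float(x) for x in b))
        if self.n_averages is not None:
            na = tuple(int(x) for x in self.n_averages)
            if len(na) != b.size or any(x < 1 for x in na):
                raise ValueError("n_averages must match bvalues and be >= 1")
            object.__setattr__(self, "n_averages", na)

    @property
    def b(self) -> np.ndarray:
        return np.asarray(self.bvalues, dtype=float)

    def __len__(self) -> int:
        return len(self.bvalues)


def paper_scheme() -> BValueScheme:
    """The 9 b-value acquisition scheme with its per-b averages."""
    return BValueScheme(PAPER_BVALUES, PAPER_AVERAGES)


@dataclass(frozen=True)
class IVIMParams:
    """Voxel IVIM parameters (S0 in signal units, D and Dstar in mm^2/s)."""

    S0: float
    D: float
    f: float
    Dstar: float

    def __post_init__(self):
        if not np.isfinite([self.S0, self.D, self.f, self.Dstar]).all():
            raise ValueError("IVIM parameters must be finite")
        if self.S0 <= 0:
            raise ValueError("S0 must be positive")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must lie in [0, 1]")
        if self.D <= 0 or self.Dstar <= self.D:
            raise ValueError("requires Dstar > D > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.S0, self.D, self.f, self.Dstar], dtype=float)


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the segmented-initialization + NLLS refinement fit.

    ``b_split`` separates the high-b tail used for the log-linear diffusion
    fit; the default 200 s/mm^2 exploits the natural gap in the acquisition
    scheme (200 -> 500), above which the perfusion term exp(-b*D*) is
    negligible for physiological D*.  Bounds use disjoint boxes for D and D*
    so the two compartments cannot swap roles during optimization; the D*
    floor sits a factor two above the D ceiling because with a merely
    touching gap, noisy high-D voxels can still be mimicked by an
    (f at bound, D* at floor) pseudo-diffusion mode.
    """

    b_split: float = 200.0
    D_bounds: tuple = (1e-6, 3e-3)
    Dstar_bounds: tuple = (6e-3, 0.3)
    f_bounds: tuple = (0.0, 0.5)
    S0_bounds: tuple = (1e-12, np.inf)
    max_iter: int = 200
    tol: float = 1e-10
    fill_value: float = np.nan

    def __post_init__(self):
        for lo, hi in (self.D_bounds, self.Dstar_bounds, self.f_bounds):
            if not lo < hi:
                raise ValueError("parameter bounds must satisfy lo < hi")
        if self.Dstar_bounds[0] < self.D_bounds[1]:
            raise ValueError("D and Dstar boxes must be disjoint (Dstar > D)")


@dataclass
class IVIMMaps:
    """Voxelwise IVIM parameter maps aligned to the source grid.

    Outside the mask (and on failed fits) the maps carry the fill value and
    ``converged`` is False; downstream stages must exclude those voxels.
    """

    D: np.ndarray
    f: np.ndarray
    Dstar: np.ndarray
    S0: np.ndarray
    rmse: np.ndarray
    converged: np.ndarray

    @property
    def shape(self):
        return self.D.shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return {"D": self.D, "f": self.f, "Dstar": self.Dstar,
                    "S0": self.S0}[name]
        except KeyError:
            raise KeyError(f"unknown IVIM channel {name!r}") from None

    def valid_mask(self) -> np.ndarray:
        return self.converged & np.isfinite(self.D) & np.isfinite(self.f)


def predict_signal(params: IVIMParams, bscheme: BValueScheme | Sequence[float]) -> np.ndarray:
    """Forward biexponential signal S(b) for one set of IVIM parameters."""
    b = bscheme.b if isinstance(bscheme, BValueScheme) else np.asarray(bscheme, float)
    p = params
    return p.S0 * (p.f * np.exp(-b * p.Dstar) + (1.0 - p.f) * np.exp(-b * p.D))


def _model(theta: np.ndarray, b: np.ndarray) -> np.ndarray:
    S0, D, f, Dstar = theta
    return S0 * (f * np.exp(-b * Dstar) + (1.0 - f) * np.exp(-b * D))


def _jacobian(theta: np.ndarray, b: np.ndarray) -> np.ndarray:
    S0, D, f, Dstar = theta
    es = np.exp(-b * Dstar)
    ed = np.exp(-b * D)
    J = np.empty((b.size, 4))
    J[:, 0] = f * es + (1 - f) * ed
    J[:, 1] = -S0 * (1 - f) * b * ed
    J[:, 2] = S0 * (es - ed)
    J[:, 3] = -S0 * f * b * es
    return J


def _segmented_init(signal: np.ndarray, b: np.ndarray, cfg: FitConfig):
    """Segmented estimate: log-linear tail fit for D, intercept deficit for f,
    1-D bounded search for D*."""
    s0_obs = signal[0]
    tail = b >= cfg.b_split
    logs = np.log(np.clip(signal[tail], 1e-12, None))
    # slope/intercept of log S on the high-b tail
    slope, intercept = np.polyfit(b[tail], logs, 1)
    D0 = float(np.clip(-slope, cfg.D_bounds[0], cfg.D_bounds[1]))
    A = np.exp(intercept)  # tissue-compartment extrapolation to b=0
    f0 = float(np.clip(1.0 - A / s0_obs, cfg.f_bounds[0], cfg.f_bounds[1]))
    S00 = float(s0_obs)

    def sse_dstar(log_dstar):
        th = np.array([S00, D0, f0, np.exp(log_dstar)])
        r = _model(th, b) - signal
        return float(r @ r)

    lo, hi = np.log(cfg.Dstar_bounds)
    res = minimize_scalar(sse_dstar, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    Dstar0 = float(np.exp(res.x))
    return np.array([S00, D0, f0, Dstar0])


_FAIL = ("failed",)


def fit_voxel(signal: Sequence[float], bscheme: BValueScheme,
              config: FitConfig | None = None):
    """Fit IVIM parameters to one voxel's signal decay.

    Returns ``(IVIMParams, diagnostics)`` where diagnostics holds the residual
    RMSE, a convergence flag and the segmented initial estimate.  Non-finite
    or non-positive b=0 signal yields a flagged failure rather than a raise,
    so that volume fitting never crashes on degenerate voxels.
    """
    cfg = config or FitConfig()
    b = bscheme.b
    if len(b) < 4:
        raise ValueError("need at least 4 b-values to fit the IVIM model")
    if not (cfg.b_split > b[0] and cfg.b_split < b[-1]):
        raise ValueError("b_split must lie strictly inside the b range")
    s = np.asarray(signal, dtype=float)
    if s.shape != b.shape:
        raise ValueError("signal length must match the number of b-values")
    if not np.isfinite(s).all() or s[0] <= 0 or np.all(s == 0):
        return None, {"converged": False, "rmse": np.nan, "init": None}

    x0 = _segmented_init(s, b, cfg)
    eps = 1e-12
    lower = [cfg.S0_bounds[0], cfg.D_bounds[0], cfg.f_bounds[0], cfg.Dstar_bounds[0]]
    upper = [np.inf, cfg.D_bounds[1], cfg.f_bounds[1], cfg.Dstar_bounds[1]]
    x0 = np.clip(x0, np.asarray(lower) + eps * 0, upper)
    sol = least_squares(
        lambda th: _model(th, b) - s, x0, jac=lambda th: _jacobian(th, b),
        bounds=(lower, upper), method="trf",
        xtol=cfg.tol, ftol=cfg.tol, gtol=cfg.tol, max_nfev=cfg.max_iter * 4,
        x_scale=[max(x0[0], 1.0), 1e-3, 0.1, 1e-2],
    )
    theta = sol.x
    rmse = float(np.sqrt(np.mean(sol.fun ** 2)))
    # keep f in bounds but report Dstar > D even at the shared numerical floor
    params = IVIMParams(S0=float(theta[0]), D=float(max(theta[1], 1e-12)),
                        f=float(theta[2]), Dstar=float(theta[3]))
    diag = {"converged": bool(sol.success), "rmse": rmse,
            "init": x0.copy(), "nfev": sol.nfev}
    return params, diag


def fit_volume(signal4d: np.ndarray, mask: np.ndarray, bscheme: BValueScheme,
               config: FitConfig | None = None) -> IVIMMaps:
    """Apply :func:`fit_voxel` to every voxel of a binary mask.

    ``signal4d`` is (x, y, z, b).  Voxels outside the mask take the fill
    value; failed fits are flagged and filled, never raised.
    """
    cfg = config or FitConfig()
    signal4d = np.asarray(signal4d, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if signal4d.ndim != 4:
        raise ValueError("signal must be a 4-D (x, y, z, b) array")
    if signal4d.shape[:3] != mask.shape:
        raise ValueError("signal grid and mask shapes disagree")
    if signal4d.shape[3] != len(bscheme):
        raise ValueError("4th axis must match the number of b-values")
    if not mask.any():
        raise ValueError("mask is empty")

    shape = mask.shape
    fill = cfg.fill_value
    maps = IVIMMaps(
        D=np.full(shape, fill), f=np.full(shape, fill),
        Dstar=np.full(shape, fill), S0=np.full(shape, fill),
        rmse=np.full(shape, fill), converged=np.zeros(shape, dtype=bool),
    )
    for idx in zip(*np.nonzero(mask)):
        params, diag = fit_voxel(signal4d[idx], bscheme, cfg)
        if params is None:
            continue
        maps.D[idx] = params.D
        maps.f[idx] = params.f
        maps.Dstar[idx] = params.Dstar
        maps.S0[idx] = params.S0
        maps.rmse[idx] = diag["rmse"]
        maps.converged[idx] = diag["converged"]
    return maps
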