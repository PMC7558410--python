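"""Dynamic light scattering analysis: cumulants fits and a regularized
inverse Laplace transform for the intensity autocorrelation function.

The measured quantity is the normalized intensity autocorrelation
g2(t).  Two complementary analyses are provided:

* :func:`fit_cumulants` -- the low-order cumulants expansion
  g2(t) = B + beta * exp(-2 Gbar t) * (1 + (mu2/2) t^2)^2,
  yielding the mean decay rate Gbar, the second moment mu2 and the
  polydispersity index PI = mu2 / Gbar^2.
* :func:`invert_contin` -- a CONTIN-style non-negative least-squares
  inversion with second-difference (smoothness) regularization,
  recovering the full intensity-weighted decay-rate distribution G(Gamma)
  from sqrt(g2(t) - B) ~ sum_i G_i exp(-Gamma_i t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, nnls

from .core import OpticalConfig, stokes_einstein_diameter

__all__ = [
    "Correlogram",
    "CumulantsFit",
    "SizeDistribution",
    "ContinResult",
    "FitError",
    "fit_cumulants",
    "invert_contin",
    "harmonic_mean_diameter",
]

#: Minimum usable correlation intercept; data below this is flagged, not fit.
MIN_INTERCEPT = 0.05


class FitError(RuntimeError):
    """Raised when a correlogram cannot be analysed (no decay, no convergence)."""


@dataclass(frozen=True)
class Correlogram:
    """A single-run DLS correlogram: lag times (us) vs g2(t)."""

    lags_us: np.ndarray
    g2: np.ndarray

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags_us, dtype=float)
        g2 = np.asarray(self.g2, dtype=float)
        object.__setattr__(self, "lags_us", lags)
        object.__setattr__(self, "g2", g2)
        if lags.ndim != 1 or g2.ndim != 1 or lags.size != g2.size:
            raise ValueError("lags_us and g2 must be 1-D arrays of equal length")
        if lags.size < 10:
            raise ValueError(f"need at least 10 correlator channels, got {lags.size}")
        if not np.all(np.isfinite(lags)) or not np.all(np.isfinite(g2)):
            raise ValueError("correlogram contains non-finite values")
        if not np.all(np.diff(lags) > 0):
            bad = int(np.flatnonzero(np.diff(lags) <= 0)[0]) + 1
            raise ValueError(f"lag times must be strictly increasing (violation at point {bad})")
        if not lags[0] > 0:
            raise ValueError("lag times must be positive")

    def __len__(self) -> int:
        return int(self.lags_us.size)


@dataclass(frozen=True)
class CumulantsFit:
    """Result of a cumulants fit of g2(t).

    ``pi`` is the polydispersity index mu2 / gamma_bar^2, a dimensionless
    measure of the width of the decay-rate distribution.
    """

    baseline: float
    amplitude: float
    gamma_bar_per_us: float
    mu2_per_us2: float
    baseline_se: float
    amplitude_se: float
    gamma_bar_se: float
    mu2_se: float
    order: int
    n_points: int
    at_bound: bool = False

    def __post_init__(self) -> None:
        if not self.gamma_bar_per_us > 0:
            raise ValueError("gamma_bar must be positive")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")
        if self.mu2_per_us2 < 0:
            raise ValueError("mu2 must be non-negative")

    @property
    def pi(self) -> float:
        """Polydispersity index mu2 / gamma_bar^2."""
        return self.mu2_per_us2 / self.gamma_bar_per_us**2

    def diameter_nm(self, cfg: OpticalConfig) -> float:
        """Cumulants mean hydrodynamic diameter under ``cfg``."""
        return stokes_einstein_diameter(self.gamma_bar_per_us, cfg)


@dataclass(frozen=True)
class SizeDistribution:
    """Normalized non-negative intensity weights on a decay-rate or diameter grid.

    ``kind`` selects the grid variable: ``"decay_rate"`` (Gamma, 1/us) or
    ``"diameter"`` (D, nm).
    """

    grid: np.ndarray
    weights: np.ndarray
    kind: str = "decay_rate"

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "weights", weights)
        if self.kind not in ("decay_rate", "diameter"):
            raise ValueError(f"unknown grid kind {self.kind!r}")
        if grid.ndim != 1 or grid.size != weights.size:
            raise ValueError("grid and weights must be 1-D arrays of equal length")
        if grid.size >= 2 and not np.all(np.diff(grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if not np.all(grid > 0):
            raise ValueError("grid values must be positive")
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")
        total = weights.sum()
        if not np.isfinite(total) or abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {total!r})")

    def diameters_nm(self, cfg: OpticalConfig) -> np.ndarray:
        """Grid mapped to hydrodynamic diameters (nm) under ``cfg``."""
        if self.kind == "diameter":
            return self.grid.copy()
        return np.array([stokes_einstein_diameter(g, cfg) for g in self.grid])

    @classmethod
    def monodisperse(cls, value: float, kind: str = "decay_rate") -> "SizeDistribution":
        """Single-component distribution concentrated at ``value``."""
        return cls(np.array([value]), np.array([1.0]), kind=kind)


@dataclass(frozen=True)
class ContinResult:
    """Output of :func:`invert_contin`: the distribution plus fit metadata."""

    distribution: SizeDistribution
    reg_lambda: float
    baseline: float
    amplitude: float
    residual_norm: float
    lcurve: dict = field(default_factory=dict, repr=False)


def _estimate_baseline(c: Correlogram) -> float:
    """Baseline B: mean of g2 over the last 10% of lag channels."""
    n_tail = max(2, len(c) // 10)
    return float(np.mean(c.g2[-n_tail:]))


def _initial_gamma(lags: np.ndarray, decay: np.ndarray) -> float:
    """Start value for Gbar from a log-linear regression of the first decade
    of the normalized decay (g2 - B)/beta against lag time."""
    mask = decay > 0.1  # first decade of the squared field correlation
    if mask.sum() < 3:
        mask = decay > 0
    if mask.sum() < 3:
        raise FitError("no visible decay above the baseline; cannot initialize fit")
    slope = np.polyfit(lags[mask], np.log(decay[mask]), 1)[0]
    gamma0 = -slope / 2.0
    if not gamma0 > 0:
        raise FitError("correlogram does not decay; initial decay-rate estimate <= 0")
    return float(gamma0)


def _cumulants_model(t: np.ndarray, B: float, beta: float, gamma: float, mu2: float) -> np.ndarray:
    return B + beta * np.exp(-2.0 * gamma * t) * (1.0 + 0.5 * mu2 * t**2) ** 2


def fit_cumulants(c: Correlogram, order: int = 2) -> CumulantsFit:
    """Least-squares cumulants fit of a correlogram.

    Fits g2(t) = B + beta exp(-2 Gbar t) (1 + (mu2/2) t^2)^2 over the full
    lag range with uniform weights.  ``order=1`` pins mu2 = 0 (single
    exponential); ``order=2`` frees the second moment.  Standard errors
    come from the fit covariance.

    Raises
    ------
    FitError
        If the intercept is too low to analyse, the decay is not visible,
        or the optimizer fails to converge.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    t = c.lags_us
    y = c.g2

    b0 = _estimate_baseline(c)
    beta0 = float(y[0] - b0)
    if beta0 < MIN_INTERCEPT:
        raise FitError(
            f"correlation intercept beta ~ {beta0:.3g} is below {MIN_INTERCEPT}; "
            "low-intercept data flagged rather than fit"
        )
    gamma0 = _initial_gamma(t, (y - b0) / beta0)

    if order == 1:
        def model(tt, B, beta, gamma):
            return _cumulants_model(tt, B, beta, gamma, 0.0)
        p0 = [b0, beta0, gamma0]
        lower = [-np.inf, 0.0, 0.0]
        upper = [np.inf, np.inf, np.inf]
    else:
        model = _cumulants_model
        p0 = [b0, beta0, gamma0, 0.0]
        lower = [-np.inf, 0.0, 0.0, 0.0]
        upper = [np.inf, np.inf, np.inf, np.inf]

    try:
        popt, pcov = curve_fit(model, t, y, p0=p0, bounds=(lower, upper), maxfev=20000)
    except RuntimeError as exc:  # no convergence
        raise FitError(f"cumulants fit did not converge: {exc}") from exc
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))

    if order == 1:
        B, beta, gamma = popt
        mu2, mu2_se = 0.0, 0.0
        b_se, beta_se, g_se = perr
    else:
        B, beta, gamma, mu2 = popt
        b_se, beta_se, g_se, mu2_se = perr

    at_bound = bool(gamma <= 10 * np.finfo(float).tiny)
    if at_bound or not np.isfinite(gamma) or gamma <= 0:
        raise FitError("fitted decay rate collapsed to the parameter bound")

    return CumulantsFit(
        baseline=float(B),
        amplitude=float(beta),
        gamma_bar_per_us=float(gamma),
        mu2_per_us2=float(mu2),
        baseline_se=float(b_se),
        amplitude_se=float(beta_se),
        gamma_bar_se=float(g_se),
        mu2_se=float(mu2_se),
        order=order,
        n_points=len(c),
        at_bound=at_bound,
    )


def _second_difference_matrix(n: int) -> np.ndarray:
    L = np.zeros((n - 2, n))
    for i in range(n - 2):
        L[i, i : i + 3] = (1.0, -2.0, 1.0)
    return L


def _nnls_regularized(A: np.ndarray, y: np.ndarray, L: np.ndarray, lam: float) -> np.ndarray:
    A_aug = np.vstack([A, np.sqrt(lam) * L])
    y_aug = np.concatenate([y, np.zeros(L.shape[0])])
    x, _ = nnls(A_aug, y_aug)
    return x


def _lcurve_corner(rho: np.ndarray, eta: np.ndarray) -> int:
    """Index of the L-curve corner on normalized log axes.

    The corner is the point of maximum perpendicular distance from the
    chord joining the endpoints of the (log rho, log eta) curve, each
    axis rescaled to [0, 1].  This triangle criterion is robust for
    non-negative least squares, where the residual branch of the curve
    is nearly flat and pointwise-curvature detectors latch onto the
    over-smoothed end.
    """
    lr = np.log10(np.maximum(rho, 1e-300))
    le = np.log10(np.maximum(eta, 1e-300))
    span_r = lr.max() - lr.min()
    span_e = le.max() - le.min()
    x = (lr - lr.min()) / (span_r if span_r > 0 else 1.0)
    y = (le - le.min()) / (span_e if span_e > 0 else 1.0)
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    norm = np.linalg.norm(chord)
    if norm == 0:
        return len(rho) // 2
    # perpendicular distance of every point from the chord
    d = np.abs(chord[0] * (y - p0[1]) - chord[1] * (x - p0[0])) / norm
    return int(np.argmax(d))


def invert_contin(
    c: Correlogram,
    grid_size: int = 80,
    reg_lambda: float | str = "auto",
    baseline: float | None = None,
    amplitude: float | None = None,
) -> ContinResult:
    """CONTIN-style inversion of a correlogram into a decay-rate distribution.

    The baseline B and intercept beta are pre-estimated (tail mean and
    first-channel excess, unless given), the data are mapped to the field
    correlation sqrt(max(g2 - B, 0) / beta), and the weights G(Gamma_i) on
    a log-spaced grid of ``grid_size`` decay rates spanning
    [0.1/t_max, 10/t_min] are found by non-negative least squares with a
    squared-second-difference smoothness penalty of strength
    ``reg_lambda``.  With ``reg_lambda="auto"`` the penalty is selected at
    the corner of the L-curve over a 20-point lambda grid; the selected
    value is reported in the result.
    """
    if grid_size < 4:
        raise ValueError("grid_size must be at least 4")
    t = c.lags_us
    b = _estimate_baseline(c) if baseline is None else float(baseline)
    beta = float(c.g2[0] - b) if amplitude is None else float(amplitude)
    if beta < MIN_INTERCEPT:
        raise FitError(
            f"correlation intercept beta ~ {beta:.3g} is below {MIN_INTERCEPT}; "
            "low-intercept data flagged rather than fit"
        )
    y = np.sqrt(np.clip(c.g2 - b, 0.0, None) / beta)

    grid = np.geomspace(0.1 / t[-1], 10.0 / t[0], grid_size)
    A = np.exp(-np.outer(t, grid))
    L = _second_difference_matrix(grid_size)

    lcurve: dict = {}
    if isinstance(reg_lambda, str):
        if reg_lambda != "auto":
            raise ValueError(f"reg_lambda must be a positive number or 'auto', got {reg_lambda!r}")
        # scale-aware lambda grid around ||A^T A|| / ||L^T L||
        scale = np.linalg.norm(A.T @ A) / np.linalg.norm(L.T @ L)
        lams = scale * np.geomspace(1e-8, 1e2, 20)
        rho = np.empty(lams.size)
        eta = np.empty(lams.size)
        sols = []
        for i, lam in enumerate(lams):
            x = _nnls_regularized(A, y, L, lam)
            sols.append(x)
            rho[i] = np.linalg.norm(A @ x - y)
            eta[i] = np.linalg.norm(L @ x)
        k = _lcurve_corner(rho, eta)
        lam, x = float(lams[k]), sols[k]
        lcurve = {"lambdas": lams, "residual_norms": rho, "seminorms": eta, "corner_index": k}
    else:
        lam = float(reg_lambda)
        if lam < 0:
            raise ValueError("reg_lambda must be non-negative")
        x = _nnls_regularized(A, y, L, lam)

    total = x.sum()
    if total <= 0:
        raise FitError("inversion produced an all-zero distribution; no decay recovered")
    dist = SizeDistribution(grid, x / total, kind="decay_rate")
    return ContinResult(
        distribution=dist,
        reg_lambda=lam,
        baseline=b,
        amplitude=beta,
        residual_norm=float(np.linalg.norm(A @ x - y)),
        lcurve=lcurve,
    )


def harmonic_mean_diameter(dist: SizeDistribution, cfg: OpticalConfig) -> float:
    """Intensity-weighted harmonic mean hydrodynamic diameter, nm.

    D_harm = [sum_i G_i / D_i]^-1 with the grid mapped to diameters by
    Stokes-Einstein.  For an intensity-weighted distribution this is the
    same average that the cumulants mean decay rate measures, so the two
    should agree for narrow distributions.
    """
    d = dist.diameters_nm(cfg)
    return float(1.0 / np.sum(dist.weights / d))
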