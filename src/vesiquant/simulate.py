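"""Forward generators for every input the assay consumes, with known truth.

No instrument raw data ship with the package; instead, each measurement
is emulated by an explicit forward model so that every analysis stage can
be validated against a known ground truth:

* correlograms from a decay-rate distribution (or directly from the
  cumulants parameters);
* two-extrusion intensity records I = k * Mw * (C/d) * P(q), with Mw and
  the form factor P(q) from the thin-shell model — quantities that cancel
  in the assay but are simulated explicitly here;
* spectrofluorimeter emission spectra with a Gaussian elastic band of
  prescribed area;
* Stewart calibration standards.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .concentration import ExtrusionPair
from .core import OpticalConfig, ShellModel, scattering_vector, shell_mass
from .dls import Correlogram, SizeDistribution
from .spectra import EmissionSpectrum

__all__ = [
    "SimulationTruth",
    "simulate_correlogram",
    "simulate_cumulants_correlogram",
    "simulate_extrusion_experiment",
    "simulate_emission_spectrum",
    "simulate_stewart_standards",
    "thin_shell_form_factor",
]


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of one simulated two-extrusion experiment."""

    true_c1_mg_ml: float
    true_c2_mg_ml: float
    size_distribution: SizeDistribution
    instrument_constant: float
    mw_Da: float
    form_factor: float
    noise_cv: float
    n_replicates: int
    seed: int
    i1_true: float = 0.0
    i2_true: float = 0.0
    extras: dict = field(default_factory=dict, repr=False)


def thin_shell_form_factor(diameter_nm: float, cfg: OpticalConfig) -> float:
    """Form factor P(q) = [sin(qR)/(qR)]^2 of an infinitely thin spherical
    shell of diameter ``diameter_nm`` at the scattering vector of ``cfg``."""
    q_per_um = scattering_vector(cfg)
    x = q_per_um * (diameter_nm * 1e-3) / 2.0  # q R, dimensionless
    if x == 0:
        return 1.0
    return (math.sin(x) / x) ** 2


def _distribution_gammas(dist: SizeDistribution, cfg: OpticalConfig) -> np.ndarray:
    if dist.kind == "decay_rate":
        return dist.grid
    from .core import gamma_from_diameter

    return np.array([gamma_from_diameter(d, cfg) for d in dist.grid])


def simulate_correlogram(
    dist: SizeDistribution,
    cfg: OpticalConfig | None = None,
    baseline: float = 1.0,
    amplitude: float = 0.8,
    noise_sd: float = 0.0,
    n_lags: int = 200,
    seed: int = 0,
    lag_span: tuple[float, float] = (0.01, 10.0),
) -> Correlogram:
    """Correlogram from a decay-rate distribution.

    g2(t) = B + beta [sum_i G_i exp(-Gamma_i t)]^2 on ``n_lags`` log-spaced
    lags spanning ``lag_span`` (in units of the inverse mean decay rate),
    plus additive zero-mean Gaussian noise of sd ``noise_sd``.
    Deterministic for a fixed seed.
    """
    cfg = cfg if cfg is not None else OpticalConfig()
    gammas = _distribution_gammas(dist, cfg)
    gamma_mean = float(np.sum(dist.weights * gammas))
    lags = np.geomspace(lag_span[0] / gamma_mean, lag_span[1] / gamma_mean, n_lags)
    field_corr = np.exp(-np.outer(lags, gammas)) @ dist.weights
    g2 = baseline + amplitude * field_corr**2
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        g2 = g2 + rng.normal(0.0, noise_sd, size=g2.shape)
    return Correlogram(lags, g2)


def simulate_cumulants_correlogram(
    gamma_bar_per_us: float,
    mu2_per_us2: float = 0.0,
    baseline: float = 1.0,
    amplitude: float = 0.8,
    noise_sd: float = 0.0,
    noise: str = "multiplicative",
    n_lags: int = 200,
    seed: int = 0,
    lag_span: tuple[float, float] = (0.01, 10.0),
) -> Correlogram:
    """Correlogram drawn directly from the truncated cumulants model.

    g2(t) = B + beta exp(-2 Gbar t) (1 + (mu2/2) t^2)^2, with
    multiplicative (relative, default) or additive Gaussian noise of
    scale ``noise_sd``.  The model is exactly the one the cumulants fit
    assumes, so recovery tests are free of truncation bias.
    """
    if noise not in ("multiplicative", "additive"):
        raise ValueError(f"noise must be 'multiplicative' or 'additive', got {noise!r}")
    lags = np.geomspace(
        lag_span[0] / gamma_bar_per_us, lag_span[1] / gamma_bar_per_us, n_lags
    )
    g2 = baseline + amplitude * np.exp(-2.0 * gamma_bar_per_us * lags) * (
        1.0 + 0.5 * mu2_per_us2 * lags**2
    ) ** 2
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        eps = rng.normal(0.0, noise_sd, size=g2.shape)
        g2 = g2 * (1.0 + eps) if noise == "multiplicative" else g2 + eps
    return Correlogram(lags, g2)


def simulate_extrusion_experiment(
    m0_mg: float = 1.0,
    v1_ml: float = 0.8,
    vt_ml: float = 1.8,
    residual_fraction: float = 0.1,
    d1: float = 50.0,
    d2: float = 5.0,
    dist: SizeDistribution | None = None,
    cfg: OpticalConfig | None = None,
    seed: int = 0,
    noise_cv: float = 0.02,
    n_replicates: int = 3,
    instrument_constant: float = 1e-4,
    dead_volume_fraction: float = 0.2,
) -> tuple[ExtrusionPair, SimulationTruth]:
    """Simulate one complete two-extrusion scattering experiment.

    The truth is fixed by construction: C1 = (1 - r) M0 / V1 and
    C2 = r M0 / (V_T - V1) with r = ``residual_fraction``, so mass closure
    holds exactly; the dead volume shares C2.  Scattered intensities are
    I = k * Mw * (C/d) * P(q), with Mw and P(q) intensity-averaged over the
    size distribution under the thin-shell model, and are emitted as
    ``n_replicates`` readings with multiplicative Gaussian noise of
    coefficient of variation ``noise_cv``; the pair records their mean and
    SE = SD/sqrt(n), mirroring the triplicate protocol.
    """
    if not 0 <= residual_fraction < 1:
        raise ValueError("residual_fraction must lie in [0, 1)")
    if not vt_ml > v1_ml:
        raise ValueError("vt_ml must exceed v1_ml")
    if not 0 <= dead_volume_fraction < 1:
        raise ValueError("dead_volume_fraction must lie in [0, 1)")
    cfg = cfg if cfg is not None else OpticalConfig()
    dist = dist if dist is not None else SizeDistribution.monodisperse(90.0, kind="diameter")

    c1 = (1.0 - residual_fraction) * m0_mg / v1_ml
    c2 = residual_fraction * m0_mg / (vt_ml - v1_ml)
    v2 = (vt_ml - v1_ml) * (1.0 - dead_volume_fraction)

    diameters = dist.diameters_nm(cfg)
    mw = float(np.sum(dist.weights * [shell_mass(d) for d in diameters]))
    p_theta = float(
        np.sum(dist.weights * [thin_shell_form_factor(d, cfg) for d in diameters])
    )

    i1_true = instrument_constant * mw * (c1 / d1) * p_theta
    i2_true = instrument_constant * mw * (c2 / d2) * p_theta

    rng = np.random.default_rng(seed)
    i1_reps = i1_true * (1.0 + noise_cv * rng.standard_normal(n_replicates))
    i2_reps = i2_true * (1.0 + noise_cv * rng.standard_normal(n_replicates))

    pair = ExtrusionPair.from_replicates(
        m0_mg=m0_mg, v1_ml=v1_ml, v2_ml=v2, vt_ml=vt_ml,
        d1=d1, d2=d2, i1_replicates=i1_reps, i2_replicates=i2_reps,
    )
    truth = SimulationTruth(
        true_c1_mg_ml=c1,
        true_c2_mg_ml=c2,
        size_distribution=dist,
        instrument_constant=instrument_constant,
        mw_Da=mw,
        form_factor=p_theta,
        noise_cv=noise_cv,
        n_replicates=n_replicates,
        seed=seed,
        i1_true=i1_true,
        i2_true=i2_true,
        extras={"i1_replicates": i1_reps.tolist(), "i2_replicates": i2_reps.tolist()},
    )
    return pair, truth


def simulate_emission_spectrum(
    intensity_equivalent: float,
    excitation_nm: float = 532.0,
    baseline: float = 0.0,
    peak_width_nm: float = 1.2,
    noise_sd: float = 0.0,
    seed: int = 0,
    half_range_nm: float = 30.0,
    step_nm: float = 0.2,
) -> EmissionSpectrum:
    """Emission scan with a Gaussian elastic band of prescribed area.

    The band is centered at the excitation wavelength with sd
    ``peak_width_nm`` and total area ``intensity_equivalent`` (a.u.*nm),
    sitting on a flat baseline, plus additive Gaussian noise.
    """
    if intensity_equivalent < 0:
        raise ValueError("intensity_equivalent must be non-negative")
    if not peak_width_nm > 0:
        raise ValueError("peak_width_nm must be positive")
    wl = np.arange(
        excitation_nm - half_range_nm, excitation_nm + half_range_nm + step_nm / 2, step_nm
    )
    amp = intensity_equivalent / (peak_width_nm * math.sqrt(2.0 * math.pi))
    it = baseline + amp * np.exp(-0.5 * ((wl - excitation_nm) / peak_width_nm) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        it = it + rng.normal(0.0, noise_sd, size=it.shape)
    return EmissionSpectrum(wl, it, excitation_nm)


def simulate_stewart_standards(
    true_slope: float = 20.0,
    true_intercept: float = 0.02,
    conc_grid=None,
    noise_sd: float = 0.01,
    n_rep: int = 3,
    seed: int = 0,
):
    """Stewart calibration standards with replicate absorbance readings.

    Absorbance = slope * C + intercept + Gaussian noise, replicated
    ``n_rep`` times per standard; each standard reports the replicate mean
    and SE = SD/sqrt(n_rep).  The default grid spans the assay's working
    range, 0.005-0.050 mg/mL.

    Returns
    -------
    (concentrations, mean_absorbances, absorbance_se) : three ndarrays
    """
    conc = (
        np.linspace(0.005, 0.050, 10) if conc_grid is None else np.asarray(conc_grid, float)
    )
    if np.any(conc <= 0):
        raise ValueError("standard concentrations must be positive")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    reps = np.repeat(true_slope * conc[:, None] + true_intercept, n_rep, axis=1)
    if noise_sd > 0:
        reps = reps + rng.normal(0.0, noise_sd, size=(conc.size, n_rep))
    mean = reps.mean(axis=1)
    se = (
        reps.std(axis=1, ddof=1) / math.sqrt(n_rep)
        if n_rep > 1
        else np.zeros_like(mean)
    )
    return conc, mean, se
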