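"""Two-extrusion mass-closure assay for vesicle weight concentration.

A vesicle preparation by extrusion leaves part of the lipid mass in the
extruder; a second rinse extrusion recovers (almost) all of it in a more
dilute sample.  Static light scattering on suitable dilutions of the two
samples, measured in the same conditions, gives intensities I1 and I2
with

    I1 * d1 / (I2 * d2) = C1 / C2 = gamma,

because the instrument constant, the weight-averaged molar mass and the
form factor are identical for the two samples (same vesicle size
distribution) and cancel in the ratio.  Conservation of the weighed-in
lipid mass M0 over the recovered volumes closes the system:

    M0 = C1 * V1 + C2 * (V_T - V1),

where the dead volume trapped in the extruder is assumed to hold the
second-extrusion concentration C2.  With alpha = M0/V1 and
upsilon = (V_T - V1)/V1 the closed-form solution is

    C2 = alpha / (gamma + upsilon),      C1 = alpha * gamma / (gamma + upsilon).

Uncertainties on the intensities (and optionally on M0 and the volumes)
are propagated to C1 and C2 by the first-order delta method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExtrusionPair",
    "ConcentrationResult",
    "StandardReference",
    "AggregateEstimate",
    "gamma_from_intensities",
    "compute_gamma",
    "solve_concentrations",
    "propagate_errors",
    "aggregate_values",
    "aggregate_preparations",
    "concentration_from_standard",
]


@dataclass(frozen=True)
class ExtrusionPair:
    """Bookkeeping and intensity record of one two-extrusion experiment.

    Parameters
    ----------
    m0_mg : float
        Total lipid mass weighed into the film, mg.
    v1_ml, v2_ml : float
        Volumes recovered from extrusion I and II, mL.
    vt_ml : float
        Total volume loaded into the extruder including the rinse, mL;
        the dead volume is vt - v1 - v2 >= 0.
    d1, d2 : float
        Dilution factors applied before the scattering measurement (>= 1).
    i1, i2 : float
        Buffer-subtracted scattered intensities of the two diluted
        samples, arbitrary units, measured in the same conditions.
    i1_se, i2_se : float
        Standard errors of the intensities (0 if unknown).
    """

    m0_mg: float
    v1_ml: float
    v2_ml: float
    vt_ml: float
    d1: float
    d2: float
    i1: float
    i2: float
    i1_se: float = 0.0
    i2_se: float = 0.0
    m0_se: float = 0.0
    v1_se: float = 0.0
    vt_se: float = 0.0

    def __post_init__(self) -> None:
        for name in ("m0_mg", "v1_ml", "v2_ml", "vt_ml", "d1", "d2", "i1"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not self.i2 > 0:
            raise ValueError(
                f"extrusion-II intensity must be positive, got {self.i2}: "
                "the rinse sample scatters at or below the buffer level (degenerate run)"
            )
        if self.d1 < 1 or self.d2 < 1:
            raise ValueError("dilution factors must be >= 1")
        if self.vt_ml < self.v1_ml + self.v2_ml - 1e-12:
            raise ValueError(
                f"total volume {self.vt_ml} mL is smaller than the recovered "
                f"volumes {self.v1_ml} + {self.v2_ml} mL (negative dead volume)"
            )
        for name in ("i1_se", "i2_se", "m0_se", "v1_se", "vt_se"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def dead_volume_ml(self) -> float:
        """Volume trapped in the extruder: vt - v1 - v2."""
        return self.vt_ml - self.v1_ml - self.v2_ml

    @classmethod
    def from_replicates(
        cls,
        m0_mg: float,
        v1_ml: float,
        v2_ml: float,
        vt_ml: float,
        d1: float,
        d2: float,
        i1_replicates,
        i2_replicates,
        buffer_replicates=None,
        **kwargs,
    ) -> "ExtrusionPair":
        """Build a pair from replicate intensity readings.

        Replicates are averaged and SE = SD/sqrt(n).  If raw readings are
        given together with ``buffer_replicates``, the buffer mean is
        subtracted from both samples and its SE added in quadrature.
        """
        def mean_se(values):
            arr = np.asarray(values, dtype=float)
            if arr.size == 0:
                raise ValueError("empty replicate list")
            se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
            return float(arr.mean()), se

        i1, i1_se = mean_se(i1_replicates)
        i2, i2_se = mean_se(i2_replicates)
        if buffer_replicates is not None:
            bg, bg_se = mean_se(buffer_replicates)
            i1, i1_se = i1 - bg, math.hypot(i1_se, bg_se)
            i2, i2_se = i2 - bg, math.hypot(i2_se, bg_se)
        return cls(
            m0_mg=m0_mg, v1_ml=v1_ml, v2_ml=v2_ml, vt_ml=vt_ml,
            d1=d1, d2=d2, i1=i1, i2=i2, i1_se=i1_se, i2_se=i2_se, **kwargs,
        )


@dataclass(frozen=True)
class ConcentrationResult:
    """Solved weight concentrations of the two extrusion samples.

    c1/c2 equals gamma and c1*v1 + c2*(vt - v1) equals m0 identically
    (closed-form solution of the two-equation system).
    """

    c1_mg_ml: float
    c2_mg_ml: float
    c1_se: float
    c2_se: float
    alpha: float      # M0 / V1, mg/mL
    upsilon: float    # (V_T - V1) / V1
    gamma: float      # (I1 d1) / (I2 d2) = C1 / C2
    closure_residual: float
    se_is_zero: bool = False

    def __post_init__(self) -> None:
        if not self.c1_mg_ml > 0 or not self.c2_mg_ml > 0:
            raise ValueError("concentrations must be positive")


@dataclass(frozen=True)
class StandardReference:
    """A previously characterized preparation used as a scattering standard.

    ``r_std`` may be an absolute Rayleigh ratio (1/cm) or a raw intensity,
    as long as the unknown sample is measured on the same scale, angle and
    setup; only the ratio R/R_std enters the assay.
    """

    r_std: float
    c_std_mg_ml: float
    d_std: float = 1.0
    composition: str = ""
    nominal_size_nm: float | None = None

    def __post_init__(self) -> None:
        if not self.r_std > 0:
            raise ValueError("standard scattering reading r_std must be positive")
        if not self.c_std_mg_ml > 0:
            raise ValueError("standard concentration must be positive")
        if not self.d_std > 0:
            raise ValueError("standard dilution must be positive")


@dataclass(frozen=True)
class AggregateEstimate:
    """Mean of two independent preparations with its attributed uncertainty."""

    mean: float
    measurement_error: float   # combined propagated SEs of the two preparations
    preparation_spread: float  # sqrt(sum of squared deviations from the mean)
    uncertainty: float         # max of the two
    source: str                # which term dominates: "measurement" or "spread"


def gamma_from_intensities(i1: float, d1: float, i2: float, d2: float) -> float:
    """Concentration ratio gamma = (I1 d1)/(I2 d2) from dilution-corrected
    intensities.  Invariant under a common rescaling of I1 and I2, hence
    independent of the instrument, angle and incident power."""
    if not i2 * d2 > 0:
        raise ValueError(
            f"extrusion-II dilution-corrected intensity must be positive, got I2*d2 = {i2 * d2}"
        )
    if not i1 * d1 > 0:
        raise ValueError("extrusion-I dilution-corrected intensity must be positive")
    return (i1 * d1) / (i2 * d2)


def compute_gamma(pair: ExtrusionPair) -> float:
    """gamma = (I1 d1)/(I2 d2) for an extrusion pair."""
    return gamma_from_intensities(pair.i1, pair.d1, pair.i2, pair.d2)


def propagate_errors(pair: ExtrusionPair) -> tuple[float, float]:
    """First-order (delta-method) standard errors of (C1, C2).

    Writing S = V1 (gamma - 1) + V_T, the solution is C2 = M0/S and
    C1 = gamma M0 / S; the gradient with respect to (I1, I2, M0, V1, V_T)
    is analytic.  By default the volumes and M0 are exact (read off the
    syringe scale / balance); their SEs enter only if set on the pair.
    Missing intensity SEs propagate as zeros with a warning.
    """
    if pair.i1_se == 0.0 and pair.i2_se == 0.0:
        warnings.warn(
            "intensity standard errors are zero; propagated concentration SEs are zero",
            stacklevel=2,
        )
    gamma = compute_gamma(pair)
    m0, v1, vt = pair.m0_mg, pair.v1_ml, pair.vt_ml
    S = v1 * (gamma - 1.0) + vt
    c2 = m0 / S
    c1 = gamma * c2

    dgamma_di1 = gamma / pair.i1
    dgamma_di2 = -gamma / pair.i2
    dc2_dgamma = -m0 * v1 / S**2
    dc1_dgamma = m0 * (vt - v1) / S**2

    # gradients wrt (m0, v1, vt)
    dc2_dm0, dc1_dm0 = c2 / m0, c1 / m0
    dc2_dv1 = -m0 * (gamma - 1.0) / S**2
    dc1_dv1 = gamma * dc2_dv1
    dc2_dvt = -m0 / S**2
    dc1_dvt = gamma * dc2_dvt

    var_c1 = (
        (dc1_dgamma * dgamma_di1 * pair.i1_se) ** 2
        + (dc1_dgamma * dgamma_di2 * pair.i2_se) ** 2
        + (dc1_dm0 * pair.m0_se) ** 2
        + (dc1_dv1 * pair.v1_se) ** 2
        + (dc1_dvt * pair.vt_se) ** 2
    )
    var_c2 = (
        (dc2_dgamma * dgamma_di1 * pair.i1_se) ** 2
        + (dc2_dgamma * dgamma_di2 * pair.i2_se) ** 2
        + (dc2_dm0 * pair.m0_se) ** 2
        + (dc2_dv1 * pair.v1_se) ** 2
        + (dc2_dvt * pair.vt_se) ** 2
    )
    return math.sqrt(var_c1), math.sqrt(var_c2)


def solve_concentrations(pair: ExtrusionPair) -> ConcentrationResult:
    """Solve the mass-closure system for (C1, C2) with propagated SEs.

    Requires V_T > V1 (a rinse volume was added).  The solution satisfies
    C1/C2 = gamma and C1 V1 + C2 (V_T - V1) = M0 identically.
    """
    if not pair.vt_ml > pair.v1_ml:
        raise ValueError(
            f"total volume vt = {pair.vt_ml} mL must exceed the first extruded "
            f"volume v1 = {pair.v1_ml} mL"
        )
    gamma = compute_gamma(pair)
    alpha = pair.m0_mg / pair.v1_ml
    upsilon = (pair.vt_ml - pair.v1_ml) / pair.v1_ml
    c2 = alpha / (gamma + upsilon)
    c1 = alpha * gamma / (gamma + upsilon)
    closure = c1 * pair.v1_ml + c2 * (pair.vt_ml - pair.v1_ml) - pair.m0_mg

    se_is_zero = pair.i1_se == 0.0 and pair.i2_se == 0.0
    if se_is_zero:
        c1_se, c2_se = 0.0, 0.0
    else:
        c1_se, c2_se = propagate_errors(pair)

    if c1 > alpha * (1 + 1e-12):
        # cannot happen for valid inputs; guards against inconsistent records
        raise ValueError("C1 exceeds M0/V1: inconsistent extrusion record")

    return ConcentrationResult(
        c1_mg_ml=c1,
        c2_mg_ml=c2,
        c1_se=c1_se,
        c2_se=c2_se,
        alpha=alpha,
        upsilon=upsilon,
        gamma=gamma,
        closure_residual=closure,
        se_is_zero=se_is_zero,
    )


def aggregate_values(
    x_a: float, se_a: float, x_b: float, se_b: float
) -> AggregateEstimate:
    """Combine two independent preparations of the same nominal sample.

    The estimate is the plain mean.  Two uncertainties compete: the
    combined measurement error of the mean,
    eps_AB = sqrt(se_A^2 + se_B^2)/2, and the preparation spread
    sigma_AB = sqrt(dx_A^2 + dx_B^2) with dx = x - mean.  The larger of
    the two is attributed to the final value, so that near-identical
    propagated errors cannot understate preparation-to-preparation
    variability.
    """
    mean = 0.5 * (x_a + x_b)
    eps = math.sqrt(se_a**2 + se_b**2) / 2.0
    sigma = math.hypot(x_a - mean, x_b - mean)
    if eps >= sigma:
        return AggregateEstimate(mean, eps, sigma, eps, "measurement")
    return AggregateEstimate(mean, eps, sigma, sigma, "spread")


def aggregate_preparations(
    res_a: ConcentrationResult, res_b: ConcentrationResult
) -> dict[str, AggregateEstimate]:
    """Aggregate the C1 and C2 estimates of two independent preparations."""
    return {
        "c1": aggregate_values(res_a.c1_mg_ml, res_a.c1_se, res_b.c1_mg_ml, res_b.c1_se),
        "c2": aggregate_values(res_a.c2_mg_ml, res_a.c2_se, res_b.c2_mg_ml, res_b.c2_se),
    }


def concentration_from_standard(
    r: float, d: float, std: StandardReference
) -> float:
    """Concentration of an unknown sample from a characterized standard.

    C = C_std * (d / d_std) * (R / R_std), valid when the unknown matches
    the standard in composition and size distribution (same molar mass and
    form factor) and both are read at the same angle on the same intensity
    scale.  The caller asserts the match; a DLS comparison of the two size
    distributions is the recommended check.
    """
    if not r > 0:
        raise ValueError("sample scattering reading must be positive")
    if not d > 0:
        raise ValueError("sample dilution must be positive")
    return std.c_std_mg_ml * (d / std.d_std) * (r / std.r_std)
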