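"""Two-electrode voltage-clamp analysis: I–V curves, reversal potentials,
rectification, Nernst/GHK permeability ratios and Hill dose–response fits.

Conventions
-----------
Voltages in mV, currents in nA (negative = inward), concentrations in mM,
blocker doses in µM.  The Nernst/GHK decade slope defaults to
``DECADE_SLOPE_MV = 58.17`` mV, the constant used for RT/zF in the
experiments this package models; it is exposed as an argument everywhere.

The two-solution GHK estimator recovers the Na+/K+ permeability ratio
r = p_Na/p_K from reversal potentials measured in two external solutions
(1) and (2) with different K+/Na+ composition:

    A = 10^((V_rev(1) - V_rev(2)) / s)
    r = (A·[K]_o(2) − [K]_o(1)) / ([Na]_o(1) − A·[Na]_o(2))

The unknown internal concentrations cancel, so none are required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from girkperm.errors import DataError, FitError

__all__ = [
    "DECADE_SLOPE_MV",
    "IVCurve",
    "SolutionPair",
    "DoseResponse",
    "HillFit",
    "net_iv",
    "reversal_potential",
    "rectification_index",
    "nernst_potential",
    "ghk_vrev",
    "permeability_ratio_from_vrev",
    "vrev_slope",
    "hill_inhibition",
    "hill_fit",
    "current_at",
]

#: RT/zF at the recording temperature, in mV per e-fold... per decade (log10).
DECADE_SLOPE_MV = 58.17


@dataclass
class IVCurve:
    """Current–voltage relationship on a strictly increasing voltage grid."""

    voltage: np.ndarray  # mV
    current: np.ndarray  # nA, negative = inward
    solution: tuple[float, float] | None = None  # ([K]_o, [Na]_o) in mM
    label: str = ""

    def __post_init__(self):
        self.voltage = np.asarray(self.voltage, float)
        self.current = np.asarray(self.current, float)
        if self.voltage.shape != self.current.shape or self.voltage.ndim != 1:
            raise DataError("voltage and current grids must be equal-length 1-D arrays")
        if self.voltage.size < 2 or not np.all(np.diff(self.voltage) > 0):
            raise DataError("voltage grid must be strictly increasing with >= 2 points")


@dataclass
class DoseResponse:
    """Blocker dose (µM) against % current inhibition."""

    concentration: np.ndarray
    inhibition: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.concentration = np.asarray(self.concentration, float)
        self.inhibition = np.asarray(self.inhibition, float)
        if self.concentration.shape != self.inhibition.shape:
            raise DataError("concentration and inhibition must have equal length")
        if np.any(self.concentration <= 0):
            raise DataError("concentrations must be positive")
        order = np.argsort(self.concentration)
        self.concentration = self.concentration[order]
        self.inhibition = self.inhibition[order]


@dataclass(frozen=True)
class SolutionPair:
    """Two external K+/Na+ solutions with their measured reversal potentials."""

    K_o_1: float
    Na_o_1: float
    K_o_2: float
    Na_o_2: float
    v_rev_1: float  # mV
    v_rev_2: float  # mV
    decade_slope: float = DECADE_SLOPE_MV

    @property
    def A(self) -> float:
        """10^(V_rev(1)/s) / 10^(V_rev(2)/s)."""
        return 10.0 ** ((self.v_rev_1 - self.v_rev_2) / self.decade_slope)


@dataclass
class HillFit:
    """Result of a Hill-equation fit: slope h, midpoint IC50, residuals."""

    h: float
    ic50: float  # µM
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def rmsd(self) -> float:
        return float(np.sqrt(np.mean(self.residuals**2))) if self.residuals.size else float("nan")


# ---------------------------------------------------------------------------
# I–V curve operations
# ---------------------------------------------------------------------------


def net_iv(raw: IVCurve, reference: IVCurve, mode: str = "blocker_insensitive_subtraction") -> IVCurve:
    """Pointwise subtraction of a reference curve from a raw recording.

    ``mode`` records how the reference was obtained: the residual current
    after full pharmacological block ("blocker_insensitive_subtraction")
    or the average of naive-cell recordings ("naive_average_subtraction").
    The reference is linearly interpolated onto the raw grid; the result
    is restricted to the overlapping voltage range.
    """
    if mode not in ("blocker_insensitive_subtraction", "naive_average_subtraction"):
        raise DataError(f"unknown subtraction mode {mode!r}")
    lo = max(raw.voltage[0], reference.voltage[0])
    hi = min(raw.voltage[-1], reference.voltage[-1])
    keep = (raw.voltage >= lo) & (raw.voltage <= hi)
    if keep.sum() < 2:
        raise DataError("raw and reference voltage ranges do not overlap")
    v = raw.voltage[keep]
    if v.shape == reference.voltage.shape and np.array_equal(v, reference.voltage):
        ref_i = reference.current  # shared grid: exact subtraction, no resampling
    else:
        ref_i = np.interp(v, reference.voltage, reference.current)
    return IVCurve(
        voltage=v,
        current=raw.current[keep] - ref_i,
        solution=raw.solution,
        label=f"{raw.label} minus {reference.label} ({mode})",
    )


def reversal_potential(iv: IVCurve, smooth: bool = False) -> float:
    """Zero crossing of the I–V curve (mV) by linear interpolation.

    With ``smooth=True`` a 5-point running median is applied first, for
    noisy ramps.  Exactly one sign change is required; none raises a
    range error, several an ambiguity error listing the crossings.
    """
    i = iv.current
    if smooth and i.size >= 5:
        from scipy.ndimage import median_filter

        i = median_filter(i, size=5, mode="nearest")
    sign = np.sign(i)
    on_zero = np.nonzero(sign == 0)[0]
    crossings = list(iv.voltage[on_zero])
    for k in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        v0, v1 = iv.voltage[k], iv.voltage[k + 1]
        i0, i1 = i[k], i[k + 1]
        crossings.append(float(v0 - i0 * (v1 - v0) / (i1 - i0)))
    if not crossings:
        raise DataError("current does not change sign within the voltage range")
    if len(crossings) > 1:
        raise DataError(f"ambiguous reversal potential; crossings at {sorted(crossings)} mV")
    return float(crossings[0])


def rectification_index(iv: IVCurve, v_rev: float) -> float:
    """F_ir = I(V_rev + 50) / I(V_rev − 50), currents linearly interpolated.

    On a net I–V curve the two currents straddle the zero crossing with
    opposite signs, so the index is reported as the magnitude ratio
    |I(V_rev+50)| / |I(V_rev−50)|: 1 for an ohmic (or any odd-symmetric)
    curve, << 1 for an inward rectifier, 0 for a fully suppressed outward
    limb.
    """
    v_plus, v_minus = v_rev + 50.0, v_rev - 50.0
    if v_minus < iv.voltage[0] or v_plus > iv.voltage[-1]:
        raise DataError(f"V_rev ± 50 mV ({v_minus:g}, {v_plus:g}) outside ramp range")
    i_plus = float(np.interp(v_plus, iv.voltage, iv.current))
    i_minus = float(np.interp(v_minus, iv.voltage, iv.current))
    if abs(i_minus) < 1e-12:
        raise DataError("inward-limb current at V_rev − 50 mV is zero; F_ir undefined")
    return abs(i_plus) / abs(i_minus)


def current_at(iv: IVCurve, v: float) -> float:
    """Linearly interpolated current (nA) at voltage v (mV)."""
    if v < iv.voltage[0] or v > iv.voltage[-1]:
        raise DataError(f"voltage {v} mV outside grid [{iv.voltage[0]}, {iv.voltage[-1]}]")
    return float(np.interp(v, iv.voltage, iv.current))


# ---------------------------------------------------------------------------
# Nernst / GHK
# ---------------------------------------------------------------------------


def nernst_potential(x_out: float, x_in: float, decade_slope: float = DECADE_SLOPE_MV) -> float:
    """Nernst potential s·log10([X]_out/[X]_in) in mV."""
    if x_out <= 0 or x_in <= 0:
        raise DataError("concentrations must be positive")
    return decade_slope * np.log10(x_out / x_in)


def ghk_vrev(
    K_o: float,
    Na_o: float,
    K_i: float,
    Na_i: float,
    r: float,
    decade_slope: float = DECADE_SLOPE_MV,
) -> float:
    """Bi-ionic GHK reversal potential s·log10[(K_o + r·Na_o)/(K_i + r·Na_i)].

    r = p_Na/p_K.  At r = 0 this reduces to the K+ Nernst potential; at
    r = 1 only total cation concentrations matter.
    """
    num = K_o + r * Na_o
    den = K_i + r * Na_i
    if num <= 0 or den <= 0:
        raise DataError("GHK numerator/denominator must be positive")
    return decade_slope * np.log10(num / den)


def permeability_ratio_from_vrev(pair: SolutionPair) -> float:
    """Recover r = p_Na/p_K from reversal potentials in two solutions.

    Internal concentrations cancel.  A negative recovered r (possible
    under measurement noise) is returned with a warning rather than
    clamped, so that averaging across cells stays unbiased.
    """
    A = pair.A
    denom = pair.Na_o_1 - A * pair.Na_o_2
    if abs(denom) < 1e-12:
        raise DataError("solutions are ill-conditioned for the GHK estimator (identical effective composition)")
    r = (A * pair.K_o_2 - pair.K_o_1) / denom
    if r < 0:
        warnings.warn(f"negative permeability ratio {r:.4g}; likely measurement noise", stacklevel=2)
    return float(r)


def vrev_slope(points) -> float:
    """Least-squares slope of V_rev (mV) against log10 [K]_o — mV/decade.

    ``points`` is a sequence of ([K]_o in mM, V_rev in mV) pairs; at least
    two distinct concentrations are required.
    """
    pts = np.asarray(list(points), float)
    if pts.ndim != 2 or pts.shape[0] < 2 or len(set(pts[:, 0])) < 2:
        raise DataError("need at least two distinct [K]_o values")
    if np.any(pts[:, 0] <= 0):
        raise DataError("concentrations must be positive")
    slope, _ = np.polyfit(np.log10(pts[:, 0]), pts[:, 1], 1)
    return float(slope)


# ---------------------------------------------------------------------------
# Hill dose–response
# ---------------------------------------------------------------------------


def hill_inhibition(x, h: float, ic50: float) -> np.ndarray:
    """% inhibition = 100·x^h / (IC50^h + x^h)."""
    x = np.asarray(x, float)
    return 100.0 * x**h / (ic50**h + x**h)


def hill_fit(dr: DoseResponse, init: tuple[float, float] | None = None) -> HillFit:
    """Nonlinear least-squares Hill fit in (log10 IC50, h) parameterisation.

    The log parameterisation keeps IC50 positive and makes the fit
    scale-equivariant.  Initial IC50 defaults to the dose closest to 50%
    inhibition, initial h to 1; a few perturbed restarts are attempted on
    non-convergence.
    """
    x, y = dr.concentration, dr.inhibition
    if len(set(x)) < 3:
        raise DataError("need at least 3 distinct concentrations")
    if np.any((y < -10.0) | (y > 110.0)):
        raise DataError("inhibition values outside [-10, 110]%")

    if init is None:
        ic0 = x[np.argmin(np.abs(y - 50.0))]
        h0 = 1.0
    else:
        ic0, h0 = init

    def resid(p):
        log_ic50, h = p
        return hill_inhibition(x, h, 10.0**log_ic50) - y

    last = None
    for attempt, (dic, dh) in enumerate([(0.0, 0.0), (0.5, 0.3), (-0.5, -0.3), (1.0, 1.0)]):
        p0 = np.array([np.log10(ic0) + dic, max(h0 + dh, 0.05)])
        sol = optimize.least_squares(resid, p0, bounds=([-12.0, 1e-3], [12.0, 20.0]))
        last = sol
        if sol.success:
            log_ic50, h = sol.x
            return HillFit(h=float(h), ic50=float(10.0**log_ic50), residuals=sol.fun)
    raise FitError("Hill fit did not converge", last_iterate=None if last is None else last.x)
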