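"""Ion selectivity from reversal potentials: GHK arithmetic, I-V analysis,
and voltage dependence of the open probability.

For a channel permeable only to K+ and Cl- in pure-KCl buffers (so the Cl-
concentration on each side equals the K+ concentration) the
Goldman-Hodgkin-Katz voltage equation gives the reversal potential

    U_rev = (RT/F) * ln( (x*[K]cis + [Cl]trans) / (x*[K]trans + [Cl]cis) )

with x = P_K/P_Cl, using the package-wide sign convention (trans relative to
cis, so a cation-selective channel under a cis-high gradient reverses at
positive potentials).  The equation inverts in closed form,

    x = (r*[Cl]cis - [Cl]trans) / ([K]cis - r*[K]trans),   r = exp(U_rev*F/RT),

valid strictly inside the Nernst bounds +-(RT/F)*ln(gradient).

Concentrations are used as-is (no activity coefficients), and the MOPS/Tris
buffer ions are treated as impermeant; selectivity is computed from the KCl
gradient alone.  Temperature defaults to 298.15 K when metadata omits it.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    NernstBoundError,
    NoSignChangeError,
    NonIdentifiableError,
    SchemaError,
)
from .trace_io import RecordingMeta

#: Gas constant / Faraday constant, SI.
R_GAS = 8.31446261815324
FARADAY = 96485.33212331001


def thermal_voltage_mV(temperature_K: float = 298.15) -> float:
    """RT/F in mV (25.693 mV at 298.15 K)."""
    return R_GAS * temperature_K / FARADAY * 1e3


@dataclasses.dataclass(frozen=True)
class IVDataset:
    """Per-voltage mean currents of one channel under stated buffers.

    ``points`` columns: voltage_mV (strictly increasing), mean_current_pA,
    sd_pA, n.
    """

    points: pd.DataFrame
    meta: RecordingMeta

    def __post_init__(self):
        pts = self.points.reset_index(drop=True)
        object.__setattr__(self, "points", pts)
        required = ["voltage_mV", "mean_current_pA", "sd_pA", "n"]
        missing = [c for c in required if c not in pts.columns]
        if missing:
            raise SchemaError(f"IV dataset missing columns {missing}")
        v = pts["voltage_mV"].to_numpy()
        if len(v) < 2 or np.any(np.diff(v) <= 0):
            raise SchemaError("voltages must be strictly increasing, >= 2 points")
        if np.any(pts["n"].to_numpy() < 1):
            raise SchemaError("each IV point needs n >= 1")


@dataclasses.dataclass(frozen=True)
class SelectivityResult:
    """Reversal potential, permeability ratio, and optional normalization."""

    u_rev_mV: float
    pk_over_pcl: float
    percent_of_reference: Optional[float] = None


def _concentrations(meta: RecordingMeta) -> Tuple[float, float, float, float]:
    # pure KCl: [Cl] == [K] per side
    k_cis, k_trans = meta.cis_K_mM, meta.trans_K_mM
    if k_cis <= 0 or k_trans <= 0:
        raise ValueError("concentrations must be positive")
    return k_cis, k_trans, k_cis, k_trans  # K_cis, K_trans, Cl_cis, Cl_trans


def ghk_reversal(pk_over_pcl: float, meta: RecordingMeta) -> float:
    """GHK reversal potential in mV for permeability ratio x = P_K/P_Cl.

    ``x = inf`` is accepted as the pure-cation limit (Nernst potential of K+).
    """
    k_cis, k_trans, cl_cis, cl_trans = _concentrations(meta)
    vt = thermal_voltage_mV(meta.temperature_K)
    x = float(pk_over_pcl)
    if x < 0:
        raise ValueError("pk_over_pcl must be >= 0")
    if math.isinf(x):
        return vt * math.log(k_cis / k_trans)
    if x == 0:
        return vt * math.log(cl_trans / cl_cis)
    return vt * math.log((x * k_cis + cl_trans) / (x * k_trans + cl_cis))


def nernst_bound_mV(meta: RecordingMeta) -> float:
    """(RT/F)*ln(gradient): the supremum of |U_rev| over finite selectivity."""
    k_cis, k_trans, _, _ = _concentrations(meta)
    vt = thermal_voltage_mV(meta.temperature_K)
    return abs(vt * math.log(k_cis / k_trans))


def ghk_permeability_ratio(u_rev_mV: float, meta: RecordingMeta) -> float:
    """Invert the GHK voltage equation: reversal potential -> P_K/P_Cl.

    Exact closed-form inverse of :func:`ghk_reversal`.  Raises
    :class:`NernstBoundError` when |U_rev| reaches the Nernst bound (the
    ratio diverges there).
    """
    k_cis, k_trans, cl_cis, cl_trans = _concentrations(meta)
    vt = thermal_voltage_mV(meta.temperature_K)
    bound = nernst_bound_mV(meta)
    if abs(u_rev_mV) >= bound:
        raise NernstBoundError(
            f"|U_rev| = {abs(u_rev_mV):.3f} mV is at/beyond the Nernst bound "
            f"{bound:.3f} mV; permeability ratio is unbounded",
            bound_mV=bound,
        )
    r = math.exp(u_rev_mV / vt)
    x = (r * cl_cis - cl_trans) / (k_cis - r * k_trans)
    if x <= 0:
        raise NernstBoundError(
            f"U_rev = {u_rev_mV:.3f} mV implies a non-positive permeability "
            f"ratio under this gradient (bound {bound:.3f} mV)",
            bound_mV=bound,
        )
    return x


def estimate_reversal(iv: IVDataset) -> Tuple[float, float]:
    """Zero crossing of the I-V relation, with standard error.

    A weighted linear fit through the two sign-change bracketing points plus
    up to two neighbors on each side; weights are n/sd^2 (uniform if sd = 0).
    Returns (u_rev_mV, se_mV).  Raises :class:`NoSignChangeError` when the
    mean currents never change sign.
    """
    v = iv.points["voltage_mV"].to_numpy(float)
    i = iv.points["mean_current_pA"].to_numpy(float)
    sd = iv.points["sd_pA"].to_numpy(float)
    n = iv.points["n"].to_numpy(float)

    if not (np.any(i < 0) and np.any(i > 0)):
        raise NoSignChangeError("I-V currents do not change sign in range")
    sign = np.sign(i)
    c = int(np.flatnonzero(sign[:-1] != sign[1:])[0])
    lo, hi = max(0, c - 2), min(len(v), c + 4)  # bracketing pair +- 2 neighbors
    vv, ii = v[lo:hi], i[lo:hi]
    with np.errstate(divide="ignore"):
        w = np.where(sd[lo:hi] > 0, n[lo:hi] / np.square(sd[lo:hi]), np.nan)
    if np.any(~np.isfinite(w)):
        w = np.ones_like(vv)

    # weighted least squares I = a*V + b
    sw = np.sqrt(w)
    A = np.column_stack([vv, np.ones_like(vv)]) * sw[:, None]
    y = ii * sw
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    a, b = coef
    if a == 0:
        raise NoSignChangeError("I-V relation is flat; no zero crossing")
    u_rev = -b / a
    resid = y - A @ coef
    dof = max(1, len(vv) - 2)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(A.T @ A)
    # delta method for -b/a
    grad = np.array([b / a**2, -1.0 / a])
    se = float(np.sqrt(grad @ cov @ grad))
    return float(u_rev), se


def selectivity_percent(x_variant: float, x_reference: float) -> float:
    """Variant selectivity as percent of a reference: 100 * x_v / x_ref."""
    if x_variant <= 0 or x_reference <= 0:
        raise ValueError("permeability ratios must be positive")
    return 100.0 * x_variant / x_reference


def boltzmann_po(v_mV, v_half_mV, v_slope_mV):
    """Open probability vs |voltage|: 1 / (1 + exp((|V| - v_half)/v_slope))."""
    return 1.0 / (1.0 + np.exp((np.abs(v_mV) - v_half_mV) / v_slope_mV))


def fit_po_voltage(
    po_points: Sequence[Tuple[float, float]]
) -> Tuple[float, float]:
    """Least-squares Boltzmann fit of open probability vs voltage.

    Returns (v_half_mV, v_slope_mV).  Raises
    :class:`NonIdentifiableError` when the points do not span a transition
    (Po range < 0.1) and ``ValueError`` for Po outside [0, 1].
    """
    pts = np.asarray(po_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 4:
        raise ValueError("need >= 4 (voltage, Po) points")
    v, po = pts[:, 0], pts[:, 1]
    if np.any((po < 0) | (po > 1)):
        raise ValueError("Po values must lie in [0, 1]")
    if po.max() - po.min() < 0.1:
        raise NonIdentifiableError(
            "open probability nearly constant; Boltzmann midpoint not identifiable"
        )
    mid_guess = float(np.abs(v)[np.argmin(np.abs(po - 0.5))])
    try:
        popt, _ = curve_fit(
            boltzmann_po, v, po, p0=[mid_guess, 10.0],
            bounds=([0.0, 0.1], [1e4, 1e3]), maxfev=10_000,
        )
    except RuntimeError as exc:
        raise NonIdentifiableError(f"Boltzmann fit did not converge: {exc}") from exc
    return float(popt[0]), float(popt[1])
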