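"""Whole-cell voltage-clamp analysis.

Turns raw sweep traces into conductance-voltage (G'-E_M) relations, fits
Boltzmann gating per cell, estimates reversal potentials from ramp
crossovers, computes Nernst equilibria, compares cell-type groups and
predicts the direction of channel-mediated K+ flux.

Units follow electrophysiological convention: with currents in pA and
voltages in mV, the ramp I-V slope is a conductance directly in nS; the
specific conductance G' = G / area is reported in mS cm^-2
(1 nS = 1e-6 mS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .boltzmann import BoltzmannFit, fit_boltzmann, gate_open_probability
from .constants import (
    DEFAULT_TEMPERATURE_K,
    FARADAY,
    GAS_CONSTANT,
    sphere_surface_area_cm2,
)
from .recording import CurrentRecording

__all__ = [
    "GVCurve",
    "ReversalEstimate",
    "ReversalPotentialEstimator",
    "GroupComparison",
    "FluxPrediction",
    "correct_ljp",
    "surface_area",
    "ramp_conductance",
    "specific_conductance",
    "extract_gv_curve",
    "estimate_reversal",
    "nernst",
    "compare_groups",
    "predict_flux_direction",
    "analyze_recording",
]


def correct_ljp(nominal_mv, ljp_mv: float):
    """Correct nominal command voltages for the liquid junction potential.

    corrected = nominal + LJP, so a nominal 0 mV holding with the -23 mV
    low-K+ bath LJP becomes a true membrane potential of -23 mV.
    """
    if ljp_mv is None:
        raise ValueError("no liquid junction potential provided for this bath")
    return np.asarray(nominal_mv, dtype=float) + float(ljp_mv)


def surface_area(diameter_um: float) -> float:
    """Protoplast surface area in cm^2 under the sphere assumption (pi d^2)."""
    return sphere_surface_area_cm2(diameter_um)


def ramp_conductance(voltage_mv, current_pa, trim_ms: float = 2.0,
                     sampling_rate_hz: float | None = None):
    """Membrane conductance from the linear I-V slope of one testing ramp.

    Parameters
    ----------
    voltage_mv, current_pa : arrays
        Corrected ramp command voltages and the recorded currents.
    trim_ms : float
        Duration discarded at each end of the ramp (clamp settling);
        requires ``sampling_rate_hz`` to convert to samples.  Set to 0 to
        keep the whole ramp.

    Returns
    -------
    (g_ns, r_squared) : tuple of float
        Ordinary-least-squares slope in nS (pA/mV) and its R^2.
    """
    v = np.asarray(voltage_mv, dtype=float).reshape(-1)
    i = np.asarray(current_pa, dtype=float).reshape(-1)
    if v.shape != i.shape:
        raise ValueError("voltage and current must have the same length")
    if trim_ms > 0:
        if sampling_rate_hz is None:
            raise ValueError("sampling_rate_hz required when trim_ms > 0")
        k = int(round(trim_ms * sampling_rate_hz / 1000.0))
        if k > 0:
            v, i = v[k:-k], i[k:-k]
    if v.size < 5:
        raise ValueError(f"need >= 5 ramp samples after trimming, got {v.size}")
    slope, intercept = np.polyfit(v, i, 1)
    resid = i - (slope * v + intercept)
    ss_tot = float(np.sum((i - i.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(slope), r2


def specific_conductance(g_ns: float, area_cm2: float) -> float:
    """Specific conductance G' (mS cm^-2) from whole-cell G (nS) and area."""
    if area_cm2 <= 0:
        raise ValueError(f"area must be positive, got {area_cm2}")
    return g_ns * 1e-6 / area_cm2


@dataclass
class GVCurve:
    """Per-pulse specific-conductance vs membrane-potential relation.

    ``e_m_mv`` are LJP-corrected pre-pulse potentials; ``g_specific`` the
    matching G' values (mS cm^-2); ``r_squared`` the ramp-fit linearity and
    ``flagged`` marks points whose ramp fell below the linearity gate.
    """

    e_m_mv: np.ndarray
    g_specific: np.ndarray
    r_squared: np.ndarray
    flagged: np.ndarray
    protoplast_id: str
    area_cm2: float

    def __post_init__(self):
        if len(np.unique(self.e_m_mv)) != len(self.e_m_mv):
            raise ValueError("pre-pulse membrane potentials must be distinct")
        if np.any(np.asarray(self.g_specific) < -1e-12):
            raise ValueError("specific conductance must be non-negative")


def extract_gv_curve(rec: CurrentRecording, trim_ms: float = 2.0,
                     r2_gate: float = 0.99) -> GVCurve:
    """Build the G'-E_M relation of one recording from its testing ramps.

    For every sweep the OLS slope of current vs corrected ramp voltage
    gives G (nS); division by the protoplast surface area gives G', keyed
    by the corrected pre-pulse potential.  Ramps with R^2 below
    ``r2_gate`` are flagged (excluded from Boltzmann fitting).
    """
    proto = rec.protocol
    area = surface_area(rec.diameter_um)
    ramp_v_nom = proto.ramp_voltages()
    e_m, g_sp, r2s, flags = [], [], [], []
    for k, level in enumerate(proto.pulse_levels):
        ramp = rec.ramp_samples(k)
        v_corr = correct_ljp(ramp_v_nom, proto.ljp_mv)
        g_ns, r2 = ramp_conductance(
            v_corr, ramp["current_pa"].to_numpy(),
            trim_ms=trim_ms, sampling_rate_hz=proto.sampling_rate_hz,
        )
        e_m.append(float(correct_ljp(level, proto.ljp_mv)))
        g_sp.append(max(specific_conductance(g_ns, area), 0.0))
        r2s.append(r2)
        flags.append(r2 < r2_gate)
    return GVCurve(
        e_m_mv=np.array(e_m), g_specific=np.array(g_sp),
        r_squared=np.array(r2s), flagged=np.array(flags),
        protoplast_id=rec.protoplast_id, area_cm2=area,
    )


@dataclass
class ReversalEstimate:
    """Reversal potential from pairwise ramp-line intersections.

    ``e_rev_mv`` is the median intersection voltage (LJP-corrected);
    ``dispersion_mv`` the median absolute deviation of the intersections.
    """

    e_rev_mv: float
    slopes: np.ndarray
    intercepts: np.ndarray
    intersections: np.ndarray
    dispersion_mv: float


class ReversalPotentialEstimator(BaseEstimator):
    """Estimate the current reversal potential from a family of ramps.

    Each testing ramp probes the instantaneous I-V relation of the channel
    population opened by its pre-pulse.  Lines fitted to ramps with
    different numbers of open channels intersect at the reversal
    potential.  The estimate is the median of all pairwise intersection
    voltages among ramps whose slopes differ by more than
    ``slope_floor_frac`` of the largest slope magnitude (near-parallel
    pairs give unstable crossings and are skipped).
    """

    def __init__(self, slope_floor_frac: float = 0.05, trim_ms: float = 2.0):
        self.slope_floor_frac = slope_floor_frac
        self.trim_ms = trim_ms

    def fit(self, ramps, sampling_rate_hz: float | None = None):
        """Fit from ``ramps``: a sequence of (voltage_mv, current_pa) pairs."""
        if len(ramps) < 3:
            raise ValueError(f"need >= 3 ramps, got {len(ramps)}")
        slopes, intercepts = [], []
        for v, i in ramps:
            v = np.asarray(v, dtype=float)
            i = np.asarray(i, dtype=float)
            if self.trim_ms > 0 and sampling_rate_hz is not None:
                k = int(round(self.trim_ms * sampling_rate_hz / 1000.0))
                if k > 0:
                    v, i = v[k:-k], i[k:-k]
            m, b = np.polyfit(v, i, 1)
            slopes.append(m)
            intercepts.append(b)
        slopes = np.array(slopes)
        intercepts = np.array(intercepts)
        floor = self.slope_floor_frac * float(np.max(np.abs(slopes)))
        xs = []
        for a, b in combinations(range(len(slopes)), 2):
            dm = slopes[a] - slopes[b]
            if abs(dm) > floor:
                xs.append((intercepts[b] - intercepts[a]) / dm)
        if not xs:
            raise ValueError("all ramp slopes are equal: no crossover point")
        xs = np.array(xs)
        self.slopes_ = slopes
        self.intercepts_ = intercepts
        self.intersections_ = xs
        self.e_rev_mv_ = float(np.median(xs))
        self.dispersion_mv_ = float(np.median(np.abs(xs - self.e_rev_mv_)))
        self.result_ = ReversalEstimate(
            e_rev_mv=self.e_rev_mv_, slopes=slopes, intercepts=intercepts,
            intersections=xs, dispersion_mv=self.dispersion_mv_,
        )
        return self


def estimate_reversal(rec: CurrentRecording, slope_floor_frac: float = 0.05,
                      trim_ms: float = 2.0) -> ReversalEstimate:
    """Reversal potential of one recording from its testing-ramp crossovers."""
    proto = rec.protocol
    ramp_v = correct_ljp(proto.ramp_voltages(), proto.ljp_mv)
    ramps = [
        (ramp_v, rec.ramp_samples(k)["current_pa"].to_numpy())
        for k in range(len(proto.pulse_levels))
    ]
    est = ReversalPotentialEstimator(
        slope_floor_frac=slope_floor_frac, trim_ms=trim_ms
    ).fit(ramps, sampling_rate_hz=proto.sampling_rate_hz)
    return est.result_


def nernst(c_out_mm: float, c_in_mm: float, valence: int,
           temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Nernst equilibrium potential in mV: (RT/zF) ln(c_out/c_in)."""
    if c_out_mm <= 0 or c_in_mm <= 0:
        raise ValueError("ion concentrations must be positive")
    if valence == 0:
        raise ValueError("valence must be non-zero")
    return (
        1000.0 * GAS_CONSTANT * temperature_k / (valence * FARADAY)
        * math.log(c_out_mm / c_in_mm)
    )


@dataclass
class GroupComparison:
    """Per-parameter group means +- SE and Welch two-sided t-test P-values."""

    table: pd.DataFrame  # index: parameter; columns: mean/se/n per group, p_value
    group_a: str
    group_b: str

    def p_value(self, parameter: str) -> float:
        return float(self.table.loc[parameter, "p_value"])

    def mean_difference(self, parameter: str) -> float:
        row = self.table.loc[parameter]
        return float(row[f"mean_{self.group_a}"] - row[f"mean_{self.group_b}"])


_FIT_PARAMS = ("g_basal", "g_max", "g_max_net", "e_half", "z")


def compare_groups(fits_by_type: dict[str, list[BoltzmannFit]],
                   parameters=_FIT_PARAMS) -> GroupComparison:
    """Compare per-cell Boltzmann parameters between two cell types.

    Follows fit-then-average: each cell contributes its own best-fit
    values; non-converged fits must be excluded by the caller.  Uses the
    Welch (unequal-variance) two-sided t-test per parameter.
    """
    if len(fits_by_type) != 2:
        raise ValueError("exactly two groups required")
    (name_a, fits_a), (name_b, fits_b) = fits_by_type.items()
    for name, fits in ((name_a, fits_a), (name_b, fits_b)):
        if len(fits) < 2:
            raise ValueError(f"group {name!r} needs >= 2 converged fits")
        if any(not f.converged for f in fits):
            raise ValueError(f"group {name!r} contains non-converged fits")
    rows = {}
    for p in parameters:
        a = np.array([getattr(f, p) for f in fits_a])
        b = np.array([getattr(f, p) for f in fits_b])
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            # degenerate zero-variance groups: the t statistic is undefined
            pval = 1.0 if a[0] == b[0] else 0.0
        else:
            pval = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows[p] = {
            f"mean_{name_a}": a.mean(), f"se_{name_a}": a.std(ddof=1) / np.sqrt(len(a)),
            f"n_{name_a}": len(a),
            f"mean_{name_b}": b.mean(), f"se_{name_b}": b.std(ddof=1) / np.sqrt(len(b)),
            f"n_{name_b}": len(b),
            "p_value": pval,
        }
    return GroupComparison(table=pd.DataFrame(rows).T, group_a=name_a, group_b=name_b)


@dataclass
class FluxPrediction:
    """Signed relative K+ flux through the gated population at E_M."""

    flux: float
    direction: str  # "influx", "efflux" or "zero"
    open_fraction: float


def predict_flux_direction(e_m_mv: float, e_k_mv: float,
                           fit: BoltzmannFit) -> FluxPrediction:
    """Relative K+ flux at membrane potential ``e_m_mv``.

    flux ∝ -[G'_b + G'_max_net * P_O(E_M)] * (E_M - E_K): positive flux is
    influx (E_M below the K+ equilibrium draws K+ in), negative is efflux.
    """
    p_o = float(gate_open_probability(e_m_mv, fit.e_half, fit.z, fit.temperature_k))
    g = fit.g_basal + fit.g_max_net * p_o
    flux = -g * (e_m_mv - e_k_mv)
    if flux > 0:
        direction = "influx"
    elif flux < 0:
        direction = "efflux"
    else:
        direction = "zero"
    return FluxPrediction(flux=flux, direction=direction, open_fraction=p_o)


def analyze_recording(rec: CurrentRecording, trim_ms: float = 2.0,
                      r2_gate: float = 0.99,
                      temperature_k: float = DEFAULT_TEMPERATURE_K):
    """Full single-cell pipeline: G-V extraction, Boltzmann fit, reversal.

    Returns ``(curve, fit, reversal)``.
    """
    curve = extract_gv_curve(rec, trim_ms=trim_ms, r2_gate=r2_gate)
    fit = fit_boltzmann(curve, temperature_k=temperature_k)
    rev = estimate_reversal(rec, trim_ms=trim_ms)
    return curve, fit, rev
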