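"""Boltzmann model of voltage-gated channel conductance.

The steady-state whole-cell specific conductance of a population of
voltage-gated channels is modelled as a two-state Boltzmann function of
membrane potential E (mV):

    G'(E) = G'_b + (G'_max - G'_b) / (1 + exp(z*F*(E - E_1/2) / (R*T)))

where G'_b is the voltage-invariant basal specific conductance, G'_max the
maximal specific conductance (both mS cm^-2), E_1/2 the half-activation
voltage (mV) and z the effective gating charge.  With z > 0 the open
fraction decreases with depolarization (an inward-rectifier convention):

    P_O(E) = 1 / (1 + exp(z*F*(E - E_1/2) / (R*T)))

so P_O(E_1/2) = 0.5 and G'(E) = G'_b + (G'_max - G'_b) * P_O(E).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

from .constants import DEFAULT_TEMPERATURE_K, thermal_voltage_mv

__all__ = [
    "BoltzmannFit",
    "BoltzmannGVFitter",
    "gate_open_probability",
    "boltzmann_conductance",
    "open_fraction",
    "fit_boltzmann",
]


def gate_open_probability(
    e_m_mv,
    e_half_mv: float,
    z: float,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    thermal_mv: float | None = None,
):
    """Steady-state open probability P_O at membrane potential ``e_m_mv``.

    ``thermal_mv`` overrides R*T/F (mV) when a specific rounded thermal
    voltage is wanted; otherwise it is computed from ``temperature_k``.
    """
    if z <= 0:
        raise ValueError(f"gating charge z must be positive, got {z}")
    vt = thermal_voltage_mv(temperature_k) if thermal_mv is None else thermal_mv
    e_m_mv = np.asarray(e_m_mv, dtype=float)
    x = z * (e_m_mv - e_half_mv) / vt
    return 1.0 / (1.0 + np.exp(x))


def boltzmann_conductance(
    e_m_mv,
    g_basal: float,
    g_max: float,
    e_half_mv: float,
    z: float,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
):
    """Specific conductance G'(E) of the Boltzmann-gated population."""
    p = gate_open_probability(e_m_mv, e_half_mv, z, temperature_k)
    return g_basal + (g_max - g_basal) * p


@dataclass
class BoltzmannFit:
    """Best-fit gating parameters for one cell.

    Attributes
    ----------
    g_basal, g_max : float
        Basal and maximal specific conductance, mS cm^-2.
    e_half : float
        Half-activation voltage, mV.
    z : float
        Effective gating charge (dimensionless, > 0).
    converged : bool
        False when the optimiser failed or the curve was degenerate;
        non-converged fits are excluded from group averaging.
    residual_norm : float
        Euclidean norm of the fit residuals.
    """

    g_basal: float
    g_max: float
    e_half: float
    z: float
    converged: bool = True
    residual_norm: float = 0.0
    temperature_k: float = DEFAULT_TEMPERATURE_K
    cell_id: str | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.converged:
            if not (self.g_max >= self.g_basal >= 0):
                raise ValueError(
                    f"require g_max >= g_basal >= 0, got {self.g_max}, {self.g_basal}"
                )
            if self.z <= 0:
                raise ValueError(f"gating charge must be positive, got {self.z}")

    @property
    def g_max_net(self) -> float:
        """Net maximal specific conductance, G'_max - G'_b (exact)."""
        return self.g_max - self.g_basal

    def conductance(self, e_m_mv):
        return boltzmann_conductance(
            e_m_mv, self.g_basal, self.g_max, self.e_half, self.z, self.temperature_k
        )

    def open_fraction(self, e_m_mv, thermal_mv: float | None = None):
        return gate_open_probability(
            e_m_mv, self.e_half, self.z, self.temperature_k, thermal_mv=thermal_mv
        )


def open_fraction(e_m_mv, fit: BoltzmannFit, temperature_k: float | None = None,
                  thermal_mv: float | None = None):
    """Open fraction P_O at ``e_m_mv`` for a fitted cell.

    Equivalent to (G'(E) - G'_b) / G'_max_net at the same voltage.
    """
    t = fit.temperature_k if temperature_k is None else temperature_k
    return gate_open_probability(e_m_mv, fit.e_half, fit.z, t, thermal_mv=thermal_mv)


class BoltzmannGVFitter(BaseEstimator):
    """Nonlinear least-squares fitter for the Boltzmann G'-E_M relation.

    Parameters
    ----------
    temperature_k : float
        Absolute temperature used for the thermal voltage R*T/F.
    z_max : float
        Upper bound on the effective gating charge.
    max_nfev : int
        Function-evaluation budget for the optimiser.

    Fitted attributes (after ``fit``): ``g_basal_``, ``g_max_``, ``e_half_``,
    ``z_``, ``g_max_net_``, ``converged_``, ``residual_norm_``, ``result_``.
    A degenerate or non-convergent fit sets ``converged_ = False`` and NaN
    parameters instead of raising.
    """

    def __init__(self, temperature_k: float = DEFAULT_TEMPERATURE_K,
                 z_max: float = 5.0, max_nfev: int = 20000):
        self.temperature_k = temperature_k
        self.z_max = z_max
        self.max_nfev = max_nfev

    def fit(self, X, y):
        """Fit to membrane potentials ``X`` (mV) and conductances ``y`` (mS cm^-2)."""
        e = np.asarray(X, dtype=float).reshape(-1)
        g = np.asarray(y, dtype=float).reshape(-1)
        if e.shape != g.shape:
            raise ValueError("X and y must have the same length")
        if e.size < 6:
            raise ValueError(f"need >= 6 G-V points to fit, got {e.size}")
        if np.any(g < 0):
            raise ValueError("specific conductance must be non-negative")

        self.n_points_ = e.size
        if np.ptp(g) == 0.0:
            # flat curve: gating parameters unidentifiable
            self._mark_failed(g)
            return self

        vt = thermal_voltage_mv(self.temperature_k)

        def model(em, g_b, g_net, e_half, z):
            return g_b + g_net / (1.0 + np.exp(z * (em - e_half) / vt))

        # mid-conductance voltage as the E_1/2 starting point
        mid = 0.5 * (g.min() + g.max())
        e0 = float(e[np.argmin(np.abs(g - mid))])
        p0 = [max(g.min(), 1e-12), max(np.ptp(g), 1e-12), e0, 1.0]
        lo = [0.0, 0.0, e.min() - 500.0, 1e-6]
        hi = [np.inf, np.inf, e.max() + 500.0, self.z_max]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    model, e, g, p0=p0, bounds=(lo, hi), max_nfev=self.max_nfev,
                    ftol=1e-14, xtol=1e-14, gtol=1e-14,
                )
        except (RuntimeError, ValueError):
            self._mark_failed(g)
            return self

        g_b, g_net, e_half, z = (float(v) for v in popt)
        resid = g - model(e, *popt)
        self.g_basal_ = g_b
        self.g_max_ = g_b + g_net
        self.g_max_net_ = g_net
        self.e_half_ = e_half
        self.z_ = z
        self.converged_ = True
        self.residual_norm_ = float(np.linalg.norm(resid))
        self.result_ = BoltzmannFit(
            g_basal=g_b, g_max=g_b + g_net, e_half=e_half, z=z,
            converged=True, residual_norm=self.residual_norm_,
            temperature_k=self.temperature_k,
        )
        return self

    def _mark_failed(self, g):
        self.g_basal_ = self.g_max_ = self.g_max_net_ = float("nan")
        self.e_half_ = self.z_ = float("nan")
        self.converged_ = False
        self.residual_norm_ = float("nan")
        self.result_ = BoltzmannFit(
            g_basal=float(np.min(g)), g_max=float(np.max(g)),
            e_half=float("nan"), z=float("nan"),
            converged=False, residual_norm=float("nan"),
            temperature_k=self.temperature_k,
        )

    def predict(self, X):
        """Predicted G'(E) at membrane potentials ``X`` (mV)."""
        if not getattr(self, "converged_", False):
            raise RuntimeError("fit did not converge; no prediction available")
        return self.result_.conductance(np.asarray(X, dtype=float).reshape(-1))


def fit_boltzmann(curve, temperature_k: float = DEFAULT_TEMPERATURE_K) -> BoltzmannFit:
    """Fit the Boltzmann relation to the unflagged points of a G-V curve.

    ``curve`` is a :class:`leafphys.ephys.GVCurve`; flagged (low-linearity)
    points are excluded before fitting.
    """
    keep = ~np.asarray(curve.flagged, dtype=bool)
    e = np.asarray(curve.e_m_mv)[keep]
    g = np.asarray(curve.g_specific)[keep]
    fitter = BoltzmannGVFitter(temperature_k=temperature_k).fit(e, g)
    result = fitter.result_
    result.cell_id = curve.protoplast_id
    return result
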