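"""Horrigan-Aldrich dual-allosteric gating model for BK channels.

Pore opening (equilibrium L), voltage-sensor activation (J, one per
subunit) and Ca2+ binding (K, one site per subunit) are coupled by
allosteric factors D (VSD-pore), C (Ca-pore) and E (Ca-VSD). For a
homotetramer the open probability is

    Po = L (1 + KC + JD + JKCDE)^4
         / [ L (1 + KC + JD + JKCDE)^4 + (1 + K + J + JKE)^4 ]

with the voltage- and Ca-dependent equilibria

    L = L0 exp(+ZL V / kT),   J = exp(+ZJ (V - VH) / kT),   K = [Ca]/KD.

Depolarization increases both L and J, so Po rises with voltage; V0.5 is the
voltage where Po = 0.5, i.e. where the open and closed partition terms are
equal. The sign convention above is the one that yields physiological
behavior and reproduces published wild-type fits (some printed forms of the
model carry inconsistent signs in the exponentials).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import logsumexp

from .ephys import BOLTZMANN_K_OVER_E0_MV

__all__ = [
    "HAParameters",
    "GatingCurve",
    "wt_ha_parameters",
    "ha_po",
    "ha_v_half",
    "ha_v_half_grid_scan",
    "sensitivity_curve",
]

DEFAULT_T = 298.15  # K; kT/e0 = 25.693 mV


@dataclass
class HAParameters:
    """Full dual-allosteric parameter set defining Po(V, Ca).

    L0 : intrinsic closed-open equilibrium at 0 mV (dimensionless).
    ZL : gating charge of pore opening (e0).
    ZJ : gating charge of voltage-sensor activation (e0).
    VH : half-activation voltage of a single voltage sensor (mV).
    KD : Ca2+ dissociation constant (uM).
    C, D, E : allosteric coupling factors (dimensionless).
    T : temperature (K).
    """

    L0: float
    ZL: float
    ZJ: float
    VH: float
    KD: float
    C: float
    D: float
    E: float
    T: float = DEFAULT_T

    def __post_init__(self) -> None:
        for name in ("L0", "ZL", "ZJ", "KD", "C", "D", "E", "T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def kT(self) -> float:
        """Thermal voltage kT/e0 in mV."""
        return BOLTZMANN_K_OVER_E0_MV * self.T

    @property
    def J0(self) -> float:
        """Voltage-sensor equilibrium at 0 mV, exp(-ZJ*VH/kT)."""
        return math.exp(-self.ZJ * self.VH / self.kT)

    def replace(self, **kw) -> "HAParameters":
        d = asdict(self)
        d.update(kw)
        return HAParameters(**d)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "HAParameters":
        with open(path) as fh:
            return cls(**json.load(fh))


def wt_ha_parameters(T: float = DEFAULT_T) -> HAParameters:
    """Published wild-type BK (Slo1) parameter set from macroscopic fits."""
    return HAParameters(L0=3.5e-7, ZL=0.18, ZJ=0.59, VH=159.0, KD=18.0,
                        C=10.0, D=48.0, E=4.2, T=T)


@dataclass
class GatingCurve:
    """Po(V) at fixed Ca, on a voltage grid."""

    Ca: float
    V: np.ndarray
    Po: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"Ca_uM": self.Ca, "V_mV": self.V, "Po": self.Po})


def _log_terms(V: np.ndarray, Ca: float, p: HAParameters
               ) -> tuple[np.ndarray, np.ndarray]:
    """(log open term, log closed term) evaluated in the log domain."""
    V = np.asarray(V, dtype=float)
    kT = p.kT
    logL = math.log(p.L0) + p.ZL * V / kT
    logJ = p.ZJ * (V - p.VH) / kT
    if Ca < 0:
        raise ValueError("Ca must be >= 0")
    logK = math.log(Ca / p.KD) if Ca > 0 else -np.inf
    zeros = np.zeros_like(V)

    def lse(terms: list[np.ndarray]) -> np.ndarray:
        return logsumexp(np.stack(np.broadcast_arrays(*terms)), axis=0)

    # open: 1 + K*C + J*D + J*K*C*D*E ; closed: 1 + K + J + J*K*E
    log_open_inner = lse([zeros,
                          zeros + logK + math.log(p.C),
                          logJ + math.log(p.D),
                          logJ + logK + math.log(p.C * p.D * p.E)])
    log_closed_inner = lse([zeros,
                            zeros + logK,
                            logJ,
                            logJ + logK + math.log(p.E)])
    log_open = logL + 4.0 * log_open_inner
    log_closed = 4.0 * log_closed_inner
    if not (np.all(np.isfinite(log_open)) and np.all(np.isfinite(log_closed))):
        bad = V[~(np.isfinite(log_open) & np.isfinite(log_closed))]
        raise FloatingPointError(f"non-finite gating term at V={bad}, Ca={Ca}")
    return log_open, log_closed


def ha_po(V, Ca: float, p: HAParameters):
    """Open probability Po(V, Ca); log-domain evaluation, stable over
    V in [-300, 400] mV and beyond."""
    scalar = np.isscalar(V)
    log_open, log_closed = _log_terms(np.atleast_1d(np.asarray(V, float)), Ca, p)
    po = 1.0 / (1.0 + np.exp(np.clip(log_closed - log_open, -700, 700)))
    return float(po[0]) if scalar else po


def gating_curve(p: HAParameters, Ca: float, V: np.ndarray) -> GatingCurve:
    return GatingCurve(Ca, np.asarray(V, float), ha_po(V, Ca, p))


def ha_v_half(Ca: float, p: HAParameters,
              bracket: tuple[float, float] = (-400.0, 500.0),
              xtol: float = 1e-9) -> float:
    """Voltage (mV) where Po = 0.5, i.e. the open and closed partition terms
    are equal; bracketed Brent root-finding on the log-term difference."""

    def residual(V: float) -> float:
        lo, lc = _log_terms(np.asarray([V]), Ca, p)
        return float(lo[0] - lc[0])

    r0, r1 = residual(bracket[0]), residual(bracket[1])
    if r0 * r1 > 0:
        raise ValueError(
            f"no Po=0.5 crossing in bracket {bracket}: residuals {r0:.3g}, {r1:.3g}")
    return float(brentq(residual, bracket[0], bracket[1], xtol=xtol))


def ha_v_half_grid_scan(Ca: float, p: HAParameters,
                        bracket: tuple[float, float] = (-400.0, 500.0),
                        step: float = 0.01) -> float:
    """Independent V0.5 estimate by a sign-scan of the equal-partition
    residual on a uniform grid; accurate to ``step`` mV. Serves as a slow
    cross-check of :func:`ha_v_half`."""
    V = np.arange(bracket[0], bracket[1] + step, step)
    lo, lc = _log_terms(V, Ca, p)
    res = lo - lc
    sign = np.sign(res)
    idx = np.flatnonzero(np.diff(sign) != 0)
    if len(idx) == 0:
        raise ValueError("no sign change on grid")
    i = idx[0]
    # linear interpolation within the bracketing step
    v0, v1, r0, r1 = V[i], V[i + 1], res[i], res[i + 1]
    return float(v0 - r0 * (v1 - v0) / (r1 - r0))


def sensitivity_curve(param: str, values, Ca_list, p: HAParameters,
                      bracket: tuple[float, float] = (-400.0, 500.0)) -> pd.DataFrame:
    """V0.5 as a function of 1/D or 1/L0 at each Ca, all other parameters held
    fixed. Returns columns (inv_value, param_value, Ca_uM, V05_mV)."""
    if param not in ("D", "L0"):
        raise ValueError("param must be 'D' or 'L0'")
    rows = []
    for v in values:
        if v <= 0:
            raise ValueError(f"{param} values must be positive, got {v}")
        q = p.replace(**{param: float(v)})
        for Ca in Ca_list:
            rows.append({"inv_value": 1.0 / v, "param_value": float(v),
                         "Ca_uM": float(Ca),
                         "V05_mV": ha_v_half(Ca, q, bracket=bracket)})
    return pd.DataFrame(rows)
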