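"""Conductance/charge--voltage extraction and Boltzmann fitting.

Relative conductance is measured from macroscopic tail currents at a fixed
repolarization voltage, so the tail amplitude is proportional to the open
probability at the end of each test pulse. Normalized G-V (or Q-V) points
are fitted with the two-state Boltzmann relation

    G/Gmax = 1 / (1 + exp(-z e0 (V - V0.5) / kT))
           = 1 / (1 + exp((V0.5 - V) / b)),

yielding the half-activation voltage V0.5 (mV), the slope factor b (mV) and
the equivalent gating charge z = kT / (e0 * b).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Model

__all__ = [
    "BOLTZMANN_K_OVER_E0_MV",
    "kT_mV",
    "SweepProtocol",
    "SweepRecording",
    "GVCurve",
    "BoltzmannFit",
    "FitError",
    "boltzmann",
    "extract_tail_gv",
    "fit_boltzmann",
    "delta_v_half",
    "read_gv_csv",
]

#: k_B / e0 in mV per kelvin
BOLTZMANN_K_OVER_E0_MV = 1.380649e-23 / 1.602176634e-19 * 1e3

#: default temperature (K); room-temperature recordings (22-24 C)
DEFAULT_T = 296.0


def kT_mV(T: float = DEFAULT_T) -> float:
    """Thermal voltage kT/e0 in mV at temperature T (K)."""
    return BOLTZMANN_K_OVER_E0_MV * T


class FitError(RuntimeError):
    """Nonlinear fit failed or is degenerate."""


@dataclass
class SweepProtocol:
    """Voltage-step protocol: hold, family of test pulses, then a tail step."""

    holding_mV: float
    test_voltages_mV: np.ndarray
    tail_mV: float
    pulse_start_ms: float
    pulse_end_ms: float

    def __post_init__(self) -> None:
        self.test_voltages_mV = np.asarray(self.test_voltages_mV, dtype=float)
        if np.any(np.diff(self.test_voltages_mV) <= 0):
            raise ValueError("test voltages must be strictly increasing")
        if self.pulse_end_ms <= self.pulse_start_ms:
            raise ValueError("pulse end must follow pulse start")


@dataclass
class SweepRecording:
    """Uniformly sampled current traces, one sweep per test voltage."""

    time_ms: np.ndarray                 # (n_samples,)
    currents_pA: np.ndarray             # (n_sweeps, n_samples)
    protocol: SweepProtocol

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.currents_pA = np.asarray(self.currents_pA, dtype=float)
        dt = np.diff(self.time_ms)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time base must be uniform")
        if self.currents_pA.shape != (len(self.protocol.test_voltages_mV), len(self.time_ms)):
            raise ValueError(
                f"currents must be (n_sweeps={len(self.protocol.test_voltages_mV)}, "
                f"n_samples={len(self.time_ms)}); got {self.currents_pA.shape}")


@dataclass
class GVCurve:
    """Voltage-indexed conductance or gating-charge relation."""

    voltages: np.ndarray                # mV, strictly increasing
    y: np.ndarray                       # amplitudes or normalized G/Gmax, Q/Qmax
    mode: str = "conductance"           # or "charge"
    sem: np.ndarray | None = None
    n_patches: int | None = None

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.voltages.shape != self.y.shape:
            raise ValueError("voltages and y must align")
        if np.any(np.diff(self.voltages) <= 0):
            raise ValueError("voltages must be strictly increasing")
        if self.mode not in ("conductance", "charge"):
            raise ValueError("mode must be 'conductance' or 'charge'")

    def to_frame(self) -> pd.DataFrame:
        data = {"V_mV": self.voltages, "y": self.y}
        if self.sem is not None:
            data["sem"] = self.sem
        return pd.DataFrame(data)


@dataclass
class BoltzmannFit:
    """Result of fitting the Boltzmann relation to a G-V or Q-V curve."""

    v_half: float                       # mV
    b: float                            # mV slope factor
    z: float                            # equivalent charges, kT/(e0*b)
    amplitude: float                    # fitted Gmax or Qmax (input units)
    v_half_se: float
    b_se: float
    T: float
    mode: str = "conductance"
    residual: float = 0.0               # sum of squared residuals

    def predict(self, V: np.ndarray, normalized: bool = True) -> np.ndarray:
        amp = 1.0 if normalized else self.amplitude
        return amp / (1.0 + np.exp((self.v_half - np.asarray(V, float)) / self.b))

    def to_dict(self) -> dict:
        return {"mode": self.mode, "V05_mV": self.v_half, "V05_se_mV": self.v_half_se,
                "b_mV": self.b, "b_se_mV": self.b_se, "z_e0": self.z,
                "amplitude": self.amplitude, "T_K": self.T, "rss": self.residual}

    def write_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def boltzmann(V, v_half, b, amplitude=1.0):
    """amplitude / (1 + exp((v_half - V)/b))."""
    return amplitude / (1.0 + np.exp((v_half - np.asarray(V, float)) / b))


def extract_tail_gv(rec: SweepRecording, window_start_ms: float,
                    window_len_ms: float,
                    baseline_window: tuple[float, float] | None = None) -> GVCurve:
    """Tail-current amplitude per test voltage (un-normalized conductance).

    The amplitude is the mean current over [window_start, window_start +
    window_len] minus the mean over ``baseline_window`` (default: everything
    before the pulse). The tail voltage is fixed across sweeps, so the
    amplitude is proportional to conductance at the end of the test pulse.
    """
    t = rec.time_ms
    if window_start_ms < rec.protocol.pulse_end_ms:
        raise ValueError(
            f"tail window start {window_start_ms} ms precedes pulse end "
            f"{rec.protocol.pulse_end_ms} ms")
    w0, w1 = window_start_ms, window_start_ms + window_len_ms
    if w1 > t[-1] + 1e-9 or w0 < t[0] - 1e-9:
        raise ValueError(f"tail window [{w0}, {w1}] ms outside trace [{t[0]}, {t[-1]}] ms")
    wmask = (t >= w0) & (t <= w1)
    if baseline_window is None:
        bmask = t < rec.protocol.pulse_start_ms
    else:
        b0, b1 = baseline_window
        if b1 > t[-1] + 1e-9 or b0 < t[0] - 1e-9:
            raise ValueError(f"baseline window [{b0}, {b1}] ms outside trace")
        bmask = (t >= b0) & (t <= b1)
    if not wmask.any() or not bmask.any():
        raise ValueError("empty tail or baseline window")
    amps = rec.currents_pA[:, wmask].mean(axis=1) - rec.currents_pA[:, bmask].mean(axis=1)
    return GVCurve(rec.protocol.test_voltages_mV, amps, mode="conductance")


def _init_v_half(V: np.ndarray, y: np.ndarray) -> float:
    """Linear-interpolated half-max crossing for initialization."""
    ymax, ymin = float(y.max()), float(y.min())
    half = 0.5 * (ymax + ymin)
    above = y >= half
    if above.all() or not above.any():
        return float(np.median(V))
    i = int(np.argmax(above))
    if i == 0:
        return float(V[0])
    x0, x1, y0, y1 = V[i - 1], V[i], y[i - 1], y[i]
    if y1 == y0:
        return float(x1)
    return float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))


def fit_boltzmann(curve: GVCurve, T: float = DEFAULT_T,
                  normalize: bool = True) -> tuple[BoltzmannFit, GVCurve]:
    """Least-squares Boltzmann fit; returns the fit and the normalized curve.

    With ``normalize`` the amplitude (Gmax or Qmax) is a free parameter and
    the returned curve's y is rescaled by it; otherwise the amplitude is
    pinned at 1 (data already normalized). V0.5 and b are invariant to
    multiplying all raw amplitudes by a constant.
    """
    V, y = curve.voltages, curve.y
    if len(V) < 4:
        raise FitError(f"need >= 4 voltage points, got {len(V)}")
    if np.ptp(y) <= 0:
        raise FitError("flat curve: no rise to fit")
    model = Model(boltzmann)
    params = model.make_params(
        v_half=_init_v_half(V, y), b=15.0,
        amplitude=float(y.max()) if normalize else 1.0)
    params["b"].set(min=1e-3)
    if not normalize:
        params["amplitude"].set(vary=False)
    result = model.fit(y, params, V=V)
    if not result.success:
        raise FitError(f"Boltzmann fit failed: {result.message}; "
                       f"init V0.5={params['v_half'].value:.1f}, b=15; "
                       f"last residual {float(np.sum(result.residual**2)):.3g}")
    p = result.params
    b = float(p["b"].value)
    if b <= 0 or not np.isfinite(b):
        raise FitError("degenerate fit: non-positive slope factor")
    amp = float(p["amplitude"].value)
    fit = BoltzmannFit(
        v_half=float(p["v_half"].value), b=b, z=kT_mV(T) / b, amplitude=amp,
        v_half_se=float(p["v_half"].stderr or np.nan),
        b_se=float(p["b"].stderr or np.nan),
        T=T, mode=curve.mode, residual=float(np.sum(result.residual ** 2)))
    norm = GVCurve(V, y / amp if normalize else y, mode=curve.mode,
                   sem=None if curve.sem is None else curve.sem / (amp if normalize else 1.0),
                   n_patches=curve.n_patches)
    return fit, norm


def delta_v_half(fit_a: BoltzmannFit, fit_b: BoltzmannFit) -> tuple[float, float]:
    """V0.5 difference (a - b, mV) with quadrature-propagated standard error."""
    d = fit_a.v_half - fit_b.v_half
    se = math.sqrt((fit_a.v_half_se or 0.0) ** 2 + (fit_b.v_half_se or 0.0) ** 2)
    return d, se


def read_gv_csv(path: str, mode: str = "conductance") -> GVCurve:
    """Read a voltage table: first column V (mV), then either one y column,
    y+sem columns, or several replicate columns (averaged, SEM computed).

    The detected layout is recorded in ``GVCurve`` metadata via ``n_patches``.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("expected at least two columns: voltage and value(s)")
    V = df.iloc[:, 0].to_numpy(dtype=float)
    rest = df.iloc[:, 1:]
    cols = [c.lower() for c in rest.columns]
    if rest.shape[1] == 1:
        return GVCurve(V, rest.iloc[:, 0].to_numpy(float), mode=mode)
    if rest.shape[1] == 2 and ("sem" in cols[1] or "se" == cols[1] or "err" in cols[1]):
        return GVCurve(V, rest.iloc[:, 0].to_numpy(float), mode=mode,
                       sem=rest.iloc[:, 1].to_numpy(float))
    vals = rest.to_numpy(dtype=float)
    return GVCurve(V, vals.mean(axis=1), mode=mode,
                   sem=vals.std(axis=1, ddof=1) / np.sqrt(vals.shape[1]),
                   n_patches=vals.shape[1])
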