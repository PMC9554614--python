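"""Summary metrics of simulated synaptic currents.

The headline readouts of a run are the peak current and conductance of the
ensemble-mean trace, the total charge transfer Q (trapezoidal integral, in
fC since pA x ms = fC), the proportion of neurotransmitter molecules captured
at least once (PNC), and the rise/decay time constants of the biexponential
template

    I(t) = Q / (tau_decay - tau_rise) * (exp(-t/tau_decay) - exp(-t/tau_rise))

fitted to the mean current by nonlinear least squares.  The two time
constants are interchangeable in the template; the fit parameterises
tau_decay = tau_rise + exp(theta) so the returned pair is always ordered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .molecules import sample_unit_vectors

__all__ = ["FitResult", "SummaryMetrics", "biexponential", "fit_biexponential",
           "summary_metrics", "msd_validation", "release_site_correlation",
           "capture_histogram", "receptor_statistics"]


@dataclass
class FitResult:
    Q_fC: float
    tau_rise_us: float
    tau_decay_ms: float
    mse: float
    converged: bool

    def __post_init__(self) -> None:
        if self.converged and self.tau_rise_us * 1e-3 >= self.tau_decay_ms:
            raise ValueError("fit returned tau_rise >= tau_decay")


def biexponential(t_ms: np.ndarray, Q_fC: float, tau_rise_ms: float,
                  tau_decay_ms: float) -> np.ndarray:
    """The template current (pA) at times t (ms)."""
    return (Q_fC / (tau_decay_ms - tau_rise_ms)
            * (np.exp(-t_ms / tau_decay_ms) - np.exp(-t_ms / tau_rise_ms)))


def fit_biexponential(t_ms: np.ndarray, current_pA: np.ndarray,
                      n_restarts: int = 5, seed: int = 0) -> FitResult:
    """Least-squares fit of the biexponential template to a current trace.

    Initialisation: tau_rise from half the time to peak, tau_decay from a
    log-linear fit of the tail, Q from the trapezoidal integral; restarts
    jitter the initial point to escape the symmetry-induced local optima.
    """
    t = np.asarray(t_ms, float)
    y = np.asarray(current_pA, float)
    if len(t) != len(y) or len(t) < 4:
        raise ValueError("need matching time/current arrays with >= 4 samples")
    if not np.any(y > 0):
        raise ValueError("no transient: the trace is never positive")

    ipk = int(np.argmax(y))
    t_peak = max(t[ipk], t[1] - t[0])
    q0 = max(np.trapezoid(y, t), 1e-6)
    tr0 = max(t_peak / 2.0, 1e-4)
    tail = y[ipk:] > 0.05 * y[ipk]
    if tail.sum() >= 3:
        tt, yy = t[ipk:][tail], y[ipk:][tail]
        slope = np.polyfit(tt, np.log(yy), 1)[0]
        td0 = -1.0 / slope if slope < 0 else 5.0 * tr0
    else:
        td0 = 5.0 * tr0
    td0 = max(td0, tr0 * 1.5)

    def resid(x):
        q, ltr, th = x
        tr = math.exp(min(ltr, 50.0))
        td = tr + math.exp(min(th, 50.0))
        with np.errstate(all="ignore"):
            r = biexponential(t, q, tr, td) - y
        return np.nan_to_num(r, nan=1e6, posinf=1e6, neginf=-1e6)

    rng = np.random.default_rng(seed)
    best = None
    x0 = np.array([q0, math.log(tr0), math.log(max(td0 - tr0, 1e-4))])
    for i in range(n_restarts):
        start = x0 if i == 0 else x0 + rng.normal(0, [0.2 * q0, 0.5, 0.5])
        try:
            sol = least_squares(resid, start, method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return FitResult(q0, tr0 * 1e3, td0, float("inf"), False)
    q, ltr, th = best.x
    tr = math.exp(ltr)
    td = tr + math.exp(th)
    mse = float(np.mean(best.fun**2))
    return FitResult(float(q), tr * 1e3, float(td), mse, bool(best.success))


@dataclass
class SummaryMetrics:
    peak_pA: float
    peak_g_pS: float
    Q_fC: float
    driving_force_mV: float
    pnc: float
    time_to_peak_ms: float


def summary_metrics(result) -> SummaryMetrics:
    """Peak current/conductance, charge, effective driving force and PNC."""
    mean_I = result.mean_current
    mean_g = result.mean_conductance_pS
    peak_I = float(mean_I.max())
    peak_g = float(mean_g.max())
    q = float(np.trapezoid(mean_I, result.time_ms))
    drive = peak_I / peak_g * 1e3 if peak_g > 0 else 0.0  # pA/pS = V -> mV
    caps = result.capture_counts
    pnc = float(np.mean(caps >= 1)) if caps.size else 0.0
    ttp = float(result.time_ms[int(np.argmax(mean_I))])
    return SummaryMetrics(peak_I, peak_g, q, drive, pnc, ttp)


def capture_histogram(result, k_max: int = 10) -> np.ndarray:
    """Fraction of released molecules captured exactly k times (k = 0..k_max)."""
    caps = result.capture_counts.reshape(-1)
    if caps.size == 0:
        return np.zeros(k_max + 1)
    clipped = np.minimum(caps, k_max)
    return np.bincount(clipped, minlength=k_max + 1) / caps.size


def receptor_statistics(result) -> dict:
    """Opening statistics over all (receptor, repetition) pairs."""
    oc = result.opening_counts.reshape(-1)
    if oc.size == 0:
        return {"fraction_never_opening": 1.0, "opening_count_distribution": np.zeros(1),
                "fraction_opening_ge": {}}
    dist = np.bincount(np.minimum(oc, 20), minlength=21) / oc.size
    return {
        "fraction_never_opening": float(np.mean(oc == 0)),
        "opening_count_distribution": dist,
        "fraction_opening_ge": {k: float(np.mean(oc >= k)) for k in (1, 2, 6, 12)},
        "mean_openings": float(oc.mean()),
    }


def msd_validation(n_molecules: int = 10_000, duration_ms: float = 1.0,
                   D: float = 0.3, dt_ns: float = 50.0, seed: int = 0) -> float:
    """Free 3D Brownian validation: fit MSD(t) = 6 D t, return the fitted D.

    Steps molecules in unbounded space with the model's step rule
    (fixed length sqrt(6 D dt) along isotropic unit vectors) and fits a line
    through the time course of the mean squared displacement.
    """
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration_ms / (dt_ns * 1e-6)))
    dr = math.sqrt(6.0 * D * 1e6 * dt_ns * 1e-6)  # nm
    pos = np.zeros((n_molecules, 3))
    msd = np.empty(n_steps)
    for t in range(n_steps):
        pos += dr * sample_unit_vectors(n_molecules, rng)
        msd[t] = np.mean(np.einsum("ij,ij->i", pos, pos))
    t_ms = (np.arange(n_steps) + 1) * dt_ns * 1e-6
    slope = np.polyfit(t_ms, msd, 1)[0]  # nm^2 / ms
    return slope / 6.0 * 1e-6  # um^2/ms


def release_site_correlation(distances_nm: np.ndarray,
                             charges_fC: np.ndarray) -> tuple[float, float]:
    """Pearson correlation between release-site distance and total charge.

    Returns (correlation, p_value); raises for fewer than 3 events.
    """
    d = np.asarray(distances_nm, float)
    q = np.asarray(charges_fC, float)
    if len(d) != len(q) or len(d) < 3:
        raise ValueError("need at least 3 events with matching distances and charges")
    r, p = stats.pearsonr(d, q)
    return float(r), float(p)
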