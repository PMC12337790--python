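"""Post-ablation recoil analysis.

After a junction is severed, the separation d(t) of its two vertices
relaxes approximately exponentially to a plateau:

    (d(t) − d0)/l_c = D∞ · (1 − exp(−(t − t0)/τ)),   t ≥ t0

with d0 the pre-ablation vertex separation, l_c the pre-ablation
junction length, D∞ = (d∞ − d0)/l_c the normalized final displacement
and τ the relaxation time.  D∞ is proportional to the initial recoil
velocity v0 = l_c·D∞/τ and is the more robust tension proxy at coarse
frame cadence, where τ itself is poorly resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares


@dataclass
class RecoilTrace:
    """A vertex-separation time series around an ablation at ``t0``."""

    times: np.ndarray  # s, strictly increasing
    distances: np.ndarray  # µm
    t0: float  # ablation time, s
    lc: float  # pre-ablation junction length, µm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.lc <= 0:
            raise ValueError("junction length lc must be positive")
        if self.times.shape != self.distances.shape or self.times.ndim != 1:
            raise ValueError("times and distances must be matching 1D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.count_nonzero(self.times >= self.t0) < 3:
            raise ValueError("need at least 3 post-ablation samples")

    @property
    def pre(self) -> np.ndarray:
        return self.distances[self.times < self.t0]

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times)))


@dataclass
class RecoilFit:
    d_inf_norm: float  # D∞ = (d∞ − d0)/l_c
    tau: float  # s
    d0: float  # µm
    lc: float  # µm
    rms: float
    converged: bool
    under_resolved: bool = False  # τ below the frame cadence
    message: str = ""


def relaxation_model(
    t: np.ndarray, d0: float, lc: float, d_inf_norm: float, tau: float, t0: float
) -> np.ndarray:
    """d(t) under the exponential-with-plateau relaxation (d0 before t0)."""
    t = np.asarray(t, dtype=float)
    out = np.full_like(t, d0)
    post = t >= t0
    out[post] = d0 + lc * d_inf_norm * (1.0 - np.exp(-(t[post] - t0) / tau))
    return out


def fit_recoil(trace: RecoilTrace, d0: float | None = None) -> RecoilFit:
    """Nonlinear least squares for (D∞, τ) with t0 and d0 held fixed.

    d0 defaults to the mean of the pre-ablation samples (the acquisition
    protocol provides several frames before the cut); t0 is the known
    ablation time, not a fitted parameter.  Fits start from three
    initial τ values and the best converged solution is kept; a fit
    whose τ falls below the frame cadence is flagged ``under_resolved``
    because the plateau amplitude, not the timescale, is then the
    trustworthy output.
    """
    if d0 is None:
        pre = trace.pre
        if pre.size == 0:
            raise ValueError("no pre-ablation samples; pass d0 explicitly")
        d0 = float(np.mean(pre))
    post = trace.times >= trace.t0
    t = trace.times[post] - trace.t0
    y = (trace.distances[post] - d0) / trace.lc
    window = float(t[-1]) if t[-1] > 0 else trace.dt

    def resid(p: np.ndarray) -> np.ndarray:
        d_inf, tau = p
        return d_inf * (1.0 - np.exp(-t / tau)) - y

    best = None
    for tau0 in (2 * trace.dt, window / 4, window):
        d_inf0 = float(np.clip(y[-1] if y.size else 0.3, -0.9, 4.9))
        sol = least_squares(
            resid,
            x0=[d_inf0, max(tau0, 1e-3)],
            bounds=([-1.0, 1e-9], [5.0, 10.0 * window]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if best is None or (sol.success, -sol.cost) > (best.success, -best.cost):
            best = sol
    assert best is not None
    d_inf, tau = best.x
    rms = float(np.sqrt(np.mean(resid(best.x) ** 2)))
    return RecoilFit(
        d_inf_norm=float(d_inf),
        tau=float(tau),
        d0=float(d0),
        lc=float(trace.lc),
        rms=rms,
        converged=bool(best.success),
        under_resolved=bool(tau < trace.dt),
        message="" if best.success else str(best.message),
    )


def initial_velocity(fit: RecoilFit) -> float:
    """Model recoil velocity at t0: v0 = l_c·D∞/τ (µm/s).

    By construction D∞ = v0·τ/l_c, the direct proportionality between
    plateau displacement and initial velocity.
    """
    return fit.lc * fit.d_inf_norm / fit.tau
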