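"""Pulsatile inlet flow waveforms.

A waveform is one cardiac cycle of volumetric flow rate samples (mm^3/s)
extended periodically.  The rest-to-exercise study family consists of five
members: three derived from a resting waveform (cycle 0.7 s) and two from a
stress waveform (cycle 0.42 s), scaled so their peak flows are evenly spaced
across a configured range (default 1.51e5-4.03e5 mm^3/s).

Patient waveforms are not shipped; a parametric two-harmonic pulse (systolic
peak plus diastolic decay) stands in for them and is what the family builder
scales by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "Waveform",
    "two_harmonic_pulse",
    "build_family",
    "early_fraction",
    "read_waveform_csv",
    "write_waveform_csv",
    "REST_PERIOD_S",
    "STRESS_PERIOD_S",
    "PEAK_FLOW_RANGE_MM3_S",
]

REST_PERIOD_S = 0.7
STRESS_PERIOD_S = 0.42
#: smallest and largest family peak flows (mm^3/s)
PEAK_FLOW_RANGE_MM3_S = (1.51e5, 4.03e5)


@dataclass(frozen=True)
class Waveform:
    """One periodic cardiac cycle of flow-rate samples.

    times are seconds within [0, period); flows are mm^3/s.  Sampling at an
    arbitrary t >= 0 interpolates linearly on the periodic extension.
    """

    times: np.ndarray
    flows: np.ndarray
    period: float
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        q = np.asarray(self.flows, dtype=float)
        if t.ndim != 1 or t.shape != q.shape or len(t) < 2:
            raise ValueError("times and flows must be equal-length 1-D, n >= 2")
        if t[0] != 0.0:
            raise ValueError("times must start at 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if t[-1] >= self.period:
            raise ValueError("last sample must precede the period")
        if not np.all(np.isfinite(q)):
            raise ValueError("flows must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "flows", q)

    @property
    def peak_flow(self) -> float:
        return float(np.max(self.flows))

    @property
    def heart_rate_bpm(self) -> float:
        return 60.0 / self.period

    def sample(self, t):
        """Flow at time t (scalar or array) on the periodic extension."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be non-negative")
        tm = np.mod(t, self.period)
        # wrap: append the t=period knot equal to flows[0]
        tk = np.concatenate([self.times, [self.period]])
        qk = np.concatenate([self.flows, [self.flows[0]]])
        out = np.interp(tm, tk, qk)
        return float(out) if out.ndim == 0 else out

    def scale(self, factor: float) -> "Waveform":
        """Multiply flows by a positive constant; times/period unchanged."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return replace(self, flows=self.flows * factor)

    def scaled_to_peak(self, peak: float) -> "Waveform":
        return self.scale(peak / self.peak_flow)


def sample(w: Waveform, t):
    return w.sample(t)


def scale(w: Waveform, factor: float) -> Waveform:
    return w.scale(factor)


def two_harmonic_pulse(
    peak_flow: float,
    period: float,
    n_samples: int = 64,
    label: str = "",
    diastolic_fraction: float = 0.15,
) -> Waveform:
    """Parametric pulse: a systolic half-sine peak over the first third of
    the cycle plus a decaying diastolic tail, normalized to ``peak_flow``.

    The shape is a smooth stand-in for a PC-MRI aortic waveform: systolic
    upstroke/downstroke, low positive diastolic flow, continuous seam.
    """
    if peak_flow <= 0 or period <= 0:
        raise ValueError("peak_flow and period must be positive")
    t = np.linspace(0.0, period, n_samples, endpoint=False)
    x = t / period
    systole = np.where(x < 1.0 / 3.0, np.sin(3.0 * np.pi * x) ** 2, 0.0)
    diastole = diastolic_fraction * np.sin(np.pi * x) ** 2
    q = systole + diastole
    q = q / q.max() * peak_flow
    return Waveform(times=t, flows=q, period=period, label=label)


def build_family(
    rest: Waveform | None = None,
    stress: Waveform | None = None,
    n: int = 5,
    peak_range: tuple = PEAK_FLOW_RANGE_MM3_S,
) -> list[Waveform]:
    """Construct the rest-to-exercise waveform family.

    The n peak flows are evenly spaced over ``peak_range``.  The lower
    ~3n/5 members are scaled copies of the rest waveform (period 0.7 s by
    default), the remainder scaled copies of the stress waveform (0.42 s):
    a 3-rest/2-stress split at n = 5, and always at least one of each.
    """
    if n < 2:
        raise ValueError("family needs at least 2 members")
    if rest is None:
        rest = two_harmonic_pulse(peak_range[0], REST_PERIOD_S, label="rest")
    if stress is None:
        stress = two_harmonic_pulse(peak_range[1], STRESS_PERIOD_S, label="stress")
    peaks = np.linspace(peak_range[0], peak_range[1], n)
    n_rest = min(max(int(round(3 * n / 5)), 1), n - 1)
    members = []
    for m, p in enumerate(peaks):
        base = rest if m < n_rest else stress
        kind = "rest" if m < n_rest else "stress"
        w = base.scaled_to_peak(p)
        members.append(replace(w, label=f"{kind}_{m}"))
    return members


def early_fraction(t_cut: float, period: float) -> float:
    """Fraction of the cardiac cycle covered by an early-truncated run."""
    if period <= 0:
        raise ValueError("period must be positive")
    if not 0 <= t_cut <= period:
        raise ValueError("t_cut must lie in [0, period]")
    return t_cut / period


def read_waveform_csv(path, period: float, label: str = "") -> Waveform:
    """Read a waveform from a CSV with header ``time_s,flow_mm3_s``."""
    df = pd.read_csv(path)
    return Waveform(
        times=df["time_s"].to_numpy(),
        flows=df["flow_mm3_s"].to_numpy(),
        period=period,
        label=label,
    )


def write_waveform_csv(w: Waveform, path) -> None:
    pd.DataFrame({"time_s": w.times, "flow_mm3_s": w.flows}).to_csv(path, index=False)
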