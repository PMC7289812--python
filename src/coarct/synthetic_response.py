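"""Analytic stand-in response surfaces over the viscosity-flow grid.

Production-scale pulsatile simulations of a patient aorta are far beyond a
workstation, so this module generates ΔP and TAWSS responses with the
qualitative structure such simulations exhibit — ΔP increasing with flow
rate (several-fold across the rest-to-exercise range) and with stenosis
severity, TAWSS increasing in both viscosity and flow rate, nonlinearly —
letting the surrogate and design-of-experiments machinery run in seconds.
All outputs are labelled synthetic.

The ΔP model is the classical stenosis pressure loss: a Poiseuille viscous
term linear in mu*Q plus a Borda-Carnot expansion (inertial) term quadratic
in Q and scaled by (1/(1-dos)^2 - 1)^2.  The loss coefficient default is
calibrated so that sweeping the default flow range quadruples ΔP at the 65%
degree of stenosis and physiological viscosity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .metrics import MMHG_PER_PA

__all__ = [
    "ResponseParams",
    "dp_response",
    "tawss_response",
    "early_wss_fractions",
    "generate_dataset",
]

#: expansion-loss coefficient calibrated for a four-fold ΔP rise over the
#: default flow range at dos = 0.65, mu = 3.5 cP
DEFAULT_K_INERTIAL = 9.12e-4


@dataclass(frozen=True)
class ResponseParams:
    """Coefficients of the analytic stenosis response surface."""

    k_visc: float = 1.0  # multiplier on the Poiseuille viscous term
    k_inertial: float = DEFAULT_K_INERTIAL  # Borda-Carnot loss coefficient
    dos: float = 0.65  # degree of stenosis (diameter fraction)
    diameter: float = 0.01  # vessel diameter (m)
    length: float = 0.1  # viscous segment length (m)
    rho: float = 1060.0  # blood density (kg/m^3)
    noise_sd_dp: float = 0.0  # additive Gaussian noise on ΔP (mmHg)
    noise_sd_tawss: float = 0.0  # additive Gaussian noise on TAWSS (Pa)

    def __post_init__(self):
        if self.k_visc < 0 or self.k_inertial < 0:
            raise ValueError("response coefficients must be non-negative")
        if self.noise_sd_dp < 0 or self.noise_sd_tawss < 0:
            raise ValueError("noise sd must be non-negative")

    def jittered(self, rel: float, seed: int) -> "ResponseParams":
        """Coefficients perturbed by +/- rel (uniform), emulating a different
        patient geometry with the same degree of stenosis."""
        rng = np.random.default_rng(seed)
        j = lambda v: float(v * (1.0 + rel * rng.uniform(-1, 1)))
        return replace(
            self,
            k_visc=j(self.k_visc),
            k_inertial=j(self.k_inertial),
            length=j(self.length),
        )


def _dp_mean(viscosity_cP, peak_flow_mm3_s, p: ResponseParams):
    mu = np.asarray(viscosity_cP, dtype=float) * 1e-3  # Pa s
    Q = np.asarray(peak_flow_mm3_s, dtype=float) * 1e-9  # m^3/s
    D = p.diameter
    A0 = np.pi * (D / 2.0) ** 2
    visc = p.k_visc * 128.0 * mu * p.length * Q / (np.pi * D**4)
    contraction = 1.0 / (1.0 - p.dos) ** 2 - 1.0
    inert = p.k_inertial * 0.5 * p.rho * (Q / A0) ** 2 * contraction**2
    return (visc + inert) * MMHG_PER_PA


def dp_response(viscosity_cP, peak_flow_mm3_s, params: ResponseParams, rng=None):
    """Peak-systole pressure drop (mmHg) across the synthetic stenosis.

    Strictly increasing in flow rate, increasing in viscosity and in the
    degree of stenosis; deterministic unless a noise sd and rng are given.
    """
    dp = _dp_mean(viscosity_cP, peak_flow_mm3_s, params)
    if params.noise_sd_dp > 0 and rng is not None:
        dp = dp + rng.normal(0.0, params.noise_sd_dp, size=np.shape(dp))
    return dp if np.ndim(dp) else float(dp)


def _tawss_mean(viscosity_cP, peak_flow_mm3_s, p: ResponseParams):
    mu = np.asarray(viscosity_cP, dtype=float) * 1e-3
    Q = np.asarray(peak_flow_mm3_s, dtype=float) * 1e-9
    R = p.diameter / 2.0
    base = 4.0 * mu * Q / (np.pi * R**3)  # Poiseuille wall shear at peak flow
    q_ref = 4.03e5 * 1e-9
    nonlinear = 1.0 + 0.5 * (Q / q_ref) ** 2  # inertial steepening
    return base * nonlinear * (1.0 + p.dos)


def tawss_response(viscosity_cP, peak_flow_mm3_s, params: ResponseParams, rng=None):
    """Cycle-averaged wall shear stress (Pa) distal to the synthetic
    stenosis; monotone increasing in both viscosity and flow rate."""
    w = _tawss_mean(viscosity_cP, peak_flow_mm3_s, params)
    if params.noise_sd_tawss > 0 and rng is not None:
        w = w + rng.normal(0.0, params.noise_sd_tawss, size=np.shape(w))
    return w if np.ndim(w) else float(w)


#: early-cycle WSS features as fractions of TAWSS (flow still developing)
EARLY_FRACTIONS = (0.45, 0.65, 0.85)
#: per-sector TAWSS factors (high-shear jet impingement in sectors 1-2)
SECTOR_FACTORS = (1.3, 1.15, 0.85, 0.7)


def early_wss_fractions(tawss_value):
    """Early-cycle WSS features correlated with (scaled fractions of) TAWSS."""
    t = np.asarray(tawss_value, dtype=float)
    return tuple(t * f for f in EARLY_FRACTIONS)


def generate_dataset(grid, params: ResponseParams, seed: int = 0) -> pd.DataFrame:
    """One synthetic record per (viscosity, waveform) pairing of a sweep grid.

    ``grid`` is a :class:`coarct.doe.SweepGrid`; the row schema matches the
    solver-derived metrics table, with ``source = "synthetic"``.  Features
    are deterministic; only the noise draws depend on the seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for dos in grid.geometries:
        p = replace(params, dos=dos)
        for visc in grid.viscosities:
            for w in grid.waveforms:
                dp = dp_response(visc, w.peak_flow, p, rng)
                tw = tawss_response(visc, w.peak_flow, p, rng)
                e1, e2, e3 = early_wss_fractions(tw)
                row = {
                    "viscosity_cP": visc,
                    "waveform": w.label,
                    "peak_flow_mm3_s": w.peak_flow,
                    "heart_rate_bpm": w.heart_rate_bpm,
                    "dos": dos,
                    "dp_mmHg": dp,
                    "tawss_pa": tw,
                    "wss_t035": e1,
                    "wss_t070": e2,
                    "wss_t105": e3,
                    "source": "synthetic",
                }
                for s, fac in enumerate(SECTOR_FACTORS, start=1):
                    row[f"tawss_s{s}_pa"] = tw * fac
                rows.append(row)
    return pd.DataFrame(rows)
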