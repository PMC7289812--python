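"""Configuration and orchestration: geometry -> solver -> metrics ->
surrogate -> design of experiments.

A :class:`RunConfig` collects the desk-scale study conditions (geometry,
waveform family, viscosity sweep, lattice/stability settings, metric plane
offsets, surrogate and DoE settings); YAML files overlay the defaults.
``run_sweep`` executes each (viscosity, waveform) pairing with the D3Q19
solver for one cardiac cycle and appends one metrics row per run
(resumable: completed pairings are skipped on rerun).  ``run_experiment``
exposes three named presets: ``full_dp`` (ΔP surrogate on the 100-run
two-geometry dataset, 70/10/20 split), ``tawss`` (TAWSS surrogate, with and
without the early-cycle WSS features), and ``doe`` (minimal-training-set
search on the 50-run single-geometry dataset plus transfer to two new
geometries).

Pressure notes: pressure *differences* redimensionalize exactly (delta
P_phys = c_s^2 delta rho * rho_phys dx^2/dt^2), so ΔP rows use the direct
conversion; the least-squares lattice-to-mmHg map (fitted against the
physiological reference waveform at 20 cycle times) fixes the unknown
additive constant for absolute pressures and is recorded per run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import boundaries, metrics, surrogate, synthetic_response
from .doe import SweepGrid, default_viscosities, minimal_set_search, transfer_protocol
from .geometry import VesselSpec, voxelize_spec
from .lbm_core import CS, CS2, LatticeSpec, Simulation, pressure_lb
from .waveforms import (
    REST_PERIOD_S,
    STRESS_PERIOD_S,
    Waveform,
    build_family,
    two_harmonic_pulse,
)

__all__ = ["RunConfig", "load_config", "run_sweep", "simulate_pairing", "run_experiment", "PRESETS"]


@dataclass
class GeometryConfig:
    diameter_m: float = 2.0e-3
    length_m: float = 8.0e-3
    dos: float = 0.65
    stenosis_center_m: float | None = None
    stenosis_span_m: float | None = 3.0e-3
    dx_m: float = 8.75e-5  # throat of the 65% vessel resolved by 8 nodes

    def vessel_spec(self, dos: float | None = None) -> VesselSpec:
        return VesselSpec(
            inlet_diameter=self.diameter_m,
            length=self.length_m,
            dos=self.dos if dos is None else dos,
            stenosis_center=self.stenosis_center_m,
            stenosis_span=self.stenosis_span_m,
        )


@dataclass
class WaveformConfig:
    # desk-scale peaks preserve the rest-to-exercise peak ratio (4.03/1.51)
    peak_min_mm3_s: float = 1.0
    peak_max_mm3_s: float = 2.669
    n: int = 5
    rest_period_s: float = REST_PERIOD_S
    stress_period_s: float = STRESS_PERIOD_S

    def family(self) -> list[Waveform]:
        rest = two_harmonic_pulse(self.peak_min_mm3_s, self.rest_period_s, label="rest")
        stress = two_harmonic_pulse(
            self.peak_max_mm3_s, self.stress_period_s, label="stress"
        )
        return build_family(
            rest, stress, n=self.n, peak_range=(self.peak_min_mm3_s, self.peak_max_mm3_s)
        )


@dataclass
class LatticeConfig:
    ma_cap: float = 0.1
    ma_target: float = 0.05
    tau_min: float = 0.55
    tau_max: float = 1.0
    rho_phys: float = 1060.0


@dataclass
class OutletConfig:
    n_outlets: int = 1
    R_pa_s_per_m3: float = 0.0


@dataclass
class MetricsConfig:
    n_snapshots: int = 140  # WSS/pressure snapshots per cardiac cycle


@dataclass
class SurrogateConfig:
    seed: int = 0
    learning_rate: float = 1e-2
    max_epochs: int = 5000
    patience: int = 250

    def train_config(self) -> surrogate.TrainConfig:
        return surrogate.TrainConfig(
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            patience=self.patience,
        )


@dataclass
class DoeConfig:
    threshold: float = 0.98
    n_subsets: int = 1000
    seed: int = 0


@dataclass
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    waveforms: WaveformConfig = field(default_factory=WaveformConfig)
    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    outlets: OutletConfig = field(default_factory=OutletConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)
    doe: DoeConfig = field(default_factory=DoeConfig)
    viscosities_cP: list = field(default_factory=lambda: default_viscosities(10))

    def __post_init__(self):
        for v in self.viscosities_cP:
            if not 1.0 <= v <= 10.0:
                raise ValueError(f"viscosity {v} cP outside the sane 1-10 cP range")
            if not 2.66 <= v <= 6.38:
                import warnings

                warnings.warn(
                    f"viscosity {v} cP outside the physiological 2.66-6.38 cP sweep",
                    stacklevel=2,
                )

    def config_hash(self) -> str:
        doc = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from defaults, a YAML file, and a dict overlay."""
    doc: dict = {}
    if path is not None:
        doc = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        doc.update(overrides)
    sections = {
        "geometry": GeometryConfig,
        "waveforms": WaveformConfig,
        "lattice": LatticeConfig,
        "outlets": OutletConfig,
        "metrics": MetricsConfig,
        "surrogate": SurrogateConfig,
        "doe": DoeConfig,
    }
    kwargs = {}
    for name, cls in sections.items():
        kwargs[name] = cls(**doc.get(name, {}))
    if "viscosities_cP" in doc:
        kwargs["viscosities_cP"] = list(doc["viscosities_cP"])
    return RunConfig(**kwargs)


def _lattice_spec_for(cfg: RunConfig, viscosity_cP: float, Q_peak_mm3_s: float, dos: float):
    nu_phys = viscosity_cP * 1e-3 / cfg.lattice.rho_phys
    throat_r = 0.5 * cfg.geometry.diameter_m * (1.0 - dos)
    u_peak = 2.0 * Q_peak_mm3_s * 1e-9 / (np.pi * throat_r**2)  # parabolic center
    return LatticeSpec.from_physical(
        dx=cfg.geometry.dx_m,
        nu_phys=nu_phys,
        u_max_phys=u_peak,
        rho_phys=cfg.lattice.rho_phys,
        ma_target=cfg.lattice.ma_target,
        ma_cap=cfg.lattice.ma_cap,
        tau_bounds=(cfg.lattice.tau_min, cfg.lattice.tau_max),
    )


def simulate_pairing(
    cfg: RunConfig,
    viscosity_cP: float,
    waveform: Waveform,
    dos: float | None = None,
    grid=None,
    log=None,
) -> dict:
    """Run one (viscosity, waveform) pairing for one cardiac cycle and
    extract the metrics row."""
    dos = cfg.geometry.dos if dos is None else dos
    if grid is None:
        grid = voxelize_spec(cfg.geometry.vessel_spec(dos), cfg.geometry.dx_m,
                             n_outlets=cfg.outlets.n_outlets)
    spec = _lattice_spec_for(cfg, viscosity_cP, waveform.peak_flow, dos)

    inlet = boundaries.InletBC(
        grid, spec, waveform=_waveform_si(waveform), ma_cap=cfg.lattice.ma_cap
    )
    outlet = boundaries.ResistanceOutletBC(grid, spec, cfg.outlets.R_pa_s_per_m3)
    sim = Simulation(grid, spec)

    T = waveform.period
    n_steps = int(np.ceil(T / spec.dt))
    n_snap = min(cfg.metrics.n_snapshots, n_steps)
    snap_steps = np.unique(np.linspace(0, n_steps, n_snap, endpoint=False).astype(int))

    i_prox, i_dist = metrics.default_dp_planes(grid)
    i_inlet_probe = max(1, i_prox // 2)
    i_slice = metrics.default_wss_slice_plane(grid)

    times, p_prox, p_dist, p_in = [], [], [], []
    wss_hist = []
    ma_max = 0.0
    done = 0
    active = grid.node_class != 0
    for s in snap_steps:
        if s > done:
            sim.step(s - done, boundaries=(inlet, outlet))
            done = s
        rho, u = sim.moments()
        p = pressure_lb(rho)
        times.append(sim.step_count * spec.dt)
        p_prox.append(metrics.plane_average(p, grid, i_prox))
        p_dist.append(metrics.plane_average(p, grid, i_dist))
        p_in.append(metrics.plane_average(p, grid, i_inlet_probe))
        wss_hist.append(metrics.wss_field(sim, spec))
        umax = float(np.linalg.norm(u[active], axis=-1).max())
        ma_max = max(ma_max, umax / CS)
    sim.step(n_steps - done, boundaries=(inlet, outlet))

    times = np.array(times)
    wss_hist = np.array(wss_hist).T  # (n_wall, n_t)

    # lattice -> mmHg map for absolute pressures (20 evenly spaced cycle times)
    fit_t = np.linspace(0, T, 20, endpoint=False)
    preset = "rest" if waveform.period >= 0.5 else "stress"
    p_ref = metrics.reference_pressure_waveform(fit_t, T, preset)
    p_lb_fit = np.interp(fit_t, times, np.array(p_in))
    try:
        slope, intercept = metrics.fit_pressure_scaling(p_lb_fit, p_ref)
    except np.linalg.LinAlgError:
        slope, intercept = float("nan"), float("nan")

    # ΔP via exact difference redimensionalization
    pa_factor = spec.rho_phys * spec.dx**2 / spec.dt**2
    series = metrics.PressureSeries(
        times=times,
        p_prox=np.array(p_prox) * pa_factor * metrics.MMHG_PER_PA,
        p_dist=np.array(p_dist) * pa_factor * metrics.MMHG_PER_PA,
    )
    t_peak = float(waveform.times[np.argmax(waveform.flows)])
    dp = metrics.delta_p(series, t_peak=t_peak)

    sl = metrics.make_wss_slice(sim, i_slice, times, wss_hist)
    sector_means, circ_mean = metrics.sector_tawss(sl, T)
    wss_circ_t = sl.wss.mean(axis=0)
    e1, e2, e3 = metrics.early_wss_features(times, wss_circ_t)

    row = {
        "viscosity_cP": float(viscosity_cP),
        "waveform": waveform.label,
        "peak_flow_mm3_s": waveform.peak_flow,
        "heart_rate_bpm": waveform.heart_rate_bpm,
        "dos": float(dos),
        "dp_mmHg": dp,
        "tawss_pa": circ_mean,
        "tawss_s1_pa": sector_means[0],
        "tawss_s2_pa": sector_means[1],
        "tawss_s3_pa": sector_means[2],
        "tawss_s4_pa": sector_means[3],
        "wss_t035": e1,
        "wss_t070": e2,
        "wss_t105": e3,
        "p_scale_slope": slope,
        "p_scale_intercept": intercept,
        "tau": spec.tau,
        "steps": n_steps,
        "max_ma": ma_max,
        "source": "lbm",
    }
    if log is not None:
        log.append(row)
    return row


def _waveform_si(w: Waveform) -> Waveform:
    """mm^3/s -> m^3/s flows for the solver-facing boundary condition."""
    return Waveform(times=w.times, flows=w.flows * 1e-9, period=w.period, label=w.label)


def run_sweep(cfg: RunConfig, out_csv=None, dos: float | None = None) -> pd.DataFrame:
    """Execute every (viscosity, waveform) pairing; resumable via out_csv."""
    family = cfg.waveforms.family()
    done = pd.DataFrame()
    if out_csv is not None and Path(out_csv).exists():
        done = pd.read_csv(out_csv)
    rows = [] if done.empty else done.to_dict("records")
    completed = {
        (round(float(r["viscosity_cP"]), 9), r["waveform"]) for r in rows
    }
    grid = voxelize_spec(
        cfg.geometry.vessel_spec(dos), cfg.geometry.dx_m, n_outlets=cfg.outlets.n_outlets
    )
    failures = []
    for v in cfg.viscosities_cP:
        for w in family:
            if (round(float(v), 9), w.label) in completed:
                continue
            try:
                row = simulate_pairing(cfg, v, w, dos=dos, grid=grid)
            except Exception as exc:  # record and continue the sweep
                failures.append({"viscosity_cP": v, "waveform": w.label, "error": str(exc)})
                continue
            rows.append(row)
            if out_csv is not None:
                pd.DataFrame(rows).to_csv(out_csv, index=False)
    df = pd.DataFrame(rows)
    if failures:
        df.attrs["failures"] = failures
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


# ---------------------------------------------------------------------------
# named experiments (on the synthetic response surfaces by default)
# ---------------------------------------------------------------------------

FULL_FEATURES = ("dos", "heart_rate_bpm", "peak_flow_mm3_s", "viscosity_cP")
EARLY_WSS_FEATURES = ("wss_t035", "wss_t070", "wss_t105")


def _synthetic_dataset(cfg: RunConfig, geometries, seed: int) -> pd.DataFrame:
    grid = SweepGrid(
        viscosities=tuple(cfg.viscosities_cP),
        waveforms=tuple(build_family(n=cfg.waveforms.n)),
        geometries=tuple(geometries),
    )
    return synthetic_response.generate_dataset(
        grid, synthetic_response.ResponseParams(), seed=seed
    )


def _split_70_10_20(n: int, seed: int):
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_tr = round(0.7 * n)
    n_va = round(0.1 * n)
    return perm[:n_tr], perm[n_tr : n_tr + n_va], perm[n_tr + n_va :]


def _fit_report(df, features, target, cfg: RunConfig, seed: int) -> dict:
    X = df.loc[:, list(features)].to_numpy(dtype=float)
    y = df.loc[:, target].to_numpy(dtype=float)
    tr, va, te = _split_70_10_20(len(df), seed)
    tcfg = cfg.surrogate.train_config()
    cv_scores, _ = surrogate.kfold_cv(
        X[np.concatenate([tr, va])], y[np.concatenate([tr, va])],
        k=5, seed=seed, config=tcfg, feature_names=list(features), target_name=target,
    )
    model = surrogate.train(
        X[tr], y[tr], seed=seed, val=(X[va], y[va]), config=tcfg,
        feature_names=list(features), target_name=target,
    )
    pred = model.predict(X[te])
    bias, loa = surrogate.bland_altman(pred, y[te])
    return {
        "features": list(features),
        "target": target,
        "n_train": len(tr),
        "n_val": len(va),
        "n_test": len(te),
        "r": surrogate.pearson_r(pred, y[te]),
        "mae": surrogate.mae(pred, y[te]),
        "bias": bias,
        "loa": list(loa),
        "cv_mse": cv_scores,
    }


def run_experiment(name: str, cfg: RunConfig | None = None, seed: int | None = None,
                   dataset: pd.DataFrame | None = None) -> dict:
    """Run a named experiment preset and return its JSON-able report."""
    cfg = cfg or RunConfig()
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    seed = cfg.surrogate.seed if seed is None else seed
    report = {"preset": name, "seed": int(seed), "config_hash": cfg.config_hash()}

    if name == "full_dp":
        df = dataset if dataset is not None else _synthetic_dataset(cfg, (0.65, 0.85), seed)
        report["result"] = _fit_report(df, FULL_FEATURES, "dp_mmHg", cfg, seed)
    elif name == "tawss":
        df = dataset if dataset is not None else _synthetic_dataset(cfg, (0.65, 0.85), seed)
        report["base"] = _fit_report(df, FULL_FEATURES, "tawss_pa", cfg, seed)
        report["with_early_wss"] = _fit_report(
            df, FULL_FEATURES + EARLY_WSS_FEATURES, "tawss_pa", cfg, seed
        )
    elif name == "doe":
        df = dataset if dataset is not None else _synthetic_dataset(cfg, (0.65,), seed)
        res = minimal_set_search(
            df, threshold=cfg.doe.threshold, n_subsets=cfg.doe.n_subsets, seed=seed
        )
        report["minimal_set"] = {
            "size": res.size,
            "pairings": res.pairings,
            "best_r": res.best_r,
            "r_trace": {str(k): v for k, v in res.r_trace.items()},
            "threshold": res.threshold,
        }
        grid = SweepGrid(
            viscosities=tuple(cfg.viscosities_cP),
            waveforms=tuple(build_family(n=cfg.waveforms.n)),
        )
        transfers = []
        for g in range(2):  # two new geometries with the same degree of stenosis
            params = synthetic_response.ResponseParams().jittered(0.1, seed + g + 1)

            def runner(pairings, params=params):
                sub = df.set_index(["viscosity_cP", "waveform"]).loc[
                    [tuple(p) for p in pairings]
                ].reset_index()
                out = sub.copy()
                rng = np.random.default_rng(seed)
                out["dp_mmHg"] = synthetic_response.dp_response(
                    out["viscosity_cP"].to_numpy(), out["peak_flow_mm3_s"].to_numpy(),
                    params, rng,
                )
                return out

            tr = transfer_protocol(res, runner, grid, n_test=9, seed=seed + g + 1)
            transfers.append(
                {"r": tr["r"], "total_runs": tr["total_runs"], "n_train": tr["n_train"]}
            )
        report["transfers"] = transfers
    return report


PRESETS = ("full_dp", "tawss", "doe")
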