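"""Design-of-experiments engine: sweep grids, the minimal-training-set
search, and the transfer protocol to new geometries.

The search starts from a full sweep (ten viscosities x five waveforms = 50
runs on one geometry) and a seeded 40/10 train/test split.  The training
set is then shrunk one run at a time: at each size the candidate training
subsets are scored by the test-set Pearson correlation of a surrogate
trained on them (test set = all remaining runs), and the descent continues
while the best candidate still reaches the correlation threshold (default
R >= 0.98).  The smallest passing subset — identified by its viscosity-flow
rate pairings — is recorded together with the R-versus-size trace.

The first reduction enumerates all drop-one subsets of the current training
set (40 combinations); subsequent sizes enumerate every k-subset of the
dataset when there are at most ``n_subsets`` of them and otherwise draw
``n_subsets`` random subsets.  Candidate scoring uses a vectorized
fixed-epoch Adam trainer that fits all candidate networks simultaneously
(same 10-ReLU-unit architecture); the recorded minimal set is refit with
the reference trainer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from . import surrogate
from .waveforms import Waveform, build_family

__all__ = [
    "SweepGrid",
    "MinimalSetResult",
    "SearchError",
    "ProtocolError",
    "default_viscosities",
    "default_grid",
    "enumerate_grid",
    "minimal_set_search",
    "transfer_protocol",
    "DOE_FEATURES",
]

#: input features of the search surrogate
DOE_FEATURES = ("viscosity_cP", "peak_flow_mm3_s", "heart_rate_bpm")

#: physiological blood-viscosity sweep endpoints (cP)
VISCOSITY_RANGE_CP = (2.66, 6.38)


class SearchError(RuntimeError):
    def __init__(self, message, r_trace):
        super().__init__(message)
        self.r_trace = r_trace


class ProtocolError(ValueError):
    """Train/test pairings overlap in the transfer protocol."""


def default_viscosities(n: int = 10) -> list[float]:
    """n viscosities evenly spanning the physiological range 2.66-6.38 cP."""
    return [float(v) for v in np.linspace(*VISCOSITY_RANGE_CP, n)]


@dataclass(frozen=True)
class SweepGrid:
    """Full factorial sweep: viscosities x waveforms per geometry."""

    viscosities: tuple
    waveforms: tuple
    geometries: tuple = (0.65,)

    @property
    def pairings(self) -> list[tuple]:
        """(viscosity, waveform label) combinations, viscosity-major."""
        return [(v, w.label) for v in self.viscosities for w in self.waveforms]

    def size(self) -> int:
        return len(self.viscosities) * len(self.waveforms) * len(self.geometries)


def default_grid(geometries=(0.65,), n_viscosities: int = 10, n_waveforms: int = 5):
    return SweepGrid(
        viscosities=tuple(default_viscosities(n_viscosities)),
        waveforms=tuple(build_family(n=n_waveforms)),
        geometries=tuple(geometries),
    )


def enumerate_grid(viscosities, waveforms, geometries) -> list[dict]:
    """Cartesian product of run configurations, deterministically ordered
    viscosity-major, then waveform, then geometry."""
    if not (len(viscosities) and len(waveforms) and len(geometries)):
        raise ValueError("viscosities, waveforms and geometries must be non-empty")
    runs = []
    for v in viscosities:
        for w in waveforms:
            for g in geometries:
                runs.append(
                    {
                        "viscosity_cP": float(v),
                        "waveform": w.label if isinstance(w, Waveform) else str(w),
                        "dos": float(g),
                    }
                )
    return runs


@dataclass
class MinimalSetResult:
    """Outcome of the minimal-training-set search."""

    pairings: list  # surviving (viscosity_cP, waveform label) pairs
    size: int
    r_trace: dict  # training-set size -> best test R
    seed: int
    threshold: float
    best_r: float  # test R of the recorded set's best model
    indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


# ---------------------------------------------------------------------------
# vectorized candidate scoring
# ---------------------------------------------------------------------------

def _batch_score(
    X: np.ndarray,
    y: np.ndarray,
    subsets: np.ndarray,
    rng: np.random.Generator,
    epochs: int = 1000,
    lr: float = 1e-2,
    hidden: int = surrogate.HIDDEN_UNITS,
    weight_decay: float = 1e-3,
    restarts: int = 3,
) -> np.ndarray:
    """Test-set Pearson R for each candidate training subset.

    Trains one 10-unit ReLU network per subset, all simultaneously
    (fixed-epoch full-batch Adam, cosine step decay, small L2 penalty,
    best-of-``restarts`` initializations by training loss — the same recipe
    as the reference trainer at a reduced epoch budget), and scores each on
    its complement.  Constant feature columns within a subset are centered
    and ignored.
    """
    M0, k = subsets.shape
    n, p = X.shape
    Xtr = X[subsets]  # (M0, k, p)
    mean = Xtr.mean(axis=1, keepdims=True)
    sd = Xtr.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Zfull0 = (X[None, :, :] - mean) / sd  # (M0, n, p)

    # restarts ride along the model axis: candidate c's restarts sit at
    # c, c + M0, c + 2*M0, ...
    M = M0 * max(restarts, 1)
    Zfull = np.tile(Zfull0, (restarts, 1, 1))
    subs_rep = np.tile(subsets, (restarts, 1))
    Ztr = np.take_along_axis(Zfull, subs_rep[:, :, None], axis=1)

    ytr = y[subsets]
    ym = ytr.mean(axis=1, keepdims=True)
    ys = ytr.std(axis=1, keepdims=True)
    ys[ys == 0] = 1.0
    t = np.tile((ytr - ym) / ys, (restarts, 1))

    lim1 = np.sqrt(6.0 / p)
    lim2 = np.sqrt(6.0 / hidden)
    params = [
        rng.uniform(-lim1, lim1, size=(M, p, hidden)),
        np.zeros((M, 1, hidden)),
        rng.uniform(-lim2, lim2, size=(M, hidden, 1)),
        np.zeros((M, 1, 1)),
    ]
    mom = [np.zeros_like(q) for q in params]
    vel = [np.zeros_like(q) for q in params]
    b1c, b2c, eps = 0.9, 0.999, 1e-8

    tcol = t[:, :, None]
    for epoch in range(1, epochs + 1):
        step = max(lr * 0.5 * (1.0 + np.cos(np.pi * epoch / epochs)), 1e-5)
        A = Ztr @ params[0] + params[1]
        H = np.maximum(A, 0.0)
        pred = H @ params[2] + params[3]  # (M, k, 1)
        g_out = (2.0 / k) * (pred - tcol)
        g_hid = (g_out @ np.swapaxes(params[2], 1, 2)) * (A > 0)
        grads = [
            np.swapaxes(Ztr, 1, 2) @ g_hid,
            g_hid.sum(axis=1, keepdims=True),
            np.swapaxes(H, 1, 2) @ g_out,
            g_out.sum(axis=1, keepdims=True),
        ]
        for q, g, m_, v_ in zip(params, grads, mom, vel):
            g = g + weight_decay * q
            m_ *= b1c
            m_ += (1 - b1c) * g
            v_ *= b2c
            v_ += (1 - b2c) * g * g
            q -= step * (m_ / (1 - b1c**epoch)) / (
                np.sqrt(v_ / (1 - b2c**epoch)) + eps
            )

    # pick, per candidate, the restart with the lowest training MSE
    A = Ztr @ params[0] + params[1]
    train_mse = (((np.maximum(A, 0.0) @ params[2] + params[3]) - tcol) ** 2).mean(
        axis=(1, 2)
    )
    pick = np.argmin(train_mse.reshape(restarts, M0), axis=0) * M0 + np.arange(M0)
    Hf = np.maximum(Zfull[pick] @ params[0][pick] + params[1][pick], 0.0)
    pred_full = (Hf @ params[2][pick] + params[3][pick])[:, :, 0] * ys + ym  # (M0, n)
    M = M0

    # complement (test) mask per candidate
    mask = np.ones((M, n), dtype=bool)
    np.put_along_axis(mask, subsets, False, axis=1)
    nt = n - k
    r = np.empty(M)
    for c in range(M):
        pt = pred_full[c, mask[c]]
        yt = y[mask[c]]
        sp, sy = pt.std(), yt.std()
        if sp == 0 or sy == 0 or nt < 3:
            r[c] = -np.inf
        else:
            r[c] = float(np.corrcoef(pt, yt)[0, 1])
    return r


def _candidate_subsets(
    n: int, k: int, current_best: np.ndarray | None, n_subsets: int, rng
) -> np.ndarray:
    """Candidate k-subsets of range(n); drop-one from the current training
    set when shrinking by exactly one, otherwise exhaustive or sampled."""
    if current_best is not None and len(current_best) == k + 1:
        first_step = True
    else:
        first_step = False
    if first_step and comb(len(current_best), k) <= max(n_subsets, len(current_best)):
        # drop-one enumeration of the current training set
        subs = [np.delete(current_best, i) for i in range(len(current_best))]
        return np.array(subs)
    if comb(n, k) <= n_subsets:
        return np.array(list(itertools.combinations(range(n), k)))
    return np.array([rng.choice(n, size=k, replace=False) for _ in range(n_subsets)])


def minimal_set_search(
    dataset: pd.DataFrame,
    threshold: float = 0.98,
    n_subsets: int = 1000,
    seed: int = 0,
    features=DOE_FEATURES,
    target: str = "dp_mmHg",
    initial_train: int = 40,
    floor: int = 4,
    score_epochs: int = 1000,
    score_lr: float = 1e-2,
) -> MinimalSetResult:
    """Shrink the training set while the best candidate keeps test R >= threshold.

    ``dataset`` holds one row per sweep run with the feature and target
    columns.  Returns the smallest passing subset (its viscosity-flow rate
    pairings), the R-versus-size trace, and the best test R at that size.
    Raises :class:`SearchError` when the threshold is unreachable even at
    the initial training size.
    """
    n = len(dataset)
    initial_train = min(initial_train, n - 3)
    if initial_train < floor:
        raise ValueError("dataset too small for the requested initial split")
    X = dataset.loc[:, list(features)].to_numpy(dtype=float)
    y = dataset.loc[:, target].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    def _verify_one(subset: np.ndarray, vseed: int) -> float:
        mask = np.ones(n, dtype=bool)
        mask[subset] = False
        model = surrogate.train(
            X[subset], y[subset], seed=vseed, allow_constant=True,
            feature_names=list(features), target_name=target,
        )
        pred = model.predict(X[mask])
        if np.std(pred) == 0:
            return -np.inf
        return float(np.corrcoef(pred, y[mask])[0, 1])

    def _verify(subset: np.ndarray, vseed: int) -> float:
        """Worst-case reference-trainer test R over two training seeds.

        The screening scores are the maximum over many noisy fits, so the
        winning candidate is verified with independent full-budget fits
        before a reduction is accepted; requiring the threshold under three
        independent training seeds keeps the recorded set reproducible
        under retraining rather than an artifact of one lucky
        initialization.
        """
        return min(
            _verify_one(subset, vseed + off) for off in (0, 7919, 104729)
        )

    r_trace: dict[int, float] = {}
    current = np.sort(rng.choice(n, size=initial_train, replace=False))
    r0 = _verify(current, seed)
    r_trace[initial_train] = float(r0)
    if r0 < threshold:
        raise SearchError(
            f"threshold {threshold} unreachable at the initial training size "
            f"{initial_train} (R = {r0:.4f})",
            r_trace,
        )

    best_set, best_r = current, float(r0)
    verify_top = 5  # screening winners re-checked per size
    for k in range(initial_train - 1, floor - 1, -1):
        cands = _candidate_subsets(n, k, current, n_subsets, rng)
        scores = _batch_score(X, y, cands, rng, score_epochs, score_lr)
        order = np.argsort(scores)[::-1]
        accepted = None
        for rank, i in enumerate(order[:verify_top]):
            if scores[i] < threshold:
                break
            r_ref = _verify(cands[i], seed + k)
            if r_ref >= threshold:
                accepted = (np.sort(cands[i]), float(r_ref))
                break
        r_trace[k] = float(
            accepted[1] if accepted is not None else max(scores)
        )
        if accepted is not None:
            current = accepted[0]
            best_set, best_r = current, accepted[1]
        else:
            break

    pair_cols = dataset.loc[:, ["viscosity_cP", "waveform"]].to_numpy()
    pairings = [(float(v), str(w)) for v, w in pair_cols[best_set]]
    return MinimalSetResult(
        pairings=pairings,
        size=len(best_set),
        r_trace=r_trace,
        seed=int(seed),
        threshold=float(threshold),
        best_r=best_r,
        indices=best_set,
    )


def transfer_protocol(
    minimal: MinimalSetResult,
    runner,
    grid: SweepGrid,
    n_test: int = 9,
    seed: int = 0,
    features=DOE_FEATURES,
    target: str = "dp_mmHg",
    train_config: surrogate.TrainConfig = surrogate.TrainConfig(),
) -> dict:
    """Apply a minimal pairing set to a new geometry and score the surrogate.

    ``runner(pairings)`` returns the new geometry's records (one row per
    pairing, same schema as the sweep table).  The model is trained on the
    minimal pairings' records from the new geometry and evaluated on
    ``n_test`` seeded-random distinct pairings drawn from the rest of the
    grid, so each new geometry costs ``len(minimal.pairings) + n_test``
    runs.
    """
    train_pairs = [tuple(p) for p in minimal.pairings]
    pool = [p for p in grid.pairings if tuple(p) not in set(train_pairs)]
    if n_test > len(pool):
        raise ProtocolError(f"cannot draw {n_test} test pairings from {len(pool)}")
    rng = np.random.default_rng(seed)
    test_pairs = [pool[i] for i in rng.choice(len(pool), size=n_test, replace=False)]
    if set(map(tuple, test_pairs)) & set(train_pairs):
        raise ProtocolError("train and test pairings overlap")

    df_train = runner(train_pairs)
    df_test = runner(test_pairs)
    model = surrogate.train(
        df_train.loc[:, list(features)].to_numpy(dtype=float),
        df_train.loc[:, target].to_numpy(dtype=float),
        seed=seed,
        config=train_config,
        feature_names=list(features),
        target_name=target,
        allow_constant=True,
    )
    pred = model.predict(df_test.loc[:, list(features)].to_numpy(dtype=float))
    r = surrogate.pearson_r(pred, df_test.loc[:, target].to_numpy(dtype=float))
    return {
        "r": float(r),
        "n_train": len(train_pairs),
        "n_test": n_test,
        "total_runs": len(train_pairs) + n_test,
        "model": model,
        "test_pairings": [tuple(p) for p in test_pairs],
    }
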