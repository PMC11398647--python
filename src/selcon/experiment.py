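"""Full study orchestration: paired training, evaluation, and the radius sweep.

For each spectral radius, a Hebbian and a non-Hebbian reservoir are trained
as a matched pair: both arms share the initial weights, the same 20-trial
stimulus session, and the same per-trial initial-state and internal-noise
realizations, differing only in whether Oja's rule is active.  One stimulus
corpus (session + test set) is shared across all radii.

Evaluation freezes everything (plasticity off, readout optimizer off) and
presents fresh test material from ``n_test_runs`` different initial states
per stimulus kind, recording the output series and a seeded random sample
of reservoir-node series.  From these it computes inter-segment and
inter-trial consistency, RMSE/NRMSE, and paired surrogate tests of the
Hebbian-vs-non-Hebbian contrast per radius and stimulus kind, Bonferroni-
corrected over radius levels x tested contrasts.

All networks in a sweep share one sparsity mask (they are rescalings of a
single random draw), which lets the training loop run every (radius, arm)
in a single compiled pass over the session.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse, stats as sp_stats

from .metrics import (
    DEFAULT_WINDOW,
    inter_segment_correlations,
    nanmean_with_count,
    nrmse_series,
    rmse_per_run,
    rmse_series,
)
from .readout import Readout, TrainingConfig, make_batch, minibatch_error, train_readout_online
from .reservoir import (
    PlasticityConfig,
    ReservoirConfig,
    ReservoirNetwork,
    init_reservoir,
    run_trial,
    spectral_radius,
)
from .stats import bonferroni_adjust, paired_surrogate_test
from .stimulus import KINDS, StimulusSession, TestSet, build_session, build_test_set, session_manifest

__all__ = [
    "SweepConfig",
    "TrainedArm",
    "TrainedPair",
    "ResultsBundle",
    "derive_seeds",
    "build_corpus",
    "train_pair",
    "evaluate_pair",
    "run_sweep",
    "selectivity_curve",
    "peak_radius",
]

_SEED_MAX = 2**31

DEFAULT_RADII = tuple(np.round(np.arange(0.1, 2.01, 0.1), 2))


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of the full spectral-radius sweep."""

    radii: tuple = DEFAULT_RADII
    n_test_runs: int = 200
    optimize_readout: bool = True
    node_sample_size: int = 5
    master_seed: int = 0
    # reservoir
    n_neurons: int = 500
    density: float = 0.1
    noise_sigma: float = 1e-3
    input_gain: float = 1.0
    update_rule: str = "standard"
    # plasticity / readout training
    alpha: float = 1e-7
    eta: float = 0.01
    steps_per_minibatch: int = 1
    # evaluation
    eval_kinds: tuple = KINDS
    comparison_kinds: tuple = ("RN", "RefRN")
    n_surrogates: int = 5000
    # test-run pairing across arms: "none" draws every test trial
    # independently per arm (pairing is by run index only); "init" presents
    # the same initial state to both arms of a pair; "full" also shares the
    # internal-noise realizations
    eval_pairing: str = "none"
    eval_dtype: str = "float32"
    normalize_stimuli: bool = False

    def __post_init__(self) -> None:
        if not self.radii or any(r <= 0 for r in self.radii):
            raise ValueError("radii must be a nonempty list of positive values")
        if self.eval_pairing not in ("none", "init", "full"):
            raise ValueError("eval_pairing must be 'none', 'init' or 'full'")

    def reservoir_config(self, radius: float, init_seed: int) -> ReservoirConfig:
        return ReservoirConfig(
            n_neurons=self.n_neurons,
            density=self.density,
            spectral_radius=float(radius),
            noise_sigma=self.noise_sigma,
            input_gain=self.input_gain,
            init_seed=init_seed,
            update_rule=self.update_rule,
        )

    @property
    def m_comparisons(self) -> int:
        """Bonferroni factor: radius levels x stimulus contrasts tested."""
        return len(self.radii) * len(self.comparison_kinds)


def derive_seeds(master_seed: int, n_trials: int = 20) -> dict:
    """Deterministically expand one master seed into every named sub-seed."""
    rng = np.random.default_rng(master_seed)

    def draw() -> int:
        return int(rng.integers(0, _SEED_MAX))

    seeds = {
        "ref_rn": draw(),
        "ref_n": draw(),
        "order": draw(),
        "fresh": draw(),
        "init": draw(),
        "test_set": draw(),
        "nodes": draw(),
        "surrogate": draw(),
        "w_out": draw(),
        "trial_init": [draw() for _ in range(n_trials)],
        "trial_noise": [draw() for _ in range(n_trials)],
        "eval": {kind: draw() for kind in KINDS},
        "eval_unpaired": {kind: {"hebb": draw(), "nonhebb": draw()}
                          for kind in KINDS},
    }
    return seeds


def build_corpus(config: SweepConfig, seeds: dict | None = None
                 ) -> tuple[StimulusSession, TestSet, dict]:
    """One stimulus session and test set, shared by all radii and both arms."""
    seeds = seeds or derive_seeds(config.master_seed)
    session = build_session(
        ref_rn_seed=seeds["ref_rn"],
        ref_n_seed=seeds["ref_n"],
        order_seed=seeds["order"],
        fresh_seeds=seeds["fresh"],
        normalize=config.normalize_stimuli,
    )
    test_set = build_test_set(session, n_runs=config.n_test_runs,
                              seed=seeds["test_set"], kinds=config.eval_kinds)
    return session, test_set, seeds


# ---------------------------------------------------------------------------
# batched session training (all radii and arms in one compiled pass)


@njit(cache=True, fastmath=True)
def _trial_batch_kernel(data, indices, indptr, w_in_eff, u, d_targets,
                        x, noise, alphas, n_plastic, w_out, grad,
                        integrator):  # pragma: no cover - exercised via wrapper
    """One training trial for B networks sharing a sparsity pattern.

    data: (nnz, B) per-network weights in CSR order; mutated by Oja's rule.
    x: (n, B) state, mutated in place; w_in_eff is (n, B).  Plastic networks
    occupy the first ``n_plastic`` columns.  Accumulates the readout
    gradient (per-network) and returns the minibatch errors E_n (B,).
    """
    n, B = x.shape
    K = u.shape[0]
    E = np.zeros(B)
    grad[:] = 0.0
    xn = np.empty((n, B))
    for k in range(K):
        for i in range(n):
            for b in range(B):
                xn[i, b] = w_in_eff[i, b] * u[k]
            for jj in range(indptr[i], indptr[i + 1]):
                c = indices[jj]
                for b in range(B):
                    xn[i, b] += data[jj, b] * x[c, b]
        if integrator:
            for i in range(n):
                for b in range(B):
                    xn[i, b] = x[i, b] + np.tanh(xn[i, b]) + noise[k, i]
        else:
            for i in range(n):
                for b in range(B):
                    xn[i, b] = np.tanh(xn[i, b]) + noise[k, i]
        for i in range(n):
            for b in range(B):
                x[i, b] = xn[i, b]
        # Oja's rule on the stored nonzeros of the plastic networks
        if n_plastic > 0:
            for i in range(n):
                for jj in range(indptr[i], indptr[i + 1]):
                    c = indices[jj]
                    for b in range(n_plastic):
                        w = data[jj, b]
                        data[jj, b] = w + alphas[b] * x[i, b] * (x[c, b] - x[i, b] * w)
        # readout: accumulate gradient of the one-step-ahead error
        if k < K - 1:
            for b in range(B):
                y = 0.0
                for i in range(n):
                    y += w_out[b, i] * x[i, b]
                resid = d_targets[k] - y
                E[b] += 0.5 * resid * resid
                for i in range(n):
                    grad[b, i] += resid * x[i, b]
    return E / (K - 1)


@dataclass
class TrainedArm:
    net: ReservoirNetwork
    readout: Readout
    plastic: bool
    rho_before: float
    rho_after: float
    training_errors: np.ndarray  # E_n per trial
    failed: bool = False
    failed_at_trial: int = -1


@dataclass
class TrainedPair:
    radius: float
    hebb: TrainedArm
    nonhebb: TrainedArm

    @property
    def arms(self) -> dict:
        return {"hebb": self.hebb, "nonhebb": self.nonhebb}


def _train_batch(
    nets: list[ReservoirNetwork],
    plastic_flags: list[bool],
    session: StimulusSession,
    config: SweepConfig,
    seeds: dict,
    w_out_init: np.ndarray | None = None,
) -> tuple[list[Readout], np.ndarray, list[int]]:
    """Train B mask-sharing networks through the session in one pass.

    The networks must share a sparsity pattern but may have distinct weight
    values and input weights.  ``w_out_init`` optionally provides per-network
    initial readouts (B, n); by default every arm starts from one shared
    random readout (the paired construction).  Returns (readouts, training
    errors (B, T), first failed trial per net, -1 where training stayed
    finite).  Network weights are updated in place.
    """
    base = nets[0]
    n = base.n_neurons
    rows, cols = base._rows, base._cols
    order = np.argsort(~np.asarray(plastic_flags), kind="stable")  # plastic first
    n_plastic = int(np.sum(plastic_flags))
    B = len(nets)

    ref = sparse.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n, n)
    )
    data = np.empty((rows.size, B))
    w_in_eff = np.empty((n, B))
    for slot, bi in enumerate(order):
        data[:, slot] = nets[bi].W[rows, cols]
        w_in_eff[:, slot] = nets[bi].W_in * config.input_gain
    alphas = np.array([
        config.alpha if plastic_flags[bi] else 0.0 for bi in order
    ])
    if w_out_init is None:
        w_out = np.tile(Readout.random(n, seeds["w_out"]).W_out, (B, 1))
    else:
        w_out = np.array([w_out_init[bi] for bi in order])
    grad = np.empty((B, n))
    x = np.empty((n, B))

    T = len(session.stimuli)
    errors = np.full((B, T), np.nan)
    failed_at = np.full(B, -1, dtype=int)
    rng_sigma = config.noise_sigma
    for t, stim in enumerate(session.stimuli):
        u = stim.processed.samples
        K = u.shape[0]
        x0 = np.random.default_rng(seeds["trial_init"][t]).uniform(-1, 1, n)
        if rng_sigma > 0:
            noise = (np.random.default_rng(seeds["trial_noise"][t])
                     .standard_normal((K, n)) * rng_sigma)
        else:
            noise = np.zeros((K, n))
        x[:] = x0[:, None]
        E = _trial_batch_kernel(
            data, ref.indices, ref.indptr, w_in_eff, u, u[1:],
            x, noise, alphas, n_plastic, w_out, grad,
            config.update_rule == "integrator",
        )
        finite = np.isfinite(x).all(axis=0) & np.isfinite(E)
        newly_failed = (~finite) & (failed_at < 0)
        failed_at[newly_failed] = t
        errors[:, t] = E
        if config.optimize_readout and config.steps_per_minibatch >= 1:
            # one descent step per trial; extra steps reuse the same states
            # only in the generic (non-batched) path
            w_out[finite] += config.eta * grad[finite] / (K - 1)

    readouts: list[Readout] = [None] * B
    failures = [0] * B
    errs = np.empty_like(errors)
    for slot, bi in enumerate(order):
        nets[bi].W[rows, cols] = data[:, slot]
        readouts[bi] = Readout(w_out[slot].copy())
        failures[bi] = int(failed_at[slot])
        errs[bi] = errors[slot]
    return readouts, errs, failures


def train_pair(
    radius: float,
    session: StimulusSession,
    config: SweepConfig,
    seeds: dict | None = None,
) -> TrainedPair:
    """Train the matched Hebbian / non-Hebbian pair at one spectral radius."""
    pairs = train_pairs([radius], session, config, seeds)
    return pairs[0]


def train_pairs(
    radii: Sequence[float],
    session: StimulusSession,
    config: SweepConfig,
    seeds: dict | None = None,
) -> list[TrainedPair]:
    """Train Hebbian/non-Hebbian pairs for several radii in one pass.

    All pairs share the same random draw (one init seed), so every network
    is a rescaling of the same sparse matrix and the whole collection can
    be trained through the shared session in a single compiled loop.
    """
    seeds = seeds or derive_seeds(config.master_seed)
    if config.steps_per_minibatch != 1 and config.optimize_readout:
        return [
            _train_pair_generic(r, session, config, seeds) for r in radii
        ]
    nets: list[ReservoirNetwork] = []
    flags: list[bool] = []
    base = init_reservoir(config.reservoir_config(radii[0], seeds["init"]))
    for r in radii:
        scale = float(r) / radii[0]
        for plastic in (True, False):
            net = base.copy()
            net.W *= scale
            net = net.with_config(spectral_radius=float(r))
            nets.append(net)
            flags.append(plastic)
    readouts, errors, failures = _train_batch(nets, flags, session, config, seeds)

    pairs = []
    for i, r in enumerate(radii):
        arms = {}
        for j, name in ((2 * i, "hebb"), (2 * i + 1, "nonhebb")):
            failed = failures[j] >= 0
            arms[name] = TrainedArm(
                net=nets[j],
                readout=readouts[j],
                plastic=flags[j],
                rho_before=float(r),
                rho_after=spectral_radius(nets[j].W) if not failed else np.nan,
                training_errors=errors[j],
                failed=failed,
                failed_at_trial=failures[j],
            )
        pairs.append(TrainedPair(radius=float(r), **arms))
    return pairs


def _train_pair_generic(radius, session, config, seeds) -> TrainedPair:
    """Reference trial-by-trial training path (supports steps_per_minibatch>1)."""
    net0 = init_reservoir(config.reservoir_config(radius, seeds["init"]))
    train_cfg = TrainingConfig(eta=config.eta,
                               steps_per_minibatch=config.steps_per_minibatch,
                               optimize=config.optimize_readout)
    arms = {}
    for name, plastic in (("hebb", True), ("nonhebb", False)):
        net = net0.copy()
        readout = Readout.random(config.n_neurons, seeds["w_out"])
        plast = PlasticityConfig(enabled=plastic, alpha=config.alpha)
        errors = np.full(len(session.stimuli), np.nan)
        failed_at = -1
        for t, stim in enumerate(session.stimuli):
            try:
                rec, net = run_trial(net, stim, seeds["trial_init"][t],
                                     plast, seeds["trial_noise"][t])
            except FloatingPointError:
                failed_at = t
                break
            errors[t] = minibatch_error(readout, make_batch(rec, stim, t))
            readout = train_readout_online(readout, rec, stim, train_cfg)
        arms[name] = TrainedArm(
            net=net, readout=readout, plastic=plastic,
            rho_before=float(radius),
            rho_after=spectral_radius(net.W) if failed_at < 0 else np.nan,
            training_errors=errors, failed=failed_at >= 0,
            failed_at_trial=failed_at,
        )
    return TrainedPair(radius=float(radius), **arms)


# ---------------------------------------------------------------------------
# evaluation


def _run_batch(
    W: np.ndarray,
    w_in_eff: np.ndarray,
    U: np.ndarray,
    sigma: float,
    rng: np.random.Generator,
    node_ids: np.ndarray,
    w_out: np.ndarray,
    integrator: bool,
    dtype=np.float32,
    init_rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run R frozen test trials side by side (plasticity and optimizer off).

    U is (R, K): one input row per run (identical rows for referenced
    stimuli).  Initial states U(-1,1)^N are drawn from ``init_rng`` (or
    ``rng`` when absent) and the per-step internal noise from ``rng``.
    Returns the output series (R, K) and the sampled node series
    (n_nodes, R, K).
    """
    W = np.ascontiguousarray(W, dtype=dtype)
    w_in_eff = w_in_eff.astype(dtype)
    w_out = w_out.astype(dtype)
    R, K = U.shape
    n = W.shape[0]
    Ut = np.ascontiguousarray(U.T, dtype=dtype)  # (K, R)
    X = (init_rng or rng).uniform(-1.0, 1.0, (n, R)).astype(dtype)
    outputs = np.empty((K, R), dtype=dtype)
    nodes = np.empty((len(node_ids), K, R), dtype=dtype)
    for k in range(K):
        pre = W @ X
        pre += w_in_eff[:, None] * Ut[k][None, :]
        Xn = np.tanh(pre)
        if sigma > 0:
            Xn += rng.standard_normal((n, R), dtype=dtype) * dtype(sigma)
        if integrator:
            Xn += X
        X = Xn
        outputs[k] = w_out @ X
        nodes[:, k, :] = X[node_ids, :]
    return outputs.T.astype(np.float64), np.swapaxes(nodes, 1, 2).astype(np.float64)


@dataclass
class EvalResult:
    """Per-(radius, arm, kind) evaluation arrays."""

    output_r: np.ndarray        # (R,) inter-segment r of the output series
    node_r: np.ndarray          # (n_nodes, R) inter-segment r per node
    inter_trial_r: float        # mean pairwise output correlation
    inter_trial_undefined: int
    rmse: np.ndarray            # (K-1,) per-time-point RMSE
    rmse_runs: np.ndarray       # (R,) per-run time-averaged RMSE


def _inter_trial_mean(series: np.ndarray, window: int = DEFAULT_WINDOW
                      ) -> tuple[float, int]:
    """Mean pairwise Pearson r between rows of (R, K) on [0, window)."""
    seg = series[:, :window]
    sd = seg.std(axis=1)
    valid = sd > 0
    n_undef_rows = int((~valid).sum())
    R = series.shape[0]
    n_pairs = R * (R - 1) // 2
    if valid.sum() < 2:
        return np.nan, n_pairs
    C = np.corrcoef(seg[valid])
    iu = np.triu_indices_from(C, k=1)
    mean = float(C[iu].mean())
    n_valid_pairs = valid.sum() * (valid.sum() - 1) // 2
    return mean, n_pairs - n_valid_pairs


def evaluate_pair(
    pair: TrainedPair,
    test_set: TestSet,
    config: SweepConfig,
    seeds: dict,
) -> dict[str, dict[str, EvalResult]]:
    """Frozen-network evaluation of both arms on every requested kind.

    Returns ``{kind: {arm: EvalResult}}``.  Failed arms are skipped.
    Under the default pairing, run i presents the same initial state to
    both arms (the paired-trial design), while each network's internal
    noise is its own.
    """
    node_ids = np.sort(
        np.random.default_rng(seeds["nodes"]).choice(
            config.n_neurons, size=config.node_sample_size, replace=False)
    )
    dtype = np.float32 if config.eval_dtype == "float32" else np.float64
    results: dict[str, dict[str, EvalResult]] = {}
    for kind in config.eval_kinds:
        U = test_set.processed_matrix(kind)
        targets = U[:, 1:]
        per_arm: dict[str, EvalResult] = {}
        for arm_name, arm in pair.arms.items():
            if arm.failed:
                continue
            if config.eval_pairing == "full":
                rng = np.random.default_rng(seeds["eval"][kind])
                init_rng = None
            else:
                rng = np.random.default_rng(
                    seeds["eval_unpaired"][kind][arm_name])
                init_rng = (np.random.default_rng(seeds["eval"][kind])
                            if config.eval_pairing == "init" else None)
            outputs, nodes = _run_batch(
                arm.net.W, arm.net.W_in * config.input_gain, U,
                config.noise_sigma, rng, node_ids, arm.readout.W_out,
                config.update_rule == "integrator", dtype=dtype,
                init_rng=init_rng,
            )
            preds = outputs[:, :-1]
            per_arm[arm_name] = EvalResult(
                output_r=inter_segment_correlations(outputs),
                node_r=np.stack([
                    inter_segment_correlations(nodes[j]) for j in range(len(node_ids))
                ]),
                inter_trial_r=_inter_trial_mean(outputs)[0],
                inter_trial_undefined=_inter_trial_mean(outputs)[1],
                rmse=rmse_series(preds, targets),
                rmse_runs=rmse_per_run(preds, targets),
            )
        results[kind] = per_arm
    return results


# ---------------------------------------------------------------------------
# sweep + results bundle


@dataclass
class ResultsBundle:
    consistency: pd.DataFrame       # radius, plastic, kind, run, level, node_id, r
    inter_trial: pd.DataFrame       # radius, plastic, kind, mean_r, n_undefined
    error_series: pd.DataFrame      # radius, plastic, kind, k, rmse, nrmse
    error_runs: pd.DataFrame        # radius, plastic, kind, run, rmse, nrmse
    tests: pd.DataFrame             # consistency surrogate tests
    error_tests: pd.DataFrame       # RefRN-vs-RN prediction error tests
    drift: pd.DataFrame             # radius, arm, rho_before, rho_after
    failures: pd.DataFrame
    provenance: dict
    artifacts: list[TrainedPair] | None = None

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("consistency", "inter_trial", "error_series",
                     "error_runs", "tests", "error_tests", "drift",
                     "failures"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, default=str))
        return out


def _consistency_rows(radius, arm_name, plastic, kind, res: EvalResult):
    rows = []
    for run, r in enumerate(res.output_r):
        rows.append((radius, arm_name, plastic, kind, run, "output", -1, r))
    for node_id in range(res.node_r.shape[0]):
        for run, r in enumerate(res.node_r[node_id]):
            rows.append((radius, arm_name, plastic, kind, run, "node",
                         node_id, r))
    return rows


def run_sweep(config: SweepConfig, return_artifacts: bool = False
              ) -> ResultsBundle:
    """Train and evaluate the full spectral-radius sweep."""
    seeds = derive_seeds(config.master_seed)
    session, test_set, _ = build_corpus(config, seeds)
    pairs = train_pairs(list(config.radii), session, config, seeds)

    cons_rows, it_rows, es_rows, er_rows = [], [], [], []
    test_rows, etest_rows, drift_rows, fail_rows = [], [], [], []
    surr_rng = np.random.default_rng(seeds["surrogate"])
    m = config.m_comparisons

    for pair in pairs:
        radius = pair.radius
        for arm_name, arm in pair.arms.items():
            drift_rows.append((radius, arm_name, arm.rho_before, arm.rho_after))
            if arm.failed:
                fail_rows.append((radius, arm_name, arm.failed_at_trial))
        results = evaluate_pair(pair, test_set, config, seeds)

        rmse_by_cond = {}
        runs_by_cond = {}
        for kind, per_arm in results.items():
            for arm_name, res in per_arm.items():
                plastic = pair.arms[arm_name].plastic
                cons_rows += _consistency_rows(radius, arm_name, plastic,
                                               kind, res)
                it_rows.append((radius, arm_name, plastic, kind,
                                res.inter_trial_r, res.inter_trial_undefined))
                if kind in ("RN", "RefRN"):
                    rmse_by_cond[(arm_name, kind)] = res.rmse
                    runs_by_cond[(arm_name, kind)] = res.rmse_runs

        # NRMSE normalization over the 2x2 plasticity-by-stimulus conditions
        if len(rmse_by_cond) == 4:
            nrmse = nrmse_series({k: v for k, v in rmse_by_cond.items()})
            grand = float(np.mean([v.mean() for v in rmse_by_cond.values()]))
            for (arm_name, kind), series in rmse_by_cond.items():
                plastic = pair.arms[arm_name].plastic
                nr = nrmse[(arm_name, kind)]
                for k in range(series.shape[0]):
                    es_rows.append((radius, arm_name, plastic, kind, k,
                                    series[k], nr[k]))
                for run, val in enumerate(runs_by_cond[(arm_name, kind)]):
                    er_rows.append((radius, arm_name, plastic, kind, run, val,
                                    val / grand if grand > 0 else np.nan))

        # paired Hebbian-vs-non-Hebbian consistency tests
        for kind in config.comparison_kinds:
            per_arm = results.get(kind, {})
            if {"hebb", "nonhebb"} - per_arm.keys():
                continue
            for level in ("output", "node"):
                if level == "output":
                    a = per_arm["hebb"].output_r
                    b = per_arm["nonhebb"].output_r
                else:
                    a = np.nanmean(per_arm["hebb"].node_r, axis=0)
                    b = np.nanmean(per_arm["nonhebb"].node_r, axis=0)
                if np.isfinite(a - b).sum() < 2:
                    continue
                res = paired_surrogate_test(
                    a, b, n_surrogates=config.n_surrogates,
                    seed=int(surr_rng.integers(0, _SEED_MAX)),
                    m_comparisons=m,
                )
                test_rows.append((radius, kind, level, res.observed_diff,
                                  res.percentile_rank, res.p_raw,
                                  res.p_adjusted, res.n_surrogates,
                                  res.m_comparisons, res.seed))

        # prediction-error contrasts: stimulus type within each arm, and
        # the plasticity dependence within each stimulus type
        err_contrasts = []
        for arm_name in ("hebb", "nonhebb"):
            err_contrasts.append(("RefRN-RN", arm_name,
                                  (arm_name, "RefRN"), (arm_name, "RN")))
        for kind in ("RN", "RefRN"):
            err_contrasts.append(("hebb-nonhebb", kind,
                                  ("hebb", kind), ("nonhebb", kind)))
        for contrast, detail, key_a, key_b in err_contrasts:
            if key_a in runs_by_cond and key_b in runs_by_cond:
                res = paired_surrogate_test(
                    runs_by_cond[key_a], runs_by_cond[key_b],
                    n_surrogates=config.n_surrogates,
                    seed=int(surr_rng.integers(0, _SEED_MAX)),
                    m_comparisons=len(config.radii),
                )
                etest_rows.append((radius, contrast, detail,
                                   res.observed_diff, res.percentile_rank,
                                   res.p_raw, res.p_adjusted, res.seed))

    bundle = ResultsBundle(
        consistency=pd.DataFrame(
            cons_rows, columns=["radius", "arm", "plastic", "kind", "run",
                                "level", "node_id", "r"]),
        inter_trial=pd.DataFrame(
            it_rows, columns=["radius", "arm", "plastic", "kind", "mean_r",
                              "n_undefined"]),
        error_series=pd.DataFrame(
            es_rows, columns=["radius", "arm", "plastic", "kind", "k",
                              "rmse", "nrmse"]),
        error_runs=pd.DataFrame(
            er_rows, columns=["radius", "arm", "plastic", "kind", "run",
                              "rmse", "nrmse"]),
        tests=pd.DataFrame(
            test_rows, columns=["radius", "kind", "level", "observed_diff",
                                "percentile_rank", "p_raw", "p_adjusted",
                                "n_surrogates", "m_comparisons", "seed"]),
        error_tests=pd.DataFrame(
            etest_rows, columns=["radius", "contrast", "detail",
                                 "observed_diff", "percentile_rank", "p_raw",
                                 "p_adjusted", "seed"]),
        drift=pd.DataFrame(
            drift_rows, columns=["radius", "arm", "rho_before", "rho_after"]),
        failures=pd.DataFrame(
            fail_rows, columns=["radius", "arm", "failed_at_trial"]),
        provenance={
            "config": asdict(config),
            "seeds": seeds,
            "session": session_manifest(session),
        },
        artifacts=pairs if return_artifacts else None,
    )
    return bundle


# ---------------------------------------------------------------------------
# paired-instance ensemble


def _run_batch_multi(W_stack, w_in_eff, U, sigma, rng, node_ids, w_out,
                     integrator, dtype=np.float32, X0=None):
    """Evaluate B networks x R frozen runs simultaneously.

    ``X0`` optionally fixes the initial states (B, n, R); internal noise is
    always drawn independently per network.  Returns output series
    (B, R, K) and node series (B, n_nodes, R, K).
    """
    W_stack = np.ascontiguousarray(W_stack, dtype=dtype)
    B, n, _ = W_stack.shape
    R, K = U.shape
    Ut = np.ascontiguousarray(U.T, dtype=dtype)
    w_in_eff = w_in_eff.astype(dtype)[:, :, None]
    w_out = w_out.astype(dtype)
    X = (rng.uniform(-1.0, 1.0, (B, n, R)) if X0 is None
         else np.asarray(X0)).astype(dtype)
    outputs = np.empty((B, R, K), dtype=dtype)
    nodes = np.empty((B, len(node_ids), R, K), dtype=dtype)
    for k in range(K):
        pre = np.matmul(W_stack, X)
        pre += w_in_eff * Ut[k][None, None, :]
        X = np.tanh(pre)
        if sigma > 0:
            X += rng.standard_normal((B, n, R), dtype=dtype) * dtype(sigma)
        if integrator:
            raise NotImplementedError(
                "integrator mode is not supported in the batched evaluator")
        outputs[:, :, k] = np.einsum("bn,bnr->br", w_out, X)
        nodes[:, :, :, k] = X[:, node_ids, :]
    return outputs.astype(np.float64), nodes.astype(np.float64)


@dataclass
class EnsembleBundle:
    """Paired-instance ensemble results.

    ``means`` holds one row per (radius, kind, level, instance) with the
    instance's mean inter-segment correlation in each arm; ``tests`` the
    across-instance paired surrogate tests.
    """

    means: pd.DataFrame
    tests: pd.DataFrame
    drift: pd.DataFrame
    provenance: dict

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.means.to_csv(out / "ensemble_means.csv", index=False)
        self.tests.to_csv(out / "ensemble_tests.csv", index=False)
        self.drift.to_csv(out / "ensemble_drift.csv", index=False)
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, default=str))
        return out


def run_ensemble(
    config: SweepConfig,
    n_instances: int = 200,
    radii: Sequence[float] | None = None,
    n_runs_per_instance: int = 20,
) -> EnsembleBundle:
    """Repeat the whole train-and-test pipeline over many paired instances.

    Every instance is an independently drawn reservoir (fresh recurrent and
    input weights on a shared sparsity pattern) whose Hebbian and
    non-Hebbian arms share all seeds; all instances see the same stimulus
    session and test material.  The unit of analysis for the surrogate test
    is the instance: each contributes its mean inter-segment correlation
    over ``n_runs_per_instance`` frozen test runs per arm, and the paired
    Hebbian-vs-non-Hebbian contrast is tested across instances.  This is
    the distribution-level replication of the radius-specific significance
    pattern; the per-instance radius sweep addresses peak localization.
    """
    radii = list(radii if radii is not None else config.radii)
    seeds = derive_seeds(config.master_seed)
    eval_config = SweepConfig(**{**asdict(config),
                                 "n_test_runs": n_runs_per_instance,
                                 "radii": tuple(radii)})
    session, test_set, _ = build_corpus(eval_config, seeds)

    n = config.n_neurons
    rng = np.random.default_rng(seeds["init"])
    mask = rng.random((n, n)) < config.density
    rows, cols = np.nonzero(mask)
    node_ids = np.sort(
        np.random.default_rng(seeds["nodes"]).choice(
            n, size=config.node_sample_size, replace=False))

    # independent weight draws per instance on the shared pattern
    inst_values, inst_w_in, inst_w_out, inst_rho = [], [], [], []
    for _ in range(n_instances):
        vals = rng.uniform(-1.0, 1.0, rows.size)
        W = np.zeros((n, n))
        W[rows, cols] = vals
        inst_rho.append(spectral_radius(W))
        inst_values.append(vals)
        inst_w_in.append(rng.uniform(-1.0, 1.0, n))
        inst_w_out.append(rng.uniform(-1.0, 1.0, n))

    mean_rows, test_rows, drift_rows = [], [], []
    surr_rng = np.random.default_rng(seeds["surrogate"])
    m = len(radii) * len(config.comparison_kinds)
    dtype = np.float32 if config.eval_dtype == "float32" else np.float64

    for radius in radii:
        nets, flags, w_out_init = [], [], []
        for i in range(n_instances):
            W = np.zeros((n, n))
            W[rows, cols] = inst_values[i] * (radius / inst_rho[i])
            for plastic in (True, False):
                nets.append(ReservoirNetwork(
                    W=W.copy(), W_in=inst_w_in[i], mask=mask,
                    config=config.reservoir_config(radius, seeds["init"]),
                    _rows=rows, _cols=cols))
                flags.append(plastic)
                w_out_init.append(inst_w_out[i])
        readouts, errors, failures = _train_batch(
            nets, flags, session, eval_config, seeds,
            w_out_init=np.asarray(w_out_init))

        for i in range(n_instances):
            h, nh = nets[2 * i], nets[2 * i + 1]
            drift_rows.append((radius, i,
                               spectral_radius(h.W) if failures[2 * i] < 0
                               else np.nan,
                               spectral_radius(nh.W) if failures[2 * i + 1] < 0
                               else np.nan))

        for kind in config.comparison_kinds:
            U = test_set.processed_matrix(kind)
            W_stack = np.stack([net.W for net in nets])
            w_in_eff = np.stack([net.W_in for net in nets]) * config.input_gain
            w_out = np.stack([
                (readouts[b].W_out if config.optimize_readout
                 else w_out_init[b]) for b in range(len(nets))])
            eval_rng = np.random.default_rng(
                seeds["eval"][kind] + int(radius * 1000))
            X0 = None
            if config.eval_pairing in ("init", "full"):
                # the two arms of every instance start from identical states
                x0_pairs = eval_rng.uniform(
                    -1.0, 1.0, (n_instances, n, test_set.n_runs))
                X0 = np.repeat(x0_pairs, 2, axis=0)
            outputs, nodes = _run_batch_multi(
                W_stack, w_in_eff, U, config.noise_sigma, eval_rng,
                node_ids, w_out, config.update_rule == "integrator",
                dtype=dtype, X0=X0)
            per_net = {
                "output": np.array([
                    nanmean_with_count(inter_segment_correlations(outputs[b]))[0]
                    for b in range(len(nets))]),
                "node": np.array([
                    np.nanmean([
                        nanmean_with_count(
                            inter_segment_correlations(nodes[b, j]))[0]
                        for j in range(len(node_ids))])
                    for b in range(len(nets))]),
            }
            for level, vals in per_net.items():
                a = vals[0::2]   # hebbian arms
                b_ = vals[1::2]  # non-hebbian arms
                ok = np.array([failures[2 * i] < 0 and failures[2 * i + 1] < 0
                               for i in range(n_instances)])
                for i in range(n_instances):
                    mean_rows.append((radius, kind, level, i,
                                      a[i] if ok[i] else np.nan,
                                      b_[i] if ok[i] else np.nan))
                if ok.sum() >= 2:
                    res = paired_surrogate_test(
                        a[ok], b_[ok], n_surrogates=config.n_surrogates,
                        seed=int(surr_rng.integers(0, _SEED_MAX)),
                        m_comparisons=m)
                    test_rows.append((radius, kind, level, int(ok.sum()),
                                      res.observed_diff, res.percentile_rank,
                                      res.p_raw, res.p_adjusted, res.seed))

    return EnsembleBundle(
        means=pd.DataFrame(mean_rows, columns=[
            "radius", "kind", "level", "instance", "hebb_r", "nonhebb_r"]),
        tests=pd.DataFrame(test_rows, columns=[
            "radius", "kind", "level", "n_instances", "observed_diff",
            "percentile_rank", "p_raw", "p_adjusted", "seed"]),
        drift=pd.DataFrame(drift_rows, columns=[
            "radius", "instance", "rho_after_hebb", "rho_after_nonhebb"]),
        provenance={"config": asdict(config), "seeds": seeds,
                    "n_instances": n_instances,
                    "n_runs_per_instance": n_runs_per_instance,
                    "radii": radii},
    )


def selectivity_curve(consistency: pd.DataFrame, kind: str = "RefRN",
                      level: str = "output") -> pd.Series:
    """Mean Hebbian-minus-non-Hebbian inter-segment r per radius."""
    sub = consistency[(consistency["kind"] == kind)
                      & (consistency["level"] == level)]
    if level == "node":
        # average the sampled nodes within each run first
        sub = (sub.groupby(["radius", "arm", "run"], as_index=False)["r"]
               .mean())
    means = sub.groupby(["radius", "arm"])["r"].mean().unstack("arm")
    return (means["hebb"] - means["nonhebb"]).sort_index()


def peak_radius(curve: pd.Series) -> float:
    """Radius at which the selectivity curve is maximal."""
    return float(curve.idxmax())


def rmse_radius_trend(error_series: pd.DataFrame) -> float:
    """Spearman correlation of mean RMSE with spectral radius."""
    means = error_series.groupby("radius")["rmse"].mean()
    rho, _ = sp_stats.spearmanr(means.index.values, means.values)
    return float(rho)
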