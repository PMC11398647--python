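"""Linear readout for one-step-ahead prediction, trained by minibatch SGD.

The output neuron computes y(k) = W_out x(k).  The task is to predict the
next input sample, d(k) = u(k+1); each training trial forms one minibatch
(all state/target pairs of that trial) and contributes a configurable
number of gradient-descent steps on the mean squared error

    E_n = (1/K_n) sum_k 1/2 (d(k) - y(k))^2 .

The optimizer has an off switch: with ``optimize=False`` the readout is
left untouched, which isolates the reservoir's own contribution to
response consistency from any supervised fitting of the output layer.
W_out is initialized U[-1, 1] like the other weight matrices (a zeros
initializer is also provided).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Readout",
    "TrainingConfig",
    "PredictionBatch",
    "compute_output",
    "one_step_targets",
    "minibatch_error",
    "gradient_step",
    "train_readout_online",
]


@dataclass
class Readout:
    """The 1 x N output weight vector."""

    W_out: np.ndarray

    @classmethod
    def zeros(cls, n_neurons: int) -> "Readout":
        return cls(W_out=np.zeros(n_neurons))

    @classmethod
    def random(cls, n_neurons: int, seed: int) -> "Readout":
        """U[-1, 1] initialization, the same convention as the other weights.

        A random initial projection keeps the output series sensitive to the
        whole reservoir (the brief minibatch training only perturbs it), so
        output-level consistency tracks reservoir-level consistency instead
        of collapsing onto the stimulus-locked subspace the optimizer favors.
        """
        return cls(W_out=np.random.default_rng(seed).uniform(-1.0, 1.0,
                                                             n_neurons))

    def copy(self) -> "Readout":
        return Readout(self.W_out.copy())


@dataclass(frozen=True)
class TrainingConfig:
    eta: float = 0.01
    steps_per_minibatch: int = 1
    optimize: bool = True

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("learning rate eta must be positive")
        if self.steps_per_minibatch < 0:
            raise ValueError("steps_per_minibatch must be non-negative")


@dataclass
class PredictionBatch:
    """One trial's minibatch: states X (K_n x N) and targets d (K_n)."""

    X: np.ndarray
    d: np.ndarray
    trial_index: int = 0

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.d.shape[0]:
            raise ValueError("states and targets disagree in length")


def compute_output(readout: Readout, x: np.ndarray) -> float | np.ndarray:
    """y = W_out . x; accepts a single state (N,) or a state matrix (K, N)."""
    x = np.asarray(x)
    if x.shape[-1] != readout.W_out.shape[0]:
        raise ValueError(
            f"state dimension {x.shape[-1]} does not match readout "
            f"{readout.W_out.shape[0]}"
        )
    return x @ readout.W_out


def one_step_targets(stimulus) -> np.ndarray:
    """Targets d(k) = u(k+1): the input shifted left by one sample.

    The state reached after consuming the final sample has no target, so a
    K-sample stimulus yields K-1 targets.
    """
    if hasattr(stimulus, "processed"):
        u = stimulus.processed.samples
    elif hasattr(stimulus, "samples"):
        u = stimulus.samples
    else:
        u = np.asarray(stimulus, dtype=np.float64)
    return u[1:]


def make_batch(trial_record, stimulus, trial_index: int = 0) -> PredictionBatch:
    """Pair a trial's states with one-step-ahead targets (last state dropped)."""
    d = one_step_targets(stimulus)
    return PredictionBatch(X=trial_record.states[: d.shape[0]], d=d,
                           trial_index=trial_index)


def minibatch_error(readout: Readout, batch: PredictionBatch) -> float:
    """E_n = (1/K_n) sum_k 1/2 (d(k) - y(k))^2."""
    if batch.d.size == 0:
        raise ValueError("empty minibatch")
    resid = batch.d - compute_output(readout, batch.X)
    return float(0.5 * np.mean(resid**2))


def gradient_step(readout: Readout, batch: PredictionBatch,
                  eta: float) -> Readout:
    """One descent step W_out <- W_out - eta * grad E_n (returns a new Readout).

    grad E_n = -(1/K_n) sum_k (d(k) - y(k)) x(k).
    """
    resid = batch.d - compute_output(readout, batch.X)
    grad = -(batch.X.T @ resid) / batch.d.shape[0]
    return Readout(readout.W_out - eta * grad)


def train_readout_online(readout: Readout, trial_record, stimulus,
                         config: TrainingConfig) -> Readout:
    """Apply the per-trial minibatch updates; a no-op when optimize=False."""
    if not config.optimize or config.steps_per_minibatch == 0:
        return readout
    batch = make_batch(trial_record, stimulus)
    for _ in range(config.steps_per_minibatch):
        readout = gradient_step(readout, batch, config.eta)
    return readout
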