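"""Plastic echo-state reservoir: initialization, dynamics, and Oja's rule.

The reservoir is a sparse random recurrent network of ``N`` tanh units.  Its
recurrent weight matrix ``W`` is drawn U[-1, 1] on a Bernoulli(density)
support mask and rescaled so its spectral radius (largest |eigenvalue|)
equals a prescribed value, the control parameter that moves the network
between order (small radius, echo state property) and chaos (large radius).

State update (``update_rule="standard"``)::

    x(k+1) = tanh(W x(k) + W_in u(k+1)) + eps,   eps ~ N(0, sigma^2 I)

An ``"integrator"`` variant that accumulates the increment onto the previous
state (x(k+1) = x(k) + tanh(...) + eps) is provided for comparison; it is
dynamically unstable for generic W and is not used by the experiments.

During training, Oja's Hebbian rule updates every stored (nonzero) weight
after each state step::

    W_ij <- W_ij + alpha * x_i * (x_j - x_i * W_ij)

The multiplicative forgetting term bounds weight growth; the sparsity
pattern is structural and never changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from numba import njit
from scipy import sparse

__all__ = [
    "ReservoirConfig",
    "PlasticityConfig",
    "ReservoirNetwork",
    "ReservoirState",
    "TrialRecord",
    "init_reservoir",
    "step",
    "oja_update",
    "run_trial",
    "spectral_radius",
    "save_network",
    "load_network",
]

UPDATE_RULES = ("standard", "integrator")


@dataclass(frozen=True)
class ReservoirConfig:
    """Reservoir hyperparameters.

    noise_sigma is the standard deviation of the per-step internal Gaussian
    noise of every unit; input_gain scales the stimulus at presentation.
    """

    n_neurons: int = 500
    density: float = 0.1
    spectral_radius: float = 1.0
    noise_sigma: float = 1e-3
    input_gain: float = 1.0
    init_seed: int = 0
    update_rule: str = "standard"

    def __post_init__(self) -> None:
        if not (0.0 < self.density <= 1.0):
            raise ValueError(f"density must be in (0, 1], got {self.density}")
        if self.spectral_radius <= 0:
            raise ValueError("spectral_radius must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.n_neurons < 1:
            raise ValueError("need at least one neuron")
        if self.update_rule not in UPDATE_RULES:
            raise ValueError(
                f"update_rule must be one of {UPDATE_RULES}, got {self.update_rule!r}"
            )


@dataclass(frozen=True)
class PlasticityConfig:
    """Oja-rule settings: enabled flag and learning rate alpha."""

    enabled: bool = True
    alpha: float = 1e-7

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


#: A reservoir state is simply the length-N activation vector.
ReservoirState = np.ndarray


class InitializationError(RuntimeError):
    """Raised when no valid random reservoir could be drawn."""


class OverflowDiagnostic(FloatingPointError):
    """Non-finite reservoir state, with the radius and step where it occurred."""

    def __init__(self, rho: float, k: int):
        super().__init__(
            f"non-finite reservoir state at step k={k} (spectral radius {rho})"
        )
        self.rho = rho
        self.k = k


@dataclass
class ReservoirNetwork:
    """A reservoir instance: dense W, its structural mask, and fixed W_in."""

    W: np.ndarray
    W_in: np.ndarray
    mask: np.ndarray
    config: ReservoirConfig
    # flat indices of the nonzero support, cached for fast plasticity updates
    _rows: np.ndarray = field(repr=False, default=None)
    _cols: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self._rows is None:
            self._rows, self._cols = np.nonzero(self.mask)

    @property
    def n_neurons(self) -> int:
        return self.W.shape[0]

    def spectral_radius(self) -> float:
        return spectral_radius(self.W)

    def copy(self) -> "ReservoirNetwork":
        return ReservoirNetwork(
            W=self.W.copy(),
            W_in=self.W_in,
            mask=self.mask,
            config=self.config,
            _rows=self._rows,
            _cols=self._cols,
        )

    def with_config(self, **changes) -> "ReservoirNetwork":
        return ReservoirNetwork(
            W=self.W, W_in=self.W_in, mask=self.mask,
            config=replace(self.config, **changes),
            _rows=self._rows, _cols=self._cols,
        )


def spectral_radius(W: np.ndarray) -> float:
    """Largest absolute eigenvalue, by dense eigendecomposition.

    Exact (to LAPACK accuracy) and cheap for the network sizes used here
    (N <= ~1000); preferred over iterative estimates.
    """
    return float(np.max(np.abs(np.linalg.eigvals(np.asarray(W, dtype=np.float64)))))


def init_reservoir(config: ReservoirConfig, max_retries: int = 5) -> ReservoirNetwork:
    """Draw a sparse random reservoir and rescale to the desired radius.

    Nonzero recurrent weights are U[-1, 1] on a seeded Bernoulli(density)
    mask; W is then multiplied by rho_desired / rho(W_random) so its
    spectral radius matches the configuration exactly.  Input weights are
    U[-1, 1].  The rare all-zero / zero-radius draw is retried.
    """
    rng = np.random.default_rng(config.init_seed)
    n = config.n_neurons
    for _ in range(max_retries):
        mask = rng.random((n, n)) < config.density
        W = np.zeros((n, n))
        W[mask] = rng.uniform(-1.0, 1.0, int(mask.sum()))
        rho = spectral_radius(W)
        if rho > 0:
            W *= config.spectral_radius / rho
            W_in = rng.uniform(-1.0, 1.0, n)
            return ReservoirNetwork(W=W, W_in=W_in, mask=mask, config=config)
    raise InitializationError(
        f"could not draw a reservoir with nonzero spectral radius "
        f"(n={n}, density={config.density}, seed={config.init_seed})"
    )


def step(
    state: ReservoirState,
    net: ReservoirNetwork,
    u_next: float,
    noise_draw: np.ndarray | float = 0.0,
) -> ReservoirState:
    """Advance the reservoir one time step under input sample ``u_next``.

    ``noise_draw`` is the realized internal-noise vector eps (pass 0 for
    deterministic dynamics).  Raises on numerical overflow, reporting the
    configured radius.
    """
    pre = net.W @ state + net.W_in * (net.config.input_gain * u_next)
    inc = np.tanh(pre) + noise_draw
    new = state + inc if net.config.update_rule == "integrator" else inc
    if not np.all(np.isfinite(new)):
        raise OverflowDiagnostic(net.config.spectral_radius, -1)
    return new


def oja_update(net: ReservoirNetwork, x: ReservoirState,
               alpha: float) -> ReservoirNetwork:
    """Apply one Oja step, W_ij += alpha*x_i*(x_j - x_i*W_ij), in place.

    Only the structural nonzeros are touched; entries outside the mask stay
    exactly zero.
    """
    r, c = net._rows, net._cols
    w = net.W[r, c]
    xi = x[r]
    net.W[r, c] = w + alpha * xi * (x[c] - xi * w)
    return net


@dataclass
class TrialRecord:
    """Full state trajectory of one stimulus presentation.

    ``states[k]`` is x after consuming input sample k (k = 0..K-1);
    ``outputs`` is filled in by the readout layer.
    """

    stimulus_ref: str
    init_seed: int
    states: np.ndarray  # (K, N)
    plastic: bool
    outputs: np.ndarray | None = None


@njit(cache=True)
def _trial_kernel(data, indices, indptr, w_in_eff, u, x0, noise,
                  alpha, integrator):  # pragma: no cover - exercised via wrapper
    """CSR-sparse trial loop; mutates ``data`` in place when alpha > 0."""
    n = x0.shape[0]
    K = u.shape[0]
    states = np.empty((K, n))
    x = x0.copy()
    for k in range(K):
        for i in range(n):
            s = 0.0
            for jj in range(indptr[i], indptr[i + 1]):
                s += data[jj] * x[indices[jj]]
            states[k, i] = np.tanh(s + w_in_eff[i] * u[k]) + noise[k, i]
        if integrator:
            for i in range(n):
                states[k, i] += x[i]
        x = states[k]
        if alpha > 0.0:
            for i in range(n):
                xi = x[i]
                for jj in range(indptr[i], indptr[i + 1]):
                    w = data[jj]
                    data[jj] = w + alpha * xi * (x[indices[jj]] - xi * w)
    return states


def initial_state(n_neurons: int, init_seed: int) -> ReservoirState:
    """Per-trial initial condition: x(0) ~ U(-1, 1)^N, seeded."""
    return np.random.default_rng(init_seed).uniform(-1.0, 1.0, n_neurons)


def _trial_noise(K: int, n: int, sigma: float, noise_seed: int) -> np.ndarray:
    if sigma == 0.0:
        return np.zeros((K, n))
    return np.random.default_rng(noise_seed).standard_normal((K, n)) * sigma


def run_trial(
    net: ReservoirNetwork,
    stimulus,
    init_seed: int,
    plasticity: PlasticityConfig | None = None,
    noise_seed: int = 0,
    engine: str = "compiled",
) -> tuple[TrialRecord, ReservoirNetwork]:
    """Present one processed stimulus to the reservoir.

    The initial state is drawn U(-1,1)^N from ``init_seed``; the internal
    noise trajectory from ``noise_seed``.  When plasticity is enabled the
    Oja update is applied after every state step using the just-computed
    activations, and the returned network carries the updated weights
    (the input network's W is modified in place).

    ``engine="reference"`` runs the plain step/oja_update composition in
    Python; ``"compiled"`` runs the numba kernel.  Both produce the same
    trajectories and are cross-checked in the test suite.
    """
    if hasattr(stimulus, "processed"):
        u = stimulus.processed.samples
    elif hasattr(stimulus, "samples"):
        u = stimulus.samples
    else:
        u = np.asarray(stimulus, dtype=np.float64)
    plasticity = plasticity or PlasticityConfig(enabled=False, alpha=0.0)
    alpha = plasticity.alpha if plasticity.enabled else 0.0
    cfg = net.config
    K, n = u.shape[0], net.n_neurons
    x0 = initial_state(n, init_seed)
    noise = _trial_noise(K, n, cfg.noise_sigma, noise_seed)

    if engine == "compiled":
        # CSR built on the structural mask itself, so explicit zeros survive;
        # np.nonzero order is row-major, matching CSR data order exactly.
        Ws = sparse.csr_matrix(
            (net.W[net._rows, net._cols].copy(), (net._rows, net._cols)),
            shape=net.W.shape,
        )
        states = _trial_kernel(
            Ws.data, Ws.indices, Ws.indptr,
            net.W_in * cfg.input_gain, u, x0, noise,
            alpha, cfg.update_rule == "integrator",
        )
        if alpha > 0.0:
            net.W[net._rows, net._cols] = Ws.data
    elif engine == "reference":
        states = np.empty((K, n))
        x = x0
        for k in range(K):
            x = step(x, net, u[k], noise[k])
            states[k] = x
            if alpha > 0.0:
                oja_update(net, x, alpha)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    if not np.all(np.isfinite(states)):
        bad = int(np.argwhere(~np.isfinite(states))[0, 0])
        raise OverflowDiagnostic(cfg.spectral_radius, bad)
    rec = TrialRecord(
        stimulus_ref=f"{getattr(stimulus, 'kind', 'series')}"
                     f":{getattr(stimulus, 'realization_seed', -1)}",
        init_seed=int(init_seed),
        states=states,
        plastic=alpha > 0.0,
    )
    return rec, net


# ---------------------------------------------------------------------------
# snapshot serialization (bit-exact round trip)


def save_network(net: ReservoirNetwork, path: str | Path) -> None:
    """Save W / W_in / mask to ``<path>.npz`` with a JSON config sidecar."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"),
                        W=net.W, W_in=net.W_in, mask=net.mask)
    cfg = {k: getattr(net.config, k) for k in (
        "n_neurons", "density", "spectral_radius", "noise_sigma",
        "input_gain", "init_seed", "update_rule")}
    path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))


def load_network(path: str | Path) -> ReservoirNetwork:
    path = Path(path)
    arrs = np.load(path.with_suffix(".npz"))
    cfg = json.loads(path.with_suffix(".json").read_text())
    return ReservoirNetwork(W=arrs["W"], W_in=arrs["W_in"],
                            mask=arrs["mask"], config=ReservoirConfig(**cfg))
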