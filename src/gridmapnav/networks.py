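"""Multilayer-perceptron navigators trained online on gradient cues.

Two implementations of the same learning problem — map the two sensed field
values at a location to the compass direction of the goal:

* **Implementation 1** (regression): a single sigmoid output encoding the
  goal direction in turns (degrees/360) relative to a per-network random
  baseline direction; squared circular-error loss; plain gradient descent
  with Nesterov momentum (lr 0.001, momentum 0.9).
* **Implementation 2** (classification): 20 sigmoid outputs, one per
  equal circular sector in a per-network randomly rotated frame;
  summed binary cross-entropy loss; Adam with standard defaults.

Both use hidden layers (10, 100, 200, 500, 200, 100) with ReLU, batch size
one, and see each training location at most once (a single epoch).  The
forward/backward passes and both optimizers are implemented here directly
on numpy arrays; the loss gradients are finite-difference-checked in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .angles import TWO_PI

HIDDEN_SIZES = (10, 100, 200, 500, 200, 100)

_ADAM_BETA1 = 0.9
_ADAM_BETA2 = 0.999
_ADAM_EPS = 1e-7
_BCE_CLAMP = 1e-7


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and optimizer hyperparameters of one implementation."""

    implementation: int = 1
    hidden_sizes: tuple = HIDDEN_SIZES
    learning_rate: float = 0.001
    momentum: float = 0.9
    n_sectors: int = 20
    wrap_loss: bool = True  # impl 1: wrap the squared error across the 0/1 seam
    decoder: str = "argmax"  # impl 2: "argmax" or "expectation"

    def __post_init__(self):
        if self.implementation not in (1, 2):
            raise ValueError("implementation must be 1 or 2")
        if self.decoder not in ("argmax", "expectation"):
            raise ValueError(f"unknown decoder {self.decoder!r}")

    @property
    def output_dim(self):
        return 1 if self.implementation == 1 else self.n_sectors

    @property
    def layer_sizes(self):
        return (2, *self.hidden_sizes, self.output_dim)


@dataclass
class NetworkState:
    """Weights, optimizer accumulators and the per-replicate frame rotation."""

    config: NetworkConfig
    weights: list  # W_l of shape (fan_in, fan_out)
    biases: list
    opt_state: dict
    reference_offset: float  # direction decoded from raw output 0 / sector frame rotation
    replicate_id: int
    rng_seed: int


def draw_reference_offset(rng):
    """The per-network random baseline direction, uniform on [0, 2*pi)."""
    return float(rng.uniform(0.0, TWO_PI))


def init_network(config, seed, replicate_id=0):
    """Glorot-uniform initialized network; fully reproducible from ``seed``."""
    if seed < 0:
        raise ValueError("seed must be non-negative")
    rng = np.random.default_rng(seed)
    offset = draw_reference_offset(rng)
    weights, biases = [], []
    sizes = config.layer_sizes
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    if config.implementation == 1:
        opt_state = {
            "vW": [np.zeros_like(w) for w in weights],
            "vb": [np.zeros_like(b) for b in biases],
        }
    else:
        opt_state = {
            "mW": [np.zeros_like(w) for w in weights],
            "vW": [np.zeros_like(w) for w in weights],
            "mb": [np.zeros_like(b) for b in biases],
            "vb": [np.zeros_like(b) for b in biases],
            "t": 0,
        }
    return NetworkState(
        config=config,
        weights=weights,
        biases=biases,
        opt_state=opt_state,
        reference_offset=offset,
        replicate_id=replicate_id,
        rng_seed=seed,
    )


def _forward(state, X):
    """Forward pass; returns (activations per layer, output)."""
    acts = [np.asarray(X, dtype=float)]
    h = acts[0]
    n_layers = len(state.weights)
    for i, (w, b) in enumerate(zip(state.weights, state.biases)):
        z = h @ w + b
        h = np.maximum(z, 0.0) if i < n_layers - 1 else 1.0 / (1.0 + np.exp(-z))
        acts.append(h)
    return acts, h


def raw_output(state, X):
    """Network output(s) before decoding: shape (..., output_dim)."""
    return _forward(state, np.atleast_2d(np.asarray(X, dtype=float)))[1]


def encode_target(true_direction, state):
    """Encode a goal direction as the training target of the implementation.

    Impl 1: the direction in turns relative to the network's baseline,
    in [0, 1).  Impl 2: one-hot over the sector (in the rotated frame)
    that encompasses the direction.
    """
    cfg = state.config
    rel = np.mod(true_direction - state.reference_offset, TWO_PI)
    if cfg.implementation == 1:
        return np.array([rel / TWO_PI])
    sector = int(rel / (TWO_PI / cfg.n_sectors)) % cfg.n_sectors
    target = np.zeros(cfg.n_sectors)
    target[sector] = 1.0
    return target


def loss_value(state, inputs, target):
    """Loss on a single datapoint, as minimised by ``train_step``."""
    out = raw_output(state, inputs)[0]
    return _loss_and_grad(state.config, out, np.asarray(target, dtype=float))[0]


def _loss_and_grad(cfg, out, target):
    """(loss, dL/d_preactivation) at the output layer for one datapoint."""
    if cfg.implementation == 1:
        d = float(out[0] - target[0])
        if cfg.wrap_loss:
            d = d - round(d)  # wrap to [-0.5, 0.5]: shortest way round the circle
        loss = d * d
        # chain through the chosen wrap branch, then the sigmoid
        dpre = 2.0 * d * out * (1.0 - out)
        return loss, dpre
    p = np.clip(out, _BCE_CLAMP, 1.0 - _BCE_CLAMP)
    loss = float(-np.sum(target * np.log(p) + (1.0 - target) * np.log1p(-p)))
    return loss, out - target


def loss_gradients(state, inputs, target):
    """Loss and backpropagated parameter gradients on one datapoint.

    Returns (loss, grads_w, grads_b) without touching the network; used by
    ``train_step`` and finite-difference-checked in the test suite.
    """
    x = np.asarray(inputs, dtype=float).reshape(1, -1)
    target = np.asarray(target, dtype=float)
    acts, out = _forward(state, x)
    loss, dpre = _loss_and_grad(state.config, out[0], target)
    delta = np.atleast_2d(dpre)
    grads_w, grads_b = [], []
    for i in range(len(state.weights) - 1, -1, -1):
        grads_w.append(acts[i].T @ delta)
        grads_b.append(delta[0].copy())
        if i > 0:
            delta = (delta @ state.weights[i].T) * (acts[i] > 0.0)
    grads_w.reverse()
    grads_b.reverse()
    return loss, grads_w, grads_b


def train_step(state, inputs, target):
    """One optimizer update on a single (inputs, target) datapoint, in place.

    Returns the pre-update loss.  Raises on a non-finite loss so a broken
    replicate aborts with a diagnostic rather than training on garbage.
    """
    cfg = state.config
    loss, grads_w, grads_b = loss_gradients(state, inputs, target)
    if not np.isfinite(loss):
        raise FloatingPointError(
            f"non-finite loss in replicate {state.replicate_id} (seed {state.rng_seed})"
        )
    if cfg.implementation == 1:
        _sgd_nesterov(state, grads_w, grads_b)
    else:
        _adam(state, grads_w, grads_b)
    return loss


def _sgd_nesterov(state, grads_w, grads_b):
    lr, mom = state.config.learning_rate, state.config.momentum
    opt = state.opt_state
    for w, b, gw, gb, vw, vb in zip(
        state.weights, state.biases, grads_w, grads_b, opt["vW"], opt["vb"]
    ):
        vw *= mom
        vw -= lr * gw
        w += mom * vw - lr * gw
        vb *= mom
        vb -= lr * gb
        b += mom * vb - lr * gb


def _adam(state, grads_w, grads_b):
    lr = state.config.learning_rate
    opt = state.opt_state
    opt["t"] += 1
    t = opt["t"]
    c1 = 1.0 - _ADAM_BETA1**t
    c2 = 1.0 - _ADAM_BETA2**t
    for params, grads, mkey, vkey in (
        (state.weights, grads_w, "mW", "vW"),
        (state.biases, grads_b, "mb", "vb"),
    ):
        for p, g, m, v in zip(params, grads, opt[mkey], opt[vkey]):
            m *= _ADAM_BETA1
            m += (1.0 - _ADAM_BETA1) * g
            v *= _ADAM_BETA2
            v += (1.0 - _ADAM_BETA2) * g * g
            p -= lr * (m / c1) / (np.sqrt(v / c2) + _ADAM_EPS)


def predict_direction(state, inputs):
    """Decode predicted compass direction(s) from the network output.

    Impl 1: raw output * 2*pi + baseline, wrapped to [0, 2*pi).  Impl 2:
    the centre angle of the winning sector in the rotated frame (argmax,
    ties to the lowest index), or a circular expectation over sectors if
    the config selects the expectation decoder.
    """
    cfg = state.config
    x = np.atleast_2d(np.asarray(inputs, dtype=float))
    out = _forward(state, x)[1]
    if cfg.implementation == 1:
        ang = np.mod(out[:, 0] * TWO_PI + state.reference_offset, TWO_PI)
    else:
        width = TWO_PI / cfg.n_sectors
        if cfg.decoder == "argmax":
            centers = (np.argmax(out, axis=1) + 0.5) * width
        else:
            sector_centers = (np.arange(cfg.n_sectors) + 0.5) * width
            s = out @ np.sin(sector_centers)
            c = out @ np.cos(sector_centers)
            centers = np.arctan2(s, c)
        ang = np.mod(centers + state.reference_offset, TWO_PI)
    if np.asarray(inputs).ndim == 1:
        return float(ang[0])
    return ang


def checkpoint_metadata(state):
    """JSON-serializable description of a network snapshot."""
    return {
        "implementation": state.config.implementation,
        "hidden_sizes": list(state.config.hidden_sizes),
        "replicate_id": state.replicate_id,
        "rng_seed": state.rng_seed,
        "reference_offset": state.reference_offset,
        "n_parameters": int(
            sum(w.size for w in state.weights) + sum(b.size for b in state.biases)
        ),
    }


def clone_config(config, **changes):
    """A modified copy of a NetworkConfig (dataclasses.replace wrapper)."""
    return replace(config, **changes)


def save_checkpoint(state, path):
    """Write a network snapshot (weights + JSON-ish metadata) to an .npz file.

    A private interchange format for resuming/inspecting runs, not meant to
    be portable to other tools.  Optimizer state is not saved: a restored
    network predicts identically but does not resume mid-momentum.
    """
    import json

    arrays = {f"W{l}": w for l, w in enumerate(state.weights)}
    arrays.update({f"b{l}": b for l, b in enumerate(state.biases)})
    arrays["meta"] = np.frombuffer(
        json.dumps(checkpoint_metadata(state)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Restore a network saved by :func:`save_checkpoint` (fresh optimizer)."""
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        config = NetworkConfig(
            implementation=meta["implementation"], hidden_sizes=tuple(meta["hidden_sizes"])
        )
        state = init_network(config, meta["rng_seed"], replicate_id=meta["replicate_id"])
        state.reference_offset = meta["reference_offset"]
        for l in range(len(state.weights)):
            state.weights[l] = data[f"W{l}"]
            state.biases[l] = data[f"b{l}"]
    return state
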