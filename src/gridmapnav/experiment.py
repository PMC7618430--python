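"""Replicate training runs, checkpointed evaluation and model scoring.

A replicate is one freshly initialized network trained online (batch size
one, single epoch) on a random order of the polar training locations, and
frozen for evaluation on the full test grid after 0, 100, 250, 500, 1000,
2000, 4000, 8000 and 14000 datapoints.  Evaluation is a pure forward pass
and never perturbs training state.

Two equivalent training paths are provided: :func:`run_replicate` trains a
single network through :mod:`gridmapnav.networks` (the reference path), and
:func:`run_population` trains all replicates in lockstep on stacked float32
weight tensors — the same initialization, update rule and data order per
replicate, executed as batched array operations.  The scoring layer turns
per-checkpoint headings into the long-format fit table consumed by the
mixed-effects comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .angles import TWO_PI, abs_diff, circular_mean_signed, wrap_signed
from .environments import goal_direction, test_locations
from .nav_models import all_model_specs, prediction_map
from .networks import _ADAM_BETA1, _ADAM_BETA2, _ADAM_EPS, init_network, predict_direction, train_step
from . import networks

logger = logging.getLogger(__name__)

CHECKPOINTS = (0, 100, 250, 500, 1000, 2000, 4000, 8000, 14000)


@dataclass(frozen=True)
class TrainingSchedule:
    """Checkpoint counts and the training-set truncation."""

    checkpoints: tuple = CHECKPOINTS
    total_datapoints: int = 14000

    def __post_init__(self):
        cps = tuple(self.checkpoints)
        if list(cps) != sorted(set(cps)):
            raise ValueError("checkpoints must be strictly increasing")
        if cps and cps[-1] > self.total_datapoints:
            raise ValueError("last checkpoint exceeds total_datapoints")


def replicate_seeds(master_seed, n):
    """Per-replicate (init_seed, order_seed) pairs from one master seed.

    Counter-based spawning keeps replicates statistically independent and
    every derived seed attributable to the master seed in the manifest.
    """
    ss = np.random.SeedSequence(master_seed)
    pairs = []
    for child in ss.spawn(n):
        s = child.generate_state(2, dtype=np.uint64)
        pairs.append((int(s[0] % (2**31)), int(s[1] % (2**31))))
    return pairs


def training_order(order_seed, n_locations, total_datapoints):
    """Uniform shuffle of all training locations, truncated to the budget.

    Sampling without replacement: each location is seen at most once.
    """
    order = np.random.default_rng(order_seed).permutation(n_locations)
    return order[:total_datapoints]


def run_replicate(env, config, schedule, init_seed, order_seed, locset=None, replicate_id=0):
    """Train one network; return (n_checkpoints, n_test) predicted headings."""
    locset = locset if locset is not None else test_locations()
    state = init_network(config, init_seed, replicate_id=replicate_id)
    order = training_order(order_seed, len(locset.training), schedule.total_datapoints)
    train_inputs = env.field_values(locset.training)
    train_dirs = goal_direction(locset.training)
    test_inputs = env.field_values(locset.test)

    headings = np.empty((len(schedule.checkpoints), len(locset.test)))
    ckpt_iter = iter(enumerate(schedule.checkpoints))
    next_ckpt = next(ckpt_iter, None)
    for step in range(schedule.total_datapoints + 1):
        if next_ckpt is not None and step == next_ckpt[1]:
            headings[next_ckpt[0]] = predict_direction(state, test_inputs)
            next_ckpt = next(ckpt_iter, None)
        if step == schedule.total_datapoints:
            break
        i = order[step]
        target = networks.encode_target(train_dirs[i], state)
        train_step(state, train_inputs[i], target)
    return headings


# ---------------------------------------------------------------------------
# lockstep population training (stacked replicate weights, float32)
# ---------------------------------------------------------------------------


class _PopulationNets:
    """R identically architected networks as stacked (R, fan_in, fan_out) tensors."""

    def __init__(self, config, init_seeds):
        self.config = config
        self.R = len(init_seeds)
        states = [init_network(config, s, replicate_id=i) for i, s in enumerate(init_seeds)]
        self.offsets = np.array([st.reference_offset for st in states])
        self.W = [
            np.stack([st.weights[l] for st in states]).astype(np.float32)
            for l in range(len(states[0].weights))
        ]
        self.B = [
            np.stack([st.biases[l] for st in states]).astype(np.float32)
            for l in range(len(states[0].biases))
        ]
        if config.implementation == 1:
            self.vW = [np.zeros_like(w) for w in self.W]
            self.vB = [np.zeros_like(b) for b in self.B]
        else:
            self.mW = [np.zeros_like(w) for w in self.W]
            self.vW = [np.zeros_like(w) for w in self.W]
            self.mB = [np.zeros_like(b) for b in self.B]
            self.vB = [np.zeros_like(b) for b in self.B]
            self.t = 0

    def forward(self, x):
        """x: (R, m, 2) -> output (R, m, out_dim)."""
        h = x
        last = len(self.W) - 1
        for i, (w, b) in enumerate(zip(self.W, self.B)):
            z = h @ w + b[:, None, :]
            if i < last:
                h = np.maximum(z, 0.0, out=z)
            else:
                np.negative(z, out=z)
                np.exp(z, out=z)
                z += 1.0
                h = np.reciprocal(z, out=z)
        return h

    def step(self, x, target):
        """One lockstep online update; x (R, 2), target (R, out_dim)."""
        cfg = self.config
        acts = [x[:, None, :].astype(np.float32)]
        h = acts[0]
        last = len(self.W) - 1
        for i, (w, b) in enumerate(zip(self.W, self.B)):
            z = h @ w + b[:, None, :]
            h = np.maximum(z, 0.0) if i < last else 1.0 / (1.0 + np.exp(-z))
            acts.append(h)
        out = h[:, 0, :]
        if cfg.implementation == 1:
            d = out - target
            if cfg.wrap_loss:
                d = d - np.round(d)
            dpre = (2.0 * d * out * (1.0 - out))[:, None, :]
        else:
            dpre = (out - target)[:, None, :]

        if cfg.implementation == 2:
            self.t += 1
            c1 = np.float32(1.0 - _ADAM_BETA1**self.t)
            c2 = np.float32(1.0 - _ADAM_BETA2**self.t)
        lr = np.float32(cfg.learning_rate)
        mom = np.float32(cfg.momentum)
        for i in range(last, -1, -1):
            gw = acts[i].transpose(0, 2, 1) @ dpre  # (R, fan_in, fan_out)
            gb = dpre[:, 0, :].copy()
            if i > 0:
                dpre = (dpre @ self.W[i].transpose(0, 2, 1)) * (acts[i] > 0.0)
            if cfg.implementation == 1:
                self._sgd(self.W[i], self.vW[i], gw, lr, mom)
                self._sgd(self.B[i], self.vB[i], gb, lr, mom)
            else:
                self._adam(self.W[i], self.mW[i], self.vW[i], gw, lr, c1, c2)
                self._adam(self.B[i], self.mB[i], self.vB[i], gb, lr, c1, c2)

    @staticmethod
    def _sgd(p, v, g, lr, mom):
        # keras-style Nesterov: v <- mom*v - lr*g ; p <- p + mom*v - lr*g
        g *= lr
        v *= mom
        v -= g
        p += mom * v
        p -= g

    @staticmethod
    def _adam(p, m, v, g, lr, c1, c2):
        m *= np.float32(_ADAM_BETA1)
        m += np.float32(1.0 - _ADAM_BETA1) * g
        v *= np.float32(_ADAM_BETA2)
        g *= g
        v += np.float32(1.0 - _ADAM_BETA2) * g
        p -= lr * (m / c1) / (np.sqrt(v / c2) + np.float32(_ADAM_EPS))

    def decode(self, out):
        """(R, m, out_dim) raw outputs -> (R, m) compass headings."""
        cfg = self.config
        if cfg.implementation == 1:
            ang = out[:, :, 0].astype(float) * TWO_PI + self.offsets[:, None]
        else:
            width = TWO_PI / cfg.n_sectors
            if cfg.decoder == "argmax":
                centers = (np.argmax(out, axis=2) + 0.5) * width
            else:
                sector_centers = (np.arange(cfg.n_sectors) + 0.5) * width
                centers = np.arctan2(out @ np.sin(sector_centers), out @ np.cos(sector_centers))
            ang = centers + self.offsets[:, None]
        return np.mod(ang, TWO_PI)

    def predict(self, test_inputs, chunk=2048):
        """Headings of every replicate at every test input, chunked for memory."""
        m = len(test_inputs)
        out_dim = self.config.output_dim
        outs = np.empty((self.R, m, out_dim), dtype=np.float32)
        x = np.broadcast_to(
            test_inputs.astype(np.float32)[None], (self.R, m, test_inputs.shape[1])
        )
        for lo in range(0, m, chunk):
            hi = min(lo + chunk, m)
            outs[:, lo:hi] = self.forward(np.ascontiguousarray(x[:, lo:hi]))
        if not np.all(np.isfinite(outs)):
            bad = sorted(set(np.where(~np.isfinite(outs))[0].tolist()))
            raise FloatingPointError(f"non-finite outputs in replicates {bad}")
        return self.decode(outs)


def _encode_targets_population(config, offsets, dirs):
    """Per-replicate encoded targets for a (R, n_steps) array of true directions."""
    rel = np.mod(dirs - offsets[:, None], TWO_PI)
    if config.implementation == 1:
        return (rel / TWO_PI)[..., None].astype(np.float32)
    sectors = (rel / (TWO_PI / config.n_sectors)).astype(int) % config.n_sectors
    targets = np.zeros((*sectors.shape, config.n_sectors), dtype=np.float32)
    np.put_along_axis(targets, sectors[..., None], 1.0, axis=-1)
    return targets


def run_population(env, config, schedule, master_seed, n_replicates, locset=None, progress=False):
    """Train ``n_replicates`` networks in lockstep.

    Returns headings of shape (n_replicates, n_checkpoints, n_test) and the
    list of per-replicate seed pairs used.
    """
    locset = locset if locset is not None else test_locations()
    seeds = replicate_seeds(master_seed, n_replicates)
    nets = _PopulationNets(config, [s for s, _ in seeds])

    n_train = len(locset.training)
    orders = np.stack(
        [training_order(os, n_train, schedule.total_datapoints) for _, os in seeds]
    )  # (R, total)
    train_inputs = env.field_values(locset.training).astype(np.float32)
    train_dirs = goal_direction(locset.training)
    test_inputs = env.field_values(locset.test)

    targets = _encode_targets_population(config, nets.offsets, train_dirs[orders])
    xs = train_inputs[orders]  # (R, total, 2)

    headings = np.empty((n_replicates, len(schedule.checkpoints), len(locset.test)))
    ckpt_index = {c: i for i, c in enumerate(schedule.checkpoints)}
    for step in range(schedule.total_datapoints + 1):
        if step in ckpt_index:
            headings[:, ckpt_index[step]] = nets.predict(test_inputs)
            if progress:
                logger.info("%s impl%d: checkpoint %d evaluated", env.label, config.implementation, step)
        if step == schedule.total_datapoints:
            break
        nets.step(xs[:, step], targets[:, step])
    return headings, seeds


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

PERFECT = "PERFECT"


def mean_abs_error(headings, env, locset):
    """Mean absolute angular error vs the true goal direction, in [0, pi].

    The goal gridpoint is excluded (direction undefined there).
    """
    true_dir = goal_direction(locset.test, env.goal)
    ok = locset.test_defined
    return float(np.mean(abs_diff(headings[..., ok], true_dir[ok])))


def mean_abs_diff(headings, pmap, locset=None):
    """Mean absolute angular difference between headings and a model map.

    Locations undefined in the map (and the goal point) are excluded
    pairwise; a warning is logged if fewer than 90% of locations remain.
    """
    ok = pmap.defined
    if locset is not None:
        ok = ok & locset.test_defined
    frac = ok.mean()
    if frac < 0.9:
        logger.warning(
            "only %.0f%% of locations defined for %s in %s",
            100 * frac,
            pmap.model.name,
            pmap.env_label,
        )
    return float(np.mean(abs_diff(headings[..., ok], pmap.headings[ok])))


def distinct_comparators(env, locset, zero_tol=1e-9, dup_tol=1e-9):
    """The navigational-model comparators with unique, non-zero predictions.

    All nine (combination x extrapolation) maps are evaluated; maps whose
    errors vanish everywhere (indistinguishable from perfect performance)
    are dropped, and coinciding maps are merged under a collapsed label
    (e.g. plain ``APPROX`` when the three extrapolations agree, or
    ``APPROX/CORRECT-Tr`` when two combinations agree).
    """
    maps = {}
    for spec in all_model_specs():
        maps[spec] = prediction_map(env, spec, locset.test, training=locset.training)

    groups = []  # list of (representative map, [specs])
    for spec, pmap in maps.items():
        err = np.where(pmap.defined, pmap.signed_errors, np.nan)
        if np.all(np.abs(err[pmap.defined]) <= zero_tol):
            continue
        for rep, members in groups:
            both = rep.defined & pmap.defined
            same_mask = np.array_equal(rep.defined, pmap.defined)
            if same_mask and np.all(
                np.abs(wrap_signed(rep.headings[both] - pmap.headings[both])) <= dup_tol
            ):
                members.append(spec)
                break
        else:
            groups.append((pmap, [spec]))

    out = {}
    for rep, members in groups:
        combos = sorted({m.combination for m in members}, key=COMBINATION_ORDER.index)
        extraps = sorted({m.extrapolation for m in members}, key=EXTRAPOLATION_ORDER.index)
        label = "/".join(combos)
        if len(extraps) < len(EXTRAPOLATION_ORDER):
            label += "-" + "/".join(e[:2].title() for e in extraps)
        out[label] = rep
    return out


COMBINATION_ORDER = ["APPROX", "DIRECTIONAL", "CORRECT"]
EXTRAPOLATION_ORDER = ["TARGET", "RELEASE", "TRAINING"]


def score_population(headings, env, locset, schedule, implementation, comparators=None):
    """Long-format fit table from per-replicate, per-checkpoint headings.

    One row per (network, checkpoint, comparator); comparators are PERFECT
    plus every distinct navigational model of the environment.
    """
    comparators = comparators if comparators is not None else distinct_comparators(env, locset)
    rows = []
    for rep in range(headings.shape[0]):
        for ci, ckpt in enumerate(schedule.checkpoints):
            h = headings[rep, ci]
            rows.append(
                {
                    "environment": env.label,
                    "implementation": implementation,
                    "network_id": rep,
                    "checkpoint": ckpt,
                    "comparator": PERFECT,
                    "mean_abs_diff": mean_abs_error(h, env, locset),
                }
            )
            for name, pmap in comparators.items():
                rows.append(
                    {
                        "environment": env.label,
                        "implementation": implementation,
                        "network_id": rep,
                        "checkpoint": ckpt,
                        "comparator": name,
                        "mean_abs_diff": mean_abs_diff(h, pmap, locset),
                    }
                )
    return pd.DataFrame(rows)


def population_signed_error_by_direction(headings_at_ckpt, env, locset):
    """Population-mean signed error per test location vs the APPROX prediction.

    ``headings_at_ckpt``: (n_replicates, n_test) headings at one checkpoint.
    Returns one row per defined test location with the location's direction
    from the target, the circular mean (over replicates) of the signed
    network errors, and the approximate model's predicted signed error.
    """
    if headings_at_ckpt.ndim != 2 or headings_at_ckpt.shape[0] < 2:
        raise ValueError("need headings from at least 2 replicates")
    true_dir = goal_direction(locset.test, env.goal)
    signed = wrap_signed(headings_at_ckpt - true_dir[None, :])
    mean_signed = circular_mean_signed(signed, axis=0)
    from .nav_models import NavModelSpec

    approx = prediction_map(
        env, NavModelSpec("APPROX", "RELEASE"), locset.test, training=locset.training
    )
    ok = locset.test_defined & approx.defined
    direction_from_target = np.mod(true_dir + np.pi, TWO_PI)  # direction of location seen from goal
    return pd.DataFrame(
        {
            "x": locset.test[ok, 0],
            "y": locset.test[ok, 1],
            "direction_from_target": direction_from_target[ok],
            "mean_signed_error": mean_signed[ok],
            "approx_predicted_error": approx.signed_errors[ok],
        }
    )
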