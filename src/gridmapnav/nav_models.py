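"""Analytic grid-map navigational models.

A navigator at point p senses the two field values, linearly extrapolates
each field's spatial structure, and combines the two cues into a goalward
heading.  Three combination rules:

* ``APPROX`` — displacement in each field independently, then vector sum;
  exact in orthogonal linear grids, predictably biased otherwise.
* ``DIRECTIONAL`` — uses only the directions along which the fields vary,
  weighting both equally and ignoring magnitudes.
* ``CORRECT`` — solves the two linearized fields conjointly (2x2 system);
  exact whenever the fields really are linear.

crossed with three linear-extrapolation rules fixing where the gradient is
taken: ``TARGET`` (at the goal), ``RELEASE`` (at the current location) or
``TRAINING`` (component-wise mean over the experienced training locations).

The field-value displacement dF is always the true sensed offset
F(p) - F(goal); only its conversion to a spatial displacement uses the
extrapolated gradient.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .angles import angle_of, wrap_signed
from .environments import field_gradient, field_value, goal_direction

COMBINATIONS = ("APPROX", "DIRECTIONAL", "CORRECT")
EXTRAPOLATIONS = ("TARGET", "RELEASE", "TRAINING")

#: condition-number ceiling above which a CORRECT solve is marked undefined
CORRECT_COND_MAX = 1e8
_EPS = 1e-12


class UndefinedHeadingError(ValueError):
    """The model's combined displacement has no direction at this point."""


class SingularGeometryError(ValueError):
    """Near-parallel extrapolated gradients: no conjoint solution."""


@dataclass(frozen=True)
class NavModelSpec:
    """One of the nine (combination x extrapolation) navigational models."""

    combination: str
    extrapolation: str

    def __post_init__(self):
        if self.combination not in COMBINATIONS:
            raise ValueError(f"unknown combination {self.combination!r}")
        if self.extrapolation not in EXTRAPOLATIONS:
            raise ValueError(f"unknown extrapolation {self.extrapolation!r}")

    @property
    def name(self):
        return f"{self.combination}-{self.extrapolation[:2].title()}"


def all_model_specs():
    return [NavModelSpec(c, e) for c, e in itertools.product(COMBINATIONS, EXTRAPOLATIONS)]


@dataclass(frozen=True)
class LinearizedField:
    """A field reduced to (value offset from goal, extrapolation gradient)."""

    base_value: float
    delta: float  # F(p) - F(goal)
    gvec: np.ndarray  # gradient used for extrapolation, shape (2,)


def linearize(env, which, mode, p, training=None):
    """Linearize one field of ``env`` at point ``p`` under an extrapolation rule."""
    p = np.asarray(p, dtype=float)
    base = float(field_value(env, which, p))
    delta = base - float(field_value(env, which, env.goal))
    if mode == "TARGET":
        gvec = field_gradient(env, which, env.goal)
    elif mode == "RELEASE":
        gvec = field_gradient(env, which, p)
    elif mode == "TRAINING":
        if training is None or len(training) == 0:
            raise ValueError("TRAINING extrapolation requires a non-empty training set")
        gvec = field_gradient(env, which, np.asarray(training, dtype=float)).mean(axis=0)
    else:
        raise ValueError(f"unknown extrapolation mode {mode!r}")
    return LinearizedField(base_value=base, delta=delta, gvec=np.asarray(gvec, dtype=float))


def displacement_estimate(lin):
    """Displacement along the extrapolated gradient explaining the value offset.

    d = dF * g / |g|^2, so that dot(d, g) recovers dF.
    """
    g = lin.gvec
    n2 = float(g @ g)
    if n2 <= _EPS**2:
        raise ValueError("zero extrapolation gradient: displacement undefined")
    return lin.delta * g / n2


def _heading_of_displacement(d):
    if float(d @ d) <= _EPS**2:
        raise UndefinedHeadingError("combined displacement vanishes")
    return float(angle_of(-d[0], -d[1]))


def combine_approximate(d_a, d_b):
    """Heading from independent per-field displacements summed vectorially."""
    return _heading_of_displacement(np.asarray(d_a, float) + np.asarray(d_b, float))


def combine_directional(lin_a, lin_b):
    """Heading from equally weighted unit gradient directions.

    Each field contributes sign(dF) * g/|g|; a field on its goal isopleth
    (dF = 0) contributes nothing.
    """
    total = np.zeros(2)
    any_cue = False
    for lin in (lin_a, lin_b):
        if lin.delta == 0.0:
            continue
        norm = float(np.hypot(*lin.gvec))
        if norm <= _EPS:
            raise ValueError("zero extrapolation gradient in DIRECTIONAL")
        total += np.sign(lin.delta) * lin.gvec / norm
        any_cue = True
    if not any_cue:
        raise UndefinedHeadingError("both fields at goal value: no directional cue")
    return _heading_of_displacement(total)


def combine_correct(lin_a, lin_b):
    """Heading from the conjoint 2x2 solve of both linearized fields."""
    g_mat = np.stack([lin_a.gvec, lin_b.gvec])
    if np.linalg.cond(g_mat) > CORRECT_COND_MAX:
        raise SingularGeometryError("near-parallel gradients: conjoint solve ill-posed")
    d = np.linalg.solve(g_mat, np.array([lin_a.delta, lin_b.delta]))
    return _heading_of_displacement(d)


def model_heading(env, model, p, training=None):
    """Predicted heading of one navigational model at a single point."""
    lin_a = linearize(env, "A", model.extrapolation, p, training)
    lin_b = linearize(env, "B", model.extrapolation, p, training)
    if model.combination == "APPROX":
        return combine_approximate(displacement_estimate(lin_a), displacement_estimate(lin_b))
    if model.combination == "DIRECTIONAL":
        return combine_directional(lin_a, lin_b)
    return combine_correct(lin_a, lin_b)


@dataclass(frozen=True)
class PredictionMap:
    """Per-location headings and signed errors of one model in one environment.

    Signed errors are wrap(heading - true direction) in (-pi, pi]; in the
    compass convention a positive error is clockwise of the true direction.
    Undefined locations (the goal point, vanished or near-parallel
    displacements) carry NaN.
    """

    model: NavModelSpec
    env_label: str
    locations: np.ndarray
    headings: np.ndarray
    signed_errors: np.ndarray

    @property
    def defined(self):
        return ~np.isnan(self.headings)


def _gradients_for(env, mode, pts, training):
    """Extrapolation gradients for both fields at ``pts``, vectorized."""
    n = len(pts)
    if mode == "TARGET":
        ga = np.broadcast_to(field_gradient(env, "A", env.goal), (n, 2))
        gb = np.broadcast_to(field_gradient(env, "B", env.goal), (n, 2))
    elif mode == "RELEASE":
        ga = field_gradient(env, "A", pts)
        gb = field_gradient(env, "B", pts)
    elif mode == "TRAINING":
        if training is None or len(training) == 0:
            raise ValueError("TRAINING extrapolation requires a non-empty training set")
        training = np.asarray(training, dtype=float)
        ga = np.broadcast_to(field_gradient(env, "A", training).mean(axis=0), (n, 2))
        gb = np.broadcast_to(field_gradient(env, "B", training).mean(axis=0), (n, 2))
    else:
        raise ValueError(f"unknown extrapolation mode {mode!r}")
    return np.ascontiguousarray(ga), np.ascontiguousarray(gb)


def prediction_map(env, model, locations, training=None):
    """Evaluate one navigational model over a set of locations.

    Per-location failures (undefined direction, singular geometry, the goal
    point itself) become NaN entries; the map never aborts as a whole.
    """
    pts = np.asarray(locations, dtype=float)
    if len(pts) == 0:
        raise ValueError("locations must be non-empty")
    goal_val = env.field_values(env.goal)
    deltas = env.field_values(pts) - goal_val  # (n, 2)
    ga, gb = _gradients_for(env, model.extrapolation, pts, training)

    with np.errstate(invalid="ignore", divide="ignore"):
        if model.combination == "APPROX":
            da = deltas[:, :1] * ga / np.sum(ga * ga, axis=1, keepdims=True)
            db = deltas[:, 1:] * gb / np.sum(gb * gb, axis=1, keepdims=True)
            disp = da + db
        elif model.combination == "DIRECTIONAL":
            ua = ga / np.linalg.norm(ga, axis=1, keepdims=True)
            ub = gb / np.linalg.norm(gb, axis=1, keepdims=True)
            disp = np.sign(deltas[:, :1]) * ua + np.sign(deltas[:, 1:]) * ub
        elif model.combination == "CORRECT":
            g_mat = np.stack([ga, gb], axis=1)  # (n, 2, 2)
            cond = np.linalg.cond(g_mat)
            disp = np.full_like(pts, np.nan)
            ok = np.isfinite(cond) & (cond <= CORRECT_COND_MAX)
            if np.any(ok):
                disp[ok] = np.linalg.solve(g_mat[ok], deltas[ok][..., None])[..., 0]
        else:  # pragma: no cover - guarded by NavModelSpec
            raise ValueError(model.combination)

        norm2 = np.sum(disp * disp, axis=1)
        headings = angle_of(-disp[:, 0], -disp[:, 1])
        headings = np.where(np.isfinite(norm2) & (norm2 > _EPS**2), headings, np.nan)
        true_dir = goal_direction(pts, env.goal)
        signed = wrap_signed(headings - true_dir)
        headings = np.where(np.isnan(true_dir), np.nan, headings)
        signed = np.where(np.isnan(headings), np.nan, signed)

    return PredictionMap(
        model=model,
        env_label=env.label,
        locations=pts,
        headings=headings,
        signed_errors=signed,
    )


def prediction_map_dataframe(pmap):
    """CSV-ready long table (x, y, heading, signed_error, defined_flag)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "x": pmap.locations[:, 0],
            "y": pmap.locations[:, 1],
            "heading": pmap.headings,
            "signed_error": pmap.signed_errors,
            "defined_flag": pmap.defined,
        }
    )
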