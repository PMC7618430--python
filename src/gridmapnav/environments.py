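"""Simulated two-gradient environments and the training/test location geometry.

Each environment pairs a fixed linear east-west field (case ``A``) with one
of seven second fields (cases ``B1`` ... ``B4ii``) covering four geometries:
linear-orthogonal, linear-non-orthogonal, non-linear-non-orthogonal and
non-linear-orthogonal.  Every field has the form

    F(x, y) = (raw(x, y) - k1) / k2

where ``raw`` is the case's defining expression and the constants are chosen
so that (i) the field is zero at the goal and (ii) all fields span the same
range over a normalization region (by default the [-5, 5]^2 test square).
The goal sits at the origin in every environment.

Training locations form a polar grid around the goal (dense near the goal);
test locations form a regular Cartesian grid.  Angles follow the compass
convention of :mod:`gridmapnav.angles`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .angles import angle_of

GOAL = np.zeros(2)

#: raw field expressions and their analytic partial derivatives
#: each entry: raw(x, y) -> value, grad(x, y) -> (dF/dx, dF/dy)
_RAW_FORMS = {
    "A": (
        lambda x, y: x,
        lambda x, y: (np.ones_like(x), np.zeros_like(x)),
    ),
    "B1": (
        lambda x, y: y,
        lambda x, y: (np.zeros_like(x), np.ones_like(x)),
    ),
    "B2i": (
        lambda x, y: x - y,
        lambda x, y: (np.ones_like(x), -np.ones_like(x)),
    ),
    "B2ii": (
        lambda x, y: x - 2.0 * y,
        lambda x, y: (np.ones_like(x), -2.0 * np.ones_like(x)),
    ),
    "B3i": (
        lambda x, y: x - (y - 1.0) ** 2,
        lambda x, y: (np.ones_like(x), -2.0 * (y - 1.0)),
    ),
    "B3ii": (
        lambda x, y: x - 0.2 * (y + 2.0) ** 2,
        lambda x, y: (np.ones_like(x), -0.4 * (y + 2.0)),
    ),
    # The B4 fields vary non-linearly along y, orthogonally to field A.
    "B4i": (
        lambda x, y: np.exp(y),
        lambda x, y: (np.zeros_like(x), np.exp(y)),
    ),
    "B4ii": (
        lambda x, y: (6.0 - y) ** 3,
        lambda x, y: (np.zeros_like(x), -3.0 * (6.0 - y) ** 2),
    ),
}

B_CASES = ("B1", "B2i", "B2ii", "B3i", "B3ii", "B4i", "B4ii")

#: environments whose B field is linear in (x, y)
LINEAR_B_CASES = frozenset({"B1", "B2i", "B2ii"})
#: environments whose two fields have everywhere-orthogonal gradients
ORTHOGONAL_B_CASES = frozenset({"B1", "B4i", "B4ii"})


@dataclass(frozen=True)
class GradientSpec:
    """One scalar gradient field, F(p) = (raw(p) - k1) / k2."""

    case_id: str
    k1: float
    k2: float

    def __post_init__(self):
        if self.case_id not in _RAW_FORMS:
            raise ValueError(f"unknown gradient case {self.case_id!r}")
        if self.k2 == 0:
            raise ValueError("k2 must be nonzero")

    def value(self, p):
        """Field value at point(s) ``p`` (shape (..., 2))."""
        p = np.asarray(p, dtype=float)
        raw, _ = _RAW_FORMS[self.case_id]
        return (raw(p[..., 0], p[..., 1]) - self.k1) / self.k2

    def gradient(self, p):
        """Analytic (dF/dx, dF/dy) at point(s) ``p``; shape (..., 2)."""
        p = np.asarray(p, dtype=float)
        _, grad = _RAW_FORMS[self.case_id]
        gx, gy = grad(p[..., 0], p[..., 1])
        return np.stack([gx, gy], axis=-1) / self.k2


@dataclass(frozen=True)
class Environment:
    """A pair of gradient fields with a goal at the origin."""

    field_A: GradientSpec
    field_B: GradientSpec
    label: str
    goal: np.ndarray = field(default_factory=lambda: GOAL.copy())

    def field(self, which):
        if which == "A":
            return self.field_A
        if which == "B":
            return self.field_B
        raise ValueError(f"which must be 'A' or 'B', got {which!r}")

    def field_values(self, p):
        """Both field values at ``p``, stacked on the last axis."""
        p = np.asarray(p, dtype=float)
        return np.stack([self.field_A.value(p), self.field_B.value(p)], axis=-1)

    @property
    def b_case(self):
        return self.field_B.case_id

    @property
    def is_linear(self):
        return self.b_case in LINEAR_B_CASES

    @property
    def is_orthogonal(self):
        return self.b_case in ORTHOGONAL_B_CASES

    def metadata(self):
        """Constants and conventions, for run manifests."""
        return {
            "label": self.label,
            "goal": list(map(float, self.goal)),
            "field_A": {"case": "A", "k1": self.field_A.k1, "k2": self.field_A.k2},
            "field_B": {
                "case": self.field_B.case_id,
                "k1": self.field_B.k1,
                "k2": self.field_B.k2,
            },
            "angle_convention": "compass: from +y, clockwise positive, [0, 2pi)",
        }


@dataclass(frozen=True)
class LocationSet:
    """Ordered training (polar grid) and test (Cartesian grid) locations."""

    training: np.ndarray  # (n_train, 2)
    test: np.ndarray  # (n_test, 2)
    test_is_goal: np.ndarray  # (n_test,) bool; excluded from angular errors

    @property
    def test_defined(self):
        return ~self.test_is_goal


def _normalization_points(region):
    if region == "test_square":
        return test_locations().test
    if region == "training_disc":
        return training_locations()
    raise ValueError(f"unknown normalization region {region!r}")


def make_environment(b_case, normalization_region="test_square"):
    """Build the environment for one B case with standardized constants.

    k1 zeroes each raw expression at the goal; k2 scales each field so that
    its range over the normalization region equals the range of field A over
    the same region (field A keeps k2 = 1).
    """
    if b_case not in B_CASES:
        raise ValueError(f"unknown B case {b_case!r}; expected one of {B_CASES}")
    pts = _normalization_points(normalization_region)
    x, y = pts[..., 0], pts[..., 1]

    raw_a, _ = _RAW_FORMS["A"]
    va = raw_a(x, y)
    target_range = float(va.max() - va.min())
    k1_a = float(raw_a(*GOAL))
    field_a = GradientSpec("A", k1=k1_a, k2=1.0)

    raw_b, _ = _RAW_FORMS[b_case]
    vb = raw_b(x, y)
    k1_b = float(raw_b(*GOAL))
    k2_b = float(vb.max() - vb.min()) / target_range
    field_b = GradientSpec(b_case, k1=k1_b, k2=k2_b)

    return Environment(field_A=field_a, field_B=field_b, label=b_case)


def all_environments(normalization_region="test_square"):
    """The seven study environments, keyed by their B case."""
    return {c: make_environment(c, normalization_region) for c in B_CASES}


def field_value(env, which, p):
    """Value of field ``which`` of ``env`` at point(s) ``p``."""
    return env.field(which).value(p)


def field_gradient(env, which, p):
    """Analytic gradient of field ``which`` of ``env`` at point(s) ``p``."""
    return env.field(which).gradient(p)


def training_locations():
    """Polar training grid: 160 distances x 90 directions around the goal.

    Distances run 0.025, 0.050, ..., 4.000; directions every 4 degrees
    clockwise from the +y axis.  Ordered distance-major (all directions at
    the smallest distance first).
    """
    distances = np.arange(1, 161) * 0.025
    directions = np.deg2rad(np.arange(0, 360, 4))
    d, th = np.meshgrid(distances, directions, indexing="ij")
    pts = np.stack([d * np.sin(th), d * np.cos(th)], axis=-1)
    return pts.reshape(-1, 2)


def test_locations():
    """Cartesian test grid over [-5, 5]^2 at 0.1 spacing, as a LocationSet.

    Coordinates are exact integer multiples of 0.1 (index * 0.1) so the
    endpoints are hit without floating-point drift.  Row-major: y varies
    fastest within each x column.  The goal gridpoint (0, 0) is flagged for
    exclusion from angular-error aggregation.
    """
    coords = np.arange(-50, 51) * 0.1
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    pts = np.stack([xx, yy], axis=-1).reshape(-1, 2)
    is_goal = (pts[:, 0] == 0.0) & (pts[:, 1] == 0.0)
    return LocationSet(training=training_locations(), test=pts, test_is_goal=is_goal)


def goal_direction(p, goal=GOAL):
    """True compass direction from location(s) ``p`` to the goal.

    Undefined at the goal itself; scalar input at the goal raises, array
    input gets NaN there.
    """
    p = np.asarray(p, dtype=float)
    v = goal - p
    at_goal = (v[..., 0] == 0.0) & (v[..., 1] == 0.0)
    if p.ndim == 1:
        if at_goal:
            raise ValueError("goal direction undefined at the goal itself")
        return float(angle_of(v[0], v[1]))
    ang = angle_of(v[..., 0], v[..., 1])
    return np.where(at_goal, np.nan, ang)


def locations_dataframe(locset):
    """Long-format table of the location geometry (set, index, x, y, distance, direction)."""
    import pandas as pd

    frames = []
    for name, pts in (("training", locset.training), ("test", locset.test)):
        d = np.hypot(pts[:, 0], pts[:, 1])
        with np.errstate(invalid="ignore"):
            direction = angle_of(pts[:, 0], pts[:, 1])
        direction = np.where(d == 0, np.nan, direction)
        frames.append(
            pd.DataFrame(
                {
                    "set": name,
                    "index": np.arange(len(pts)),
                    "x": pts[:, 0],
                    "y": pts[:, 1],
                    "distance": d,
                    "direction": direction,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
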