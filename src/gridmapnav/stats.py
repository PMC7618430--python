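"""Best-model comparison via a mixed model with per-network random intercepts.

The fit of each comparator (PERFECT plus the distinct navigational models)
to a population of networks is assessed with the linear mixed model

    mean_abs_diff ~ comparator + (1 | network_id)

Comparator is a categorical fixed effect; each network gets a random
intercept absorbing its individual bias.  The fit table is balanced by
construction (every network scored against every comparator), which makes
the REML solution available in closed form from the two-way layout:

* fixed-effect comparator means are the per-comparator cell means,
* sigma^2_e = MS_residual with (n-1)(k-1) degrees of freedom,
* sigma^2_net = (MS_network - MS_residual) / k, truncated at zero
  (on truncation the model collapses to OLS and the residual pools the
  network sum of squares).

A contrast between two comparators is a within-network comparison, so its
variance depends only on sigma^2_e; Satterthwaite's degrees of freedom for
such a contrast equal the residual degrees of freedom (the variance
estimate is a pure chi-square).  With exactly two comparators this
reproduces the paired t-test.  The implementation is cross-checked against
a numerically fitted mixed model in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .experiment import PERFECT


@dataclass(frozen=True)
class MixedFit:
    """Closed-form REML fit of the balanced comparator model."""

    comparators: tuple
    means: np.ndarray  # estimated fixed-effect mean per comparator
    n_networks: int
    sigma2_net: float  # random-intercept variance
    sigma2_resid: float
    df_resid: float  # Satterthwaite df for within-network contrasts
    pooled: bool  # True when the network variance truncated to zero

    def mean_of(self, comparator):
        return float(self.means[self.comparators.index(comparator)])

    def se_of_mean(self, comparator):
        return float(np.sqrt((self.sigma2_net + self.sigma2_resid) / self.n_networks))

    def contrast(self, a, b):
        """t-test of comparator ``a`` minus comparator ``b`` (Satterthwaite df).

        Returns (estimate, se, t, df, p).  Degenerate zero-variance tables
        get exact limits: p = 1 for a zero difference, p = 0 otherwise.
        """
        est = self.mean_of(a) - self.mean_of(b)
        se = float(np.sqrt(2.0 * self.sigma2_resid / self.n_networks))
        if se == 0.0:
            p = 1.0 if est == 0.0 else 0.0
            return est, se, np.inf if est else 0.0, self.df_resid, p
        t = est / se
        p = 2.0 * sps.t.sf(abs(t), self.df_resid)
        return est, se, t, self.df_resid, p


def fit_mixed(table):
    """Fit the comparator model on one balanced (network x comparator) slice.

    ``table`` needs columns ``network_id``, ``comparator``, ``mean_abs_diff``
    with exactly one row per cell.
    """
    pivot = table.pivot(index="network_id", columns="comparator", values="mean_abs_diff")
    if pivot.isna().any().any():
        raise ValueError("unbalanced table: every network needs every comparator")
    y = pivot.to_numpy(dtype=float)
    n, k = y.shape
    if k < 2:
        raise ValueError("need at least 2 comparators")
    if n < 3:
        raise ValueError("need at least 3 networks")

    col_means = y.mean(axis=0)
    row_means = y.mean(axis=1)
    grand = y.mean()
    ss_net = k * float(((row_means - grand) ** 2).sum())
    resid = y - col_means[None, :] - row_means[:, None] + grand
    ss_resid = float((resid**2).sum())
    ms_resid = ss_resid / ((n - 1) * (k - 1))
    ms_net = ss_net / (n - 1)

    if ms_net > ms_resid:
        sigma2_net = (ms_net - ms_resid) / k
        sigma2_resid = ms_resid
        df_resid = (n - 1) * (k - 1)
        pooled = False
    else:
        sigma2_net = 0.0
        sigma2_resid = (ss_net + ss_resid) / (n * k - k)
        df_resid = n * k - k
        pooled = True
    return MixedFit(
        comparators=tuple(pivot.columns),
        means=col_means,
        n_networks=n,
        sigma2_net=sigma2_net,
        sigma2_resid=sigma2_resid,
        df_resid=df_resid,
        pooled=pooled,
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Best-model identification at one (environment, implementation, checkpoint)."""

    environment: str
    implementation: int
    checkpoint: int
    comparator_means: dict
    comparator_ses: dict
    best_model: str  # lowest estimated mean among all comparators (incl. PERFECT)
    next_best: str
    best_nav_model: str  # lowest estimated mean among navigational models only
    p_best_vs_next: float
    p_best_vs_perfect: float  # best navigational model vs the PERFECT baseline
    best_beats_perfect: bool  # best nav model both lower and significant at 5%
    best_beats_next: bool
    note: str = ""


def fit_comparison(table):
    """Full comparison for one (environment, implementation, checkpoint) slice."""
    env = table["environment"].iloc[0] if "environment" in table else ""
    impl = int(table["implementation"].iloc[0]) if "implementation" in table else 0
    ckpt = int(table["checkpoint"].iloc[0]) if "checkpoint" in table else -1
    fit = fit_mixed(table)

    order = np.argsort(fit.means, kind="stable")
    ranked = [fit.comparators[i] for i in order]
    best, next_best = ranked[0], ranked[1]
    nav = [c for c in fit.comparators if c != PERFECT]
    if not nav:
        raise ValueError("no navigational-model comparators in table")
    best_nav = min(nav, key=fit.mean_of)

    _, _, _, _, p_next = fit.contrast(best, next_best)
    if PERFECT in fit.comparators:
        est_p, _, _, _, p_perf = fit.contrast(best_nav, PERFECT)
    else:
        est_p, p_perf = np.nan, np.nan
    return ComparisonResult(
        environment=env,
        implementation=impl,
        checkpoint=ckpt,
        comparator_means={c: fit.mean_of(c) for c in fit.comparators},
        comparator_ses={c: fit.se_of_mean(c) for c in fit.comparators},
        best_model=best,
        next_best=next_best,
        best_nav_model=best_nav,
        p_best_vs_next=float(p_next),
        p_best_vs_perfect=float(p_perf),
        best_beats_perfect=bool(est_p < 0 and p_perf < 0.05),
        best_beats_next=bool(p_next < 0.05),
        note="pooled network variance (boundary REML)" if fit.pooled else "",
    )


def compare_across_checkpoints(fit_table):
    """fit_comparison per checkpoint of one environment/implementation table."""
    results = []
    for _, slice_ in fit_table.groupby("checkpoint", sort=True):
        results.append(fit_comparison(slice_))
    return results


def _stars(p):
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def summarize_training(results):
    """Figure-ready table of comparator fits relative to the PERFECT baseline.

    One row per (checkpoint, comparator) with the estimated mean difference
    minus the PERFECT baseline mean (bar height; negative means the model
    fits the networks better than perfect performance does), plus the two
    star annotations: ``stars_vs_perfect`` (best navigational model
    significantly closer than the baseline) and ``stars_vs_next`` (best
    model significantly better than the next best).
    """
    rows = []
    for res in sorted(results, key=lambda r: r.checkpoint):
        baseline = res.comparator_means.get(PERFECT, np.nan)
        for comp, mean in res.comparator_means.items():
            if comp == PERFECT:
                continue
            is_best = comp == res.best_nav_model
            rows.append(
                {
                    "environment": res.environment,
                    "implementation": res.implementation,
                    "checkpoint": res.checkpoint,
                    "comparator": comp,
                    "mean_abs_diff": mean,
                    "se": res.comparator_ses[comp],
                    "relative_to_perfect": mean - baseline,
                    "is_best_model": is_best,
                    "stars_vs_perfect": _stars(res.p_best_vs_perfect)
                    if is_best and res.comparator_means[comp] < baseline
                    else "",
                    "stars_vs_next": _stars(res.p_best_vs_next)
                    if is_best and res.best_model == comp
                    else "",
                }
            )
    return pd.DataFrame(rows)


def comparison_records(results):
    """JSON-serializable records of ComparisonResults."""
    out = []
    for r in results:
        out.append(
            {
                "environment": r.environment,
                "implementation": r.implementation,
                "checkpoint": r.checkpoint,
                "comparator_means": {k: float(v) for k, v in r.comparator_means.items()},
                "best_model": r.best_model,
                "next_best": r.next_best,
                "best_nav_model": r.best_nav_model,
                "p_best_vs_next": float(r.p_best_vs_next),
                "p_best_vs_perfect": float(r.p_best_vs_perfect),
                "best_beats_perfect": r.best_beats_perfect,
                "best_beats_next": r.best_beats_next,
                "note": r.note,
            }
        )
    return out
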