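"""Posterior and descriptive summaries for the barrens analysis.

Turns fitted models into the quantities practitioners report: odds ratios
and percent changes in odds per unit covariate, conditional
probability-of-barrens curves (posterior draws pushed through the inverse
logit with random effects set to zero), posterior model probabilities from
marginal likelihoods under equal prior weights, and percent-barrens tables
with binomial standard errors by site-year or 1-m depth bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

from .imagefilter import AnalysisTable
from .stmodel import FIXED_EFFECT_NAMES, ModelFit
from .terrain import logit_rugosity

logger = logging.getLogger(__name__)

__all__ = [
    "ConditionalCurve",
    "pct_change_odds",
    "odds_ratio",
    "conditional_curve",
    "model_probabilities",
    "percent_barrens_summary",
    "plot_conditional_curve",
    "plot_percent_barrens",
]


def pct_change_odds(beta):
    """Percent change in odds per unit covariate: (exp(beta) - 1) * 100.

    Accepts a scalar or an array of posterior draws; arrays map
    elementwise (summarise with e.g. ``np.median``).
    """
    b = np.asarray(beta, dtype=float)
    out = (np.exp(b) - 1.0) * 100.0
    return float(out) if out.ndim == 0 else out


def odds_ratio(beta):
    """Multiplicative effect on the odds scale: exp(beta)."""
    b = np.asarray(beta, dtype=float)
    out = np.exp(b)
    return float(out) if out.ndim == 0 else out


def model_probabilities(log_mls) -> np.ndarray:
    """Posterior model probabilities under equal prior model weights.

    Overflow-safe softmax of the log marginal likelihoods; invariant to
    adding a constant to every input.
    """
    lml = np.asarray(log_mls, dtype=float)
    if lml.size < 2:
        raise ValueError("need at least two models to compare")
    if not np.all(np.isfinite(lml)):
        raise ValueError("log marginal likelihoods must be finite")
    return np.exp(lml - logsumexp(lml))


@dataclass
class ConditionalCurve:
    """Posterior probability-of-barrens curve along one covariate.

    Probabilities are per-draw inverse logits of X(g) beta with random
    effects zero, averaged over draws; ``conditioning`` records the values
    every other covariate was held at (natural units).
    """

    covariate: str
    grid: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    conditioning: dict
    n_draws: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            self.covariate: self.grid,
            "p_mean": self.mean,
            "p_lower": self.lower,
            "p_upper": self.upper,
        })


def conditional_curve(
    fit: ModelFit,
    covariate: str,
    grid,
    table: AnalysisTable,
    conditioning: dict | None = None,
    n_draws: int = 5000,
    rng: np.random.Generator | None = None,
) -> ConditionalCurve:
    """Conditional effect curve for ``covariate`` in {year, depth, rugosity}.

    ``grid`` is in natural units (survey year, depth in metres, raw
    rugosity); the analysis table's standardisations are applied before
    the linear predictor.  ``conditioning`` holds the remaining covariates
    (keys ntr, year, depth, rugosity; natural units).  Defaults condition
    on the NTR in the last survey year with the NTR means of depth and
    rugosity - the convention used for reporting covariate effects.

    The returned mean is the across-draw average of the per-draw
    probabilities (not the probability at the average coefficient).
    """
    if covariate not in {"year", "depth", "rugosity"}:
        raise ValueError(f"covariate {covariate!r} not in the model")
    beta_cols = [c for c in FIXED_EFFECT_NAMES if c in fit.draws.columns]
    if len(beta_cols) != len(FIXED_EFFECT_NAMES):
        missing = set(FIXED_EFFECT_NAMES) - set(beta_cols)
        raise ValueError(f"fit draws missing coefficients: {sorted(missing)}")
    draws = fit.draws[FIXED_EFFECT_NAMES].to_numpy()
    if n_draws > len(draws):
        raise ValueError(
            f"requested {n_draws} draws but only {len(draws)} available"
        )
    if n_draws < len(draws):
        rng = rng if rng is not None else np.random.default_rng(0)
        draws = draws[rng.choice(len(draws), size=n_draws, replace=False)]

    df = table.df
    ntr_mask = df["ntr"] == 1
    base = ntr_mask if ntr_mask.any() else np.ones(len(df), dtype=bool)
    defaults = {
        "ntr": 1,
        "year": int(df["year"].max()),
        "depth": float(df.loc[base, "depth_m"].mean()),
        "rugosity": float(df.loc[base, "rugosity"].mean()),
    }
    cond = {**defaults, **(conditioning or {})}

    grid = np.asarray(grid, dtype=float)
    m = len(grid)
    vals = {k: np.full(m, float(v)) for k, v in cond.items()}
    vals[covariate] = grid

    stz = table.standardizations
    year_coded = vals["year"] - table.first_year
    depth_std = stz["depth"].apply(vals["depth"])
    depth_sq_std = stz["depth_sq"].apply(vals["depth"] ** 2)
    rug_std = stz["rugosity_logit"].apply(logit_rugosity(vals["rugosity"]))

    X = np.column_stack([
        np.ones(m),
        vals["ntr"],
        year_coded,
        rug_std,
        depth_std,
        depth_sq_std,
        vals["ntr"] * year_coded,
    ])
    probs = expit(draws @ X.T)  # (n_draws, m)
    lower, upper = np.percentile(probs, [2.5, 97.5], axis=0)
    cond_record = dict(cond)
    cond_record.pop(covariate, None)
    cond_record["random_effects"] = 0.0
    return ConditionalCurve(
        covariate=covariate,
        grid=grid,
        mean=probs.mean(axis=0),
        lower=lower,
        upper=upper,
        conditioning=cond_record,
        n_draws=len(draws),
    )


def percent_barrens_summary(records: pd.DataFrame, group_keys) -> pd.DataFrame:
    """Percent of images classified as barrens, by group.

    ``group_keys`` is a list of record columns, with the special key
    ``depth_bin`` meaning 1-m bins [d, d+1).  Percent = 100 k/n with the
    binomial proportion standard error 100 sqrt(p(1-p)/n); all-absent
    groups report SE 0 (degenerate, flagged in the log).
    """
    if "barren" not in records.columns:
        raise ValueError("records must be classified first (missing 'barren')")
    if isinstance(group_keys, str):
        group_keys = [group_keys]
    df = records.copy()
    keys = []
    for key in group_keys:
        if key == "depth_bin":
            df["depth_bin"] = np.floor(df["depth_m"]).astype(int)
            keys.append("depth_bin")
        elif key in df.columns:
            keys.append(key)
        else:
            raise ValueError(f"unknown group key {key!r}")
    rows = []
    for name, grp in df.groupby(keys, sort=True):
        n = len(grp)
        if n == 0:
            continue
        k = int(grp["barren"].sum())
        p = k / n
        se = 100.0 * np.sqrt(p * (1.0 - p) / n)
        if k in (0, n):
            logger.info("group %s: degenerate proportion (k=%d of %d)", name, k, n)
        row = dict(zip(keys, name if isinstance(name, tuple) else (name,)))
        row.update({"n": n, "k": k, "percent": 100.0 * p, "se": se})
        rows.append(row)
    return pd.DataFrame(rows)


def plot_conditional_curve(curve: ConditionalCurve, ax=None, log_y: bool = False):
    """Render a conditional curve: posterior-mean line with a shaded 95%
    band.  ``log_y`` mirrors the logarithmic probability axis used when
    reserve and reference trajectories differ by orders of magnitude."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.grid, curve.mean, lw=1.5)
    ax.fill_between(curve.grid, curve.lower, curve.upper, alpha=0.3)
    ax.set_xlabel(curve.covariate)
    ax.set_ylabel("probability of barrens presence")
    if log_y:
        ax.set_yscale("log")
    return ax


def plot_percent_barrens(summary: pd.DataFrame, ax=None):
    """Percent-barrens points with binomial standard-error bars, grouped
    by site (if present) along the remaining key."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    keys = [c for c in summary.columns if c not in {"n", "k", "percent", "se"}]
    xkey = keys[-1]
    if "site_id" in keys and xkey != "site_id":
        for site, grp in summary.groupby("site_id"):
            ax.errorbar(grp[xkey], grp["percent"], yerr=grp["se"],
                        marker="o", capsize=3, label=str(site))
        ax.legend(title="site")
    else:
        ax.errorbar(summary[xkey], summary["percent"], yerr=summary["se"],
                    marker="o", capsize=3)
    ax.set_xlabel(xkey)
    ax.set_ylabel("percent barrens")
    return ax
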