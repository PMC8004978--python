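"""Per-individual Bayesian quadratic weight trajectories.

Each trial participant contributes a handful of weights — two baseline
measurements (both at t = 0 months), two interim self-reports (t = 2, 4) and
a closeout measurement (t = 6) — modelled as

    y(t) = a + b t + c t^2 + eps,   eps ~ Normal(0, sigma_eps)

with a the starting weight (kg), b the linear rate (kg/month), c curvature
(kg/month^2).  Priors are weakly informative: b, c ~ Normal(0, 10),
sigma_eps ~ HalfNormal(10), and a ~ Normal(first observed weight, 10 kg).
Fitting the whole series, rather than differencing two visits, yields a
posterior for each individual's weight change with honest uncertainty, from
which responders (significant loss or gain) are identified: the 6-month
change as a percentage of starting weight is computed per posterior draw,
and a participant is a responder when the 5th-95th percentile interval
excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._bayes import ConjugateLinearModel, split_rhat

__all__ = [
    "WeightSeries",
    "TrajectoryPosterior",
    "WeightChangeSummary",
    "fit_quadratic_weight",
    "weight_change_posterior",
    "percent_weight_change",
    "fit_weight_table",
]

DEFAULT_VISIT_TIMES = (0.0, 0.0, 2.0, 4.0, 6.0)
PERCENTILES = (5, 25, 50, 75, 95)


@dataclass
class WeightSeries:
    """One participant's visit-time / weight pairs."""

    participant_id: str
    t: np.ndarray                      # months since randomisation
    weights: np.ndarray                # kg
    arm: str | None = None             # "TRE" or "SDA"
    self_reported: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if t.shape != w.shape:
            raise ValueError("t and weights must have equal length")
        if np.any(np.diff(t) < 0):
            raise ValueError("visit times must be non-decreasing")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        if self.arm is not None and self.arm not in ("TRE", "SDA"):
            raise ValueError(f"unknown arm {self.arm!r}")
        self.t, self.weights = t, w


@dataclass
class TrajectoryPosterior:
    """Posterior draws of (a, b, c, sigma_eps) for one participant."""

    participant_id: str
    a: np.ndarray          # (chains, samples)
    b: np.ndarray
    c: np.ndarray
    sigma: np.ndarray
    rhat: np.ndarray       # for (a, b, c)
    arm: str | None = None

    def flat(self, name: str) -> np.ndarray:
        return getattr(self, name).ravel()

    def change_draws(self, horizon: float = 6.0, percent: bool = True) -> np.ndarray:
        """Per-draw model-predicted weight change from t=0 to the horizon."""
        delta = self.flat("b") * horizon + self.flat("c") * horizon**2
        if percent:
            return 100.0 * delta / self.flat("a")
        return delta


@dataclass
class WeightChangeSummary:
    """Percentile summary of the posterior weight change at a horizon."""

    participant_id: str
    horizon: float
    percentiles: dict[int, float]
    significant: bool
    direction: int                    # sign of the median change; 0 if not significant
    arm: str | None = None

    def __post_init__(self) -> None:
        vals = [self.percentiles[p] for p in sorted(self.percentiles)]
        if np.any(np.diff(vals) < 0):
            raise ValueError("percentiles must be monotone")


def fit_quadratic_weight(
    series: WeightSeries,
    chains: int = 4,
    samples: int = 1000,
    seed: int | None = None,
    prior_center_a: float | None = None,
    prior_sd_a: float = 10.0,
    prior_sd_bc: float = 10.0,
    prior_sd_sigma: float = 10.0,
) -> TrajectoryPosterior:
    """Fit the quadratic trajectory model to one weight series.

    Requires at least three observations.  Both baseline weights (t = 0)
    enter as separate observations, which tightens the starting-weight
    posterior.  ``prior_center_a`` defaults to the first observed weight.
    """
    n = series.t.size
    if n < 3:
        raise ValueError(f"need at least 3 observations to fit, got {n}")
    rng = np.random.default_rng(seed)
    center = float(series.weights[0]) if prior_center_a is None else float(prior_center_a)
    T = np.column_stack([np.ones(n), series.t, series.t**2])
    model = ConjugateLinearModel(
        T,
        series.weights,
        prior_mean=np.array([center, 0.0, 0.0]),
        prior_sd=np.array([prior_sd_a, prior_sd_bc, prior_sd_bc]),
        sigma_prior_sd=prior_sd_sigma,
    )
    beta, sigma = model.sample(chains * samples, rng)
    beta = beta.reshape(chains, samples, 3)
    return TrajectoryPosterior(
        participant_id=series.participant_id,
        a=beta[:, :, 0],
        b=beta[:, :, 1],
        c=beta[:, :, 2],
        sigma=sigma.reshape(chains, samples),
        rhat=split_rhat(beta),
        arm=series.arm,
    )


def weight_change_posterior(
    tp: TrajectoryPosterior,
    horizon: float = 6.0,
    percent: bool = True,
    band: tuple[int, int] = (5, 95),
) -> WeightChangeSummary:
    """Percentile summary and responder flag for the posterior weight change.

    The change is significant when the central interval spanned by ``band``
    (default the 5th-95th percentiles, as plotted by box-whisker summaries)
    excludes zero; the direction is then the sign of the median.
    """
    draws = tp.change_draws(horizon=horizon, percent=percent)
    pcts = {p: float(np.percentile(draws, p)) for p in sorted(set(PERCENTILES) | set(band))}
    lo, hi = pcts[band[0]], pcts[band[1]]
    significant = lo > 0.0 or hi < 0.0
    direction = int(np.sign(pcts[50])) if significant else 0
    return WeightChangeSummary(
        participant_id=tp.participant_id,
        horizon=horizon,
        percentiles={p: pcts[p] for p in PERCENTILES},
        significant=significant,
        direction=direction,
        arm=tp.arm,
    )


def percent_weight_change(pre: float, post: float) -> float:
    """Weight change as a percentage of the initial weight."""
    if pre <= 0:
        raise ValueError("initial weight must be positive")
    return 100.0 * (post - pre) / pre


def fit_weight_table(
    weights: pd.DataFrame,
    horizon: float = 6.0,
    chains: int = 4,
    samples: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fit every participant in a long weight table and summarise changes.

    Expects columns ``participant_id``, ``t_months``, ``weight_kg`` and
    optionally ``arm``; participants with fewer than three visits are
    skipped.  Returns one row per participant with change percentiles and
    the responder flag.
    """
    seeds = np.random.SeedSequence(seed).spawn(weights["participant_id"].nunique())
    rows = []
    for (pid, grp), ss in zip(weights.groupby("participant_id", sort=True), seeds):
        grp = grp.sort_values("t_months")
        arm = grp["arm"].iloc[0] if "arm" in grp.columns else None
        if len(grp) < 3:
            continue
        series = WeightSeries(
            participant_id=str(pid),
            t=grp["t_months"].to_numpy(),
            weights=grp["weight_kg"].to_numpy(),
            arm=None if pd.isna(arm) else arm,
        )
        tp = fit_quadratic_weight(
            series, chains=chains, samples=samples, seed=ss.generate_state(1)[0] % (2**31)
        )
        summ = weight_change_posterior(tp, horizon=horizon)
        row = {
            "participant_id": str(pid),
            "arm": series.arm,
            "n_visits": len(grp),
            "significant": summ.significant,
            "direction": summ.direction,
        }
        row.update({f"pct_{p}": v for p, v in summ.percentiles.items()})
        rows.append(row)
    return pd.DataFrame(rows)
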