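"""Synthetic cohorts with the statistical structure the analysis assumes.

The study's participant-level data are not public, so every downstream stage
is exercised on simulated cohorts instead: multi-day smartphone food logs
with realistic clock-time clustering and typo-bearing free text, covariate
tables, clinical outcomes generated from a linear model with known
coefficients, and per-visit weight series drawn from the quadratic
trajectory model.  The generating parameters travel with the cohort
(``truth``) so recovery tests can compare estimates against ground truth.

Defaults emulate the study conditions: a 28-day observation phase, around
seven ingestion events per day, eating windows of roughly 14 h starting near
08:00, a 71% female cohort aged around 40, and weight series at visit times
t = 0, 0, 2, 4, 6 months with 0.5 kg measurement noise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .nova_annotation import Lexicon, load_lexicon
from .weight_trajectory import WeightSeries

__all__ = [
    "WindowParams",
    "WeightParams",
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_food_log",
    "generate_weight_series",
    "write_cohort",
    "DEFAULT_TRUE_BETA",
]

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"
_TZ = "+01:00"  # fixed local offset; participants do not change timezone
_START_DATE = "2020-01-06"

# Standardized-scale coefficients emulating the directions reported for a
# European adult cohort: unprocessed food and physical activity protective,
# age adverse, female sex lowering waist/BP/triglycerides/glucose.
DEFAULT_TRUE_BETA: dict[str, dict[str, float]] = {
    "bmi": {"age": 0.20, "n_NOVA1": -0.20, "sleep_dur_w": -0.10, "ipaq": -0.20},
    "waist": {"age": 0.25, "sex": -0.20, "n_NOVA4": 0.20, "ipaq": -0.15},
    "sbp": {"age": 0.30, "sex": -0.20},
    "dbp": {"age": 0.25, "n_NOVA1": -0.15},
    "glucose": {"age": 0.30, "sex": -0.20, "eating_duration": -0.10},
    "hdl": {"n_NOVA1": 0.20, "n_A": 0.15, "ipaq": 0.15},
    "triglycerides": {"age": 0.20, "sex": -0.20, "n_C": 0.15, "n_S": 0.10, "ipaq": -0.15},
    "hba1c": {"age": 0.30},
}

# per-outcome location/scale on the log scale used to invert standardisation
_OUTCOME_SCALES = {
    "bmi": (np.log(25.0), 0.15),
    "waist": (np.log(86.0), 0.12),
    "sbp": (np.log(124.0), 0.08),
    "dbp": (np.log(78.0), 0.09),
    "glucose": (np.log(5.0), 0.10),
    "hdl": (np.log(1.5), 0.20),
    "triglycerides": (np.log(1.2), 0.40),
    "hba1c": (np.log(5.3), 0.06),
}


@dataclass
class WindowParams:
    """Per-participant eating-window distributions (hours)."""

    start_mean: float = 8.0
    start_sd: float = 1.0
    duration_mean: float = 14.0
    duration_sd: float = 1.5
    events_per_day: float = 7.0
    outlier_fraction: float = 0.02


@dataclass
class WeightParams:
    """Distributions of the quadratic trajectory parameters."""

    a_mean: float = 80.0
    a_sd: float = 12.0
    b_mean: float = -0.1
    b_sd: float = 0.25
    c_mean: float = 0.0
    c_sd: float = 0.02
    sigma_eps: float = 0.5
    visit_times: tuple[float, ...] = (0.0, 0.0, 2.0, 4.0, 6.0)


@dataclass
class CohortConfig:
    """Generating parameters for one synthetic cohort."""

    n_participants: int = 60
    days: int = 28
    seed: int = 0
    typo_rate: float = 0.1
    special_rate: float = 0.04        # water / medication entries
    multi_item_rate: float = 0.15     # comma-joined two-item annotations
    female_fraction: float = 0.71
    true_beta: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRUE_BETA.items()}
    )
    noise_sd: float | dict[str, float] = 1.0
    window_params: WindowParams = field(default_factory=WindowParams)
    weight_params: WeightParams = field(default_factory=WeightParams)
    simulate_trial: bool = True
    intervention_days: int = 28       # logged days in the intervention phase
    compliance_rate: float = 0.8

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be at least 2")
        if self.days < 1:
            raise ValueError("days must be at least 1")
        for name in ("typo_rate", "special_rate", "multi_item_rate",
                     "female_fraction", "compliance_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        noise = self.noise_sd
        values = noise.values() if isinstance(noise, dict) else [noise]
        if any(v <= 0 for v in values):
            raise ValueError("noise_sd must be positive")
        if not 0.0 < self.window_params.duration_mean < 24.0:
            raise ValueError("window_params.duration_mean must be in (0, 24)")
        if self.window_params.duration_sd <= 0 or self.window_params.start_sd <= 0:
            raise ValueError("window_params SDs must be positive")
        if self.weight_params.sigma_eps < 0:
            raise ValueError("weight_params.sigma_eps must be non-negative")


@dataclass
class SyntheticCohort:
    """A generated cohort plus the parameters that produced it."""

    participants: pd.DataFrame
    food_log: pd.DataFrame
    outcomes: pd.DataFrame
    weights: pd.DataFrame
    truth: dict
    outcomes_post: pd.DataFrame | None = None
    visits: pd.DataFrame | None = None


# --------------------------------------------------------------------- #
# food logs


def _typo(entry: str, rng: np.random.Generator) -> str:
    """One random single-character edit (Levenshtein distance exactly 1)."""
    op = rng.integers(3)
    if op == 0 and len(entry) >= 2:  # deletion
        i = int(rng.integers(len(entry)))
        return entry[:i] + entry[i + 1 :]
    if op == 1:  # substitution with a different character
        i = int(rng.integers(len(entry)))
        choices = [c for c in _ALPHABET if c != entry[i]]
        return entry[:i] + choices[int(rng.integers(len(choices)))] + entry[i + 1 :]
    i = int(rng.integers(len(entry) + 1))  # insertion
    return entry[:i] + _ALPHABET[int(rng.integers(26))] + entry[i:]


def _lexicon_pools(lexicon: Lexicon) -> tuple[list[str], np.ndarray, list[str]]:
    foods = sorted(e for e, l in lexicon.entries.items() if not l.is_special)
    specials = sorted(e for e, l in lexicon.entries.items() if l.is_special)
    if not foods:
        raise ValueError("lexicon contains no food entries")
    # Zipf-like popularity so a few items (coffee, bread ...) dominate, as in
    # real logs where the top entry alone covers thousands of events
    w = 1.0 / (1.0 + np.arange(len(foods)))
    return foods, w / w.sum(), specials


def generate_food_log(
    participant_id: str,
    days: int,
    window_start: float,
    window_duration: float,
    events_per_day: float,
    lexicon: Lexicon | Sequence[str],
    typo_rate: float,
    seed: int | np.random.SeedSequence,
    outlier_fraction: float = 0.02,
    special_rate: float = 0.0,
    multi_item_rate: float = 0.0,
    item_weights: Mapping[str, float] | None = None,
    start_date: str = _START_DATE,
    phase: str = "observation",
) -> pd.DataFrame:
    """Simulate one participant's timestamped, annotated food log.

    Event clock times are uniform inside ``[window_start, window_start +
    window_duration)`` except for an ``outlier_fraction`` drawn uniformly on
    the 24 h clock (these exercise the percentile trimming).  Annotations are
    drawn from the lexicon with single-character typos injected at
    ``typo_rate``; the pre-typo source entries are kept in ``true_items``.
    Times past midnight roll into the next calendar date.
    """
    if not 0.0 < window_duration < 24.0:
        raise ValueError(f"window_duration must be in (0, 24), got {window_duration}")
    if isinstance(lexicon, Lexicon):
        foods, weights, specials = _lexicon_pools(lexicon)
    else:
        foods = sorted(lexicon)
        if not foods:
            raise ValueError("lexicon must not be empty")
        w = 1.0 / (1.0 + np.arange(len(foods)))
        weights = w / w.sum()
        specials = []
    if item_weights is not None:
        w = np.array([item_weights.get(f, 1.0) for f in foods]) * weights
        weights = w / w.sum()
    rng = np.random.default_rng(seed)
    base = pd.Timestamp(start_date)
    dur_sec = max(int(window_duration * 3600), 2)
    rows = []
    for day in range(days):
        n_events = max(1, int(rng.poisson(events_per_day)))
        n_out = int(rng.binomial(n_events, outlier_fraction)) if outlier_fraction > 0 else 0
        # distinct integer seconds keep timestamps strictly ordered per day
        in_sec = rng.choice(dur_sec, size=min(n_events - n_out, dur_sec), replace=False)
        clock = window_start + in_sec / 3600.0
        if n_out:
            out_sec = rng.choice(86400, size=n_out, replace=False)
            clock = np.concatenate([clock, out_sec / 3600.0])
        clock = np.unique(clock)  # cross-set second collisions are dropped
        for h in clock:
            date = base + pd.Timedelta(days=day + int(h // 24))
            frac = h % 24
            ts = (date + pd.Timedelta(hours=frac)).strftime("%Y-%m-%dT%H:%M:%S") + _TZ
            if specials and rng.random() < special_rate:
                items = [specials[int(rng.integers(len(specials)))]]
            else:
                k = 2 if rng.random() < multi_item_rate else 1
                items = list(rng.choice(foods, size=k, replace=False, p=weights))
            texts = [
                _typo(i, rng) if rng.random() < typo_rate else i for i in items
            ]
            rows.append(
                {
                    "participant_id": participant_id,
                    "timestamp": ts,
                    "text": ", ".join(texts),
                    "true_items": "|".join(items),
                    "phase": phase,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- #
# weight series


def generate_weight_series(
    a: float,
    b: float,
    c: float,
    sigma_eps: float,
    visit_times: Sequence[float] = WeightParams.visit_times,
    seed: int | np.random.SeedSequence | None = None,
    participant_id: str = "P000",
    arm: str | None = None,
) -> WeightSeries:
    """Draw one weight series from the quadratic trajectory model.

    weights = a + b t + c t^2 + Normal(0, sigma_eps) at each visit time.
    """
    if a <= 0:
        raise ValueError(f"starting weight a must be positive, got {a}")
    if sigma_eps < 0:
        raise ValueError("sigma_eps must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.asarray(visit_times, dtype=float)
    w = a + b * t + c * t**2 + sigma_eps * rng.standard_normal(t.size)
    return WeightSeries(participant_id=participant_id, t=t, weights=w, arm=arm)


# --------------------------------------------------------------------- #
# full cohorts


def _standardize(col: np.ndarray) -> np.ndarray:
    sd = col.std()
    if sd == 0:
        return np.zeros_like(col)
    return (col - col.mean()) / sd


def generate_cohort(config: CohortConfig, lexicon: Lexicon | None = None) -> SyntheticCohort:
    """Generate a full cohort: covariates, food logs, outcomes, weights.

    Outcomes obey ``y = X beta_true + eps`` on the standardized scale, where
    X holds the z-scored covariates (including the realized per-participant
    NOVA/drink event counts and eating duration from the generated logs),
    and are then mapped to raw measurement units by inverting the log/z
    transform.  One master seed fans out to per-participant substreams, so
    the same seed always reproduces the same cohort.
    """
    if lexicon is None:
        lexicon = load_lexicon()
    master = np.random.SeedSequence(config.seed)
    ss_cov, ss_food, ss_out, ss_wt, ss_trial = master.spawn(5)
    rng = np.random.default_rng(ss_cov)
    n = config.n_participants
    pids = [f"P{i:03d}" for i in range(n)]

    # covariates
    female = rng.random(n) < config.female_fraction
    age = np.clip(rng.normal(40.0, 13.0, n), 18.0, 77.0)
    sleep_w = np.clip(rng.normal(7.3, 0.9, n), 4.0, 11.0)
    sleep_f = np.clip(rng.normal(8.0, 1.0, n), 4.0, 12.0)
    mid_w = np.clip(rng.normal(3.4, 0.8, n), 0.5, 7.0)
    mid_f = np.clip(rng.normal(4.5, 1.0, n), 0.5, 9.0)
    psqi = np.clip(np.round(rng.normal(5.0, 2.5, n)), 0, 21)
    ipaq = rng.gamma(1.6, 1000.0, n)
    height = np.clip(rng.normal(1.70, 0.09, n), 1.45, 2.05)
    participants = pd.DataFrame(
        {
            "participant_id": pids,
            "age": age,
            "sex": np.where(female, "female", "male"),
            "sleep_dur_w": sleep_w,
            "sleep_dur_f": sleep_f,
            "midsleep_w": mid_w,
            "midsleep_f": mid_f,
            "psqi": psqi,
            "ipaq": ipaq,
            "height": height,
        }
    )

    # observation-phase food logs
    wp = config.window_params
    win_start = rng.normal(wp.start_mean, wp.start_sd, n)
    win_dur = np.clip(rng.normal(wp.duration_mean, wp.duration_sd, n), 6.0, 20.0)
    logs = []
    food_seeds = ss_food.spawn(2 * n)
    for i, pid in enumerate(pids):
        logs.append(
            generate_food_log(
                pid,
                config.days,
                win_start[i],
                win_dur[i],
                wp.events_per_day,
                lexicon,
                config.typo_rate,
                food_seeds[i],
                outlier_fraction=wp.outlier_fraction,
                special_rate=config.special_rate,
                multi_item_rate=config.multi_item_rate,
            )
        )

    # realized per-participant behaviour covariates from the generated logs
    obs_log = pd.concat(logs, ignore_index=True)
    counts = _true_category_counts(obs_log, lexicon)
    duration_real = _realized_duration(obs_log)
    for c in counts.columns:
        participants[c] = counts[c].to_numpy()
    participants["eating_duration"] = duration_real

    X_cols = {
        "age": age,
        "sex": female.astype(float),
        **{c: counts[c].to_numpy(dtype=float) for c in counts.columns},
        "eating_duration": duration_real,
        "midsleep_w": mid_w,
        "midsleep_f": mid_f,
        "sleep_dur_w": sleep_w,
        "sleep_dur_f": sleep_f,
        "psqi": psqi.astype(float),
        "ipaq": np.sqrt(ipaq),
    }
    Xz = {k: _standardize(v) for k, v in X_cols.items()}

    rng_out = np.random.default_rng(ss_out)
    outcomes = pd.DataFrame({"participant_id": pids})
    truth_beta = {}
    for d, (loc, scale) in _OUTCOME_SCALES.items():
        beta = config.true_beta.get(d, {})
        truth_beta[d] = dict(beta)
        sd = config.noise_sd[d] if isinstance(config.noise_sd, dict) else config.noise_sd
        y_std = sum(b * Xz[k] for k, b in beta.items()) if beta else np.zeros(n)
        y_std = y_std + sd * rng_out.standard_normal(n)
        # invert the log/z transform: (log y - loc) / scale recovers y_std exactly
        outcomes[d] = np.exp(loc + scale * y_std)
    outcomes["height"] = height
    outcomes["weight"] = outcomes["bmi"] * height**2
    outcomes["sex"] = participants["sex"]
    outcomes["age"] = age

    # weight series and arms (synthetic 1:1 randomisation of the whole cohort)
    rng_wt = np.random.default_rng(ss_wt)
    arms = np.array(["TRE", "SDA"] * (n // 2 + 1))[:n]
    rng_wt.shuffle(arms)
    wtp = config.weight_params
    b_i = rng_wt.normal(wtp.b_mean, wtp.b_sd, n)
    c_i = rng_wt.normal(wtp.c_mean, wtp.c_sd, n)
    a_i = outcomes["weight"].to_numpy()
    wt_seeds = ss_wt.spawn(n)
    weight_rows = []
    for i, pid in enumerate(pids):
        series = generate_weight_series(
            a_i[i], b_i[i], c_i[i], wtp.sigma_eps,
            visit_times=wtp.visit_times, seed=wt_seeds[i],
            participant_id=pid, arm=arms[i],
        )
        for j, (t, w) in enumerate(zip(series.t, series.weights)):
            weight_rows.append(
                {
                    "participant_id": pid,
                    "visit": j + 1,
                    "t_months": t,
                    "weight_kg": w,
                    "self_reported": bool(0 < t < max(series.t)),
                    "arm": arms[i],
                }
            )
    weights = pd.DataFrame(weight_rows)
    participants["arm"] = arms

    truth = {
        "seed": config.seed,
        "beta": truth_beta,
        "noise_sd": config.noise_sd,
        "window_start": dict(zip(pids, win_start.tolist())),
        "window_duration": dict(zip(pids, win_dur.tolist())),
        "weight_a": dict(zip(pids, a_i.tolist())),
        "weight_b": dict(zip(pids, b_i.tolist())),
        "weight_c": dict(zip(pids, c_i.tolist())),
        "sigma_eps": wtp.sigma_eps,
        "design_standardized": {k: v.tolist() for k, v in Xz.items()},
        "outcome_log_scales": {d: list(v) for d, v in _OUTCOME_SCALES.items()},
    }

    cohort = SyntheticCohort(
        participants=participants,
        food_log=obs_log,
        outcomes=outcomes,
        weights=weights,
        truth=truth,
    )

    if config.simulate_trial:
        _simulate_intervention(cohort, config, lexicon, food_seeds[n:], ss_trial)
    return cohort


def _true_category_counts(log: pd.DataFrame, lexicon: Lexicon) -> pd.DataFrame:
    """Ground-truth NOVA/drink event counts straight from the source items."""
    from .nova_annotation import DRINK_FLAGS, NOVA_ORDER, annotate_entry, composite_dish_category

    recs = {}
    for pid, grp in log.groupby("participant_id", sort=True):
        row = {f"n_{c}": 0 for c in NOVA_ORDER}
        row.update({f"n_{f}": 0 for f in DRINK_FLAGS})
        for true_items in grp["true_items"]:
            labels = [annotate_entry(i, lexicon) for i in true_items.split("|")]
            informative = [l for l in labels if l.nova != "none"]
            if not informative:
                continue
            lab = composite_dish_category(informative)
            row[f"n_{lab.nova}"] += 1
            for f in lab.drink_flags:
                row[f"n_{f}"] += 1
        recs[pid] = row
    return pd.DataFrame.from_dict(recs, orient="index")


def _realized_duration(log: pd.DataFrame) -> np.ndarray:
    from .eating_window import window_table

    frame = log.copy()
    tbl = window_table(frame.drop(columns=["phase"]))
    return tbl.set_index("participant_id")["duration"].to_numpy()


def _simulate_intervention(
    cohort: SyntheticCohort,
    config: CohortConfig,
    lexicon: Lexicon,
    food_seeds,
    ss_trial: np.random.SeedSequence,
) -> None:
    """Add intervention-phase logs, closeout outcomes and a visits table.

    Compliant TRE participants narrow their window towards the 12 h target
    (with a later start and earlier end); compliant SDA participants shift
    their item mix towards unprocessed foods and away from ultra-processed
    ones.  Closeout weight equals the trajectory value at t = 6 months so the
    outcome table and the weight series agree.
    """
    rng = np.random.default_rng(ss_trial)
    wp = config.window_params
    pids = cohort.participants["participant_id"].tolist()
    arms = cohort.participants["arm"].tolist()
    start0 = cohort.truth["window_start"]
    dur0 = cohort.truth["window_duration"]
    rand_date = pd.Timestamp(_START_DATE) + pd.Timedelta(days=config.days)
    close_date = rand_date + pd.Timedelta(days=180)

    # ultra-processed / unprocessed pools for the SDA mix shift
    from .nova_annotation import annotate_entry

    nova_of = {e: annotate_entry(e, lexicon).nova for e in lexicon.entries}
    logs = [cohort.food_log]
    compliant_truth = {}
    for i, pid in enumerate(pids):
        compliant = bool(rng.random() < config.compliance_rate)
        compliant_truth[pid] = compliant
        start, dur = start0[pid], dur0[pid]
        item_weights = None
        if arms[i] == "TRE" and compliant:
            target = float(np.clip(rng.normal(11.5, 0.5), 9.0, 12.0))
            if target < dur:
                start = start + 0.6 * (dur - target)  # later start, earlier end
                dur = target
        if arms[i] == "SDA" and compliant:
            item_weights = {
                e: (2.5 if nova_of[e] == "NOVA1" else 0.35 if nova_of[e] == "NOVA4" else 1.0)
                for e in nova_of
            }
        logs.append(
            generate_food_log(
                pid,
                config.intervention_days,
                start,
                dur,
                wp.events_per_day,
                lexicon,
                config.typo_rate,
                food_seeds[i],
                outlier_fraction=wp.outlier_fraction,
                special_rate=config.special_rate,
                multi_item_rate=config.multi_item_rate,
                item_weights=item_weights,
                start_date=str(rand_date.date()),
                phase="intervention",
            )
        )
    cohort.food_log = pd.concat(logs, ignore_index=True)
    cohort.truth["compliant"] = compliant_truth

    # closeout outcomes: weight from the trajectory at t=6, others drift mildly
    wt = cohort.weights
    final = wt[wt["t_months"] == wt["t_months"].max()].set_index("participant_id")["weight_kg"]
    post = cohort.outcomes.copy()
    post["weight"] = [final[pid] for pid in pids]
    post["bmi"] = post["weight"] / post["height"] ** 2
    for col in ("waist", "sbp", "dbp", "glucose", "hdl", "triglycerides", "hba1c"):
        post[col] = cohort.outcomes[col] * np.exp(rng.normal(0.0, 0.03, len(post)))
    cohort.outcomes_post = post
    cohort.visits = pd.DataFrame(
        {
            "participant_id": pids,
            "randomisation_date": str(rand_date.date()),
            "closeout_date": str(close_date.date()),
        }
    )


def regression_table(cohort: SyntheticCohort) -> pd.DataFrame:
    """Merge covariates and baseline outcomes into one regression-ready table.

    Sex is coded numerically (female = 1, male = 0) so that coefficient signs
    read as the effect of being female.
    """
    cov = cohort.participants.copy()
    cov["sex"] = (cov["sex"] == "female").astype(float)
    out_cols = ["participant_id"] + list(_OUTCOME_SCALES)
    return cov.merge(cohort.outcomes[out_cols], on="participant_id")


# --------------------------------------------------------------------- #
# persistence


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write a cohort to disk: JSONL + CSV food log, CSV tables, JSON truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    log = cohort.food_log[["participant_id", "timestamp", "text", "phase"]]
    jsonl = outdir / "food_log.jsonl"
    with jsonl.open("w") as fh:
        for rec in log.to_dict(orient="records"):
            fh.write(json.dumps(rec) + "\n")
    paths["food_log_jsonl"] = jsonl
    paths["food_log_csv"] = outdir / "food_log.csv"
    log.to_csv(paths["food_log_csv"], index=False)

    for name, frame in (
        ("participants", cohort.participants),
        ("outcomes", cohort.outcomes),
        ("weights", cohort.weights),
        ("outcomes_post", cohort.outcomes_post),
        ("visits", cohort.visits),
    ):
        if frame is None:
            continue
        paths[name] = outdir / f"{name}.csv"
        frame.to_csv(paths[name], index=False)

    paths["truth"] = outdir / "truth.json"
    with paths["truth"].open("w") as fh:
        json.dump(cohort.truth, fh, indent=2, default=_json_default)
    return paths


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (WindowParams, WeightParams, CohortConfig)):
        return asdict(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
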