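"""Seeded synthetic EMA cohorts with the structure the analysis assumes.

Each patient belongs to a latent low- or high-variability cluster.  The
cluster determines the follow-up length (truncated normal), the target
per-domain variability vector (multivariate normal) and the clinical
feature distributions.  Prompts follow a decaying schedule; at each
prompt one to five of the 32 items are drawn with weights and a
turn-over system so no item repeats within a cycle.  Domain trajectories
are random walks whose increments are calibrated so that the slope-MAD
statistic recovers the drawn target when clipping to [0, 100] is
inactive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import CohortConfig, FeatureSpec
from .items import DOMAINS, default_item_meta
from .preprocess import inverse_rescale

CLUSTERS = ("low", "high")


def halfnormal_mad() -> float:
    """MAD of |eps| for standard normal eps, by root-finding on the CDF.

    median(|eps|) = Phi^-1(0.75) ~ 0.6745 and the MAD around it solves
    Phi(m+c) - Phi(m-c) = 1/4, giving c ~ 0.3991.
    """
    m = stats.norm.ppf(0.75)
    return optimize.brentq(
        lambda c: stats.norm.cdf(m + c) - stats.norm.cdf(m - c) - 0.25, 1e-9, 2.0
    )


#: slope-MAD of a unit-sigma random-walk series (sigma scaling divisor)
HALF_NORMAL_MAD = 0.3990915958298085


def prompt_schedule(followup_days: float, schedule_phases, rng,
                    extend_last: bool = True) -> np.ndarray:
    """Prompt times (fractional days) over a follow-up window.

    Walks through the phases in steps of each phase's period, draws a
    uniform prompt count in [min, max] per period and scatters the
    prompts uniformly within it, keeping only times inside the phase and
    the follow-up window (so partial periods contribute proportionally).
    With `extend_last` the final phase continues past its nominal
    duration until the follow-up ends.
    """
    if followup_days < 0:
        raise ValueError("follow-up length must be nonnegative")
    if followup_days == 0 or not schedule_phases:
        return np.empty(0)
    coverage = sum(ph.duration_days for ph in schedule_phases)
    if coverage < followup_days and not extend_last:
        raise ValueError("schedule phases do not cover the follow-up window")
    times: list[float] = []
    t0 = 0.0
    for i, ph in enumerate(schedule_phases):
        last = i == len(schedule_phases) - 1
        phase_end = followup_days if (last and extend_last) else min(
            t0 + ph.duration_days, followup_days)
        t = t0
        while t < phase_end:
            n = int(rng.integers(ph.min_prompts, ph.max_prompts + 1))
            if n > 0:
                draws = t + rng.uniform(0.0, ph.period_days, size=n)
                times.extend(draws[draws < phase_end])
            t += ph.period_days
        t0 = t0 + ph.duration_days
        if t0 >= followup_days:
            break
    out = np.sort(np.asarray(times))
    # fractional-day draws collide with probability ~0; drop exact ties anyway
    if out.size > 1:
        out = np.concatenate([[out[0]], out[1:][np.diff(out) > 0]])
    return out


def sample_questions(n_items: int, item_weights: np.ndarray,
                     turnover_state: np.ndarray, rng) -> list[int]:
    """Draw items for one prompt under weighted turn-over sampling.

    `turnover_state` is a boolean availability mask over items (True =
    not yet asked in the current cycle), updated in place.  Items are
    drawn one at a time without replacement with probability
    proportional to weight among the available ones; when the cycle is
    exhausted it resets, excluding items already drawn at this prompt.
    Returned ids are positions 0..n-1 into the weight vector.
    """
    w = np.asarray(item_weights, dtype=float)
    if not 1 <= n_items <= len(w):
        raise ValueError("n_items out of range")
    if np.any(w <= 0):
        raise ValueError("item weights must be positive")
    chosen: list[int] = []
    for _ in range(n_items):
        if not turnover_state.any():
            turnover_state[:] = True
            turnover_state[chosen] = False
        cum = np.cumsum(w * turnover_state)
        idx = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        chosen.append(idx)
        turnover_state[idx] = False
    return chosen


def simulate_domain_series(prompt_times: np.ndarray, target_variability: float,
                           baseline: float, rng,
                           clip: tuple[float, float] = (0.0, 100.0)) -> np.ndarray:
    """Random-walk trajectory whose slope-MAD targets `target_variability`.

    Increments are dy = sigma * dt * eps with standard-normal eps and
    sigma = v / MAD(|eps|), so the successive slopes are sigma * eps and
    their |.|-MAD is v in expectation.  Values are clipped to `clip`.
    """
    if target_variability < 0:
        raise ValueError("target variability must be nonnegative")
    t = np.asarray(prompt_times, dtype=float)
    if t.size == 0:
        return np.empty(0)
    sigma = target_variability / HALF_NORMAL_MAD
    eps = rng.standard_normal(t.size - 1)
    y = baseline + np.concatenate([[0.0], np.cumsum(sigma * np.diff(t) * eps)])
    return np.clip(y, clip[0], clip[1])


def simulate_features(labels: pd.DataFrame, feature_spec: list[FeatureSpec],
                      n_noise_features: int, rng,
                      noise_missing_rate: float = 0.0) -> pd.DataFrame:
    """Clinical feature table with cluster signal and missing values.

    Informative features follow their cluster-specific distributions;
    noise features are standard normal in both clusters.  Values are
    masked missing independently at each feature's configured rate.
    """
    n = len(labels)
    is_high = (labels["cluster"] == "high").to_numpy()
    out = pd.DataFrame(index=pd.Index(labels["patient_id"], name="patient_id"))
    for fs in feature_spec:
        if fs.kind == "numeric":
            (m0, s0), (m1, s1) = fs.low, fs.high
            vals = np.where(is_high, rng.normal(m1, s1, n), rng.normal(m0, s0, n))
            col = pd.Series(vals, index=out.index, dtype=float)
        elif fs.kind == "categorical":
            cats = list(fs.low)
            if list(fs.high) != cats:
                raise ValueError(f"feature {fs.name}: category sets differ by cluster")
            p0 = np.asarray([fs.low[c] for c in cats], dtype=float)
            p1 = np.asarray([fs.high[c] for c in cats], dtype=float)
            p0, p1 = p0 / p0.sum(), p1 / p1.sum()
            draws = [
                cats[rng.choice(len(cats), p=(p1 if hi else p0))] for hi in is_high
            ]
            col = pd.Series(draws, index=out.index, dtype=object)
        else:
            raise ValueError(f"unknown feature type {fs.kind!r} for {fs.name}")
        if fs.missing_rate > 0:
            mask = rng.random(n) < fs.missing_rate
            col[mask] = np.nan if fs.kind == "numeric" else None
        out[fs.name] = col
    for j in range(n_noise_features):
        col = pd.Series(rng.standard_normal(n), index=out.index)
        if noise_missing_rate > 0:
            col[rng.random(n) < noise_missing_rate] = np.nan
        out[f"noise_{j + 1:02d}"] = col
    return out


def generate_cohort(config: CohortConfig, seed: int | None = None,
                    item_meta: pd.DataFrame | None = None):
    """Generate one synthetic cohort.

    Returns (ema, features, labels):
      ema       long table patient_id, item_id, t_days, value_raw
      features  per-patient clinical table (NaN/None = missing)
      labels    patient_id, cluster, followup_days and the drawn
                per-domain variability targets (ground truth)
    Fully reproducible given the seed (``config.seed`` unless
    overridden).
    """
    config.validate()
    if item_meta is None:
        item_meta = default_item_meta()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    meta = item_meta.sort_values("item_id").reset_index(drop=True)
    item_ids = meta["item_id"].to_numpy()
    weights = (np.asarray(config.item_weights, dtype=float)
               if config.item_weights is not None
               else meta["weight"].to_numpy(dtype=float))
    domain_of = meta["domain"].to_numpy()

    params = {}
    for name in CLUSTERS:
        mean = np.asarray(config.domain_var_means[name], dtype=float)
        cov = np.asarray(config.domain_var_cov[name], dtype=float)
        try:
            np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"invalid covariance for cluster {name!r}") from exc
        mu_f, sd_f = config.followup_mean_sd[name]
        params[name] = (mean, cov, mu_f, sd_f)

    ema_rows: list[tuple] = []
    label_rows: list[dict] = []
    for pid in range(1, config.n_patients + 1):
        cluster = "low" if rng.random() < config.mix_low else "high"
        mean, cov, mu_f, sd_f = params[cluster]
        a = (config.followup_min_days - mu_f) / sd_f
        followup = float(stats.truncnorm.rvs(a, np.inf, loc=mu_f, scale=sd_f,
                                             random_state=rng))
        targets = np.clip(rng.multivariate_normal(mean, cov),
                          config.min_target_variability, None)
        baselines = rng.uniform(*config.baseline_range, size=len(DOMAINS))

        times = prompt_schedule(followup, config.schedule_phases, rng)
        answered = times[rng.random(times.size) < config.response_rate] \
            if config.response_rate < 1.0 else times

        turnover = np.ones(len(item_ids), dtype=bool)
        prompt_items = []
        for t in answered:
            k = int(rng.integers(config.items_per_prompt[0],
                                 config.items_per_prompt[1] + 1))
            prompt_items.append(sample_questions(k, weights, turnover, rng))

        # evaluate each domain's latent walk at the times its items occur
        for d, dom in enumerate(DOMAINS):
            dom_positions = {i for i in range(len(item_ids)) if domain_of[i] == dom}
            tlist, per_prompt = [], []
            for t, idxs in zip(answered, prompt_items):
                hit = [i for i in idxs if i in dom_positions]
                if hit:
                    tlist.append(t)
                    per_prompt.append(hit)
            if not tlist:
                continue
            values = simulate_domain_series(np.asarray(tlist), targets[d],
                                            baselines[d], rng)
            for t, hit, val in zip(tlist, per_prompt, values):
                for i in hit:
                    row = meta.iloc[i]
                    raw = inverse_rescale(val, row["raw_min"], row["raw_max"],
                                          bool(row["reverse_worded"]))
                    ema_rows.append((pid, int(item_ids[i]), float(t), float(raw)))

        rec = dict(patient_id=pid, cluster=cluster, followup_days=followup)
        rec.update({f"v_{dom}": targets[d] for d, dom in enumerate(DOMAINS)})
        label_rows.append(rec)

    ema = pd.DataFrame(ema_rows, columns=["patient_id", "item_id", "t_days",
                                          "value_raw"])
    ema = ema.sort_values(["patient_id", "t_days", "item_id"]).reset_index(drop=True)
    labels = pd.DataFrame(label_rows)
    feat_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 1]))
    features = simulate_features(labels, config.feature_spec,
                                 config.n_noise_features, feat_rng,
                                 config.noise_missing_rate)
    return ema, features, labels
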