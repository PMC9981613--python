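"""Response rescaling, questionnaire imputation, feature pruning and
Kendall validation of the EMA domains.

All momentary responses are mapped linearly onto 0-100 with 100 the worst
possible condition, flipping reverse-worded items.  Questionnaire scores
use ipsative-mean imputation (a patient's own mean over available items)
with a hard discard above 20% missing items.  The six domains are
validated by requiring significantly positive Kendall tau-b correlations
between items of the same domain, computed across patients on per-patient
mean scaled responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# rescaling

def rescale_responses(responses: pd.DataFrame, item_meta: pd.DataFrame) -> pd.DataFrame:
    """Map raw responses onto the 0-100 'higher = worse' scale.

    `responses` is a long table with columns patient_id, item_id, t_days,
    value_raw.  Returns a copy with an added `value_scaled` column.
    Raises ValueError naming the offending item and patient if a raw value
    falls outside the declared range.
    """
    meta = item_meta.set_index("item_id")
    out = responses.merge(
        meta[["raw_min", "raw_max", "reverse_worded"]],
        left_on="item_id",
        right_index=True,
        how="left",
    )
    if out["raw_min"].isna().any():
        bad = out.loc[out["raw_min"].isna(), "item_id"].unique()
        raise ValueError(f"items without metadata: {sorted(bad)}")
    low = out["value_raw"] < out["raw_min"] - 1e-9
    high = out["value_raw"] > out["raw_max"] + 1e-9
    if (low | high).any():
        row = out[low | high].iloc[0]
        raise ValueError(
            f"raw value {row['value_raw']} outside [{row['raw_min']}, "
            f"{row['raw_max']}] for item {row['item_id']} of patient "
            f"{row['patient_id']}"
        )
    span = out["raw_max"] - out["raw_min"]
    scaled = 100.0 * (out["value_raw"] - out["raw_min"]) / span
    scaled = np.where(out["reverse_worded"], 100.0 - scaled, scaled)
    res = responses.copy()
    res["value_scaled"] = scaled
    return res


def inverse_rescale(scaled: np.ndarray, raw_min: float, raw_max: float,
                    reverse_worded: bool) -> np.ndarray:
    """Inverse of the 0-100 map; exact bijection per item."""
    s = np.asarray(scaled, dtype=float)
    if reverse_worded:
        s = 100.0 - s
    return raw_min + (raw_max - raw_min) * s / 100.0


# ---------------------------------------------------------------------------
# questionnaire scores

def ipsative_impute(items: pd.DataFrame, reverse: dict[str, bool] | None = None,
                    item_range: tuple[float, float] | None = None,
                    max_missing: float = 0.20,
                    aggregate: str = "mean"):
    """Impute a questionnaire's missing items with each patient's own mean.

    `items` holds one questionnaire (or one of its dimensions): rows are
    patients, columns items, NaN means unanswered.  Reverse-scored items
    (per `reverse`) are aligned first using `item_range` (min, max).
    Patients whose missing rate is strictly greater than `max_missing`
    (default 20%) are discarded: their score is NaN and the returned
    mask marks them.

    Returns (scores, imputed_items, discarded_mask).
    """
    mat = items.astype(float).copy()
    if reverse:
        if item_range is None:
            raise ValueError("item_range required to align reverse-scored items")
        lo, hi = item_range
        for col, flag in reverse.items():
            if flag:
                mat[col] = lo + hi - mat[col]
    miss_rate = mat.isna().mean(axis=1)
    discarded = miss_rate > max_missing
    person_mean = mat.mean(axis=1)  # ipsative mean over available items
    imputed = mat.apply(lambda col: col.fillna(person_mean))
    if aggregate == "mean":
        scores = imputed.mean(axis=1)
    elif aggregate == "sum":
        scores = imputed.sum(axis=1)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    scores[discarded | mat.isna().all(axis=1)] = np.nan
    discarded = discarded | mat.isna().all(axis=1)
    return scores, imputed, discarded


def score_change(baseline, followup):
    """Follow-up minus baseline; missing propagates.

    With scores oriented 'higher = worse', a negative change is an
    improvement.
    """
    return followup - baseline


def prune_features(features: pd.DataFrame, min_prevalence: float = 0.05,
                   binary_columns: list[str] | None = None,
                   overall_score_map: dict[str, list[str]] | None = None):
    """Drop marginal binary diagnoses and redundant overall scores.

    Binary columns (auto-detected as two-level categorical/boolean unless
    given explicitly) are removed when the positive class covers fewer
    than `min_prevalence` of all patients.  `overall_score_map` maps an
    instrument's overall-score column to its dimension subscores; the
    overall score is dropped whenever at least one subscore is present.

    Returns (pruned_table, removal_log).
    """
    out = features.copy()
    log: list[dict] = []
    n = len(out)
    if binary_columns is None:
        binary_columns = []
        for col in out.columns:
            vals = out[col].dropna().unique()
            if len(vals) == 2 and not pd.api.types.is_float_dtype(out[col]):
                binary_columns.append(col)
            elif len(vals) <= 2 and set(np.asarray(vals).tolist()) <= {0, 1, 0.0, 1.0}:
                binary_columns.append(col)
    for col in binary_columns:
        if col not in out.columns:
            continue
        vals = out[col]
        positive = vals.isin([1, 1.0, True, "yes"])
        prevalence = positive.sum() / n
        if prevalence < min_prevalence:
            out = out.drop(columns=col)
            log.append(dict(column=col, reason="prevalence", value=prevalence))
    if overall_score_map:
        for overall, subs in overall_score_map.items():
            if overall in out.columns and any(s in out.columns for s in subs):
                out = out.drop(columns=overall)
                log.append(dict(column=overall, reason="overall_with_subscores",
                                value=np.nan))
    return out, pd.DataFrame(log, columns=["column", "reason", "value"])


# ---------------------------------------------------------------------------
# Kendall validation of domains

@dataclass
class KendallReport:
    """Pairwise tau-b matrix, p-values and per-item removal flags."""

    items: list[int]
    tau: pd.DataFrame
    pvalue: pd.DataFrame
    assessable: pd.DataFrame
    fails_within_domain: pd.DataFrame
    removed: dict[int, str] = field(default_factory=dict)

    def removed_items(self) -> list[int]:
        return sorted(self.removed)


def _pair_fails(tau: float, p: float, assessable: bool, alpha: float) -> bool:
    if not assessable:
        return True
    return (tau <= 0) or (p >= alpha)


def kendall_validate_domains(scaled: pd.DataFrame, item_meta: pd.DataFrame,
                             alpha: float = 0.05,
                             min_patients: int = 2) -> KendallReport:
    """Validate that items within each domain correlate positively.

    Per-patient mean scaled responses are computed for every item; tau-b
    (tie-corrected, asymptotic two-sided p) is then evaluated across
    patients for every item pair.  A within-domain pair *fails* when its
    tau is non-positive, non-significant at `alpha`, or not assessable
    (fewer than `min_patients` overlapping patients).  Items are removed
    greedily: while failing within-domain pairs remain, the item involved
    in the most failures is flagged and its pairs dropped, so a single
    discordant item does not drag down its partners.
    """
    per_patient = (
        scaled.pivot_table(index="patient_id", columns="item_id",
                           values="value_scaled", aggfunc="mean")
    )
    items = sorted(item_meta["item_id"])
    domain_of = item_meta.set_index("item_id")["domain"].to_dict()
    k = len(items)
    tau = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    assessable = np.zeros((k, k), dtype=bool)
    for a in range(k):
        for b in range(a + 1, k):
            ia, ib = items[a], items[b]
            if ia not in per_patient.columns or ib not in per_patient.columns:
                continue
            sub = per_patient[[ia, ib]].dropna()
            if len(sub) < min_patients:
                continue
            res = stats.kendalltau(sub[ia], sub[ib], variant="b",
                                   method="asymptotic")
            if np.isnan(res.statistic):
                continue
            tau[a, b] = tau[b, a] = res.statistic
            pval[a, b] = pval[b, a] = res.pvalue
            assessable[a, b] = assessable[b, a] = True

    fails = np.zeros((k, k), dtype=bool)
    for a in range(k):
        for b in range(a + 1, k):
            ia, ib = items[a], items[b]
            if domain_of.get(ia) != domain_of.get(ib):
                continue
            f = _pair_fails(tau[a, b], pval[a, b], assessable[a, b], alpha)
            fails[a, b] = fails[b, a] = f

    removed: dict[int, str] = {}
    active = fails.copy()
    while active.any():
        n_fail = active.sum(axis=1)
        worst = int(np.argmax(n_fail))  # ties -> lowest item index
        partners = [items[j] for j in np.flatnonzero(active[worst])]
        removed[items[worst]] = (
            f"fails within-domain positivity/significance vs {partners}"
        )
        active[worst, :] = False
        active[:, worst] = False

    idx = pd.Index(items, name="item_id")
    return KendallReport(
        items=items,
        tau=pd.DataFrame(tau, index=idx, columns=idx),
        pvalue=pd.DataFrame(pval, index=idx, columns=idx),
        assessable=pd.DataFrame(assessable, index=idx, columns=idx),
        fails_within_domain=pd.DataFrame(fails, index=idx, columns=idx),
        removed=removed,
    )
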