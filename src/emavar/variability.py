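"""The instability statistic: MAD of absolute successive slopes.

For an irregularly sampled series (t_i, y_i) the successive slopes are
s_i = (y_{i+1} - y_i) / (t_{i+1} - t_i); the per-domain variability is
the median absolute deviation of |s_i|, i.e.

    v = median( | |s_i| - median(|s_i|) | )

with no consistency scaling by default.  Units are response points per
day (t is measured in days).  A domain contributes a value only when the
patient answered at least `min_prompts` (default 3) prompts in it, which
yields at least two slopes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .items import DOMAINS

#: multiply MAD by this to make it a consistent sigma estimate for normals
NORMAL_CONSISTENCY = 1.4826022185056018


def successive_slopes(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Slopes between consecutive observations, points per day.

    Requires at least two observations at strictly increasing times.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("t and y must be 1-d arrays of equal length")
    if len(t) < 2:
        raise ValueError("need at least two time points to form a slope")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing (aggregate duplicates first)")
    return np.diff(y) / dt


def mad_abs_slopes(slopes: np.ndarray, consistency: bool = False) -> float:
    """MAD of the absolute slopes; NaN when fewer than two slopes.

    `consistency=True` multiplies by 1.4826 (the normal-consistency
    constant); the default is the plain MAD.
    """
    s = np.abs(np.asarray(slopes, dtype=float))
    if s.size < 2:
        return float("nan")
    v = float(np.median(np.abs(s - np.median(s))))
    return v * NORMAL_CONSISTENCY if consistency else v


def domain_series(scaled: pd.DataFrame, item_meta: pd.DataFrame,
                  removed_items: list[int] | None = None) -> pd.DataFrame:
    """Pool items of each domain into one series per patient and domain.

    Responses to different items of a domain are treated as the same
    question; simultaneous responses (identical timestamp within a
    patient-domain) are averaged so that slopes are always defined.
    Returns a long table (patient_id, domain, t_days, value) sorted by
    time.
    """
    removed = set(removed_items or [])
    meta = item_meta.set_index("item_id")
    unknown = set(meta["domain"].unique()) - set(DOMAINS)
    if unknown:
        raise ValueError(f"unknown domains in item metadata: {sorted(unknown)}")
    df = scaled[~scaled["item_id"].isin(removed)].merge(
        meta[["domain"]], left_on="item_id", right_index=True
    )
    pooled = (
        df.groupby(["patient_id", "domain", "t_days"], as_index=False)["value_scaled"]
        .mean()
        .rename(columns={"value_scaled": "value"})
        .sort_values(["patient_id", "domain", "t_days"])
    )
    return pooled


def patient_variability_matrix(scaled: pd.DataFrame, item_meta: pd.DataFrame,
                               removed_items: list[int] | None = None,
                               min_prompts: int = 3,
                               consistency: bool = False):
    """Patient x domain matrix of slope-MAD variability values.

    Entries are NaN where the patient answered fewer than `min_prompts`
    prompts in the domain.  Patients with no computable domain at all are
    excluded and returned in the second element.

    Returns (matrix, excluded, prompt_counts); matrix columns follow the
    canonical domain order, prompt_counts mirrors its shape.
    """
    pooled = domain_series(scaled, item_meta, removed_items)
    patients = sorted(scaled["patient_id"].unique())
    mat = pd.DataFrame(np.nan, index=pd.Index(patients, name="patient_id"),
                       columns=DOMAINS)
    counts = pd.DataFrame(0, index=mat.index, columns=DOMAINS, dtype=int)
    for (pid, dom), grp in pooled.groupby(["patient_id", "domain"]):
        counts.loc[pid, dom] = len(grp)
        if len(grp) >= min_prompts:
            s = successive_slopes(grp["t_days"].to_numpy(), grp["value"].to_numpy())
            mat.loc[pid, dom] = mad_abs_slopes(s, consistency=consistency)
    keep = mat.notna().any(axis=1)
    excluded = list(mat.index[~keep])
    return mat[keep], excluded, counts[keep]
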