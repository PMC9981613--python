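"""Cohort and run configuration objects with YAML round-tripping.

The cohort defaults encode the study conditions the analysis assumes:
275 patients, a 65/35 low/high-variability mixture, cluster-specific
follow-up lengths of 148(116) vs 98(66) days (truncated at 7), a prompt
schedule that decays from 4-5 prompts per week in the first month to 1-2
per week after month three, and a clinical feature table whose
informative columns follow the group summaries of the cohort's
phenotypic comparison table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import yaml

from .items import DOMAINS


@dataclass
class SchedulePhase:
    duration_days: float
    min_prompts: int
    max_prompts: int
    period_days: float = 7.0


@dataclass
class FeatureSpec:
    """One clinical feature of the synthetic table.

    numeric: low/high are (mean, sd) per cluster.
    categorical: low/high map category -> probability per cluster.
    """

    name: str
    kind: str  # "numeric" | "categorical"
    low: Any
    high: Any
    missing_rate: float = 0.0


def _default_schedule() -> list[SchedulePhase]:
    return [
        SchedulePhase(30.0, 4, 5, 7.0),
        SchedulePhase(60.0, 3, 4, 7.0),
        SchedulePhase(90.0, 1, 2, 7.0),
    ]


# Cluster-level variability targets (points/day).  Social withdrawal is the
# most variable domain in both clusters; the high cluster's sleep and
# suicide-risk means sit 4.53x and 2.31x above the low cluster's.  The
# magnitudes are chosen so that the random-walk trajectories rarely reach
# the 0/100 bounds over a months-long follow-up, keeping the slope-MAD
# statistic recoverable.
_LOW_MEANS = np.array([0.13, 0.12, 0.11, 0.30, 0.08, 0.10])
_FOLD = np.array([2.31, 2.20, 2.00, 1.50, 4.53, 1.80])
_HIGH_MEANS = _LOW_MEANS * _FOLD


def _equicorr_cov(sds: np.ndarray, rho: float,
                  anti_idx: int | None = None, anti_rho: float = 0.0) -> np.ndarray:
    d = len(sds)
    corr = np.full((d, d), rho)
    np.fill_diagonal(corr, 1.0)
    if anti_idx is not None:
        corr[anti_idx, :] = anti_rho
        corr[:, anti_idx] = anti_rho
        corr[anti_idx, anti_idx] = 1.0
    return corr * np.outer(sds, sds)


def _default_cov_low() -> np.ndarray:
    # homogeneous cluster: smaller spread, all-positive covariances
    return _equicorr_cov(0.25 * _LOW_MEANS, 0.30)


def _default_cov_high() -> np.ndarray:
    # heterogeneous cluster: sleep variability anti-correlates with the rest
    sleep = DOMAINS.index("sleep")
    return _equicorr_cov(0.45 * _HIGH_MEANS, 0.25, anti_idx=sleep, anti_rho=-0.20)


def default_feature_spec() -> list[FeatureSpec]:
    """Ten informative features mirroring the cohort's group summaries.

    Numeric parameters are the per-cluster (mean, sd) pairs of the
    phenotypic comparison table; categorical parameters its per-cluster
    proportions; missing rates its per-row available-n counts.
    """
    marital_low = {"married": 0.3876, "separated": 0.2079,
                   "widowed": 0.0281, "single": 0.3764}
    marital_high = {"married": 0.3053, "separated": 0.0947,
                    "widowed": 0.0105, "single": 0.5895}
    return [
        FeatureSpec("depression_ids_baseline", "numeric", (34.53, 14.44), (38.98, 16.66), 0.051),
        FeatureSpec("bis_cognitive_instability", "numeric", (48.97, 23.56), (51.58, 24.13), 0.265),
        FeatureSpec("marital_status", "categorical", marital_low, marital_high, 0.007),
        FeatureSpec("cssrs_si_frequency_baseline", "numeric", (3.08, 1.37), (3.33, 1.51), 0.342),
        FeatureSpec("cssrs_si_frequency_change", "numeric", (-0.33, 1.13), (-0.59, 1.96), 0.705),
        FeatureSpec("cssrs_si_intensity_change", "numeric", (-0.61, 1.49), (-0.48, 1.48), 0.673),
        FeatureSpec("cssrs_si_control_change", "numeric", (0.23, 2.09), (-0.23, 1.50), 0.695),
        FeatureSpec("ftnd_nicotine_baseline", "numeric", (17.95, 27.10), (20.94, 29.93), 0.273),
        FeatureSpec("binge_eating_disorder", "categorical",
                    {"no": 0.9497, "yes": 0.0503}, {"no": 0.8542, "yes": 0.1458}, 0.0),
        FeatureSpec("clinical_events_followup", "categorical",
                    {"no": 0.7778, "yes": 0.2222}, {"no": 0.6848, "yes": 0.3152}, 0.044),
    ]


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator."""

    n_patients: int = 275
    mix_low: float = 0.65
    domain_var_means: dict = field(default_factory=lambda: {
        "low": _LOW_MEANS.copy(), "high": _HIGH_MEANS.copy()})
    domain_var_cov: dict = field(default_factory=lambda: {
        "low": _default_cov_low(), "high": _default_cov_high()})
    followup_mean_sd: dict = field(default_factory=lambda: {
        "low": (148.0, 116.0), "high": (98.0, 66.0)})
    followup_min_days: float = 7.0
    schedule_phases: list = field(default_factory=_default_schedule)
    items_per_prompt: tuple = (1, 5)
    item_weights: Any = None  # default: from item metadata
    response_rate: float = 1.0
    baseline_range: tuple = (30.0, 70.0)
    feature_spec: list = field(default_factory=default_feature_spec)
    n_noise_features: int = 15
    noise_missing_rate: float = 0.10
    min_target_variability: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.mix_low < 1.0 and self.mix_low != 1.0:
            raise ValueError("mix_low must lie in (0, 1]")
        if not 0.0 <= self.response_rate <= 1.0:
            raise ValueError("response_rate must lie in [0, 1]")
        for name in ("low", "high"):
            means = np.asarray(self.domain_var_means[name], dtype=float)
            if means.shape != (len(DOMAINS),) or np.any(means <= 0):
                raise ValueError(f"variability means of cluster {name!r} must be "
                                 f"{len(DOMAINS)} positive values")
            cov = np.asarray(self.domain_var_cov[name], dtype=float)
            if not np.allclose(cov, cov.T):
                raise ValueError(f"covariance of cluster {name!r} not symmetric")
            if np.linalg.eigvalsh(cov).min() < -1e-8:
                raise ValueError(f"covariance of cluster {name!r} not positive "
                                 "semidefinite")
        for ph in self.schedule_phases:
            if ph.min_prompts > ph.max_prompts or ph.min_prompts < 0:
                raise ValueError("invalid prompt range in schedule phase")


# ---------------------------------------------------------------------------
# YAML round-trip helpers

def _to_plain(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def cohort_config_to_dict(cfg: CohortConfig) -> dict:
    return _to_plain(asdict(cfg))


def cohort_config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    if "schedule_phases" in d:
        d["schedule_phases"] = [
            SchedulePhase(**ph) if isinstance(ph, dict) else SchedulePhase(*ph)
            for ph in d["schedule_phases"]
        ]
    if "feature_spec" in d:
        d["feature_spec"] = [
            FeatureSpec(**fs) if isinstance(fs, dict) else fs
            for fs in d["feature_spec"]
        ]
    for key in ("domain_var_means", "domain_var_cov"):
        if key in d:
            d[key] = {k: np.asarray(v, dtype=float) for k, v in d[key].items()}
    if "items_per_prompt" in d:
        d["items_per_prompt"] = tuple(d["items_per_prompt"])
    if "baseline_range" in d:
        d["baseline_range"] = tuple(d["baseline_range"])
    return CohortConfig(**d)


def save_cohort_config(cfg: CohortConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cohort_config_to_dict(cfg), fh, sort_keys=False)


def load_cohort_config(path) -> CohortConfig:
    with open(path) as fh:
        return cohort_config_from_dict(yaml.safe_load(fh))
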