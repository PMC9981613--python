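"""End-to-end orchestration: simulate -> preprocess -> variability ->
cluster -> classify -> compare.

One global seed fans out deterministically to per-stage seeds through
`numpy.random.SeedSequence([seed, stage_index])`, so any stage can be
rerun in isolation.  Every stage writes CSV/YAML outputs with the seed
recorded in a header comment, and the run manifest records row counts
and SHA-256 hashes so a rerun with the same config can be verified
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import CohortConfig, cohort_config_to_dict
from .forest import ForestParams, fit_forest, oob_predict, roc_auc_ci, \
    forward_select, feature_importance
from .gmm import select_k, assign_labels
from .group_stats import compare_clusters
from .items import DOMAINS, default_item_meta
from .preprocess import kendall_validate_domains, rescale_responses
from .synthetic import generate_cohort
from .variability import patient_variability_matrix

STAGES = ["simulate", "preprocess", "variability", "cluster", "classify",
          "compare"]


@dataclass
class RunConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    k_range: tuple = (1, 5)
    em_restarts: int = 10
    forest: ForestParams = field(default_factory=lambda: ForestParams(n_trees=100))
    max_features: int = 15
    min_gain: float = 0.001
    run_forward_selection: bool = True
    roc_bootstrap: int = 2000
    stages: tuple = tuple(STAGES)

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        order = [s for s in STAGES if s in self.stages]
        deps = {"preprocess": "simulate", "variability": "preprocess",
                "cluster": "variability", "classify": "cluster",
                "compare": "cluster"}
        for stage, dep in deps.items():
            if stage in order and dep not in order:
                raise ValueError(f"stage {stage!r} requires {dep!r}")


def stage_seed(seed: int, stage: str) -> int:
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))


def _write_csv(df: pd.DataFrame, path: Path, seed: int, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=index)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the configured stages, returning the manifest dict."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}, "files": {}}
    ctx: dict = {}
    current = {"stage": None}

    def record(stage: str, files: list[Path], **info):
        manifest["stages"][stage] = {"seed": stage_seed(config.seed, stage),
                                     **info}
        for f in files:
            manifest["files"][f.name] = _sha256(f)

    try:
        if "simulate" in config.stages:
            current["stage"] = "simulate"
            s = stage_seed(config.seed, "simulate")
            ema, features, labels = generate_cohort(config.cohort, seed=s)
            meta = default_item_meta()
            ctx.update(ema=ema, features=features, true_labels=labels, meta=meta)
            f1, f2, f3 = out / "ema_long.csv", out / "features.csv", out / "true_labels.csv"
            _write_csv(ema, f1, s)
            _write_csv(features.reset_index(), f2, s)
            _write_csv(labels, f3, s)
            f4 = out / "cohort_config.yaml"
            with open(f4, "w") as fh:
                yaml.safe_dump({"seed": s, **cohort_config_to_dict(config.cohort)},
                               fh, sort_keys=False)
            record("simulate", [f1, f2, f3, f4], n_answers=len(ema),
                   n_patients=len(labels))

        if "preprocess" in config.stages:
            current["stage"] = "preprocess"
            s = stage_seed(config.seed, "preprocess")
            scaled = rescale_responses(ctx["ema"], ctx["meta"])
            report = kendall_validate_domains(scaled, ctx["meta"])
            ctx.update(scaled=scaled, removed_items=report.removed_items())
            f1 = out / "ema_scaled.csv"
            _write_csv(scaled, f1, s)
            f2 = out / "kendall_report.csv"
            long = report.tau.stack().rename("tau").to_frame()
            long["pvalue"] = report.pvalue.stack()
            long["fails_within_domain"] = report.fails_within_domain.stack()
            _write_csv(long.reset_index(names=["item_a", "item_b"]), f2, s)
            record("preprocess", [f1, f2], removed_items=report.removed_items())

        if "variability" in config.stages:
            current["stage"] = "variability"
            s = stage_seed(config.seed, "variability")
            mat, excluded, counts = patient_variability_matrix(
                ctx["scaled"], ctx["meta"], ctx.get("removed_items"))
            ctx.update(vmat=mat, excluded=excluded)
            f1 = out / "variability_matrix.csv"
            both = mat.add_prefix("v_").join(counts.add_prefix("n_"))
            _write_csv(both.reset_index(), f1, s)
            record("variability", [f1], n_included=len(mat),
                   n_excluded=len(excluded))

        if "cluster" in config.stages:
            current["stage"] = "cluster"
            s = stage_seed(config.seed, "cluster")
            X = ctx["vmat"].to_numpy()
            best_k, models, table = select_k(
                X, range(config.k_range[0], config.k_range[1] + 1),
                seed=s, n_restarts=config.em_restarts)
            model = models[best_k]
            # downstream stages compare/classify the two-group solution;
            # the low/high labelling therefore always comes from the K=2 fit
            if 2 not in models:
                raise RuntimeError("no two-component fit available for labelling")
            assign = assign_labels(models[2])
            ctx.update(gmm=model, best_k=best_k, assign=assign)
            f1 = out / "bic_table.csv"
            _write_csv(table.reset_index(), f1, s)
            f2 = out / "cluster_assignments.csv"
            adf = pd.DataFrame({"patient_id": ctx["vmat"].index,
                                "label": assign["labels"]})
            if assign["posterior"] is not None:
                adf["posterior_low"] = assign["posterior"]
            _write_csv(adf, f2, s)
            ctx["assign_df"] = adf
            two = models[2]
            ctx["gmm2"] = two
            f3 = out / "gmm_model.yaml"
            with open(f3, "w") as fh:
                yaml.safe_dump({
                    "seed": s, "K": int(best_k),
                    "weights": two.weights.tolist(),
                    "means": {d: two.means[:, i].tolist()
                              for i, d in enumerate(DOMAINS)},
                    "covariances": [c.tolist() for c in two.covariances],
                    "bic": float(two.bic),
                    "mixing_share_low": assign.get("mixing_share"),
                    "hard_share_low": assign.get("hard_share"),
                }, fh, sort_keys=False)
            record("cluster", [f1, f2, f3], best_k=int(best_k),
                   mixing_share_low=assign.get("mixing_share"),
                   hard_share_low=assign.get("hard_share"))

        if "classify" in config.stages:
            current["stage"] = "classify"
            s = stage_seed(config.seed, "classify")
            feats = ctx["features"].loc[ctx["vmat"].index]
            y = ctx["assign_df"]["label"].to_numpy()
            files = []
            if config.run_forward_selection:
                selected, trace = forward_select(
                    feats, y, config.forest, max_features=config.max_features,
                    min_gain=config.min_gain, seed=s)
                f0 = out / "forward_selection_trace.csv"
                _write_csv(trace, f0, s)
                files.append(f0)
            else:
                selected = list(feats.columns)
            use = feats[selected] if selected else feats
            forest = fit_forest(use, y, config.forest, seed=s)
            scores = oob_predict(forest)
            roc = roc_auc_ci(scores, y, n_boot=config.roc_bootstrap, seed=s)
            imp = feature_importance(forest)
            ctx.update(selected=selected, roc=roc, forest=forest)
            f1 = out / "selected_features.csv"
            _write_csv(pd.DataFrame({"feature": selected}), f1, s)
            f2 = out / "roc_points.csv"
            _write_csv(pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr}), f2, s)
            f3 = out / "importance.csv"
            imp_df = imp.rename("importance").rename_axis("feature").reset_index()
            _write_csv(imp_df, f3, s)
            record("classify", files + [f1, f2, f3],
                   oob_auc=float(roc.auc), ci=list(roc.ci),
                   n_selected=len(selected))

        if "compare" in config.stages:
            current["stage"] = "compare"
            s = stage_seed(config.seed, "compare")
            feats = ctx["features"].loc[ctx["vmat"].index]
            y = ctx["assign_df"]["label"].to_numpy()
            table = compare_clusters(feats, y)
            f1 = out / "cluster_comparison.csv"
            _write_csv(table, f1, s)
            record("compare", [f1],
                   n_nominal=int(table["significant_nominal"].sum()),
                   n_holm=int(table["significant_holm"].sum()))
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {current['stage']!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
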