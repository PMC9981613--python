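"""Phenotypic comparison of the two clusters: pooled t / chi-squared
homogeneity per feature with Holm multiple-comparison correction."""

import warnings

from emavar.pipeline import RunConfig, read_csv, run_pipeline

SEED = 1
OUT = "results/run"


def main() -> None:
    cfg = RunConfig(seed=SEED, stages=("simulate", "preprocess",
                                       "variability", "cluster", "compare"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        manifest = run_pipeline(cfg, OUT)
    info = manifest["stages"]["compare"]
    table = read_csv(f"{OUT}/cluster_comparison.csv")
    nominal = table[table["significant_nominal"] == True]  # noqa: E712
    print(f"{info['n_nominal']} features nominally significant at 0.05, "
          f"{info['n_holm']} after Holm correction")
    cols = ["feature", "kind", "statistic", "p_nominal", "p_holm"]
    if len(nominal):
        print(nominal[cols].to_string(index=False))


if __name__ == "__main__":
    main()
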