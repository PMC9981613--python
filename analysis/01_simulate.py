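"""Generate the default synthetic cohort and describe its shape.

Writes the EMA long table, the clinical feature table and the ground-truth
labels under results/run/.
"""

from emavar.pipeline import RunConfig, run_pipeline

SEED = 1
OUT = "results/run"


def main() -> None:
    cfg = RunConfig(seed=SEED, stages=("simulate",))
    manifest = run_pipeline(cfg, OUT)
    info = manifest["stages"]["simulate"]
    print(f"cohort: {info['n_patients']} patients, "
          f"{info['n_answers']} answered EMA questions "
          f"(~{info['n_answers'] / info['n_patients']:.0f} per patient)")
    print(f"outputs in {OUT}/: ema_long.csv, features.csv, true_labels.csv")


if __name__ == "__main__":
    main()
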