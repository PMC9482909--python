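#!/usr/bin/env python
"""QC-filter, annotate and level the simulated cohort.

Runs the pipeline through confidence-level assignment (QC RSD filter,
spectral library search, suspect screening, formula annotation, the three
rule schemes) and prints the per-scheme level tallies.  Outputs land under
results/run/ (qc_stats.csv, annotation.csv, suspect_hits*.csv).
"""

from exposcreen.config import RunConfig
from exposcreen.pipeline import run_pipeline


def main() -> None:
    cfg = RunConfig(dataset_dir="results/dataset", out_dir="results/run")
    res = run_pipeline(cfg, through_stage="levels")
    n_in = len(res["data"]["features"])
    print(f"QC filter: {n_in} -> {len(res['retained'])} features (RSD < {cfg.qc_rsd_max_pct}%)")
    print(f"suspect hits: {len(res['hits'])}")
    for scheme, counts in res["level_counts"].items():
        ordered = {k: counts[k] for k in sorted(counts)}
        print(f"  {scheme}: {ordered}")


if __name__ == "__main__":
    main()
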