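#!/usr/bin/env python
"""Cross-mode overlap and pathway over-representation.

Compares annotated InChIKey sets across ESI modes and LC modes, then runs
hypergeometric over-representation of the selected compounds against the
pathway definitions.  Writes overlap_*.csv and ora.csv under results/run/.
"""

from exposcreen.config import RunConfig
from exposcreen.pipeline import run_pipeline


def main() -> None:
    cfg = RunConfig(dataset_dir="results/dataset", out_dir="results/run")
    res = run_pipeline(cfg, through_stage="ora")
    for axis, rep in res["overlap"].items():
        print(f"overlap by {axis}: sets {rep.set_names}, union {rep.union_size}, "
              f"no-key excluded {rep.excluded_count}")
        for _, row in rep.to_frame().iterrows():
            if row["count"]:
                print(f"  {row['sets']}: {row['count']}")
    print("pathway over-representation (hypergeometric upper tail):")
    for r in res["ora"]:
        print(f"  {r.pathway_id}: {r.hits}/{r.pathway_size} hits, p = {r.p_value:.4g}")


if __name__ == "__main__":
    main()
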