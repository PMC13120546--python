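#!/usr/bin/env python
"""Daily FSI trajectories and the cohort symmetry table.

Recomputes each subject's session FSI for every day from freshly generated
streams, prints the per-subject Day-1 / Day-15 / improvement table with
cohort means, and writes the table CSV plus a JSON summary. With noise
switched off this reproduces the published values exactly; with the default
sensor noise the cohort means land within a few thousandths.
"""

import argparse
import json
from pathlib import Path

from gaitwalker import pipeline, symmetry, synth


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--noise-sd", type=float, default=0.0,
                    help="force sensor noise (N); 0 reproduces the table exactly")
    args = ap.parse_args()

    cohort = synth.default_cohort(seed=args.seed, noise_sd_force=args.noise_sd)
    rows = []
    for p in cohort.subjects:
        d1 = symmetry.session_fsi(synth.generate_force_pair(p, 1, cohort))
        d15 = symmetry.session_fsi(
            synth.generate_force_pair(p, cohort.n_days, cohort))
        rows.append((p.subject_id, d1, d15))
    summary = symmetry.cohort_summary(rows)
    print(pipeline.render_table4_report(summary))

    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "symmetry_table.csv").write_text(pipeline.table4_csv(summary))
    (args.out / "symmetry_summary.json").write_text(json.dumps({
        "mean_fsi_day1": summary.mean_fsi_day1,
        "mean_fsi_day15": summary.mean_fsi_day15,
        "mean_improvement_pct": summary.mean_improvement_pct,
        "noise_sd_force": args.noise_sd, "seed": args.seed,
    }, indent=2, sort_keys=True))
    print(f"\nwrote {args.out / 'symmetry_table.csv'}")


if __name__ == "__main__":
    main()
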