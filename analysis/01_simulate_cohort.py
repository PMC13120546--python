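#!/usr/bin/env python
"""Generate the synthetic ten-subject, 15-day multimodal cohort.

Writes one force-stream CSV per subject and day (with a JSON metadata
sidecar on the first stream), using the published per-subject Day-1/Day-15
FSI profiles as generation targets. Downstream scripts re-derive everything
from these files or regenerate streams on the fly.
"""

import argparse
from pathlib import Path

from gaitwalker import io, synth


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/cohort"))
    ap.add_argument("--session-seconds", type=float, default=60.0)
    args = ap.parse_args()

    cohort = synth.default_cohort(seed=args.seed,
                                  session_length_s=args.session_seconds)
    n_files = 0
    for p in cohort.subjects:
        for day in range(1, cohort.n_days + 1):
            df = synth.generate_force_pair(p, day, cohort)
            meta = {"seed": cohort.seed, "subject": p.subject_id, "day": day,
                    "fs_force": cohort.fs_force,
                    "noise_sd_force": cohort.noise_sd_force} if day == 1 else None
            io.write_stream(
                df, args.out / f"{p.subject_id.replace(' ', '_')}_day{day:02d}.csv",
                "force", metadata=meta)
            n_files += 1
    print(f"wrote {n_files} force streams for {len(cohort.subjects)} subjects "
          f"x {cohort.n_days} days under {args.out}")
    print(f"each stream: {int(cohort.session_length_s * cohort.fs_force)} samples "
          f"at {cohort.fs_force:.0f} Hz, force noise sd {cohort.noise_sd_force} N")


if __name__ == "__main__":
    main()
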