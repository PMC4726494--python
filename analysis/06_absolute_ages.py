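#!/usr/bin/env python
"""Absolute-time conversion: the final calibration step.

Reads the outputs of 03_clone_age.py and 05_msc_dating.py (running them
first if needed is up to the user), converts the MSC divergence times to
MYA through a synthetic outgroup split, and assembles the dated summary —
clone age in years beside speciation times in MYA, all on the shared
calibration.  Writes results/absolute_ages.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from cobitis.calib import absolute_speciation_times


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--clone-age", default="results/clone_age.json")
    ap.add_argument("--msc", default="results/msc_dating.json")
    ap.add_argument("--outgroup-age", type=float, default=16.17,
                    help="MYA; divergence of the outgroup from the ingroup")
    ap.add_argument("--outgroup-tau", type=float, default=0.05,
                    help="expected substitutions/site at the outgroup split")
    ap.add_argument("--out", default="results/absolute_ages.json")
    args = ap.parse_args()

    clone = json.loads(Path(args.clone_age).read_text())
    msc = json.loads(Path(args.msc).read_text())

    report = {"outgroup_age_mya": args.outgroup_age,
              "clone_age_mya": clone["age_theta_propagated"]["age_mya"],
              "clone_age_ci_mya": [clone["age_theta_propagated"]["ci_low_years"] / 1e6,
                                   clone["age_theta_propagated"]["ci_high_years"] / 1e6],
              "speciation_mya": {}}
    print(f"clone age: {report['clone_age_mya']:.3f} MYA "
          f"(95% {report['clone_age_ci_mya'][0]:.3f}-{report['clone_age_ci_mya'][1]:.3f})")
    for key in ("tau_TN", "tau_TNE"):
        post = msc["posterior"][key]
        mean_samples = np.array([post["ci"][0], post["mean"], post["ci"][1]])
        mya, _ = absolute_speciation_times(mean_samples, args.outgroup_tau,
                                           args.outgroup_age)
        report["speciation_mya"][key] = {"mean": mya[1], "ci": [mya[0], mya[2]]}
        print(f"{key}: {mya[1]:.2f} MYA (95% {mya[0]:.2f}-{mya[2]:.2f})")

    out = Path(args.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
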