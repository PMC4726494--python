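#!/usr/bin/env python
"""Study-design summary: individuals, metaphases, GISH experiments.

Recomputes per-biotype and per-age-class totals from the locality-level
table and writes results/cohort_summary.json.
"""

import argparse
import json
from pathlib import Path

from cobitis.cohort import aggregate_cohort, load_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", default="results/cohort_summary.json")
    args = ap.parse_args()

    records = load_cohort()
    by_biotype = aggregate_cohort(records, "biotype")
    by_age = aggregate_cohort(records, "age_class")
    hybrids = aggregate_cohort(records, "all-hybrids")["all-hybrids"]

    print(f"{len(records)} locality records, "
          f"{sum(r.noi for r in records)} individuals")
    print(f"hybrids: {hybrids['noi']} individuals, "
          f"{hybrids['nomka']} metaphases inspected, "
          f"{hybrids['noge']} GISH experiments")
    for bt, agg in sorted(by_biotype.items()):
        print(f"  {bt:4s} NOI {agg['noi']:3d}  NOMKA {agg['nomka']:3d}")

    out = Path(args.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps({
        "by_biotype": by_biotype, "by_age_class": by_age,
        "all_hybrids": hybrids,
    }, indent=2, sort_keys=True) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
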