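#!/usr/bin/env python
"""Call locus copy number from the simulated ddPCR droplet counts.

The target amplicon was simulated at the same template concentration as the
two two-copy reference amplicons (expected CN = 2, i.e. copy-neutral LOH),
and the control amplicon at half that concentration (expected CN = 1).
Writes results/ddpcr_copy_number.json.
"""

import json
from pathlib import Path

from lohkit import io
from lohkit.ddpcr import copy_number

RESULTS = Path(__file__).resolve().parent.parent / "results"
SIM = RESULTS / "simulated"
REFS = ("REF_LEFT", "REF_RIGHT")


def main() -> None:
    assays = {a.amplicon_id: a for a in io.read_ddpcr_csv(SIM / "ddpcr.csv")}
    ref1, ref2 = (assays[r] for r in REFS)
    out = {"lambda": {aid: round(a.lam, 5) for aid, a in assays.items()}, "calls": {}}
    print(f"reference concentrations: {ref1.amplicon_id}={ref1.lam:.4f}, "
          f"{ref2.amplicon_id}={ref2.lam:.4f} copies/droplet")
    for aid, assay in sorted(assays.items()):
        if aid in REFS:
            continue
        call = copy_number(assay.lam, ref1.lam, ref2.lam, target_id=aid)
        out["calls"][aid] = {"CN": call.CN, "integer": call.integer}
        print(f"  {aid}: lambda={assay.lam:.4f} -> CN={call.CN:.3f} "
              f"(integer call: {call.integer})")

    (RESULTS / "ddpcr_copy_number.json").write_text(json.dumps(out, indent=2) + "\n")
    print(f"copy numbers -> {RESULTS / 'ddpcr_copy_number.json'}")


if __name__ == "__main__":
    main()
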