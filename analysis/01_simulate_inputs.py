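#!/usr/bin/env python
"""Generate the synthetic study inputs every later analysis step consumes.

Emulates the case-study's data layout: a phased heterozygous marker map for
a small three-chromosome diploid genome with a recessive causal locus
(A8 wild / A7 mutant homopolymer alleles, mutant on the M homolog), fourteen
four-spore tetrads, an all-pairs cross panel, twenty selected LOH clones,
a 24-culture fluctuation assay and a four-amplicon ddPCR run. Everything is
written under results/simulated/ together with the planted truth.
"""

from pathlib import Path

from lohkit.cli import simulate_all

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "simulated"
SEED = 7


def main() -> None:
    simulate_all.callback(outdir=str(OUTDIR), seed=SEED, n_tetrads=14, config_path=None)
    print(f"simulated inputs written to {OUTDIR} (seed {SEED})")
    for name in sorted(p.name for p in OUTDIR.iterdir()):
        print(f"  {name}")


if __name__ == "__main__":
    main()
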