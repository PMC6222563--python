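#!/usr/bin/env python
"""Build a phased high-confidence marker map from simulated tetrad calls.

Simulates fourteen tetrads with 2% genotyping error and 1% missing calls,
applies the high-confidence filter (biallelic + 2:2 in every complete
tetrad), phases each chromosome by greedy adjacent-marker linkage, and
scores the result against the planted phase. Writes the phased map and a
per-chromosome summary under results/.
"""

from collections import Counter
from pathlib import Path

import pandas as pd

from lohkit import io
from lohkit.phasing import PhasedMarkerMap, filter_high_confidence, phase_chromosome
from lohkit.simulate import (
    MeiosisConfig,
    RecessiveLocusModel,
    default_config,
    simulate_parent,
    simulate_tetrads,
    sites_from_spores,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 7


def main() -> None:
    config = default_config()
    locus = RecessiveLocusModel(chrom="chr01", pos=280_000)
    truth_map, _ = simulate_parent(config, seed=SEED, locus=locus)
    sim = simulate_tetrads(
        truth_map, config,
        MeiosisConfig(crossover_rate=1.0, error_rate=0.02, missing_rate=0.01),
        n_tetrads=14, seed=SEED + 1,
    )
    sites = sites_from_spores(truth_map, sim)
    verdicts = [filter_high_confidence(s) for s in sites]
    reasons = Counter(v.reason for v in verdicts if not v.keep)
    kept_by_chrom: dict[str, list] = {}
    for site, v in zip(sites, verdicts):
        if v.keep:
            kept_by_chrom.setdefault(site.chrom, []).append(site)

    print(f"{len(sites)} candidate sites from 14 tetrads "
          f"(2% allele error, 1% missing)")
    print(f"  kept {sum(v.keep for v in verdicts)}; dropped by reason: {dict(reasons)}")

    rows = []
    all_markers = []
    for chrom, chrom_sites in sorted(kept_by_chrom.items()):
        frag, conf = phase_chromosome(chrom_sites)
        all_markers.extend(frag.markers)
        truth = {m.pos: m for m in truth_map.chromosome(chrom)}
        first = truth[frag.markers[0].pos]
        flip = min(first.allele_M, first.allele_P) != first.allele_M
        agree = sum(
            (truth[m.pos].allele_P if flip else truth[m.pos].allele_M) == m.allele_M
            for m in frag.markers)
        n_blocks = len(set(frag.provenance["blocks"].values()))
        rows.append({
            "chrom": chrom, "markers": len(frag), "blocks": n_blocks,
            "min_adjacency_confidence": round(min(conf), 3),
            "phase_accuracy": round(agree / len(frag), 4),
        })
        print(f"  {chrom}: {len(frag)} markers in {n_blocks} block(s), "
              f"min adjacency confidence {min(conf):.3f}, "
              f"planted phase recovered at {agree}/{len(frag)} markers")

    RESULTS.mkdir(exist_ok=True)
    io.write_marker_map(PhasedMarkerMap(all_markers), RESULTS / "phased_map.tsv")
    pd.DataFrame(rows).to_csv(RESULTS / "phasing_summary.tsv", sep="\t", index=False)
    print(f"phased map -> {RESULTS / 'phased_map.tsv'}")


if __name__ == "__main__":
    main()
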