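"""Tetrad-filter and phasing behaviour against planted truth."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from lohkit.phasing import (
    AlleleMismatchError,
    PhasedMarker,
    PhasedMarkerMap,
    SiteCalls,
    encode_against_map,
    filter_high_confidence,
    phase_chromosome,
)
from lohkit.simulate import MeiosisConfig, SimGenomeConfig, ChromosomeSpec, \
    simulate_parent, simulate_tetrads, sites_from_spores


def _site(allele_by_spore: dict[str, str | None], n_tetrads: int | None = None) -> SiteCalls:
    spores = sorted(allele_by_spore)
    tetrad_of = {sp: f"T{int(i // 4) + 1}" for i, sp in enumerate(spores)}
    return SiteCalls("chrA", 1000, allele_by_spore, tetrad_of)


def _tetrads(patterns: list[str]) -> SiteCalls:
    """One site from per-tetrad 4-character allele strings ('.' = missing)."""
    calls: dict[str, str | None] = {}
    for t, pat in enumerate(patterns):
        for j, ch in enumerate(pat):
            calls[f"T{t + 1}S{j + 1}"] = None if ch == "." else ch
    return _site(calls)


class TestHighConfidenceFilter:
    def test_fourteen_clean_tetrads_kept(self):
        site = _tetrads(["AACC"] * 14)
        assert filter_high_confidence(site).keep

    def test_gene_conversion_like_tetrad_dropped(self):
        site = _tetrads(["AACC"] * 13 + ["AAAC"])
        res = filter_high_confidence(site)
        assert not res.keep and res.reason == "non-2:2 tetrad"

    def test_triallelic_dropped(self):
        site = _tetrads(["AACC"] * 3 + ["AAGG"])
        assert filter_high_confidence(site).reason == "not biallelic"

    def test_incomplete_tetrads_tolerated_up_to_budget(self):
        site = _tetrads(["AACC"] * 12 + ["AAC.", ".ACC"])
        assert filter_high_confidence(site, max_missing_tetrads=2).keep
        res = filter_high_confidence(site, max_missing_tetrads=1)
        assert not res.keep and res.reason == "insufficient data"

    def test_no_calls_is_an_error(self):
        site = _tetrads(["...."])
        with pytest.raises(ValueError, match="no calls"):
            filter_high_confidence(site)

    def test_filter_matches_bruteforce_recount_under_error(self):
        """Error-injected sites: keep/drop equals an independent recount."""
        config = SimGenomeConfig(
            chromosomes=[ChromosomeSpec("chrA", 500_000, 250_000, ((100_000, 450_000),))],
            marker_density_per_kb=2.0,
        )
        marker_map, _ = simulate_parent(config, seed=21)
        sim = simulate_tetrads(
            marker_map, config,
            MeiosisConfig(crossover_rate=1.0, error_rate=0.02, missing_rate=0.01),
            n_tetrads=14, seed=22,
        )
        sites = sites_from_spores(marker_map, sim)
        assert len(sites) > 500

        def brute_force_keep(site: SiteCalls, budget: int = 2) -> bool:
            alleles = {a for a in site.allele_calls.values() if a is not None}
            if len(alleles) != 2:
                return False
            by_tetrad: dict[str, list] = {}
            for sp, tet in site.tetrad_of.items():
                by_tetrad.setdefault(tet, []).append(site.allele_calls.get(sp))
            complete = [c for c in by_tetrad.values() if all(a is not None for a in c)]
            if len(by_tetrad) - len(complete) > budget or not complete:
                return False
            return all(sorted(Counter(c).values()) == [2, 2] for c in complete)

        verdicts = [filter_high_confidence(s).keep for s in sites]
        oracle = [brute_force_keep(s) for s in sites]
        assert verdicts == oracle
        # with 2% error some sites must actually be dropped for this test to bite
        assert 0 < sum(not v for v in verdicts) < len(sites)


class TestPhaseChromosome:
    def test_perfect_linkage_two_markers(self):
        sites = [
            _site({f"s{i}": ("A" if i < 4 else "C") for i in range(8)}),
            _site({f"s{i}": ("G" if i < 4 else "T") for i in range(8)}),
        ]
        sites[1].pos = 2000
        frag, conf = phase_chromosome(sites)
        assert conf == [1.0]
        assert set(frag.provenance["blocks"].values()) == {0}
        # canonical: first marker's lex-smaller allele is M, partner follows
        assert (frag.markers[0].allele_M, frag.markers[1].allele_M) == ("A", "G")

    def test_recovers_planted_phase(self, genome_config, causal_locus, parent_map, tetrad_sim):
        """>=99% of markers recover planted phase after canonicalization."""
        sites = sites_from_spores(parent_map, tetrad_sim)
        kept = {}
        for s in sites:
            if filter_high_confidence(s).keep:
                kept.setdefault(s.chrom, []).append(s)
        for chrom, chrom_sites in kept.items():
            frag, _ = phase_chromosome(chrom_sites)
            truth = {m.pos: m for m in parent_map.chromosome(chrom)}
            # canonicalize the truth the same way: global flip if needed
            first = truth[frag.markers[0].pos]
            flip = min(first.allele_M, first.allele_P) != first.allele_M
            agree = sum(
                (truth[pm.pos].allele_P if flip else truth[pm.pos].allele_M) == pm.allele_M
                for pm in frag.markers
            )
            assert agree / len(frag.markers) >= 0.99

    def test_zero_crossovers_full_confidence(self, genome_config, causal_locus):
        marker_map, _ = simulate_parent(genome_config, seed=31, locus=causal_locus)
        sim = simulate_tetrads(marker_map, genome_config,
                               MeiosisConfig(crossover_rate=0.0), n_tetrads=6, seed=32)
        sites = sites_from_spores(marker_map, sim)
        chrom_sites = [s for s in sites if s.chrom == "chr01"]
        frag, conf = phase_chromosome(chrom_sites)
        assert all(c == 1.0 for c in conf)
        truth = {m.pos: m for m in marker_map.chromosome("chr01")}
        first = truth[frag.markers[0].pos]
        flip = min(first.allele_M, first.allele_P) != first.allele_M
        for pm in frag.markers:
            expect = truth[pm.pos].allele_P if flip else truth[pm.pos].allele_M
            assert pm.allele_M == expect

    def test_global_allele_swap_gives_identical_map(self, parent_map, tetrad_sim):
        sites = sites_from_spores(parent_map, tetrad_sim)
        chrom_sites = [s for s in sites if s.chrom == "chr02"]
        flipped = []
        for s in chrom_sites:
            a, b = s.observed_alleles()
            swap = {a: b, b: a}
            flipped.append(
                SiteCalls(s.chrom, s.pos,
                          {sp: (None if al is None else swap[al])
                           for sp, al in s.allele_calls.items()},
                          s.tetrad_of)
            )
        frag1, _ = phase_chromosome(chrom_sites)
        frag2, _ = phase_chromosome(flipped)
        assert [(m.pos, m.allele_M, m.allele_P) for m in frag1] == [
            (m.pos, m.allele_M, m.allele_P) for m in frag2
        ]

    def test_fifty_percent_adjacency_breaks_chain(self):
        # two tetrads, second marker co-segregates with the first in exactly
        # half the spores -> unresolvable adjacency, two phase blocks
        m1 = {"s0": "A", "s1": "A", "s2": "C", "s3": "C",
              "s4": "A", "s5": "A", "s6": "C", "s7": "C"}
        m2 = {"s0": "G", "s1": "T", "s2": "G", "s3": "T",
              "s4": "G", "s5": "T", "s6": "G", "s7": "T"}
        sites = [_site(m1), _site(m2)]
        sites[1].pos = 2000
        frag, conf = phase_chromosome(sites)
        assert conf == [0.5]
        assert len(set(frag.provenance["blocks"].values())) == 2


class TestEncodeAgainstMap:
    @pytest.fixture()
    def tiny_map(self):
        return PhasedMarkerMap([
            PhasedMarker("chrA", 100, "m1", "A", "C"),
            PhasedMarker("chrA", 200, "m2", "G", "T"),
            PhasedMarker("chrA", 300, "m3", "A8", "A7"),
        ])

    def test_haploid_all_maternal(self, tiny_map):
        vec = encode_against_map({"m1": "A", "m2": "G", "m3": "A8"}, tiny_map)
        assert vec.calls == ["M", "M", "M"]

    def test_diploid_all_het(self, tiny_map):
        vec = encode_against_map(
            {"m1": ("A", "C"), "m2": ("T", "G"), "m3": ("A7", "A8")}, tiny_map, ploidy=2
        )
        assert vec.calls == ["HET", "HET", "HET"]

    def test_roundtrip_random_mosaic(self, tiny_map):
        rng = np.random.default_rng(5)
        code_to_allele = {
            "m1": {"M": "A", "P": "C"}, "m2": {"M": "G", "P": "T"},
            "m3": {"M": "A8", "P": "A7"},
        }
        for _ in range(50):
            planted = [str(rng.choice(["M", "P"])) for _ in range(3)]
            raw = {mid: code_to_allele[mid][c]
                   for mid, c in zip(["m1", "m2", "m3"], planted)}
            assert encode_against_map(raw, tiny_map).calls == planted

    def test_unknown_allele_reports_marker(self, tiny_map):
        with pytest.raises(AlleleMismatchError, match="m2"):
            encode_against_map({"m1": "A", "m2": "A"}, tiny_map)

    def test_missing_markers_encode_missing(self, tiny_map):
        assert encode_against_map({"m2": "T"}, tiny_map).calls == ["MISSING", "P", "MISSING"]
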