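"""Shared fixtures: a small simulated genome and a chr12-like marker panel.

All data are generated programmatically with fixed seeds; the ``fig12``
fixtures are a synthetic stand-in for the study-style twelve-marker RFLP
panel (left-arm markers, centromere, a causal locus flanked 8.7 kb apart,
and a most-distal marker bounding the heterozygous region).
"""

from __future__ import annotations

import pytest

from lohkit.phasing import PhasedMarker, PhasedMarkerMap, encode_against_map
from lohkit.simulate import (
    MeiosisConfig,
    RecessiveLocusModel,
    default_config,
    simulate_parent,
    simulate_tetrads,
)

CEN12 = 151_000


@pytest.fixture(scope="session")
def genome_config():
    return default_config()


@pytest.fixture(scope="session")
def causal_locus():
    return RecessiveLocusModel(chrom="chr01", pos=280_000)


@pytest.fixture(scope="session")
def parent_map(genome_config, causal_locus):
    marker_map, _ = simulate_parent(genome_config, seed=11, locus=causal_locus)
    return marker_map


@pytest.fixture(scope="session")
def tetrad_sim(parent_map, genome_config):
    """Fourteen error-free tetrads with ~1 crossover per chromosome."""
    return simulate_tetrads(
        parent_map, genome_config, MeiosisConfig(crossover_rate=1.0), n_tetrads=14, seed=12
    )


@pytest.fixture(scope="session")
def spore_vectors(parent_map, tetrad_sim):
    return {
        sp: encode_against_map(
            {mid: a for mid, a in tetrad_sim.spore_calls[sp].items() if a is not None},
            parent_map,
            sample_id=sp,
            ploidy=1,
        )
        for sp in tetrad_sim.spores
    }


# synthetic chr12-like panel: positions in bp; the causal marker at 405 kb is
# flanked by markers 8.7 kb apart (401.3 and 410 kb); 450 kb is the most
# distal heterozygous marker (the het region ends there)
FIG12_POSITIONS = [
    33_000, 100_000,  # left arm
    162_000, 227_000, 292_000, 366_000, 380_000,
    401_300, 405_000, 410_000, 430_000, 450_000,  # right arm
]
FIG12_CAUSAL = "chr12_405000"
FIG12_LENGTH = 1_078_000

# five endpoint intervals between the centromere and the cassette marker
FIG12_INTERVALS = [
    (151_000.0, 162_000.0),
    (162_000.0, 227_000.0),
    (227_000.0, 292_000.0),
    (292_000.0, 366_000.0),
    (366_000.0, 401_300.0),
]


@pytest.fixture(scope="session")
def fig12_map():
    markers = []
    for pos in FIG12_POSITIONS:
        if pos == 405_000:
            markers.append(PhasedMarker("chr12", pos, FIG12_CAUSAL, "A7", "A8"))
        else:
            markers.append(PhasedMarker("chr12", pos, f"chr12_{pos}", "A", "C"))
    return PhasedMarkerMap(markers, provenance={"synthetic": True})


def fig12_calls(hom_positions: dict[int, str]) -> list[str]:
    """Build a 12-marker diploid call vector; unlisted positions are HET."""
    return [hom_positions.get(pos, "HET") for pos in FIG12_POSITIONS]
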