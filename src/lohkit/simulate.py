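"""Synthetic data with the statistical structure the analyses assume.

The generator emulates a heterothallic diploid whose chromosomes carry
heterozygous blocks interspersed with homozygous stretches (markers exist
only inside het blocks), meiosis of that diploid into four-spore tetrads
with reciprocal crossovers (2:2 segregation preserved by construction) and
optional gene conversions (3:1 sites), genotyping error and missingness,
all-pairs cross panels for a recessive locus, and LOH clones generated by
a mix of mechanisms: terminal crossover/BIR tracts, interstitial gene
conversions, and point homopolymer contractions. Every generator takes an
explicit seed and records the planted truth so downstream calls can be
checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phasing import M, P, PhasedMarker, PhasedMarkerMap
from .tracts import CloneGenotypes
from .trait_mapping import ROUGH, SMOOTH, CrossMatrix

__all__ = [
    "ChromosomeSpec",
    "SimGenomeConfig",
    "RecessiveLocusModel",
    "MeiosisConfig",
    "LOHMechanismMix",
    "TetradSimulation",
    "default_config",
    "jay270_like_config",
    "simulate_parent",
    "simulate_tetrads",
    "sites_from_spores",
    "simulate_cross_matrix",
    "simulate_loh_clone",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ChromosomeSpec:
    name: str
    length: int  # bp
    centromere: int  # bp
    het_blocks: tuple[tuple[int, int], ...]  # half-open (start, end] bp

    def __post_init__(self) -> None:
        for start, end in self.het_blocks:
            if not (0 <= start < end <= self.length):
                raise ValueError(f"{self.name}: het block ({start}, {end}] outside chromosome")


@dataclass
class SimGenomeConfig:
    """Genome layout for the simulated parent diploid.

    The default is deliberately small — three 500 kb chromosomes with one
    150 kb heterozygous block each — so whole-pipeline tests run in
    seconds; :func:`jay270_like_config` scales to a 16-chromosome genome
    with ~12,000 markers.
    """

    chromosomes: list[ChromosomeSpec]
    marker_density_per_kb: float = 0.2

    def __post_init__(self) -> None:
        if self.marker_density_per_kb <= 0:
            raise ValueError("marker density must be > 0")


def default_config() -> SimGenomeConfig:
    chroms = [
        ChromosomeSpec(f"chr{i + 1:02d}", 500_000, 250_000, ((200_000, 350_000),))
        for i in range(3)
    ]
    return SimGenomeConfig(chromosomes=chroms)


def jay270_like_config() -> SimGenomeConfig:
    """A 16-chromosome genome with ~12,000 markers in uneven het blocks."""
    rngless_lengths = [
        230, 810, 320, 1530, 580, 270, 1090, 560,
        440, 750, 670, 1080, 920, 780, 1090, 950,
    ]  # kb, yeast-like
    chroms = []
    for i, lkb in enumerate(rngless_lengths):
        length = lkb * 1000
        cen = length // 3
        # two het blocks covering ~60% of the chromosome
        blocks = (
            (int(length * 0.05), int(length * 0.40)),
            (int(length * 0.55), int(length * 0.80)),
        )
        chroms.append(ChromosomeSpec(f"chr{i + 1:02d}", length, cen, blocks))
    return SimGenomeConfig(chromosomes=chroms, marker_density_per_kb=1.66)


@dataclass(frozen=True)
class RecessiveLocusModel:
    """A recessive mutant allele in a homopolymer run (e.g. A8 wild, A7 mutant).

    Diploids show the mutant phenotype iff homozygous mutant; the mutant
    allele is placed on the homolog labelled M, mirroring the convention of
    designating the mutation-carrying homolog maternal.
    """

    chrom: str
    pos: int
    wild_allele: str = "A8"
    mutant_allele: str = "A7"
    marker_id: str = "causal_locus"


@dataclass
class MeiosisConfig:
    crossover_rate: float = 1.0  # expected crossovers per chromosome per meiosis
    gene_conversion_rate: float = 0.0  # expected conversions per chromosome per meiosis
    conversion_mean_kb: float = 2.0
    error_rate: float = 0.0  # per-spore per-marker allele flip probability
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("crossover_rate", "gene_conversion_rate", "conversion_mean_kb",
                     "error_rate", "missing_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class LOHMechanismMix:
    """Proportions of LOH mechanisms and their tract-length parameters."""

    p_terminal: float = 0.9  # crossover / BIR: homozygous to the chromosome end
    p_conversion: float = 0.08  # interstitial gene conversion around the selected site
    p_contraction: float = 0.02  # point event at the selected site only
    conversion_mean_kb: float = 10.0
    # optional hotspot: half-open (left, right] intervals with sampling weights
    breakpoint_weights: list[tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        total = self.p_terminal + self.p_conversion + self.p_contraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError("mechanism proportions must sum to 1")


@dataclass
class TetradSimulation:
    """Simulated spore genotypes plus the planted truth."""

    spore_calls: dict[str, dict[str, str | None]]  # spore -> marker_id -> allele
    tetrad_of: dict[str, str]
    mating_type: dict[str, str]  # 'a' | 'alpha'
    truth_haplotypes: dict[str, dict[str, str]]  # spore -> marker_id -> M/P (pre-error)
    crossovers: dict[str, dict[str, list[int]]]  # tetrad -> chrom -> positions
    conversions: dict[str, dict[str, list[tuple[int, int]]]]

    @property
    def spores(self) -> list[str]:
        return sorted(self.spore_calls)


def simulate_parent(
    config: SimGenomeConfig,
    seed: int | np.random.Generator | None = None,
    locus: RecessiveLocusModel | None = None,
) -> tuple[PhasedMarkerMap, dict]:
    """Place phased heterozygous markers in the configured het blocks.

    Marker counts per block are Poisson(density x block length); positions
    are uniform. Each marker gets two distinct random base alleles with a
    random M/P assignment. When a recessive locus model is supplied, its
    site is inserted as an extra marker with the mutant allele on M.
    Returns the map and a truth record (block boundaries, marker counts).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    markers: list[PhasedMarker] = []
    truth: dict = {"het_blocks": {}, "n_markers": {}}
    for chrom in config.chromosomes:
        truth["het_blocks"][chrom.name] = list(chrom.het_blocks)
        positions: set[int] = set()
        for start, end in chrom.het_blocks:
            n = rng.poisson(config.marker_density_per_kb * (end - start) / 1000.0)
            positions.update(int(p) for p in rng.integers(start + 1, end + 1, size=n))
        if locus is not None and locus.chrom == chrom.name:
            positions.discard(locus.pos)
        for pos in sorted(positions):
            a, b = rng.choice(4, size=2, replace=False)
            alleles = [_BASES[a], _BASES[b]]
            markers.append(
                PhasedMarker(chrom.name, pos, f"{chrom.name}_{pos}", alleles[0], alleles[1])
            )
        truth["n_markers"][chrom.name] = len(positions)
        if locus is not None and locus.chrom == chrom.name:
            markers.append(
                PhasedMarker(chrom.name, locus.pos, locus.marker_id,
                             locus.mutant_allele, locus.wild_allele)
            )
    return PhasedMarkerMap(markers, provenance={"simulated": True}), truth


def _meiosis_chromosome(
    marker_pos: np.ndarray,
    chrom_length: int,
    cfg: MeiosisConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[int], list[tuple[int, int]]]:
    """One meiosis of one chromosome: 4 x n_markers origin matrix (0=M, 1=P).

    Crossovers are reciprocal exchanges between two random chromatids
    (suffix swap), which preserves 2:2 segregation at every marker exactly.
    Gene conversions copy a tract from a homolog onto one chromatid and may
    break 2:2 (3:1 sites) — that is their point.
    """
    n = len(marker_pos)
    chromatids = np.array([[0] * n, [0] * n, [1] * n, [1] * n], dtype=np.int8)
    xo_positions: list[int] = []
    for _ in range(rng.poisson(cfg.crossover_rate)):
        x = int(rng.integers(1, chrom_length))
        i, j = rng.choice(4, size=2, replace=False)
        distal = marker_pos > x
        chromatids[i, distal], chromatids[j, distal] = (
            chromatids[j, distal].copy(),
            chromatids[i, distal].copy(),
        )
        xo_positions.append(x)
    conv_tracts: list[tuple[int, int]] = []
    for _ in range(rng.poisson(cfg.gene_conversion_rate)):
        start = int(rng.integers(1, chrom_length))
        length = max(1, int(rng.exponential(cfg.conversion_mean_kb * 1000)))
        end = min(chrom_length, start + length)
        i = int(rng.integers(4))
        covered = (marker_pos > start) & (marker_pos <= end)
        chromatids[i, covered] = 1 - chromatids[i, covered]
        conv_tracts.append((start, end))
    return chromatids, sorted(xo_positions), conv_tracts


def simulate_tetrads(
    marker_map: PhasedMarkerMap,
    config: SimGenomeConfig,
    meiosis: MeiosisConfig,
    n_tetrads: int = 14,
    seed: int | np.random.Generator | None = None,
) -> TetradSimulation:
    """Simulate ``n_tetrads`` four-spore tetrads from the phased parent.

    Spores are named ``T<k>S<j>``; two spores per tetrad are assigned each
    mating type (2:2, random pairing). Genotyping error flips a call to the
    other mapped allele; missingness nulls it; both are applied after the
    error-free haplotypes are recorded as truth.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chrom_specs = {c.name: c for c in config.chromosomes}
    by_chrom = {chrom: marker_map.chromosome(chrom) for chrom in marker_map.chromosomes}

    spore_calls: dict[str, dict[str, str | None]] = {}
    truth_hap: dict[str, dict[str, str]] = {}
    tetrad_of: dict[str, str] = {}
    mating_type: dict[str, str] = {}
    crossovers: dict[str, dict[str, list[int]]] = {}
    conversions: dict[str, dict[str, list[tuple[int, int]]]] = {}

    for t in range(n_tetrads):
        tet = f"T{t + 1:02d}"
        spores = [f"{tet}S{j + 1}" for j in range(4)]
        a_pair = rng.choice(4, size=2, replace=False)
        for j, sp in enumerate(spores):
            tetrad_of[sp] = tet
            mating_type[sp] = "a" if j in a_pair else "alpha"
            spore_calls[sp] = {}
            truth_hap[sp] = {}
        crossovers[tet] = {}
        conversions[tet] = {}
        for chrom, markers in by_chrom.items():
            pos = np.array([mk.pos for mk in markers])
            chromatids, xos, convs = _meiosis_chromosome(
                pos, chrom_specs[chrom].length, meiosis, rng
            )
            crossovers[tet][chrom] = xos
            conversions[tet][chrom] = convs
            for j, sp in enumerate(spores):
                for k, mk in enumerate(markers):
                    origin = M if chromatids[j, k] == 0 else P
                    truth_hap[sp][mk.marker_id] = origin
                    allele = mk.allele_M if origin == M else mk.allele_P
                    if meiosis.error_rate and rng.random() < meiosis.error_rate:
                        allele = mk.allele_P if allele == mk.allele_M else mk.allele_M
                    if meiosis.missing_rate and rng.random() < meiosis.missing_rate:
                        spore_calls[sp][mk.marker_id] = None
                    else:
                        spore_calls[sp][mk.marker_id] = allele
    return TetradSimulation(
        spore_calls=spore_calls,
        tetrad_of=tetrad_of,
        mating_type=mating_type,
        truth_haplotypes=truth_hap,
        crossovers=crossovers,
        conversions=conversions,
    )


def sites_from_spores(
    marker_map: PhasedMarkerMap,
    sim: TetradSimulation,
):
    """Repackage simulated spore calls as per-site :class:`SiteCalls`."""
    from .phasing import SiteCalls

    sites = []
    for mk in marker_map:
        calls = {sp: sim.spore_calls[sp].get(mk.marker_id) for sp in sim.spore_calls}
        sites.append(SiteCalls(mk.chrom, mk.pos, calls, dict(sim.tetrad_of)))
    return sites


def simulate_cross_matrix(
    carrier: dict[str, bool],
    mating_type: dict[str, str],
) -> CrossMatrix:
    """All-pairs MATa x MATalpha panel under the recessive single-gene rule.

    A cross is ROUGH iff both parents carry the mutant allele.
    """
    mata = sorted(s for s, mt in mating_type.items() if mt == "a")
    malpha = sorted(s for s, mt in mating_type.items() if mt == "alpha")
    cells = {
        (a, b): (ROUGH if carrier[a] and carrier[b] else SMOOTH)
        for a in mata
        for b in malpha
    }
    return CrossMatrix(mata_ids=mata, matalpha_ids=malpha, cells=cells)


def simulate_loh_clone(
    marker_map: PhasedMarkerMap,
    mix: LOHMechanismMix,
    selected_marker_id: str,
    selected_direction: str,
    centromere_pos: int,
    seed: int | np.random.Generator | None = None,
) -> tuple[CloneGenotypes, dict]:
    """Simulate one selected LOH clone on the selected marker's chromosome.

    Terminal (crossover/BIR): a breakpoint is drawn between the centromere
    and the selected marker — uniformly, or per the mix's interval weights
    when a hotspot is configured — and every marker distal to it on that
    arm becomes homozygous for the selected direction. Gene conversion: an
    interstitial tract covering the selected marker, with exponential
    length. Contraction: the selected marker alone. The selection
    constraint (homozygous selected allele at the selected marker) holds by
    construction. Returns the clone and a truth record with the mechanism
    and exact event interval.
    """
    if selected_direction not in (M, P):
        raise ValueError("selected_direction must be M or P")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sel = marker_map[selected_marker_id]
    chrom_markers = marker_map.chromosome(sel.chrom)
    positions = np.array([mk.pos for mk in chrom_markers])
    sel_on_right = sel.pos >= centromere_pos

    mech = rng.choice(
        ["terminal", "conversion", "contraction"],
        p=[mix.p_terminal, mix.p_conversion, mix.p_contraction],
    )
    calls = ["HET"] * len(chrom_markers)
    truth: dict = {"mechanism": str(mech), "chrom": sel.chrom}
    if mech == "terminal":
        lo, hi = sorted((centromere_pos, sel.pos))
        if mix.breakpoint_weights:
            lefts, rights, weights = zip(*mix.breakpoint_weights)
            w = np.asarray(weights, float)
            j = rng.choice(len(w), p=w / w.sum())
            bp = float(rng.uniform(lefts[j], rights[j]))
        else:
            bp = float(rng.uniform(lo, hi))
        if sel_on_right:
            hom = positions > bp
        else:
            hom = positions < bp
        truth["breakpoint_bp"] = bp
    elif mech == "conversion":
        length = max(1.0, rng.exponential(mix.conversion_mean_kb * 1000.0))
        left = sel.pos - rng.uniform(0.0, length)
        right = left + length
        hom = (positions > left) & (positions <= right)
        truth["tract"] = (float(left), float(right))
    else:  # contraction: the selected site only
        hom = positions == sel.pos
        truth["tract"] = (float(sel.pos) - 0.5, float(sel.pos) + 0.5)
    for i in np.flatnonzero(hom):
        calls[i] = selected_direction
    clone = CloneGenotypes(
        clone_id=f"clone_{mech}",
        chrom=sel.chrom,
        calls=calls,
        selected_marker_id=selected_marker_id,
        selected_direction=selected_direction,
    )
    return clone, truth
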