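"""Tetrad-based phasing of heterozygous SNP markers.

A heterothallic diploid carries two alleles at every HetSNP. Sequencing the
four haploid spores of complete tetrads turns each heterozygous site into a
2:2 segregation observation, and co-segregation of alleles at adjacent sites
across many meioses reveals which allele sits on which homolog. This module
filters sites to a high-confidence marker set (biallelic, 2:2 in every
complete tetrad), chains adjacent markers into phase blocks by greedy
linkage, and encodes haploid or diploid genotypes against the resulting
phased marker map.

The maternal/paternal (M/P) labels are arbitrary; orientation is
canonicalized so that the lexicographically smaller allele of the first
marker of each phase block is assigned to M. Marker positions are 1-based;
inter-marker intervals are half-open ``(left, right]``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "SiteCalls",
    "PhasedMarker",
    "PhasedMarkerMap",
    "PhaseVector",
    "FilterResult",
    "filter_high_confidence",
    "phase_chromosome",
    "encode_against_map",
]

# genotype codes used throughout the package
M, P, HET, MISSING = "M", "P", "HET", "MISSING"


class AlleleMismatchError(ValueError):
    """An observed allele is not one of the two mapped alleles at a marker."""


@dataclass
class SiteCalls:
    """Per-spore allele observations at one candidate heterozygous site.

    Parameters
    ----------
    chrom, pos
        Chromosome id and 1-based position.
    allele_calls
        Mapping spore id -> observed allele symbol (base or short indel
        token such as ``A8``), or ``None`` for a missing call.
    tetrad_of
        Mapping spore id -> tetrad id; every spore belongs to one tetrad.
    """

    chrom: str
    pos: int
    allele_calls: dict[str, str | None]
    tetrad_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        unknown = set(self.allele_calls) - set(self.tetrad_of)
        if unknown:
            raise ValueError(f"spores without tetrad assignment: {sorted(unknown)}")

    def observed_alleles(self) -> list[str]:
        """Distinct non-missing allele symbols, sorted lexicographically."""
        return sorted({a for a in self.allele_calls.values() if a is not None})


@dataclass(frozen=True)
class PhasedMarker:
    chrom: str
    pos: int
    marker_id: str
    allele_M: str
    allele_P: str

    def __post_init__(self) -> None:
        if self.allele_M == self.allele_P:
            raise ValueError(f"{self.marker_id}: allele_M == allele_P ({self.allele_M})")


@dataclass
class PhasedMarkerMap:
    """Ordered, phased marker set for one or more chromosomes.

    ``markers`` is kept position-sorted within each chromosome; positions
    must be unique per chromosome. ``provenance`` records how the map was
    built (number of tetrads, filters applied, phase-block confidences).
    """

    markers: list[PhasedMarker]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.markers = sorted(self.markers, key=lambda m: (m.chrom, m.pos))
        seen: set[tuple[str, int]] = set()
        ids: set[str] = set()
        for m in self.markers:
            if (m.chrom, m.pos) in seen:
                raise ValueError(f"duplicate position {m.chrom}:{m.pos}")
            if m.marker_id in ids:
                raise ValueError(f"duplicate marker_id {m.marker_id}")
            seen.add((m.chrom, m.pos))
            ids.add(m.marker_id)
        self._by_id = {m.marker_id: m for m in self.markers}

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def __getitem__(self, marker_id: str) -> PhasedMarker:
        return self._by_id[marker_id]

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self._by_id

    @property
    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for m in self.markers:
            if not out or out[-1] != m.chrom:
                out.append(m.chrom)
        return out

    def chromosome(self, chrom: str) -> list[PhasedMarker]:
        return [m for m in self.markers if m.chrom == chrom]

    def index_of(self, marker_id: str) -> int:
        """Index of a marker within its chromosome's ordered marker list."""
        marker = self[marker_id]
        return self.chromosome(marker.chrom).index(marker)


@dataclass
class PhaseVector:
    """A sample's genotype encoded against a map region.

    ``calls`` is ordered like the map markers it covers, each element one of
    ``M``, ``P``, ``HET`` (diploids only) or ``MISSING``.
    """

    sample_id: str
    calls: list[str]

    def __post_init__(self) -> None:
        bad = set(self.calls) - {M, P, HET, MISSING}
        if bad:
            raise ValueError(f"invalid phase codes: {sorted(bad)}")


@dataclass(frozen=True)
class FilterResult:
    keep: bool
    reason: str  # "ok" when kept


def _tetrad_groups(site: SiteCalls) -> dict[str, dict[str, str | None]]:
    groups: dict[str, dict[str, str | None]] = {}
    for spore, tet in site.tetrad_of.items():
        groups.setdefault(tet, {})[spore] = site.allele_calls.get(spore)
    return groups


def filter_high_confidence(site: SiteCalls, max_missing_tetrads: int = 2) -> FilterResult:
    """Decide whether a site qualifies as a high-confidence HetSNP marker.

    A site is kept iff it is biallelic and every *complete* tetrad (all four
    spores called) segregates exactly 2:2. Tetrads with any missing spore are
    ignored, up to ``max_missing_tetrads``; beyond that the site is dropped
    with reason ``"insufficient data"``. 2:2 segregation in every meiosis is
    the Mendelian expectation for a true heterozygous site, so departures
    flag genotyping error, gene conversion, or paralogous mapping.

    Raises
    ------
    ValueError
        If the site has no non-missing calls at all.
    """
    alleles = site.observed_alleles()
    if not alleles:
        raise ValueError("no calls")
    if len(alleles) != 2:
        return FilterResult(False, "not biallelic")

    groups = _tetrad_groups(site)
    n_incomplete = 0
    complete: list[dict[str, str | None]] = []
    for calls in groups.values():
        if len(calls) == 4 and all(a is not None for a in calls.values()):
            complete.append(calls)
        else:
            n_incomplete += 1
    if n_incomplete > max_missing_tetrads or not complete:
        return FilterResult(False, "insufficient data")
    for calls in complete:
        counts = Counter(calls.values())
        if sorted(counts.values()) != [2, 2]:
            return FilterResult(False, "non-2:2 tetrad")
    return FilterResult(True, "ok")


def _binary_site(site: SiteCalls) -> tuple[tuple[str, str], dict[str, int]]:
    """Sorted allele pair and spore -> {0,1} codes (0 = lex-smaller allele)."""
    alleles = site.observed_alleles()
    if len(alleles) != 2:
        raise ValueError(f"site {site.chrom}:{site.pos} is not biallelic")
    a, b = alleles
    codes = {s: (0 if al == a else 1) for s, al in site.allele_calls.items() if al is not None}
    return (a, b), codes


def phase_chromosome(
    sites: list[SiteCalls],
    marker_ids: list[str] | None = None,
) -> tuple[PhasedMarkerMap, list[float]]:
    """Phase one chromosome's retained sites by greedy adjacent linkage.

    For each pair of adjacent markers, spores called at both are tallied
    by whether their alleles co-segregate under the current orientation;
    the pairing that maximizes co-segregation wins. This works because
    crossovers between adjacent markers are rare per meiosis, so the
    majority vote across spores identifies the cis configuration. An
    adjacency with exactly 50% agreement is unresolvable ("unphaseable"):
    the chain is broken and a new phase block starts rather than guessing.

    Each block is canonicalized so that the lexicographically smaller allele
    of its first marker is labelled M — a global M/P flip of the input
    therefore yields an identical map.

    Returns
    -------
    map_fragment, confidences
        The phased map for this chromosome (block ids and per-block
        confidences recorded in ``provenance``), and the per-adjacency
        agreement fraction (length ``len(sites) - 1``).
    """
    if len(sites) < 2:
        raise ValueError("need >= 2 markers to phase")
    sites = sorted(sites, key=lambda s: s.pos)
    chrom = sites[0].chrom
    if any(s.chrom != chrom for s in sites):
        raise ValueError("phase_chromosome expects a single chromosome")
    n_tetrads = len({t for s in sites for t in s.tetrad_of.values()})
    if n_tetrads < 2:
        raise ValueError("need >= 2 tetrads to phase")
    if marker_ids is None:
        marker_ids = [f"{chrom}:{s.pos}" for s in sites]

    pairs_codes = [_binary_site(s) for s in sites]

    # orientation[i]: 0 if code 0 at marker i is on the same homolog as
    # code 0 at the start of its block, 1 if flipped
    orientation = [0] * len(sites)
    block_id = [0] * len(sites)
    confidences: list[float] = []
    block = 0
    for i in range(len(sites) - 1):
        (_, codes_l), (_, codes_r) = pairs_codes[i], pairs_codes[i + 1]
        shared = codes_l.keys() & codes_r.keys()
        match = sum(codes_l[s] == codes_r[s] for s in shared)
        total = len(shared)
        mismatch = total - match
        conf = max(match, mismatch) / total if total else 0.0
        confidences.append(conf)
        if total == 0 or match == mismatch:
            # unphaseable adjacency: break the chain
            block += 1
            orientation[i + 1] = 0
        else:
            flip_step = 1 if mismatch > match else 0
            orientation[i + 1] = orientation[i] ^ flip_step
        block_id[i + 1] = block

    # canonicalize per block: first marker of block keeps orientation 0,
    # i.e. its lex-smaller allele becomes M (true by construction since the
    # block start is assigned orientation 0 above)
    markers = []
    for i, site in enumerate(sites):
        (a, b), _ = pairs_codes[i]
        allele_m, allele_p = (a, b) if orientation[i] == 0 else (b, a)
        markers.append(PhasedMarker(chrom, site.pos, marker_ids[i], allele_m, allele_p))

    frag = PhasedMarkerMap(
        markers,
        provenance={
            "n_tetrads": n_tetrads,
            "blocks": {marker_ids[i]: block_id[i] for i in range(len(sites))},
            "adjacency_confidence": dict(zip(marker_ids[1:], confidences)),
        },
    )
    return frag, confidences


def encode_against_map(
    raw_calls: dict[str, str | tuple[str, str] | None],
    marker_map: PhasedMarkerMap,
    sample_id: str = "sample",
    ploidy: int = 1,
) -> PhaseVector:
    """Encode raw allele calls as an M/P/HET/MISSING vector over the map.

    Haploid samples supply one allele per marker; diploids an unordered
    allele pair (or a single symbol meaning homozygous for it). Any allele
    not in the map at its marker raises :class:`AlleleMismatchError`.
    """
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    calls: list[str] = []
    for marker in marker_map:
        obs = raw_calls.get(marker.marker_id)
        if obs is None:
            calls.append(MISSING)
            continue
        pair = (obs, obs) if isinstance(obs, str) else tuple(obs)
        if ploidy == 1:
            if isinstance(obs, tuple) and obs[0] != obs[1]:
                raise ValueError(f"haploid sample with two alleles at {marker.marker_id}")
            pair = (pair[0], pair[0])
        for a in pair:
            if a not in (marker.allele_M, marker.allele_P):
                raise AlleleMismatchError(
                    f"allele mismatch at {marker.marker_id}: {a!r} not in "
                    f"({marker.allele_M!r}, {marker.allele_P!r})"
                )
        if pair[0] != pair[1]:
            calls.append(HET)
        elif pair[0] == marker.allele_M:
            calls.append(M)
        else:
            calls.append(P)
    return PhaseVector(sample_id, calls)
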