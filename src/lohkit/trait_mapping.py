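"""Recessive-trait carrier inference and strict co-segregation mapping.

A recessive allele that produces a phenotype only in homozygous diploids
(such as a frameshift in a transcription factor for mother/daughter cell
separation, rough colonies only in mutant/mutant diploids) cannot be scored
in haploids directly. Crossing panels of MATa x MATalpha haploids and
scoring the diploid phenotypes lets the haploid genotypes be inferred: a
mutant-phenotype cross proves both parents carry the allele, and a
wild-type cross against a proven carrier proves the other parent does not.

With carrier and non-carrier groups in hand, the causal locus is mapped by
scanning a phased marker map for markers where one allele co-segregates
with every carrier and the other with every non-carrier (the strict
co-segregation criterion); runs of passing markers are merged into
candidate regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .phasing import HET, M, MISSING, P, PhasedMarkerMap, PhaseVector

__all__ = [
    "ROUGH",
    "SMOOTH",
    "CrossMatrix",
    "CarrierInference",
    "MarkerScan",
    "CandidateRegion",
    "GeneInterval",
    "infer_carriers",
    "cosegregation_scan",
    "merge_candidate_regions",
]

ROUGH, SMOOTH = "ROUGH", "SMOOTH"


@dataclass
class CrossMatrix:
    """Diploid phenotypes from an all-pairs MATa x MATalpha cross panel.

    ``cells[(a, alpha)]`` holds ``ROUGH`` or ``SMOOTH``; untested pairs are
    simply absent. Row and column id sets must be disjoint.
    """

    mata_ids: list[str]
    matalpha_ids: list[str]
    cells: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.mata_ids) & set(self.matalpha_ids)
        if overlap:
            raise ValueError(f"MATa/MATalpha ids overlap: {sorted(overlap)}")
        for (a, b), pheno in self.cells.items():
            if a not in self.mata_ids or b not in self.matalpha_ids:
                raise ValueError(f"cross ({a}, {b}) references unknown haploid")
            if pheno not in (ROUGH, SMOOTH):
                raise ValueError(f"invalid phenotype {pheno!r}")

    @property
    def all_ids(self) -> list[str]:
        return list(self.mata_ids) + list(self.matalpha_ids)

    def tested(self) -> list[tuple[str, str, str]]:
        return [(a, b, p) for (a, b), p in self.cells.items()]

    def count(self, phenotype: str) -> int:
        return sum(1 for p in self.cells.values() if p == phenotype)


@dataclass
class CarrierInference:
    confirmed_carriers: set[str]
    confirmed_noncarriers: set[str]
    unknown: set[str]
    consistent: bool
    witness: tuple[str, str] | None = None  # violating cross when inconsistent


def infer_carriers(matrix: CrossMatrix) -> CarrierInference:
    """Infer carrier status of each haploid from diploid cross phenotypes.

    Under a single-gene recessive model a cross is ROUGH iff both parents
    carry the mutant allele. Hence:

    * any participant of a ROUGH cross is a confirmed carrier;
    * any participant of a SMOOTH cross whose partner is a confirmed carrier
      is a confirmed non-carrier;
    * everything else stays unknown (e.g. an all-SMOOTH matrix is consistent
      with one whole mating type carrying the allele).

    The model is consistent iff some 0/1 carrier assignment reproduces every
    tested cell. Since ROUGH cells *force* both parents to carrier and
    SMOOTH cells only forbid the carrier/carrier combination, such an
    assignment exists exactly when no SMOOTH cross joins two forced
    carriers — that check is exhaustive over the forced set, so the result
    is exact. Inconsistency is a returned state (with the violating cross as
    witness), not an error.
    """
    if not matrix.cells:
        raise ValueError("matrix has no tested cells")
    carriers: set[str] = set()
    for a, b, pheno in matrix.tested():
        if pheno == ROUGH:
            carriers.update((a, b))
    witness = None
    for a, b, pheno in matrix.tested():
        if pheno == SMOOTH and a in carriers and b in carriers:
            witness = (a, b)
            break
    noncarriers: set[str] = set()
    if witness is None:
        for a, b, pheno in matrix.tested():
            if pheno == SMOOTH:
                if a in carriers:
                    noncarriers.add(b)
                if b in carriers:
                    noncarriers.add(a)
    unknown = set(matrix.all_ids) - carriers - noncarriers
    return CarrierInference(
        confirmed_carriers=carriers,
        confirmed_noncarriers=noncarriers,
        unknown=unknown,
        consistent=witness is None,
        witness=witness,
    )


@dataclass(frozen=True)
class MarkerScan:
    marker_id: str
    chrom: str
    pos: int
    passed: bool
    orientation: str | None  # "group1=M" | "group1=P" | None


@dataclass
class CandidateRegion:
    chrom: str
    start_pos: int
    end_pos: int
    n_markers: int
    orientation: str
    marker_ids: list[str]
    n_genes: int | None = None

    def __post_init__(self) -> None:
        if self.start_pos > self.end_pos:
            raise ValueError("start_pos > end_pos")
        if self.n_markers < 1:
            raise ValueError("n_markers < 1")


@dataclass(frozen=True)
class GeneInterval:
    chrom: str
    start: int
    end: int
    name: str


def cosegregation_scan(
    marker_map: PhasedMarkerMap,
    vectors: dict[str, PhaseVector],
    group1: list[str],
    group2: list[str],
    max_missing: int = 0,
) -> list[MarkerScan]:
    """Scan every marker for strict co-segregation between two groups.

    A marker passes iff all group-1 haploids carry one homolog's allele and
    all group-2 haploids the other (orientation reported), with at most
    ``max_missing`` MISSING calls across both groups. MISSING never counts
    as agreement — it is tolerated, not credited — so with the default
    ``max_missing=0`` the criterion is fully strict. HET calls (impossible
    for haploids) always fail the marker.
    """
    g1, g2 = set(group1), set(group2)
    if not g1 or not g2:
        raise ValueError("groups must be non-empty")
    if g1 & g2:
        raise ValueError(f"groups overlap: {sorted(g1 & g2)}")
    n_markers = len(marker_map)
    for sid in list(g1 | g2):
        if sid not in vectors:
            raise KeyError(f"index mismatch: no vector for {sid}")
        if len(vectors[sid].calls) != n_markers:
            raise ValueError(f"index mismatch: vector {sid} length != map size")

    results: list[MarkerScan] = []
    for idx, marker in enumerate(marker_map):
        calls1 = [vectors[s].calls[idx] for s in sorted(g1)]
        calls2 = [vectors[s].calls[idx] for s in sorted(g2)]
        n_missing = sum(c == MISSING for c in calls1 + calls2)
        passed, orient = False, None
        if n_missing <= max_missing and HET not in calls1 + calls2:
            obs1 = {c for c in calls1 if c != MISSING}
            obs2 = {c for c in calls2 if c != MISSING}
            if obs1 <= {M} and obs2 <= {P}:
                passed, orient = True, "group1=M"
            elif obs1 <= {P} and obs2 <= {M}:
                passed, orient = True, "group1=P"
        results.append(MarkerScan(marker.marker_id, marker.chrom, marker.pos, passed, orient))
    return results


def merge_candidate_regions(
    scan: list[MarkerScan],
    marker_map: PhasedMarkerMap,
    genes: list[GeneInterval] | None = None,
    extend_to_flanks: bool = False,
) -> list[CandidateRegion]:
    """Merge maximal runs of consecutive passing markers into regions.

    Region span is reported marker-to-marker (first to last passing marker
    position); with ``extend_to_flanks`` the span is widened to the
    midpoints toward the nearest flanking failing markers, where present.
    When a gene annotation is supplied, ``n_genes`` counts genes whose
    interval shares at least one bp with the region span.
    """
    by_id = {s.marker_id: s for s in scan}
    regions: list[CandidateRegion] = []
    for chrom in marker_map.chromosomes:
        chrom_markers = marker_map.chromosome(chrom)
        run: list = []
        runs: list[list] = []
        for i, mk in enumerate(chrom_markers):
            s = by_id.get(mk.marker_id)
            if s is not None and s.passed:
                run.append((i, mk, s))
            elif run:
                runs.append(run)
                run = []
        if run:
            runs.append(run)
        for run in runs:
            start = run[0][1].pos
            end = run[-1][1].pos
            if extend_to_flanks:
                i_first, i_last = run[0][0], run[-1][0]
                if i_first > 0:
                    start = (chrom_markers[i_first - 1].pos + start) // 2
                if i_last < len(chrom_markers) - 1:
                    end = (end + chrom_markers[i_last + 1].pos) // 2
            orients = {s.orientation for _, _, s in run}
            orientation = orients.pop() if len(orients) == 1 else "mixed"
            n_genes = None
            if genes is not None:
                n_genes = sum(
                    1 for g in genes if g.chrom == chrom and g.start <= end and g.end >= start
                )
            regions.append(
                CandidateRegion(
                    chrom=chrom,
                    start_pos=start,
                    end_pos=end,
                    n_markers=len(run),
                    orientation=orientation,
                    marker_ids=[mk.marker_id for _, mk, _ in run],
                    n_genes=n_genes,
                )
            )
    return regions
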