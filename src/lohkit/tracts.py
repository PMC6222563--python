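"""LOH tract calling, endpoint mapping and interval-size null tests.

Clones selected for loss of heterozygosity (e.g. 5-FOA-resistant loss of a
URA3 cassette) are genotyped at a panel of phased markers. Maximal runs of
same-direction homozygous calls become tracts; because marker panels are
sparse, a tract's true breakpoint is only known to lie between the
outermost homozygous marker and the adjacent heterozygous one, and the
midpoint of that gap is reported as the approximate endpoint. A run that
reaches the most distal marker cannot be distinguished from a tract running
to the telomere and is flagged accordingly.

Endpoint counts binned into marker-delimited intervals are tested against
the null that breakpoints fall in proportion to physical interval size
(chi-square goodness of fit), and between two selection configurations
(chi-square homogeneity); both tests use df = J - 1 for J intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .phasing import HET, M, MISSING, P, PhasedMarkerMap

__all__ = [
    "CloneGenotypes",
    "LOHTract",
    "ArmReport",
    "CloneClassification",
    "EndpointTable",
    "ChisqResult",
    "call_tracts",
    "classify_clone",
    "endpoint_midpoint",
    "tally_endpoints",
    "chi2_pvalue",
    "chisq_size_model",
    "chisq_homogeneity",
]

INTERSTITIAL = "interstitial"
REACHES_LAST_MARKER = "reaches-last-marker"

SIMPLE = "simple"
COMPLEX = "complex"


@dataclass
class CloneGenotypes:
    """Per-marker diploid genotype calls of one LOH clone on one chromosome."""

    clone_id: str
    chrom: str
    calls: list[str]  # ordered over the map's markers for this chromosome
    selected_marker_id: str | None = None
    selected_direction: str | None = None  # M or P

    def __post_init__(self) -> None:
        bad = set(self.calls) - {M, P, HET, MISSING}
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")
        if self.selected_direction not in (None, M, P):
            raise ValueError("selected_direction must be M or P")


@dataclass
class LOHTract:
    chrom: str
    arm: str  # "left" | "right"
    direction: str  # M or P
    first_hom_idx: int  # chromosome-marker indices, proximal-to-distal order
    last_hom_idx: int
    proximal_endpoint_bp: float | None  # midpoint toward the centromere side
    distal_endpoint_bp: float | None  # None when terminal
    terminal_flag: str  # interstitial | reaches-last-marker
    length_bound_kb: tuple[float, float]  # (min span, max span)

    def __post_init__(self) -> None:
        if self.length_bound_kb[0] > self.length_bound_kb[1] + 1e-9:
            raise ValueError("min span exceeds max span")


@dataclass
class ArmReport:
    arm: str
    informative: bool
    tracts: list[LOHTract] = field(default_factory=list)
    n_runs: int = 0  # homozygous runs before any filtering


@dataclass
class CloneClassification:
    clone_id: str
    label: str  # simple | complex
    coincident_multi_arm: bool
    notes: list[str] = field(default_factory=list)


@dataclass
class EndpointTable:
    intervals: list[tuple[float, float]]  # half-open (left, right]
    lengths: np.ndarray  # L_j in bp
    observed: np.ndarray  # O_j
    n_outside: int = 0

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.observed = np.asarray(self.observed, dtype=float)
        if len(self.intervals) != len(self.lengths) or len(self.lengths) != len(self.observed):
            raise ValueError("intervals, lengths and observed must align")

    def expected(self) -> np.ndarray:
        """E_j under the interval-size null: endpoints proportional to length."""
        return self.observed.sum() * self.lengths / self.lengths.sum()


@dataclass
class ChisqResult:
    chi2: float
    df: int
    p: float

    def __post_init__(self) -> None:
        if self.chi2 < 0 or not (0 <= self.p <= 1):
            raise ValueError("invalid chi-square result")


def chi2_pvalue(chi2_stat: float, df: int) -> float:
    """Upper-tail chi-square probability — the p-value convention used by
    both endpoint tests (df = J - 1 for J intervals)."""
    return float(stats.chi2.sf(chi2_stat, df))


def endpoint_midpoint(left_marker_pos: float, right_marker_pos: float) -> float:
    """Midpoint between two flanking markers — the approximate breakpoint."""
    if left_marker_pos == right_marker_pos:
        raise ValueError("flanking marker positions are equal")
    lo, hi = sorted((left_marker_pos, right_marker_pos))
    return (lo + hi) / 2.0


def _arm_runs(codes: list[str], missing_breaks: bool = False) -> list[tuple[int, int, str]]:
    """Maximal same-direction homozygous runs over proximal->distal codes.

    MISSING is transparent by default: it never breaks, starts, or ends a
    run (PCR gaps should not fabricate interruptions). With
    ``missing_breaks`` it terminates runs like a HET call. Returns
    (first_idx, last_idx, direction) with indices into ``codes``.
    """
    runs: list[tuple[int, int, str]] = []
    cur_dir: str | None = None
    first = last = -1
    for i, c in enumerate(codes):
        if c == MISSING:
            if missing_breaks and cur_dir is not None:
                runs.append((first, last, cur_dir))
                cur_dir = None
            continue
        if c in (M, P):
            if c == cur_dir:
                last = i
            else:
                if cur_dir is not None:
                    runs.append((first, last, cur_dir))
                cur_dir, first, last = c, i, i
        else:  # HET breaks any run
            if cur_dir is not None:
                runs.append((first, last, cur_dir))
            cur_dir = None
    if cur_dir is not None:
        runs.append((first, last, cur_dir))
    return runs


def call_tracts(
    clone: CloneGenotypes,
    marker_map: PhasedMarkerMap,
    centromere_pos: int,
    chrom_length: int | None = None,
    missing_breaks: bool = False,
) -> dict[str, ArmReport]:
    """Resolve a clone's marker calls into LOH tracts, per chromosome arm.

    Markers are split by the supplied centromere position and each arm is
    walked proximal-to-distal. For every homozygous run the approximate
    endpoints are midpoints between the run's outermost homozygous marker
    and the adjacent non-missing heterozygous marker; a run touching the
    arm's most distal marker has no distal endpoint and is flagged
    ``reaches-last-marker``. The minimum span is the distance between the
    outermost homozygous markers, the maximum span the distance between the
    flanking heterozygous markers (or the chromosome end, when known, for
    terminal runs). An arm whose informative (non-missing) calls contain no
    HET marker is reported uninformative: with every marker homozygous there
    is no internal evidence of where heterozygosity ever was.
    """
    chrom_markers = marker_map.chromosome(clone.chrom)
    if len(clone.calls) != len(chrom_markers):
        raise ValueError("calls not aligned to map chromosome")
    left_idx = [i for i, mk in enumerate(chrom_markers) if mk.pos < centromere_pos]
    right_idx = [i for i, mk in enumerate(chrom_markers) if mk.pos >= centromere_pos]
    # proximal-to-distal order: right arm ascending, left arm descending
    arms = {"left": list(reversed(left_idx)), "right": right_idx}
    reports: dict[str, ArmReport] = {}
    for arm, idxs in arms.items():
        if not idxs:
            reports[arm] = ArmReport(arm=arm, informative=False)
            continue
        codes = [clone.calls[i] for i in idxs]
        informative_codes = [c for c in codes if c != MISSING]
        runs = _arm_runs(codes, missing_breaks=missing_breaks)
        # an arm with no HET call is uninformative — homozygosity there
        # cannot be bounded internally — but its runs are still reported
        informative = HET in informative_codes
        positions = [chrom_markers[i].pos for i in idxs]
        tracts: list[LOHTract] = []
        for first, last, direction in runs:
            # flanking non-missing HET markers (MISSING is transparent)
            prox_flank = next(
                (j for j in range(first - 1, -1, -1) if codes[j] != MISSING), None
            )
            dist_flank = next(
                (j for j in range(last + 1, len(codes)) if codes[j] != MISSING), None
            )
            prox_end = (
                endpoint_midpoint(positions[prox_flank], positions[first])
                if prox_flank is not None
                else None
            )
            if dist_flank is not None:
                dist_end = endpoint_midpoint(positions[last], positions[dist_flank])
                terminal = INTERSTITIAL
            else:
                dist_end = None
                terminal = REACHES_LAST_MARKER
            min_span = abs(positions[last] - positions[first])
            max_lo = positions[prox_flank] if prox_flank is not None else positions[first]
            if dist_flank is not None:
                max_hi = positions[dist_flank]
            elif chrom_length is not None and arm == "right":
                max_hi = chrom_length
            elif chrom_length is not None and arm == "left":
                max_hi = 1  # left-arm distal end is the chromosome start
            else:
                max_hi = positions[last]
            max_span = max(abs(max_hi - max_lo), min_span)
            tracts.append(
                LOHTract(
                    chrom=clone.chrom,
                    arm=arm,
                    direction=direction,
                    first_hom_idx=idxs[first],
                    last_hom_idx=idxs[last],
                    proximal_endpoint_bp=prox_end,
                    distal_endpoint_bp=dist_end,
                    terminal_flag=terminal,
                    length_bound_kb=(min_span / 1000.0, max_span / 1000.0),
                )
            )
        reports[arm] = ArmReport(arm=arm, informative=informative, tracts=tracts,
                                 n_runs=len(runs))
    return reports


def classify_clone(
    arm_reports: dict[str, ArmReport],
    clone: CloneGenotypes,
    marker_map: PhasedMarkerMap,
    selected_arm: str = "right",
) -> CloneClassification:
    """Classify a clone as simple or complex, noting coincident events.

    Simple: exactly one tract on the selected arm, in the selected
    direction, containing the selected marker. Interrupted runs or
    homozygosity for the homolog opposite to the selection on the selected
    arm make the clone complex. Tracts on the other arm are coincident
    (unselected) events — annotated, but not in themselves complexity.
    """
    if clone.selected_marker_id is None or clone.selected_direction is None:
        raise ValueError("clone has no selection information")
    sel_idx = marker_map.index_of(clone.selected_marker_id)
    report = arm_reports[selected_arm]
    notes: list[str] = []
    sel_dir_tracts = [t for t in report.tracts if t.direction == clone.selected_direction]
    opp_tracts = [t for t in report.tracts if t.direction != clone.selected_direction]
    label = SIMPLE
    if len(sel_dir_tracts) != 1:
        label = COMPLEX
        notes.append(f"{len(sel_dir_tracts)} selected-direction runs on selected arm")
    if opp_tracts:
        label = COMPLEX
        notes.append("opposite-direction homozygosity on selected arm")
    if label == SIMPLE:
        t = sel_dir_tracts[0]
        lo, hi = sorted((t.first_hom_idx, t.last_hom_idx))
        if not (lo <= sel_idx <= hi):
            label = COMPLEX
            notes.append("selected marker outside the called tract")
    other_arm = "left" if selected_arm == "right" else "right"
    coincident = bool(arm_reports.get(other_arm) and arm_reports[other_arm].tracts)
    if coincident:
        notes.append(f"coincident unselected LOH on {other_arm} arm")
    return CloneClassification(
        clone_id=clone.clone_id,
        label=label,
        coincident_multi_arm=coincident,
        notes=notes,
    )


def tally_endpoints(
    endpoints_bp: list[float],
    intervals: list[tuple[float, float]],
) -> EndpointTable:
    """Bin centromere-proximal endpoints into half-open (left, right] intervals.

    An endpoint exactly on a marker position belongs to the interval ending
    there. Endpoints outside every interval are excluded with a warning and
    counted in ``n_outside``.
    """
    for left, right in intervals:
        if right <= left:
            raise ValueError(f"invalid interval ({left}, {right}]")
    observed = np.zeros(len(intervals), dtype=float)
    outside = 0
    for e in endpoints_bp:
        for j, (left, right) in enumerate(intervals):
            if left < e <= right:
                observed[j] += 1
                break
        else:
            outside += 1
    if outside:
        warnings.warn(f"{outside} endpoint(s) outside the interval set were excluded")
    lengths = np.array([right - left for left, right in intervals], dtype=float)
    return EndpointTable(intervals=list(intervals), lengths=lengths, observed=observed,
                         n_outside=outside)


def chisq_size_model(observed, lengths) -> ChisqResult:
    """Goodness-of-fit of endpoint counts to the interval-size null.

    Expected counts are proportional to physical interval lengths,
    E_j = (sum O) * L_j / (sum L); the statistic is Pearson's
    chi2 = sum (O_j - E_j)^2 / E_j on df = J - 1.
    """
    observed = np.asarray(observed, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if len(observed) < 2 or len(observed) != len(lengths):
        raise ValueError("need >= 2 aligned intervals")
    if observed.sum() <= 0:
        raise ValueError("no observed endpoints")
    if np.any(lengths <= 0):
        raise ValueError("interval lengths must be > 0")
    expected = observed.sum() * lengths / lengths.sum()
    if np.any(expected < 5):
        warnings.warn("some expected counts < 5; chi-square approximation is rough")
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = len(observed) - 1
    p = chi2_pvalue(chi2, df)
    return ChisqResult(chi2=chi2, df=df, p=p)


def chisq_homogeneity(observed_a, observed_b) -> ChisqResult:
    """2 x J contingency chi-square between two endpoint distributions.

    Tests whether two selection configurations (e.g. the cassette on either
    homolog) share one endpoint distribution; df = J - 1 after dropping
    intervals empty in both rows. Symmetric in its arguments.
    """
    a = np.asarray(observed_a, dtype=float)
    b = np.asarray(observed_b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need >= 2 aligned intervals")
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    if len(a) < 2:
        raise ValueError("fewer than 2 non-empty intervals")
    if np.array_equal(a, b):
        return ChisqResult(chi2=0.0, df=len(a) - 1, p=1.0)
    chi2, p, df, _ = stats.chi2_contingency(np.vstack([a, b]), correction=False)
    return ChisqResult(chi2=float(chi2), df=int(df), p=float(p))
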