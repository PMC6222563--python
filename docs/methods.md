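# Methods

This note documents the models, parameter choices and numerical
conventions behind `lohkit`, and what the synthetic data do and do not
establish about real data.

## Coordinates and genotype codes

Marker positions are 1-based base pairs. All inter-marker intervals are
half-open `(left, right]` with length `right − left`; a breakpoint or
endpoint lying exactly on a marker position belongs to the interval ending
there. Genotypes are encoded `M`/`P` (homolog of origin), `HET` (diploids
only) and `MISSING`; on disk the cells are `M`/`P`/`H`/`-`. The
maternal/paternal labels carry no biological meaning — the assignment of a
homolog to "M" is arbitrary, and the package canonicalizes orientation so
that the lexicographically smaller allele of the first marker of each
phase block is labelled M. Any global allele swap of the input therefore
produces an identical map.

## High-confidence marker filter

A candidate heterozygous site is retained iff it is biallelic after
filtering and every *complete* tetrad (four called spores) segregates
exactly 2:2. Tetrads with any missing spore are ignored up to
`max_missing_tetrads` (default 2, of 14); beyond that the site is dropped
as insufficiently observed. 2:2 segregation in every meiosis is the
Mendelian expectation for a true heterozygous site; a single miscalled
spore, a gene conversion, or reads mismapped between paralogs all break
it. The filter is deliberately conservative: with a per-spore error rate
`e` the probability a site survives is roughly `(1−e)^(4·T)` for `T`
complete tetrads (~32% at e = 0.02, T = 14), which costs marker density
but keeps the retained map essentially error-free. Sequencing-level
criteria (depth, base quality) are upstream of this package, whose input
begins at per-spore allele calls.

## Phasing by greedy adjacent linkage

For each pair of adjacent retained markers, every spore called at both
contributes one co-segregation observation; the allele pairing supported
by the majority of spores is taken as cis. This is justified by scale:
across 14 meioses, crossovers between markers a few kb apart are rare, so
the majority vote identifies the parental configuration with error
probability decaying geometrically in spore count. The agreement fraction
is reported as the adjacency's confidence. An adjacency at exactly 50%
(or with no doubly-called spore) is unresolvable; the chain is broken into
independent phase blocks rather than guessed. No attempt is made to phase
across blocks — with dense markers inside heterozygous blocks this occurs
only at data gaps.

## Carrier inference and the strict co-segregation criterion

The recessive single-gene model makes a cross's phenotype a pure AND of
its parents' carrier status. Carrier inference is exact, not heuristic:
mutant-phenotype crosses force both parents to carriers; a consistent 0/1
assignment exists iff no wild-type cross joins two forced carriers (any
remaining haploid can be set to non-carrier), so consistency checking is a
single scan with the violating cross returned as a witness. An
all-wild-type panel confirms nothing — one entire mating type could carry
the allele — so those haploids stay "unknown" rather than being guessed
non-carriers.

The scan then requires, marker by marker, that all carriers show one
homolog's allele and all non-carriers the other, with `max_missing = 0`
by default (missing calls are never credited as agreement). Runs of
passing markers are merged into candidate regions reported
marker-to-marker; `extend_to_flanks` widens spans to the midpoints toward
the nearest failing markers for users who prefer the outer bound. Gene
content is counted as any-bp overlap with supplied gene intervals.

With twelve haploids drawn from three tetrads, group members share whole
parental chromosomes by chance, so an occasional spurious co-segregating
region on an unlinked chromosome is expected (about one per genome scan at
these panel sizes) — the worked example reproduces this, and it mirrors
the second candidate region such studies report. Candidate prioritization
beyond the scan (gene annotation review) is left to the user.

## Fluctuation analysis

The Lea-Coulson method of the median solves

    r̃/m − ln m = 1.24

for `m`, the expected mutational events per culture, where `r̃` is the
median whole-culture mutant count. The left side is strictly decreasing in
`m`, so the root is unique; it is bracketed and solved by Brent's method
to 1e-12 relative tolerance, and the returned value satisfies the
defining equation to < 1e-6 (property-tested). The rate per cell division
is μ = m/N with N the mean viable cells per culture (arithmetic mean by
default; a flag selects the median). Plate counts are scaled to
whole-culture values by `count · dilution / plated_fraction`, with mutant
counts rounded half-up.

95% confidence intervals exponentiate `ln m ± 1.96·σ̂` with

    σ̂_ln m = 1.225 · m^(−0.315) / √C

for C cultures — the dispersion model used by the FALCOR lineage of
fluctuation calculators. **Known limitation:** this formula describes the
Ma-Sandri-Sarkar maximum-likelihood estimator's dispersion, and the
median-based estimator is noisier; intervals built from it are therefore
anti-conservative, increasingly so at large `m` (hundreds of events per
culture). The acceptance suite measures this coverage shortfall directly
at the worked example's assay scale rather than hiding it. Users needing
calibrated intervals at large `m` should treat these CIs as lower bounds
on uncertainty.

Experiments are compared with a two-sided Mann-Whitney test on
per-culture mutant frequencies `r_i/N_i` (raw frequencies are what an
assay yields per culture; a flag compares counts instead): exact null
distribution when the pooled sample is ≤ 20 untied values, normal
approximation with tie correction otherwise, `p = 1` for degenerate
all-tied data. Per-kb normalization divides μ by the
centromere-to-cassette distance, since any crossover/BIR breakpoint in
that interval produces the selected LOH.

The simulator implements the deterministic-growth ("quick") Luria-Delbruck
model: events per culture ~ Poisson(m = μN); a clone founded when the
culture still had to grow 1/u-fold (u ~ Uniform(0,1]) reaches size
⌊1/u⌋, capped at N. `growth="stochastic"` multiplies clone sizes by an
Exponential(1) factor to mimic stochastic clone expansion. The simulator
refuses μN > N/10 (mutations must be rare for the model to apply). Its
median reproduces m(ln m + 1.24) and the estimator chain recovers planted
m within 10% at C = 10,000 across m ∈ [5, 2000] (tested).

## LOH tracts and endpoint tests

Within one chromosome, markers are split at the supplied centromere and
each arm walked proximal→distal. Maximal runs of same-direction homozygous
calls become tracts. `MISSING` is transparent — it never starts, ends, or
breaks a run — because a PCR-RFLP gap is absence of evidence, not evidence
of interruption (`missing_breaks` inverts this for sensitivity analysis).
Endpoints are midpoints between the run's outermost homozygous marker and
the adjacent heterozygous marker; the true breakpoint is provably inside
that marker gap, so the midpoint error is bounded by half the local
marker spacing (tested at 100% containment on simulated clones). A run
touching the arm's most distal marker gets no distal endpoint and is
flagged `reaches-last-marker`: a very long interstitial event and a
telomere-reaching event are indistinguishable without more distal markers.
Tract spans are reported as (min, max) bounds: outermost homozygous
markers vs flanking heterozygous markers (or the chromosome end, when its
length is known). An arm with no heterozygous call is flagged
uninformative — homozygosity there cannot be bounded internally — though
its runs are still reported.

Clones are classified `simple` (exactly one selected-arm tract, in the
selected direction, containing the selected marker) or `complex`
(interrupted runs or opposite-direction homozygosity on the selected arm);
tracts on the other arm are annotated as coincident unselected events and
are not, by themselves, complexity. Complex clones are excluded from
endpoint tallies by default, matching standard practice of omitting
non-contiguous/bidirectional tracts from endpoint distributions.

Endpoint counts over J marker-delimited intervals are tested against the
null that breakpoints land in proportion to physical interval length:
`E_j = ΣO · L_j/ΣL`, Pearson χ² with `df = J − 1`, upper-tail p. Two
endpoint distributions are compared with a 2×J contingency χ², also
`df = J − 1` (intervals empty in both rows are dropped). The df
convention is validated by recovering the published statistic→p pairs
(18.51 → ~0.001 and 0.855 → ~0.93 at five intervals). Expected counts
below 5 trigger a warning rather than an error: at cohort sizes of tens
of clones the χ² tail is approximate, which is the field's accepted
practice for these tables.

## ddPCR copy number

Droplets are Poisson partitions: with positive fraction `p`, the
concentration is λ = −ln(1 − p) copies/droplet (computed via `log1p` for
small-p accuracy); a fully positive reaction is saturated and rejected.
Copy number is `target λ / (mean(ref1 λ, ref2 λ)/2)` against two
reference amplicons of known two-copy status; the construction is
scale-invariant in template amount, so pipetting differences cancel.
Droplet volume (default 0.85 nL, instrument-typical) affects only
volumetric units, never CN. Calls are reported unrounded plus a
nearest-integer interpretation within a ±0.3 band — at 20,000 droplets
the sampling error of CN is ~1–2%, so the band separates integer states
decisively.

## Synthetic data: what it emulates, and what it does not

The generator plants every structure the analyses assume, with truth
records for verification:

- **Parent genome** (default): three 500 kb chromosomes, centromere at
  250 kb, one 150 kb heterozygous block (200–350 kb) per chromosome,
  marker density 0.2/kb — ~30 markers per chromosome, sized so the whole
  pipeline runs in seconds. A 16-chromosome preset with yeast-like
  lengths and ~12,000 markers exercises genome scale. Markers exist only
  inside heterozygous blocks; alleles are random distinct bases. The
  recessive locus uses homopolymer tokens (A8 wild / A7 mutant) with the
  mutant allele on the M homolog.
- **Meiosis**: per chromosome, Poisson(crossover_rate = 1) reciprocal
  exchanges between two random chromatids at uniform positions — this
  preserves 2:2 segregation *exactly*, by construction, which is what
  makes the filter oracle tests sharp. Gene conversions copy exponential
  tracts onto one chromatid and deliberately break 2:2. Genotyping error
  (allele flip) and missingness are applied after truth is recorded.
  Crossover interference is not modeled; no tested property needs it.
- **LOH clones**: a mechanism mix of terminal crossover/BIR events
  (breakpoint uniform between centromere and selected marker, or drawn
  from per-interval hotspot weights; homozygous to the chromosome end),
  interstitial gene conversions (exponential tract over the selected
  marker, mean 10 kb), and point contractions (selected marker only),
  default proportions 0.90/0.08/0.02 reflecting the predominance of
  long tracts among selected clones. The selection constraint always
  holds by construction.
- **Fluctuation and ddPCR tables** are emitted at the worked example's
  assay scale (μ = 1.5e-5, N = 5.75e7, 24 cultures; λ = 0.7 at 20,000
  droplets).

Not emulated: sequence reads and variant-calling error structure (input
begins at allele calls), rDNA repeat dynamics, crossover interference,
chromatid-level mechanism signatures (the mechanism labels are tract-shape
categories, not molecular assignments), and selection/fitness effects.
Passing tests therefore demonstrate the *inference machinery* is correct
under the stated statistical model; they do not validate upstream variant
calling or mechanism attribution on real data.

## Problem sizes

Defaults were chosen so each analysis step completes in seconds and the
full suite in well under a minute of compute: 14 tetrads × ~95 markers for
phasing and mapping; 20 seeds for locus-recovery replication; 10,000
cultures for simulator/estimator closure; 1,000 replicate experiments for
CI coverage; 150–200 clones for endpoint properties; 20,000 droplets per
ddPCR amplicon.
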