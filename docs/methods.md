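# Methods

## Coordinate system and standardization

Migration distances are dimensionless gel-units normalized to a 0–100
lane (0 = well). Raw distances are digitized manually, so no physical
unit is assumed. Each lane carries three internal migration standards of
known identity; the warp onto the reference system is the piecewise-linear
monotone interpolant through the (observed, reference) pairs, with linear
extrapolation from the terminal segments. Linear-in-segments is the
minimal monotone choice consistent with three anchor points; it is exact
for any affine per-gel distortion (the dominant distortion mode in
practice and in the simulator) and exact at the standards for any
monotone distortion. Standards observed at identical distances
(co-migration) indicate a failed gel and raise an error rather than being
averaged; observed order contradicting reference order raises a
gel-inversion error. At least two shared standards are required to fit a
warp; lanes without amplification product are never standardized.

## Artifact screening

Heteroduplex artifacts — chimeric double strands formed during community
PCR — appear as thin and/or faint bands either near the top of the gel or
adjacent to an intense band. The screen is purely morphological: a band
is flagged iff it carries the faint/thin digitization flag AND (its
standardized distance is above the top-zone cutoff, default 5.0 units, OR
a bright class-3 band lies within the adjacency window, default 1.0
unit). Flagged bands are excluded from every downstream count. The
defaults are qualitative-knowledge choices (the source material describes
heteroduplex morphology without numbers); both are exposed in
`AssignParams`.

## Ladder matching and sequence affiliation

A standardized band matches the diversity ladder's unique nearest entry
within a tolerance of 0.5 units (0.5% of lane length — half the smallest
plausible inter-species spacing, so adjacent ladder entries can never
both claim a band); an equidistant tie is deliberately left unmatched
rather than broken arbitrarily. Bands absent from the ladder but carrying
an excised-band sequence are affiliated by global alignment: the
alignment maximizes matches (match +1, mismatch 0, gap 0) and identity is
`100 × matches / alignment_columns`, gaps counting toward the
denominator — a conservative definition for near-identical V2–V3
amplicons, which rarely gap. Among co-optimal alignments the shortest is
used, which makes identity well defined; the dynamic program is checked
against exhaustive alignment enumeration in the tests. Two phylotypes
belong to the same SLOTU when identity exceeds 99%; otherwise a new SLOTU
is minted with a content-hash id (`SLOTU-<sha1[:8]>`) so re-runs are
reproducible. Ladder matching always outranks sequence affiliation
because only off-ladder bands were ever sequenced in the workflow this
pipeline models. Unmatched, sequence-less bands are `not_determined`;
their distinct migration distances are reported but not clustered.

## Taxonomy

The packaged default map carries the 50 reference SLOTUs with explicit
GLOTU and PLOTU entries, plus override entries that beat genus-name
derivation: the Enterobacteriaceae merge (*Escherichia*, *Enterobacter*,
*Klebsiella* are not resolvable at 16S V2–V3 level), *Clostridium
innocuum* → Erysipelotrichaceae, *Sarcina ventriculi* as its own
Sarcina/Clostridiaceae group, and an unidentified Burkholderiales
distinct from *Aquabacterium*. Roll-up precedence is override → explicit
map → first-word genus derivation (accepted only if the derived genus is
a known GLOTU). At PLOTU level the phylum Firmicutes is split into its
classes; Erysipelotrichaceae and *Anaerococcus* are tallied with
Clostridia, the operational grouping under which the reference cohort's
50 SLOTUs form exactly 19 GLOTUs and 6 PLOTUs (Bacilli, Clostridia,
Negativicutes, Actinobacteria, Proteobacteria, Fusobacteria). A
class-level Erysipelotrichia group would be defensible cladistically but
would split a six-group scheme that treats these rare bands as
Clostridia-adjacent; user-supplied maps may do so.

## Scores and longitudinal statistics

Band intensity classes 1/2/3 (weak/moderate/bright) are the
semi-quantitative score of the underlying OTU; multiple bands of one
SLOTU in a lane (16S intragenomic variability) take the maximum. Absence
is 0. Days of life bin to weeks by `ceil(day/7)`, so a day-3 first stool
is week 1 and day 56 is week 8. Weekly GLOTU scores average over the
week's analyzable samples and over the GLOTU's member OTUs detected at
least once in that infant — never-detected members contribute nothing,
detected-then-absent members contribute 0 — consistent with a
mean-over-detected-OTUs definition; the weekly maximum is kept separately
for the mean-maximal-score statistic. Samples that failed to amplify are
excluded from all denominators (they carry no information), not treated
as all-zero. Cohort weekly dynamics report both the fraction of infants
sampled that week and the fraction of the whole cohort, because
discharge and death truncate follow-up and the appropriate denominator
is analysis-dependent. Colonization is persistent when strictly more
than 50% of the samples after the first positive are positive; with no
subsequent samples the episode is transient (the rule divides by the
subsequent-sample count and the conservative call is chosen for the
empty case). The classifier is verified against exhaustive enumeration
of all ±-series up to length 8.

## Packaged reference fixture

`load_paper_table1()` returns the transcribed per-SLOTU summary of the
reference cohort: 50 rows (plus a separate not-determined row), each with
positive-sample and infant counts, detection period and score-class
counts, together with the cohort constants (30 infants, 354 samples, 14
amplification failures, 2 infants colonized by both *Enterococcus*
SLOTUs). Loading enforces integrity invariants — 50 rows, score-class
counts summing to the sample count per row — and percentages are always
recomputed from counts at render time; one printed-percentage typo in the
source table (*S. hominis*, 13 samples printed as 13.7% where 13/354 =
3.7%) is preserved verbatim in a remarks field rather than silently
corrected.

## Simulator

The generator emulates the study design the pipeline targets, and its
defaults are the study conditions, not tuning knobs: 30 infants, stools
once or twice a week between day 3 and day 56 (4–15 samples each, mean
≈ 11; dropout 3%/week after week 3 models discharge), 4% amplification
failures, and per-GLOTU colonization parameters chosen so that
staphylococci are near-universal from week 1, enterococci reach ~60% of
infants, clostridia ~70% from week 2 on, enterobacteria ~33% and late,
veillonellae ~27%, bifidobacteria rare. Colonization of a (infant, GLOTU)
pair draws an onset week from a categorical distribution (residual mass =
never colonized); the first sample at or after onset is the initial
recovery; later samples are positive with a per-sample persistence
probability; one SLOTU is drawn per episode (multi-SLOTU carriage exists
in real cohorts — up to 4 staphylococcal or 5 clostridial OTUs per
infant — and can be emulated by adding pool entries, but single-SLOTU
episodes keep ground truth unambiguous). Scores start from an initial
1–3 distribution and evolve by a lazy random walk (stay 0.7, ±1
otherwise, clipped), as no quantitative intensity dynamics are
available to fit.

Gels are rendered one per infant with an affine distortion (slope
0.9–1.1, intercept ±2) applied to true ladder positions; the three
standards pass through the same distortion exactly, bands additionally
receive Gaussian jitter (sd 0.15 units, well inside the 0.5 matching
tolerance). Heteroduplex satellites arise only in samples with ≥ 2
co-amplified taxa (probability 0.55 per taxon pair, calibrated so ~25% of
rendered bands are artifacts, the rate the morphology screen must cope
with); they are faint/thin and placed either in the top zone or 0.6–0.95
units from a bright parent band — outside the matching tolerance but
inside the adjacency window. Spurious faint bands (Poisson mean 0.17 per
lane, yielding a ~7–9% not-determined fraction) fall at off-ladder
positions. Real bands never carry the faint/thin morphology flag: the
flag models the distinctive fuzzy appearance of heteroduplexes, not low
intensity, so a weak (class 1) genuine band is not artifact-eligible.
Everything is reproducible from the seed; band tables from identical
configurations are byte-identical.

What passing the synthetic tests does and does not show: the simulator
shares the pipeline's coordinate conventions and its artifact morphology
model, so recovery tests validate internal consistency, numerical
correctness of the warp/match/score/classify chain, and robustness to the
modeled noise (affine distortion, jitter, artifact load) — they cannot
certify the morphology screen against real gels, detection-limit bias of
TTGE toward dominant populations, nonlinear warps, or co-migration of
distinct species, none of which the generator produces by default.

## Problem sizes and numerics

The default validation workloads are deliberately small — a 30-infant
cohort (~300 lanes, ~900 bands) for end-to-end checks and 100 infants for
parameter recovery — sizes at which every statistic is exact arithmetic
and the whole suite runs in seconds. Matching uses an absolute tie
epsilon of 1e-9 on distances; identity comparisons use exact rational
arithmetic implicitly (integer matches over integer columns). Degenerate
inputs are defined rather than accidental: empty ladders leave all bands
unmatched, empty lanes yield empty assignments, infants with no
affiliated bands have empty profiles and zero diversity, and weeks
without samples are absent from weekly mappings rather than zero.

## Known limitations

- The heteroduplex screen is morphology-only; sequence-level confirmation
  (the decisive evidence in practice) is out of scope.
- One band is assumed per (SLOTU, lane) except through the max-score
  rule; taxa with complex multi-band TTGE profiles are represented as
  several ladder entries mapping to one SLOTU, not modeled mechanistically.
- The identity definition counts gaps as mismatches; for divergent
  sequences (< 95% identity) this underestimates similarity relative to
  gap-excluded definitions, which is irrelevant at the 99% threshold.
- Weekly statistics assume sampling days are exchangeable within a week;
  no within-week time ordering is used.
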