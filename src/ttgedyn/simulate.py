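"""Synthetic cohort and gel simulator with ground truth.

The generator emulates the study conditions the pipeline is built for:
30 very preterm infants sampled once to twice a week between day 3 and
day 56 of life (4-15 samples each, truncated by discharge), dominant
staphylococcal colonization from the first week, delayed enterococcal /
clostridial / enterobacterial colonization, occasional amplification
failures (~4% of samples), heteroduplex artifacts (~25% of rendered
bands) and unassignable faint off-ladder bands (~7%).

Colonization is modeled per (infant, GLOTU): an onset week is drawn from
a categorical distribution over weeks 1-8 (the residual mass is "never
colonized"); the first sample at or after onset is the initial recovery;
each subsequent sample is positive with a per-sample persistence
probability; the SLOTU identity is drawn once per episode; scores start
from an initial 1-3 distribution and evolve by a lazy random walk.

Gels are rendered one per infant: an affine per-gel distortion is applied
to true ladder positions and to the three internal migration standards
(standards exactly, bands with additional Gaussian jitter), heteroduplex
satellites are placed faint/thin in the top zone or just outside the
matching tolerance of a bright parent band, and spurious faint bands fall
at off-ladder positions. Every rendered band carries a provenance label
(real / heteroduplex / spurious) in the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assign import AFFILIATED, ARTIFACT, NOT_DETERMINED, Assignment
from .dynamics import (CohortTimeline, classify_colonization,
                       colonization_status, week_of_life)
from .errors import ConfigError, RecoveryAlignmentError, RenderError
from .model import Band, DiversityLadder, Fingerprint

REAL, HETERODUPLEX, SPURIOUS = "real", "heteroduplex", "spurious"

#: shared reference positions of the three internal migration standards
DEFAULT_STANDARDS = (("STD1", 10.0), ("STD2", 50.0), ("STD3", 90.0))


@dataclass
class GlotuSimParams:
    """Colonization dynamics of one GLOTU in the simulated cohort."""

    onset_week: dict[int, float]       # week -> probability; rest = never
    persistence: float                 # per-sample positivity after onset
    initial_score: dict[int, float]    # score in {1,2,3} at first recovery
    score_stay: float = 0.7            # lazy-walk stay probability

    def validate(self, name: str) -> None:
        tot = sum(self.onset_week.values())
        if not 0 <= tot <= 1 + 1e-9:
            raise ConfigError(f"{name}: onset probabilities sum to {tot}")
        if any(w < 1 for w in self.onset_week):
            raise ConfigError(f"{name}: onset week < 1")
        for p in (self.persistence, self.score_stay):
            if not 0 <= p <= 1:
                raise ConfigError(f"{name}: probability {p} outside [0,1]")
        if abs(sum(self.initial_score.values()) - 1) > 1e-9 or \
                set(self.initial_score) - {1, 2, 3}:
            raise ConfigError(f"{name}: invalid initial score "
                              f"distribution {self.initial_score}")


@dataclass
class GelSimParams:
    """Per-gel distortion and artifact model."""

    slope_range: tuple[float, float] = (0.9, 1.1)
    intercept_range: tuple[float, float] = (-2.0, 2.0)
    jitter_sd: float = 0.15
    heteroduplex_prob: float = 0.55    # per co-amplified taxon pair
    spurious_rate: float = 0.17        # Poisson mean per lane
    failure_prob: float = 0.04         # amplification failure per sample

    def validate(self) -> None:
        for p in (self.heteroduplex_prob, self.failure_prob):
            if not 0 <= p <= 1:
                raise ConfigError(f"probability {p} outside [0,1]")
        if self.jitter_sd < 0 or self.spurious_rate < 0:
            raise ConfigError("jitter_sd and spurious_rate must be >= 0")


def default_glotu_params() -> dict[str, GlotuSimParams]:
    """Colonization defaults reflecting the reference cohort's dynamics:
    universal early staphylococci; enterococci in ~60% of infants with
    onset spread over the study; clostridia in ~70% from week 2 on;
    enterobacteria delayed (~33%, mostly after day 25); veillonellae in
    ~27%; bifidobacteria rare."""
    return {
        "Staphylococcus": GlotuSimParams(
            {1: 0.85, 2: 0.10, 3: 0.05}, 0.90,
            {1: 0.15, 2: 0.25, 3: 0.60}),
        "Enterococcus": GlotuSimParams(
            {1: 0.13, 2: 0.08, 3: 0.08, 4: 0.10, 5: 0.10, 6: 0.06,
             7: 0.05}, 0.85, {1: 0.15, 2: 0.20, 3: 0.65}),
        "Clostridium/Clostridiaceae": GlotuSimParams(
            {2: 0.10, 3: 0.10, 4: 0.15, 5: 0.20, 6: 0.15}, 0.60,
            {1: 0.30, 2: 0.30, 3: 0.40}),
        "Enterobacteriaceae": GlotuSimParams(
            {4: 0.05, 5: 0.05, 6: 0.10, 7: 0.08, 8: 0.05}, 0.70,
            {1: 0.40, 2: 0.10, 3: 0.50}),
        "Veillonella": GlotuSimParams(
            {1: 0.05, 4: 0.10, 5: 0.07, 6: 0.05}, 0.80,
            {1: 0.60, 2: 0.15, 3: 0.25}),
        "Bifidobacterium": GlotuSimParams(
            {1: 0.03, 3: 0.04}, 0.70, {1: 0.35, 2: 0.55, 3: 0.10}),
    }


def default_slotu_pool() -> dict[str, list[tuple[str, float]]]:
    """SLOTUs per GLOTU with their ladder positions (standardized units);
    spacing >= 2.5 units keeps matching unambiguous at tolerance 0.5."""
    return {
        "Staphylococcus": [
            ("Staphylococcus epidermidis group", 20.0),
            ("Staphylococcus haemolyticus", 23.5),
            ("Staphylococcus warneri", 27.0)],
        "Enterococcus": [
            ("Enterococcus faecalis", 35.0),
            ("Enterococcus durans group", 38.0)],
        "Clostridium/Clostridiaceae": [
            ("Clostridium butyricum", 50.0),
            ("Clostridium difficile", 53.0),
            ("Clostridium neonatale", 56.0),
            ("Clostridium perfringens", 59.0)],
        "Enterobacteriaceae": [
            ("Escherichia coli", 70.0),
            ("Klebsiella oxytoca", 73.0)],
        "Veillonella": [
            ("Veillonella dispar", 80.0),
            ("Veillonella parvula", 83.0)],
        "Bifidobacterium": [("Bifidobacterium breve", 88.0)],
    }


@dataclass
class SimConfig:
    seed: int
    n_infants: int = 30
    start_day: int = 3
    end_day: int = 56
    samples_per_week: tuple[int, int] = (1, 2)
    #: weekly probability of leaving the unit (discharge/transfer/death);
    #: applied only after week ``min_followup_weeks`` so every infant has
    #: a few samples, as in the emulated cohort (4-15 samples each)
    dropout_prob: float = 0.03
    min_followup_weeks: int = 3
    glotus: dict[str, GlotuSimParams] = field(
        default_factory=default_glotu_params)
    slotu_pool: dict[str, list[tuple[str, float]]] = field(
        default_factory=default_slotu_pool)
    gel: GelSimParams = field(default_factory=GelSimParams)
    standards_reference: tuple = DEFAULT_STANDARDS

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.end_day < self.start_day:
            raise ConfigError("end_day < start_day")
        if not 0 <= self.dropout_prob <= 1:
            raise ConfigError(f"dropout_prob {self.dropout_prob} "
                              f"outside [0,1]")
        for name, g in self.glotus.items():
            g.validate(name)
            if name not in self.slotu_pool or not self.slotu_pool[name]:
                raise ConfigError(f"GLOTU {name!r} has no SLOTU pool")
        self.gel.validate()

    def ladder(self) -> DiversityLadder:
        entries = [e for pool in self.slotu_pool.values() for e in pool]
        return DiversityLadder(entries=entries)


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort."""

    #: (infant_id, day) -> {slotu: score} for analyzable samples
    scores: dict[tuple[str, int], dict[str, int]] = field(
        default_factory=dict)
    failed: set[tuple[str, int]] = field(default_factory=set)
    #: gel_id -> (slope, intercept) of the affine distortion
    distortions: dict[str, tuple[float, float]] = field(
        default_factory=dict)
    #: band_id -> (provenance, slotu-or-None)
    provenance: dict[str, tuple[str, str | None]] = field(
        default_factory=dict)
    #: (infant_id, glotu) -> onset week drawn (None = never colonized)
    onset: dict[tuple[str, str], int | None] = field(default_factory=dict)

    def sample_keys(self) -> list[tuple[str, int]]:
        return sorted(set(self.scores) | self.failed)


def _categorical(rng, dist: dict[int, float]):
    items = sorted(dist.items())
    u = rng.random()
    acc = 0.0
    for value, p in items:
        acc += p
        if u < acc:
            return value
    return None


def simulate_cohort(config: SimConfig) -> SimTruth:
    """Draw sampling days and true colonization for every infant."""
    rng = np.random.default_rng(config.seed)
    truth = SimTruth()
    n_weeks = week_of_life(config.end_day)
    for i in range(config.n_infants):
        infant = f"I{i + 1:03d}"
        days: list[int] = []
        for week in range(1, n_weeks + 1):
            if week > config.min_followup_weeks and \
                    rng.random() < config.dropout_prob:
                break
            lo = max(config.start_day, (week - 1) * 7 + 1)
            hi = min(config.end_day, week * 7)
            if lo > hi:
                continue
            lo_n, hi_n = config.samples_per_week
            n = int(rng.integers(lo_n, hi_n + 1))
            n = min(n, hi - lo + 1)
            picked = rng.choice(np.arange(lo, hi + 1), size=n,
                                replace=False)
            days.extend(int(d) for d in picked)
        days.sort()
        # colonization per GLOTU, one SLOTU per episode
        sample_scores: dict[int, dict[str, int]] = {d: {} for d in days}
        for glotu in sorted(config.glotus):
            params = config.glotus[glotu]
            onset = _categorical(rng, params.onset_week)
            truth.onset[(infant, glotu)] = onset
            if onset is None:
                continue
            pool = config.slotu_pool[glotu]
            slotu = pool[int(rng.integers(len(pool)))][0]
            score = None
            for day in days:
                if week_of_life(day) < onset:
                    continue
                if score is None:  # initial recovery, always positive
                    score = _categorical(rng, params.initial_score)
                    sample_scores[day][slotu] = score
                    continue
                if rng.random() < params.persistence:
                    if rng.random() >= params.score_stay:
                        step = 1 if rng.random() < 0.5 else -1
                        score = min(3, max(1, score + step))
                    sample_scores[day][slotu] = score
        for day in days:
            if rng.random() < config.gel.failure_prob:
                truth.failed.add((infant, day))
            else:
                truth.scores[(infant, day)] = sample_scores[day]
    return truth


def render_gels(truth: SimTruth, config: SimConfig
                ) -> list[tuple[str, int, Fingerprint]]:
    """Render one gel per infant into band tables with standards."""
    rng = np.random.default_rng(config.seed + 1)
    positions = {slotu: pos for pool in config.slotu_pool.values()
                 for slotu, pos in pool}
    ladder_pos = np.array(sorted(positions.values()))
    gel_p = config.gel
    out: list[tuple[str, int, Fingerprint]] = []
    by_infant: dict[str, list[int]] = {}
    for infant, day in truth.sample_keys():
        by_infant.setdefault(infant, []).append(day)
    for infant in sorted(by_infant):
        gel_id = f"G-{infant}"
        a = rng.uniform(*gel_p.slope_range)
        b = rng.uniform(*gel_p.intercept_range)
        truth.distortions[gel_id] = (a, b)
        for day in sorted(by_infant[infant]):
            sample_id = f"{infant}:d{day:02d}"
            if (infant, day) in truth.failed:
                out.append((infant, day, Fingerprint(
                    sample_id=sample_id, gel_id=gel_id,
                    lane_id=sample_id, amplification_failed=True)))
                continue
            scores = truth.scores[(infant, day)]
            bands: list[Band] = []

            def add_band(true_pos: float, intensity: int,
                         faint_thin: bool, prov: str,
                         slotu: str | None, jitter: bool = True) -> None:
                raw = a * true_pos + b
                if jitter and gel_p.jitter_sd > 0:
                    raw += rng.normal(0.0, gel_p.jitter_sd)
                band_id = f"{sample_id}#{len(bands)}"
                bands.append(Band(band_id=band_id,
                                  distance_raw=max(0.0, raw),
                                  intensity_class=intensity,
                                  is_faint_thin=faint_thin))
                truth.provenance[band_id] = (prov, slotu)

            for slotu in sorted(scores):
                if slotu not in positions:
                    raise RenderError(f"SLOTU {slotu!r} has no ladder "
                                      f"position")
                add_band(positions[slotu], scores[slotu], False, REAL,
                         slotu)
            # heteroduplex satellites need >= 2 co-amplified taxa
            taxa = sorted(scores)
            if len(taxa) >= 2:
                bright = [t for t in taxa if scores[t] == 3]
                n_pairs = len(taxa) * (len(taxa) - 1) // 2
                for _ in range(n_pairs):
                    if rng.random() >= gel_p.heteroduplex_prob:
                        continue
                    if bright and rng.random() < 0.5:
                        parent = bright[int(rng.integers(len(bright)))]
                        offset = rng.uniform(0.6, 0.95) * \
                            (1 if rng.random() < 0.5 else -1)
                        pos = positions[parent] + offset
                    else:
                        pos = rng.uniform(0.5, 4.5)
                    add_band(pos, 1, True, HETERODUPLEX, None,
                             jitter=False)
            # spurious faint off-ladder bands
            for _ in range(int(rng.poisson(gel_p.spurious_rate))):
                for _attempt in range(50):
                    pos = rng.uniform(6.0, 95.0)
                    if np.min(np.abs(ladder_pos - pos)) > 1.2:
                        break
                add_band(pos, 1, False, SPURIOUS, None)
            standards = [(sid, a * ref + b)
                         for sid, ref in config.standards_reference]
            out.append((infant, day, Fingerprint(
                sample_id=sample_id, gel_id=gel_id, lane_id=sample_id,
                bands=bands, standards_observed=standards)))
    return out


def truth_timeline(truth: SimTruth) -> CohortTimeline:
    """The ground-truth cohort timeline (what a perfect pipeline sees)."""
    from .dynamics import SampleRecord
    records = []
    for (infant, day), scores in truth.scores.items():
        records.append(SampleRecord(infant, day, True, dict(scores)))
    for infant, day in truth.failed:
        records.append(SampleRecord(infant, day, False))
    return CohortTimeline(records)


@dataclass
class RecoveryReport:
    """Agreement between pipeline output and simulation ground truth."""

    n_bands: int
    affiliation_precision: float | None
    affiliation_recall: float | None
    artifact_sensitivity: float | None
    artifact_specificity: float | None
    artifact_fraction_true: float
    nd_rate: float
    score_agreement: float | None
    status_agreement: float | None


def evaluate_recovery(assignments_by_sample: dict[str, list[Assignment]],
                      timeline: CohortTimeline,
                      truth: SimTruth) -> RecoveryReport:
    """Score pipeline output against the simulator's ground truth."""
    prov = truth.provenance
    sample_of_band = {}
    for sample_id, assigns in assignments_by_sample.items():
        for a in assigns:
            sample_of_band[a.band_id] = sample_id
            if a.band_id not in prov:
                raise RecoveryAlignmentError(
                    f"band {a.band_id!r} (sample {sample_id!r}) absent "
                    f"from truth")
    all_assigns = [a for assigns in assignments_by_sample.values()
                   for a in assigns]
    n_bands = len(all_assigns)

    def frac(num: int, den: int) -> float | None:
        return num / den if den else None

    pred_aff = [a for a in all_assigns if a.status == AFFILIATED]
    true_real = [a for a in all_assigns if prov[a.band_id][0] == REAL]
    correct = [a for a in pred_aff
               if prov[a.band_id] == (REAL, a.slotu_id)]
    pred_art = [a for a in all_assigns if a.status == ARTIFACT]
    true_hd = [a for a in all_assigns
               if prov[a.band_id][0] == HETERODUPLEX]
    hd_caught = sum(1 for a in pred_art
                    if prov[a.band_id][0] == HETERODUPLEX)
    non_hd = n_bands - len(true_hd)
    non_hd_kept = sum(1 for a in all_assigns
                      if prov[a.band_id][0] != HETERODUPLEX
                      and a.status != ARTIFACT)
    nd = sum(1 for a in all_assigns if a.status == NOT_DETERMINED)

    # per-(infant, day, slotu) score agreement on true positives
    n_scores = n_match = 0
    rec_by_key = {(r.infant_id, r.day): r for r in timeline.records}
    for (infant, day), scores in truth.scores.items():
        rec = rec_by_key.get((infant, day))
        for slotu, score in scores.items():
            n_scores += 1
            if rec is not None and rec.scores.get(slotu, 0) == score:
                n_match += 1

    # per-(infant, slotu) transient/persistent agreement
    n_status = n_status_match = 0
    infants = set(timeline.infant_ids)
    truth_tl = truth_timeline(truth)
    for infant in sorted(infants):
        for slotu in truth_tl.detected_otus(infant):
            n_status += 1
            want = colonization_status(truth_tl, infant, slotu).status
            got = colonization_status(timeline, infant, slotu).status
            n_status_match += want == got
    return RecoveryReport(
        n_bands=n_bands,
        affiliation_precision=frac(len(correct), len(pred_aff)),
        affiliation_recall=frac(len(correct), len(true_real)),
        artifact_sensitivity=frac(hd_caught, len(true_hd)),
        artifact_specificity=frac(non_hd_kept, non_hd),
        artifact_fraction_true=frac(len(true_hd), n_bands) or 0.0,
        nd_rate=frac(nd, n_bands) or 0.0,
        score_agreement=frac(n_match, n_scores),
        status_agreement=frac(n_status_match, n_status),
    )
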