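"""Longitudinal colonization statistics on a scored cohort timeline.

The substrate for every statistic here is the :class:`CohortTimeline`:
for each (infant, day of life) an analyzable flag and a mapping
SLOTU -> semi-quantitative score. Scores are the ordinal 0-3 scale derived
from band intensity (0 absent, 1 weak, 2 moderate, 3 bright); a score of 0
is implicit for any OTU absent from a sample. Days are binned into weeks
of life by ``ceil(day / 7)`` so that the day 3-56 study window spans weeks
1-8. Samples with amplification failure carry no information and are
excluded from all denominators rather than counted as all-zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .assign import AFFILIATED, Assignment
from .errors import ScopeLookupError, ValidationError
from .model import Fingerprint
from .taxonomy import rollup_glotu

TRANSIENT = "transient"
PERSISTENT = "persistent"
NOT_COLONIZED = "not_colonized"


def week_of_life(day_of_life: int) -> int:
    """Week index of a day of life: days 1-7 -> 1, ..., days 50-56 -> 8."""
    if day_of_life < 1:
        raise ValidationError(f"day_of_life {day_of_life} < 1")
    return math.ceil(day_of_life / 7)


def score_sample(fp: Fingerprint,
                 assignments: list[Assignment]) -> dict[str, int]:
    """Per-OTU semi-quantitative score of one sample.

    The score is the band's intensity class; when several bands of a lane
    carry the same SLOTU (e.g. taxa with intragenomic 16S variability),
    the maximum intensity wins. Absent OTUs are implicitly 0.
    """
    intensity = {b.band_id: b.intensity_class for b in fp.bands}
    scores: dict[str, int] = {}
    for a in assignments:
        if a.status != AFFILIATED:
            continue
        if a.band_id not in intensity:
            raise ScopeLookupError(f"assignment for unknown band "
                                   f"{a.band_id!r}")
        scores[a.slotu_id] = max(scores.get(a.slotu_id, 0),
                                 intensity[a.band_id])
    return scores


@dataclass
class SampleRecord:
    infant_id: str
    day: int
    analyzable: bool
    scores: dict[str, int] = field(default_factory=dict)

    @property
    def week(self) -> int:
        return week_of_life(self.day)


@dataclass
class ColonizationStatus:
    otu_id: str
    infant_id: str
    status: str
    first_day: int | None = None
    last_day: int | None = None
    n_subsequent_positive: int = 0
    n_subsequent_total: int = 0


class CohortTimeline:
    """Scored samples of a cohort, indexed by infant and day of life."""

    def __init__(self, records: list[SampleRecord]):
        self.records = sorted(records, key=lambda r: (r.infant_id, r.day))
        self._by_infant: dict[str, list[SampleRecord]] = {}
        for r in self.records:
            self._by_infant.setdefault(r.infant_id, []).append(r)

    @classmethod
    def from_assignments(
            cls,
            samples: list[tuple[str, int, Fingerprint]],
            assignments_by_sample: dict[str, list[Assignment]]
    ) -> "CohortTimeline":
        """Build from ``(infant_id, day, fingerprint)`` triples.

        Failed lanes become non-analyzable records with no scores.
        """
        records = []
        for infant_id, day, fp in samples:
            if fp.amplification_failed:
                records.append(SampleRecord(infant_id, day, False))
                continue
            scores = score_sample(
                fp, assignments_by_sample.get(fp.sample_id, []))
            records.append(SampleRecord(infant_id, day, True, scores))
        return cls(records)

    # -- basic access -----------------------------------------------------

    @property
    def infant_ids(self) -> list[str]:
        return sorted(self._by_infant)

    def samples_of(self, infant_id: str,
                   analyzable_only: bool = True) -> list[SampleRecord]:
        if infant_id not in self._by_infant:
            raise ScopeLookupError(f"unknown infant {infant_id!r}")
        recs = self._by_infant[infant_id]
        return [r for r in recs if r.analyzable] if analyzable_only else recs

    def detected_otus(self, infant_id: str | None = None) -> set[str]:
        recs = (self.samples_of(infant_id) if infant_id is not None
                else [r for r in self.records if r.analyzable])
        return {otu for r in recs for otu, s in r.scores.items() if s > 0}

    # -- weekly statistics ------------------------------------------------

    def weekly_glotu_score(self, infant_id: str, glotu_id: str,
                           tmap) -> dict[int, float]:
        """Mean weekly score of a GLOTU in one infant.

        The mean runs over the week's analyzable samples and over the
        GLOTU's member OTUs that were detected at least once in this
        infant; a detected-then-absent OTU contributes 0 for absent
        samples, while never-detected members contribute nothing. Weeks
        without samples are absent from the mapping.
        """
        members = {otu for otu in self.detected_otus(infant_id)
                   if rollup_glotu(otu, tmap) == glotu_id}
        if not members:
            return {}
        by_week: dict[int, list[float]] = {}
        for rec in self.samples_of(infant_id):
            vals = [rec.scores.get(otu, 0) for otu in sorted(members)]
            by_week.setdefault(rec.week, []).extend(vals)
        return {w: sum(v) / len(v) for w, v in sorted(by_week.items())}

    def weekly_glotu_max(self, infant_id: str, glotu_id: str,
                         tmap) -> dict[int, int]:
        """Max single-sample score of a GLOTU per week in one infant."""
        members = {otu for otu in self.detected_otus(infant_id)
                   if rollup_glotu(otu, tmap) == glotu_id}
        if not members:
            return {}
        by_week: dict[int, int] = {}
        for rec in self.samples_of(infant_id):
            top = max((rec.scores.get(otu, 0) for otu in members),
                      default=0)
            by_week[rec.week] = max(by_week.get(rec.week, 0), top)
        return dict(sorted(by_week.items()))


@dataclass
class WeeklyGlotuStats:
    """One week of cohort-level dynamics for a GLOTU (Figure-4 style)."""

    week: int
    n_sampled: int            # infants with >= 1 analyzable sample
    n_colonized: int          # of those, infants with week score > 0
    fraction_colonized: float         # n_colonized / n_sampled
    fraction_of_cohort: float         # n_colonized / all infants
    mean_score: float | None          # mean weekly score, colonized only
    mean_max_score: float | None      # mean weekly max score, colonized only


def cohort_weekly_dynamics(timeline: CohortTimeline, glotu_id: str,
                           tmap) -> dict[int, WeeklyGlotuStats]:
    """Weekly colonized counts / fractions and mean (max) scores.

    ``fraction_colonized`` uses infants actually sampled that week as the
    denominator; ``fraction_of_cohort`` uses all infants of the timeline
    (both are reported because discharge and death truncate follow-up).
    Means are computed only over the colonized sub-population and are
    ``None`` for weeks without colonized infants.
    """
    n_total = len(timeline.infant_ids)
    sampled: dict[int, set[str]] = {}
    for rec in timeline.records:
        if rec.analyzable:
            sampled.setdefault(rec.week, set()).add(rec.infant_id)
    out: dict[int, WeeklyGlotuStats] = {}
    for week in sorted(sampled):
        scores, maxima = [], []
        for infant in sampled[week]:
            wk_mean = timeline.weekly_glotu_score(infant, glotu_id, tmap)
            wk_max = timeline.weekly_glotu_max(infant, glotu_id, tmap)
            if wk_max.get(week, 0) > 0:
                scores.append(wk_mean[week])
                maxima.append(wk_max[week])
        n_sampled = len(sampled[week])
        n_col = len(scores)
        out[week] = WeeklyGlotuStats(
            week=week, n_sampled=n_sampled, n_colonized=n_col,
            fraction_colonized=n_col / n_sampled,
            fraction_of_cohort=n_col / n_total if n_total else 0.0,
            mean_score=sum(scores) / n_col if n_col else None,
            mean_max_score=sum(maxima) / n_col if n_col else None,
        )
    return out


def detection_period(timeline: CohortTimeline, otu_id: str,
                     infant_id: str | None = None
                     ) -> tuple[int, int] | None:
    """(first_day, last_day) over positive samples, or None if never seen.

    With ``infant_id=None`` the scope is the whole cohort: the earliest
    first and the latest last day over all infants.
    """
    recs = (timeline.samples_of(infant_id) if infant_id is not None
            else [r for r in timeline.records if r.analyzable])
    days = [r.day for r in recs if r.scores.get(otu_id, 0) > 0]
    if not days:
        return None
    return min(days), max(days)


def classify_colonization(series: list[tuple[int, int]], otu_id: str = "",
                          infant_id: str = "") -> ColonizationStatus:
    """Transient/persistent call from a day-sorted (day, score) series.

    Samples strictly after the first positive form the subsequent set;
    the OTU is persistent when more than half of them are positive and
    transient otherwise (including the edge where the first positive is
    the last sample, i.e. the subsequent set is empty).
    """
    series = sorted(series, key=lambda t: t[0])
    positives = [i for i, (_, s) in enumerate(series) if s > 0]
    if not positives:
        return ColonizationStatus(otu_id, infant_id, NOT_COLONIZED)
    first = positives[0]
    subsequent = series[first + 1:]
    n_total = len(subsequent)
    n_pos = sum(1 for _, s in subsequent if s > 0)
    status = PERSISTENT if n_total > 0 and n_pos / n_total > 0.5 \
        else TRANSIENT
    pos_days = [series[i][0] for i in positives]
    return ColonizationStatus(otu_id, infant_id, status,
                              first_day=min(pos_days),
                              last_day=max(pos_days),
                              n_subsequent_positive=n_pos,
                              n_subsequent_total=n_total)


def colonization_status(timeline: CohortTimeline, infant_id: str,
                        otu_id: str) -> ColonizationStatus:
    series = [(r.day, r.scores.get(otu_id, 0))
              for r in timeline.samples_of(infant_id)]
    return classify_colonization(series, otu_id=otu_id,
                                 infant_id=infant_id)


@dataclass
class InfantDiversity:
    infant_id: str
    weekly_mean_otus: dict[int, float]
    max_otus_per_sample: int
    total_otus: int


def diversity_stats(timeline: CohortTimeline) -> dict[str, InfantDiversity]:
    """Per infant: weekly mean distinct SLOTUs per sample, the maximum
    observed in any single sample, and the total over all samples."""
    out: dict[str, InfantDiversity] = {}
    for infant in timeline.infant_ids:
        recs = timeline.samples_of(infant)
        per_week: dict[int, list[int]] = {}
        for r in recs:
            n = sum(1 for s in r.scores.values() if s > 0)
            per_week.setdefault(r.week, []).append(n)
        weekly = {w: sum(v) / len(v) for w, v in sorted(per_week.items())}
        max_per_sample = max(
            (sum(1 for s in r.scores.values() if s > 0) for r in recs),
            default=0)
        out[infant] = InfantDiversity(
            infant_id=infant, weekly_mean_otus=weekly,
            max_otus_per_sample=max_per_sample,
            total_otus=len(timeline.detected_otus(infant)))
    return out
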