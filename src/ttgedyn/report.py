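"""Cohort-level summary artifacts.

Covers the band-accounting reconciliation (detected = artifact +
unassigned + affiliated), the per-SLOTU frequency/score summary table,
the GLOTU repartition of affiliated bands, per-patient PLOTU profiles,
and the packaged machine-readable transcription of the reference cohort's
published summary table (30 very preterm infants, 354 stool samples of
which 14 failed to amplify, 50 SLOTUs).
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

from .assign import AFFILIATED, ARTIFACT, NOT_DETERMINED, Assignment
from .dynamics import CohortTimeline
from .errors import FixtureIntegrityError, ScopeLookupError, ValidationError
from .model import TaxonomyMap
from .taxonomy import rollup_glotu, slotu_to_plotu


@dataclass(frozen=True)
class BandAccounting:
    """Partition of all detected bands into the three assignment fates."""

    n_detected: int
    n_artifact: int
    n_unassigned: int
    n_affiliated: int

    def __post_init__(self) -> None:
        parts = self.n_artifact + self.n_unassigned + self.n_affiliated
        if self.n_detected != parts:
            raise ValidationError(
                f"band accounting does not reconcile: {self.n_detected} "
                f"detected != {self.n_artifact} + {self.n_unassigned} + "
                f"{self.n_affiliated}")

    @classmethod
    def from_counts(cls, n_detected: int, n_artifact: int,
                    n_unassigned: int) -> "BandAccounting":
        return cls(n_detected, n_artifact, n_unassigned,
                   n_detected - n_artifact - n_unassigned)


def reconcile_bands(assignments: list[Assignment]) -> BandAccounting:
    counts = Counter(a.status for a in assignments)
    return BandAccounting(
        n_detected=len(assignments),
        n_artifact=counts.get(ARTIFACT, 0),
        n_unassigned=counts.get(NOT_DETERMINED, 0),
        n_affiliated=counts.get(AFFILIATED, 0))


@dataclass
class OtuSummaryRow:
    """One SLOTU's frequency and semi-quantitative summary."""

    slotu_id: str
    glotu_id: str
    n_samples: int
    n_infants: int
    first_day: int
    last_day: int
    n_score1: int
    n_score2: int
    n_score3: int
    remarks: str = ""

    @property
    def modal_score(self) -> int:
        counts = {1: self.n_score1, 2: self.n_score2, 3: self.n_score3}
        top = max(counts.values())
        # ties resolved toward the higher class
        return max(k for k, v in counts.items() if v == top)

    def pct_samples(self, n_total_samples: int) -> float:
        return 100.0 * self.n_samples / n_total_samples

    def pct_infants(self, n_total_infants: int) -> float:
        return 100.0 * self.n_infants / n_total_infants


def otu_summary_table(timeline: CohortTimeline,
                      tmap: TaxonomyMap) -> list[OtuSummaryRow]:
    """One row per detected SLOTU, sorted by GLOTU occurrence (total
    positive samples, descending) then within-GLOTU sample count."""
    rows = []
    for otu in sorted(timeline.detected_otus()):
        positive = [r for r in timeline.records
                    if r.analyzable and r.scores.get(otu, 0) > 0]
        score_counts = Counter(r.scores[otu] for r in positive)
        rows.append(OtuSummaryRow(
            slotu_id=otu,
            glotu_id=rollup_glotu(otu, tmap),
            n_samples=len(positive),
            n_infants=len({r.infant_id for r in positive}),
            first_day=min(r.day for r in positive),
            last_day=max(r.day for r in positive),
            n_score1=score_counts.get(1, 0),
            n_score2=score_counts.get(2, 0),
            n_score3=score_counts.get(3, 0)))
    glotu_occurrence = Counter()
    for row in rows:
        glotu_occurrence[row.glotu_id] += row.n_samples
    rows.sort(key=lambda r: (-glotu_occurrence[r.glotu_id], r.glotu_id,
                             -r.n_samples, r.slotu_id))
    return rows


def glotu_repartition(assignments: list[Assignment],
                      tmap: TaxonomyMap) -> dict[str, tuple[int, float]]:
    """Per GLOTU: (affiliated band count, % of all affiliated bands)."""
    counts: Counter = Counter()
    for a in assignments:
        if a.status == AFFILIATED:
            counts[rollup_glotu(a.slotu_id, tmap)] += 1
    total = sum(counts.values())
    return {g: (n, 100.0 * n / total)
            for g, n in counts.most_common()}


def patient_plotu_profile(timeline: CohortTimeline, infant_id: str,
                          tmap: TaxonomyMap) -> dict[str, float]:
    """Fraction of an infant's positive OTU occurrences per PLOTU."""
    if infant_id not in timeline.infant_ids:
        raise ScopeLookupError(f"unknown infant {infant_id!r}")
    counts: Counter = Counter()
    for rec in timeline.samples_of(infant_id):
        for otu, score in rec.scores.items():
            if score > 0:
                counts[slotu_to_plotu(otu, tmap)] += 1
    total = sum(counts.values())
    return {p: n / total for p, n in counts.most_common()}


# -- packaged reference summary table ------------------------------------

@dataclass
class FixtureRow(OtuSummaryRow):
    pct_samples_printed: float = 0.0
    pct_infants_printed: float = 0.0


@dataclass
class PaperTable1Fixture:
    """Machine-readable transcription of the reference cohort summary."""

    rows: list[FixtureRow]
    nd_row: FixtureRow
    n_infants: int = 30
    n_samples: int = 354
    n_failed_samples: int = 14
    #: infants colonized by both Enterococcus SLOTUs (stated in the text;
    #: needed to form the genus-level infant union from per-SLOTU counts)
    n_both_enterococcus: int = 2

    @property
    def n_analyzable_samples(self) -> int:
        return self.n_samples - self.n_failed_samples

    @property
    def mean_samples_per_infant(self) -> float:
        return self.n_samples / self.n_infants

    def slotu_ids(self) -> list[str]:
        return [r.slotu_id for r in self.rows]

    def row(self, slotu_id: str) -> FixtureRow:
        for r in self.rows:
            if r.slotu_id == slotu_id:
                return r
        raise ScopeLookupError(f"no fixture row for {slotu_id!r}")

    def infants_with_glotu(self, glotu_id: str,
                           n_multi_colonized: int = 0) -> int:
        """Infants carrying any SLOTU of a GLOTU, by inclusion-exclusion.

        Per-SLOTU infant counts overlap when an infant carries several
        member SLOTUs; ``n_multi_colonized`` is the number of such
        double-counted infants (pairwise overlaps for two-member groups).
        """
        total = sum(r.n_infants for r in self.rows
                    if r.glotu_id == glotu_id)
        return total - n_multi_colonized


def load_paper_table1() -> PaperTable1Fixture:
    """Load and integrity-check the packaged summary-table fixture."""
    path = resources.files("ttgedyn.data") / "table1.tsv"
    rows, nd_row = [], None
    with resources.as_file(path) as p, open(p, newline="") as fh:
        for rec in csv.DictReader(fh, delimiter="\t"):
            row = FixtureRow(
                slotu_id=rec["slotu_id"], glotu_id=rec["glotu_id"],
                n_samples=int(rec["n_samples"]),
                n_infants=int(rec["n_infants"]),
                first_day=int(rec["first_day"]),
                last_day=int(rec["last_day"]),
                n_score1=int(rec["n_score1"]),
                n_score2=int(rec["n_score2"]),
                n_score3=int(rec["n_score3"]),
                remarks=rec.get("remarks") or "",
                pct_samples_printed=float(rec["pct_samples_printed"]),
                pct_infants_printed=float(rec["pct_infants_printed"]))
            if rec["is_nd"] == "1":
                nd_row = row
            else:
                rows.append(row)
    if nd_row is None:
        raise FixtureIntegrityError("fixture lacks the ND row")
    fixture = PaperTable1Fixture(rows=rows, nd_row=nd_row)
    if len(fixture.rows) != 50:
        raise FixtureIntegrityError(
            f"expected 50 SLOTU rows, found {len(fixture.rows)}")
    for row in fixture.rows + [nd_row]:
        if row.n_score1 + row.n_score2 + row.n_score3 != row.n_samples:
            raise FixtureIntegrityError(
                f"{row.slotu_id}: score-class counts do not sum to "
                f"n_samples")
    return fixture


# -- TSV rendering --------------------------------------------------------

def write_summary_table(rows: list[OtuSummaryRow], path,
                        n_total_samples: int, n_total_infants: int) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["slotu_id", "glotu_id", "n_samples", "pct_samples",
                    "n_infants", "pct_infants", "first_day", "last_day",
                    "n_score1", "n_score2", "n_score3", "modal_score"])
        for r in rows:
            w.writerow([r.slotu_id, r.glotu_id, r.n_samples,
                        f"{r.pct_samples(n_total_samples):.1f}",
                        r.n_infants,
                        f"{r.pct_infants(n_total_infants):.1f}",
                        r.first_day, r.last_day,
                        r.n_score1, r.n_score2, r.n_score3, r.modal_score])


def write_accounting(acc: BandAccounting, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["n_detected", "n_artifact", "n_unassigned",
                    "n_affiliated"])
        w.writerow([acc.n_detected, acc.n_artifact, acc.n_unassigned,
                    acc.n_affiliated])


def write_repartition(rep: dict[str, tuple[int, float]], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["glotu_id", "n_bands", "pct_affiliated_bands"])
        for glotu, (n, pct) in rep.items():
            w.writerow([glotu, n, f"{pct:.1f}"])


def write_patient_profiles(timeline: CohortTimeline, tmap: TaxonomyMap,
                           path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["infant_id", "plotu_id", "fraction"])
        for infant in timeline.infant_ids:
            for plotu, frac in patient_plotu_profile(
                    timeline, infant, tmap).items():
                w.writerow([infant, plotu, f"{frac:.4f}"])
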