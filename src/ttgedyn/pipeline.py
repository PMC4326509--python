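"""End-to-end orchestration: standardize -> assign -> score -> timeline."""

from __future__ import annotations

from .assign import AssignParams, Assignment, SlotuRegistry, \
    assign_fingerprint
from .dynamics import CohortTimeline
from .model import DiversityLadder, Fingerprint
from .standardize import standardize_fingerprint


def analyze_cohort(samples: list[tuple[str, int, Fingerprint]],
                   standards_reference: list[tuple[str, float]],
                   ladder: DiversityLadder,
                   params: AssignParams | None = None,
                   sequences: dict[str, str] | None = None,
                   ) -> tuple[CohortTimeline,
                              dict[str, list[Assignment]]]:
    """Run the full analysis over ``(infant_id, day, fingerprint)`` triples.

    Failed lanes pass through unstandardized (they carry no bands) and
    become non-analyzable timeline records. Returns the scored timeline
    and the per-sample assignments.
    """
    params = params or AssignParams()
    registry = SlotuRegistry()
    standardized: list[tuple[str, int, Fingerprint]] = []
    assignments: dict[str, list[Assignment]] = {}
    for infant_id, day, fp in samples:
        if fp.amplification_failed:
            standardized.append((infant_id, day, fp))
            assignments[fp.sample_id] = []
            continue
        std = standardize_fingerprint(fp, list(standards_reference))
        standardized.append((infant_id, day, std))
        assignments[fp.sample_id] = assign_fingerprint(
            std, ladder, params, sequences=sequences, registry=registry)
    timeline = CohortTimeline.from_assignments(standardized, assignments)
    return timeline, assignments
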