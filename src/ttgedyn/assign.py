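"""Band assignment: artifact screening, ladder matching, sequence affiliation.

Assignment proceeds in a fixed order for every standardized lane:

1. heteroduplex screening — faint/thin bands near the top of the gel or
   adjacent to a bright (class 3) band are PCR artifacts (chimeric
   double strands) and are excluded from all downstream counting;
2. ladder matching — the band's standardized distance is compared with the
   diversity ladder; the unique nearest entry within tolerance wins, a
   symmetric tie is left unmatched;
3. sequence affiliation — unmatched bands with an excised-band sequence are
   affiliated to the reference SLOTU of maximal identity when that identity
   exceeds 99%, otherwise a new SLOTU is minted with the sequence as
   representative;
4. anything left is ``not_determined`` (typically too faint to excise).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

from .errors import ValidationError
from .model import DiversityLadder, Fingerprint

AFFILIATED = "affiliated"
ARTIFACT = "artifact_heteroduplex"
NOT_DETERMINED = "not_determined"

#: identity (percent) above which two phylotypes are the same SLOTU
SLOTU_IDENTITY_THRESHOLD = 99.0

_TIE_EPS = 1e-9


@dataclass(frozen=True)
class AssignParams:
    """Tunable thresholds of the assignment stage (standardized gel-units).

    tolerance
        maximum |standardized distance - ladder entry| for a ladder match;
        0.5 (0.5% of lane length) keeps adjacent ladder entries from both
        falling inside one window.
    hd_top_zone
        distance below which a faint/thin band is artifact-eligible.
    hd_adjacency
        maximum gap to a class-3 band for satellite-artifact flagging.
    """

    tolerance: float = 0.5
    hd_top_zone: float = 5.0
    hd_adjacency: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tolerance", "hd_top_zone", "hd_adjacency"):
            if getattr(self, name) <= 0:
                raise ValidationError(
                    f"AssignParams.{name} must be > 0, got "
                    f"{getattr(self, name)}")


@dataclass
class Assignment:
    """Outcome for one band: exactly one of the three statuses."""

    band_id: str
    status: str
    slotu_id: str | None = None
    method: str | None = None  # "ladder" | "sequence" when affiliated
    match_delta: float | None = None

    def __post_init__(self) -> None:
        if self.status not in (AFFILIATED, ARTIFACT, NOT_DETERMINED):
            raise ValidationError(f"unknown assignment status "
                                  f"{self.status!r}")
        if (self.slotu_id is not None) != (self.status == AFFILIATED):
            raise ValidationError(
                f"band {self.band_id!r}: slotu_id must be present iff "
                f"affiliated")


@dataclass
class SlotuRegistry:
    """Reference SLOTU representative sequences, extensible by minting."""

    references: list[tuple[str, str]] = field(default_factory=list)

    def ids(self) -> list[str]:
        return [sid for sid, _ in self.references]


def _std(band) -> float:
    if band.distance_std is None:
        raise ValidationError(
            f"band {band.band_id!r} has no standardized distance; "
            f"run standardization first")
    return band.distance_std


def flag_heteroduplex(fp: Fingerprint, params: AssignParams) -> set[str]:
    """Return band_ids of heteroduplex-artifact candidates in a lane.

    A band is flagged iff it is faint/thin AND (it sits above
    ``hd_top_zone`` OR a bright class-3 band lies within ``hd_adjacency``
    of it on either side).
    """
    flagged: set[str] = set()
    bright = [_std(b) for b in fp.bands if b.intensity_class == 3]
    for band in fp.bands:
        if not band.is_faint_thin:
            continue
        d = _std(band)
        if d < params.hd_top_zone:
            flagged.add(band.band_id)
        elif any(abs(d - bd) <= params.hd_adjacency for bd in bright):
            flagged.add(band.band_id)
    return flagged


def match_ladder(distance_std: float, ladder: DiversityLadder,
                 tolerance: float) -> str | None:
    """Nearest ladder entry within tolerance; ``None`` if absent or tied."""
    best_id, best_delta = None, None
    tied = False
    for slotu, ref in ladder.entries:
        delta = abs(distance_std - ref)
        if delta > tolerance:
            continue
        if best_delta is None or delta < best_delta - _TIE_EPS:
            best_id, best_delta, tied = slotu, delta, False
        elif abs(delta - best_delta) <= _TIE_EPS:
            tied = True
    return None if tied else best_id


def seq_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of the global alignment maximizing matches.

    Scoring: match +1, mismatch 0, gaps 0 (a gap column counts as a
    mismatch in the identity denominator). Among alignments with maximal
    matches the shortest (fewest columns) is used, so
    ``identity = 100 * matches / alignment_length``. Symmetric in its
    arguments.
    """
    a, b = seq_a.upper(), seq_b.upper()
    for name, s in (("seq_a", a), ("seq_b", b)):
        if not s:
            raise ValidationError(f"{name} is empty")
        bad = sorted(set(s) - set("ACGTN"))
        if bad:
            raise ValidationError(f"{name}: non-DNA character(s) {bad}")
    n, m = len(a), len(b)
    # DP over (matches, -columns), maximized lexicographically.
    prev = [(0, -j) for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [(0, -i)]
        ai = a[i - 1]
        for j in range(1, m + 1):
            mm, mc = prev[j - 1]
            diag = (mm + (1 if ai == b[j - 1] else 0), mc - 1)
            um, uc = prev[j]
            lm, lc = cur[j - 1]
            cur.append(max(diag, (um, uc - 1), (lm, lc - 1)))
        prev = cur
    matches, neg_cols = prev[m]
    return 100.0 * matches / (-neg_cols)


def affiliate_sequence(seq: str, registry: SlotuRegistry,
                       threshold: float = SLOTU_IDENTITY_THRESHOLD) -> str:
    """Affiliate a band sequence to a SLOTU, minting a new one if needed.

    The sequence joins the reference SLOTU of maximal identity when that
    identity strictly exceeds ``threshold`` (ties broken by first-listed
    reference); otherwise a new SLOTU keyed by a content hash of the
    sequence is appended to the registry and returned.
    """
    best_id, best_ident = None, -1.0
    for slotu, ref_seq in registry.references:
        ident = seq_identity(seq, ref_seq)
        if ident > best_ident + _TIE_EPS:
            best_id, best_ident = slotu, ident
    if best_id is not None and best_ident > threshold:
        return best_id
    digest = hashlib.sha1(seq.upper().encode()).hexdigest()[:8]
    new_id = f"SLOTU-{digest}"
    if new_id not in registry.ids():
        registry.references.append((new_id, seq.upper()))
    return new_id


def assign_fingerprint(fp: Fingerprint, ladder: DiversityLadder,
                       params: AssignParams,
                       sequences: dict[str, str] | None = None,
                       registry: SlotuRegistry | None = None
                       ) -> list[Assignment]:
    """Assign every band of a standardized lane; see module docstring."""
    sequences = sequences or {}
    flagged = flag_heteroduplex(fp, params)
    out: list[Assignment] = []
    for band in fp.bands:
        if band.band_id in flagged:
            out.append(Assignment(band.band_id, ARTIFACT))
            continue
        d = _std(band)
        slotu = match_ladder(d, ladder, params.tolerance)
        if slotu is not None:
            ref = dict(ladder.entries)[slotu]
            out.append(Assignment(band.band_id, AFFILIATED, slotu_id=slotu,
                                  method="ladder",
                                  match_delta=abs(d - ref)))
            continue
        if band.sequence_ref and band.sequence_ref in sequences:
            if registry is None:
                registry = SlotuRegistry()
            slotu = affiliate_sequence(sequences[band.sequence_ref],
                                       registry)
            out.append(Assignment(band.band_id, AFFILIATED, slotu_id=slotu,
                                  method="sequence"))
            continue
        out.append(Assignment(band.band_id, NOT_DETERMINED))
    return out
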