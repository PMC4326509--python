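"""Core domain types of the TTGE fingerprint pipeline.

Migration distances are dimensionless gel-units on a 0-100 scale
(0 = well / top of the gel, increasing downward); lanes are digitized
with the distance of each band, an ordinal intensity class in {1, 2, 3}
(weak / moderate / bright) and a faint-or-thin morphology flag used by
heteroduplex-artifact screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import ValidationError

INTENSITY_CLASSES = (1, 2, 3)

#: Default study window (days of life) for stool sampling.
STUDY_WINDOW = (1, 56)


@dataclass
class Band:
    """One detected gel band inside a lane."""

    band_id: str
    distance_raw: float
    intensity_class: int
    is_faint_thin: bool = False
    sequence_ref: str | None = None
    #: filled by standardization; ``None`` until the lane has been warped
    distance_std: float | None = None

    def __post_init__(self) -> None:
        if self.distance_raw < 0:
            raise ValidationError(
                f"band {self.band_id!r}: negative migration distance "
                f"{self.distance_raw}"
            )
        if self.intensity_class not in INTENSITY_CLASSES:
            raise ValidationError(
                f"band {self.band_id!r}: intensity class "
                f"{self.intensity_class!r} not in {INTENSITY_CLASSES}"
            )


@dataclass
class Fingerprint:
    """All bands of one sample's lane, plus its internal migration standards.

    ``standards_observed`` holds ``(standard_id, observed_distance)`` pairs
    for the internal migration standards co-loaded in the lane; they anchor
    the warp onto the shared reference coordinate system.
    """

    sample_id: str
    gel_id: str
    lane_id: str
    bands: list[Band] = field(default_factory=list)
    standards_observed: list[tuple[str, float]] = field(default_factory=list)
    amplification_failed: bool = False

    def __post_init__(self) -> None:
        if self.amplification_failed and self.bands:
            raise ValidationError(
                f"lane {self.lane_id!r}: amplification failed but "
                f"{len(self.bands)} bands present"
            )
        self.bands = sorted(self.bands, key=lambda b: b.distance_raw)

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def with_bands(self, bands: list[Band]) -> "Fingerprint":
        return replace(self, bands=bands)


@dataclass
class DiversityLadder:
    """Reference migration distances of known SLOTUs (the matching target).

    The ladder is a lane of amplicons from identified isolates; a band is
    affiliated to a SLOTU when it co-migrates with the SLOTU's ladder entry.
    """

    entries: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [slotu for slotu, _ in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate ladder SLOTU id(s): {dup}")
        for slotu, dist in self.entries:
            if dist <= 0:
                raise ValidationError(
                    f"ladder entry {slotu!r}: non-positive distance {dist}"
                )
        self.entries = sorted(self.entries, key=lambda e: e[1])

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def slotu_ids(self) -> list[str]:
        return [slotu for slotu, _ in self.entries]

    @property
    def distances(self) -> list[float]:
        return [dist for _, dist in self.entries]


@dataclass
class StoolSample:
    """One stool specimen: an infant, a day of life, and its fingerprint."""

    infant_id: str
    day_of_life: int
    fingerprint: Fingerprint

    def __post_init__(self) -> None:
        if self.day_of_life < 1:
            raise ValidationError(
                f"sample of infant {self.infant_id!r}: day_of_life "
                f"{self.day_of_life} < 1"
            )

    def check_window(self, window: tuple[int, int] = STUDY_WINDOW) -> None:
        lo, hi = window
        if not lo <= self.day_of_life <= hi:
            raise ValidationError(
                f"sample of infant {self.infant_id!r}: day "
                f"{self.day_of_life} outside study window {window}"
            )


@dataclass
class Infant:
    infant_id: str
    gestational_age_weeks: float | None = None
    birth_weight_g: float | None = None
    samples: list[StoolSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = sorted(self.samples, key=lambda s: s.day_of_life)


@dataclass
class TaxonomyMap:
    """SLOTU -> GLOTU -> PLOTU hierarchy with explicit override entries.

    ``overrides`` take precedence over ``slotu_to_glotu``, which in turn
    takes precedence over genus-name derivation (first word of the SLOTU id).
    """

    slotu_to_glotu: dict[str, str] = field(default_factory=dict)
    glotu_to_plotu: dict[str, str] = field(default_factory=dict)
    overrides: dict[str, str] = field(default_factory=dict)
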