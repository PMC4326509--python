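"""Shared fixtures: hand-built lanes and a small scored cohort."""

from __future__ import annotations

import pytest

from ttgedyn import Band, CohortTimeline, Fingerprint, SampleRecord

STANDARDS_REF = [("STD1", 10.0), ("STD2", 50.0), ("STD3", 90.0)]


def make_band(band_id: str, distance: float, intensity: int = 2,
              faint_thin: bool = False, std: float | None = None,
              seq_ref: str | None = None) -> Band:
    band = Band(band_id=band_id, distance_raw=distance,
                intensity_class=intensity, is_faint_thin=faint_thin,
                sequence_ref=seq_ref)
    band.distance_std = distance if std is None else std
    return band


def make_lane(bands: list[Band], sample_id: str = "S1",
              standards=None) -> Fingerprint:
    return Fingerprint(sample_id=sample_id, gel_id="G1",
                       lane_id=sample_id, bands=bands,
                       standards_observed=standards or
                       [(s, d) for s, d in STANDARDS_REF])


@pytest.fixture
def standards_ref():
    return list(STANDARDS_REF)


@pytest.fixture
def two_infant_timeline() -> CohortTimeline:
    """Two infants, four samples, two OTUs; OTU A in 3 of 4 samples."""
    return CohortTimeline([
        SampleRecord("I1", 5, True, {"A": 3, "B": 1}),
        SampleRecord("I1", 12, True, {"A": 1}),
        SampleRecord("I2", 6, True, {"A": 2}),
        SampleRecord("I2", 20, True, {"B": 2}),
    ])
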