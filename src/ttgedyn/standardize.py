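"""Lane standardization onto the shared reference coordinate system.

Each lane carries three internal migration standards of known identity.
Comparing their observed migration distances with the shared reference
positions yields a monotone piecewise-linear warp (linear extrapolation
beyond the terminal standards) that maps every band of the lane into
standardized gel-units, making bands comparable across lanes and gels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import interp1d

from .errors import GelInversionError, StandardizationError
from .model import Fingerprint


@dataclass(frozen=True)
class WarpFunction:
    """Monotone piecewise-linear map observed -> reference distance."""

    knots: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.knots) < 2:
            raise StandardizationError(
                f"warp needs >= 2 knots, got {len(self.knots)}")
        obs = [k[0] for k in self.knots]
        ref = [k[1] for k in self.knots]
        if any(b <= a for a, b in zip(obs, obs[1:])):
            raise StandardizationError(
                f"warp knots not strictly increasing in observed "
                f"coordinate: {obs}")
        if any(b <= a for a, b in zip(ref, ref[1:])):
            raise GelInversionError(
                f"warp knots not strictly increasing in reference "
                f"coordinate: {ref}")

    def __call__(self, distance_raw):
        obs = np.array([k[0] for k in self.knots])
        ref = np.array([k[1] for k in self.knots])
        f = interp1d(obs, ref, kind="linear", fill_value="extrapolate",
                     assume_sorted=True)
        out = f(distance_raw)
        return float(out) if np.isscalar(distance_raw) else out


def fit_warp(standards_observed: list[tuple[str, float]],
             standards_reference: list[tuple[str, float]]) -> WarpFunction:
    """Fit the lane warp from observed vs reference standard positions.

    Standards are matched by id; at least two must be shared. Two standards
    observed at the same distance (co-migration) indicate a failed gel and
    raise; observed order contradicting reference order raises a
    gel-inversion error.
    """
    ref_by_id = dict(standards_reference)
    shared = [(obs, ref_by_id[sid]) for sid, obs in standards_observed
              if sid in ref_by_id]
    if len(shared) < 2:
        raise StandardizationError(
            f"need >= 2 shared standards to standardize, got {len(shared)}")
    shared.sort(key=lambda k: k[0])
    obs = [o for o, _ in shared]
    if any(b == a for a, b in zip(obs, obs[1:])):
        raise StandardizationError(
            f"co-migrating standards (duplicate observed distance) in "
            f"{obs}; gel failure")
    return WarpFunction(knots=tuple(shared))


def apply_warp(warp: WarpFunction, distance_raw):
    """Standardize one distance (or an array of distances)."""
    return warp(distance_raw)


def standardize_fingerprint(
        fp: Fingerprint,
        standards_reference: list[tuple[str, float]]) -> Fingerprint:
    """Return a copy of ``fp`` with ``distance_std`` set on every band."""
    if fp.amplification_failed:
        raise StandardizationError(
            f"lane {fp.lane_id!r}: cannot standardize a failed lane")
    try:
        warp = fit_warp(fp.standards_observed, standards_reference)
    except StandardizationError as exc:
        raise type(exc)(f"lane {fp.lane_id!r}: {exc}") from exc
    bands = [replace(b, distance_std=apply_warp(warp, b.distance_raw))
             for b in fp.bands]
    return fp.with_bands(bands)
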