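"""Readers and writers for the pipeline's tab-separated artifacts.

File formats
------------
band table (TSV)
    columns ``gel_id, lane_id, sample_id, distance, intensity, faint_thin,
    seq_ref, failed``; one row per band. A lane that yielded no PCR product
    is encoded as a single sidecar row with ``failed = 1`` and empty band
    fields. An optional ``distance_std`` column is written after
    standardization. Internal-standard observations travel in a separate
    standards TSV (``gel_id, lane_id, standard_id, distance`` for observed,
    or ``standard_id, distance`` for the shared reference positions).
ladder (TSV)
    columns ``slotu_id, reference_distance``.
taxonomy map (TSV)
    columns ``slotu_id, glotu_id, plotu_id``.
metadata (TSV)
    columns ``sample_id, infant_id, day_of_life``.
sequences (FASTA)
    excised-band sequences keyed by the band table's ``seq_ref``.
"""

from __future__ import annotations

import csv
from pathlib import Path

from Bio import SeqIO

from .errors import FormatError, ValidationError
from .model import Band, DiversityLadder, Fingerprint, TaxonomyMap

_BAND_COLUMNS = ["gel_id", "lane_id", "sample_id", "distance", "intensity",
                 "faint_thin", "seq_ref", "failed"]

_DNA_ALPHABET = set("ACGTN")


def _read_rows(path: str | Path, required: list[str]) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in required:
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        return list(reader)


def _parse_bool(value: str) -> bool:
    return value.strip().lower() in {"1", "true", "yes", "y"}


def read_band_table(path: str | Path) -> list[Fingerprint]:
    """Parse a band table into one :class:`Fingerprint` per (gel, lane)."""
    rows = _read_rows(path, ["gel_id", "lane_id", "sample_id", "distance",
                             "intensity", "faint_thin"])
    lanes: dict[tuple[str, str], dict] = {}
    for i, row in enumerate(rows, start=2):  # 1-based incl. header
        key = (row["gel_id"], row["lane_id"])
        lane = lanes.setdefault(key, {"sample_id": row["sample_id"],
                                      "bands": [], "failed": False})
        if _parse_bool(row.get("failed") or ""):
            lane["failed"] = True
            continue
        try:
            distance = float(row["distance"])
            intensity = int(row["intensity"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
        if intensity not in (1, 2, 3):
            raise ValidationError(
                f"{path}: row {i}: intensity {intensity} outside {{1,2,3}}")
        if distance < 0:
            raise ValidationError(
                f"{path}: row {i}: negative distance {distance}")
        band = Band(
            band_id=f"{row['gel_id']}:{row['lane_id']}:{len(lane['bands'])}",
            distance_raw=distance,
            intensity_class=intensity,
            is_faint_thin=_parse_bool(row["faint_thin"]),
            sequence_ref=(row.get("seq_ref") or None) or None,
        )
        if "distance_std" in row and (row["distance_std"] or "").strip():
            band.distance_std = float(row["distance_std"])
        lane["bands"].append(band)
    out = []
    for (gel_id, lane_id), lane in lanes.items():
        out.append(Fingerprint(
            sample_id=lane["sample_id"], gel_id=gel_id, lane_id=lane_id,
            bands=[] if lane["failed"] else lane["bands"],
            amplification_failed=lane["failed"],
        ))
    return out


def write_band_table(fingerprints: list[Fingerprint],
                     path: str | Path) -> None:
    with_std = any(b.distance_std is not None
                   for fp in fingerprints for b in fp.bands)
    cols = _BAND_COLUMNS + (["distance_std"] if with_std else [])
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for fp in fingerprints:
            if fp.amplification_failed:
                writer.writerow([fp.gel_id, fp.lane_id, fp.sample_id,
                                 "", "", "", "", "1"] +
                                ([""] if with_std else []))
                continue
            for b in fp.bands:
                row = [fp.gel_id, fp.lane_id, fp.sample_id,
                       f"{b.distance_raw:g}", b.intensity_class,
                       int(b.is_faint_thin), b.sequence_ref or "", "0"]
                if with_std:
                    row.append("" if b.distance_std is None
                               else f"{b.distance_std:g}")
                writer.writerow(row)


def read_standards(path: str | Path) -> dict:
    """Read internal-standard positions.

    With ``gel_id``/``lane_id`` columns, returns
    ``{(gel_id, lane_id): [(standard_id, distance), ...]}``; without them,
    returns the shared reference list ``[(standard_id, distance), ...]``.
    """
    with open(path, newline="") as fh:
        header = (fh.readline() or "").rstrip("\n").split("\t")
    per_lane = "lane_id" in header
    required = (["gel_id", "lane_id"] if per_lane else []) + \
        ["standard_id", "distance"]
    rows = _read_rows(path, required)
    if not per_lane:
        return [(r["standard_id"], float(r["distance"])) for r in rows]
    out: dict[tuple[str, str], list[tuple[str, float]]] = {}
    for r in rows:
        out.setdefault((r["gel_id"], r["lane_id"]), []).append(
            (r["standard_id"], float(r["distance"])))
    return out


def read_ladder(path: str | Path) -> DiversityLadder:
    rows = _read_rows(path, ["slotu_id", "reference_distance"])
    entries = [(r["slotu_id"], float(r["reference_distance"])) for r in rows]
    return DiversityLadder(entries=entries)  # validates duplicates/sign


def write_ladder(ladder: DiversityLadder, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["slotu_id", "reference_distance"])
        for slotu, dist in ladder.entries:
            writer.writerow([slotu, f"{dist:g}"])


def read_sequences(path: str | Path) -> dict[str, str]:
    """Read excised-band sequences from FASTA, keyed by record id.

    Sequences are uppercased and restricted to the DNA alphabet ACGTN.
    """
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise ValidationError(f"{path}: duplicate sequence id "
                                  f"{record.id!r}")
        seq = str(record.seq).upper()
        bad = sorted(set(seq) - _DNA_ALPHABET)
        if bad:
            raise ValidationError(
                f"{path}: record {record.id!r}: non-DNA character(s) {bad}")
        out[record.id] = seq
    return out


def read_taxonomy(path: str | Path,
                  overrides: dict[str, str] | None = None) -> TaxonomyMap:
    rows = _read_rows(path, ["slotu_id", "glotu_id", "plotu_id"])
    slotu_to_glotu: dict[str, str] = {}
    glotu_to_plotu: dict[str, str] = {}
    for r in rows:
        if r["slotu_id"] in slotu_to_glotu:
            raise ValidationError(f"{path}: duplicate SLOTU "
                                  f"{r['slotu_id']!r}")
        slotu_to_glotu[r["slotu_id"]] = r["glotu_id"]
        prev = glotu_to_plotu.get(r["glotu_id"])
        if prev is not None and prev != r["plotu_id"]:
            raise ValidationError(
                f"{path}: GLOTU {r['glotu_id']!r} mapped to both "
                f"{prev!r} and {r['plotu_id']!r}")
        glotu_to_plotu[r["glotu_id"]] = r["plotu_id"]
    return TaxonomyMap(slotu_to_glotu=slotu_to_glotu,
                       glotu_to_plotu=glotu_to_plotu,
                       overrides=dict(overrides or {}))


def write_assignments(assignments_by_sample: dict[str, list],
                      path: str | Path) -> None:
    """Write per-band assignments (``sample_id, band_id, status,
    slotu_id, method, match_delta``)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "band_id", "status", "slotu_id",
                         "method", "match_delta"])
        for sample_id in sorted(assignments_by_sample):
            for a in assignments_by_sample[sample_id]:
                writer.writerow([
                    sample_id, a.band_id, a.status, a.slotu_id or "",
                    a.method or "",
                    "" if a.match_delta is None
                    else f"{a.match_delta:.4f}"])


def read_assignments(path: str | Path) -> dict[str, list]:
    from .assign import Assignment

    rows = _read_rows(path, ["sample_id", "band_id", "status"])
    out: dict[str, list] = {}
    for r in rows:
        out.setdefault(r["sample_id"], []).append(Assignment(
            band_id=r["band_id"], status=r["status"],
            slotu_id=(r.get("slotu_id") or None) or None,
            method=(r.get("method") or None) or None,
            match_delta=(float(r["match_delta"])
                         if (r.get("match_delta") or "").strip() else None)))
    return out


def read_metadata(path: str | Path) -> dict[str, tuple[str, int]]:
    """Map ``sample_id`` to ``(infant_id, day_of_life)``."""
    rows = _read_rows(path, ["sample_id", "infant_id", "day_of_life"])
    out: dict[str, tuple[str, int]] = {}
    for r in rows:
        if r["sample_id"] in out:
            raise ValidationError(f"{path}: duplicate sample id "
                                  f"{r['sample_id']!r}")
        day = int(r["day_of_life"])
        if day < 1:
            raise ValidationError(f"{path}: sample {r['sample_id']!r}: "
                                  f"day_of_life {day} < 1")
        out[r["sample_id"]] = (r["infant_id"], day)
    return out
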