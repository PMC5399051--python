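"""Reading, writing, validating and bilaterally merging wing-landmark data.

Two plain-text containers are supported:

* the TPS dialect common in morphometrics (``LM=``, ``ID=``, ``IMAGE=``,
  ``SCALE=`` records, 2-D only), and
* a delimited table with header ``specimen_id,taxon,side,x1,y1,...,xk,yk``.

Landmark order is semantic: index *i* in one configuration is homologous to
index *i* in every other, so readers never reorder points and reject records
whose landmark count differs from the dataset's declared count.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._geometry import (
    DegenerateConfigurationError,
    as_points,
    centroid_size,
    preshape,
    rotation_onto,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LandmarkError",
    "TpsParseError",
    "TableParseError",
    "LandmarkConfiguration",
    "SpecimenRecord",
    "read_tps",
    "write_tps",
    "read_table",
    "write_table",
    "reflect",
    "merge_sides",
    "build_records",
]

SIDES = ("left", "right", "merged")

#: relative tolerance below which a configuration counts as collinear
_COLLINEARITY_RTOL = 1e-10


class LandmarkError(ValueError):
    """Invalid landmark data (wrong count, collinear, bad side, ...)."""


class TpsParseError(LandmarkError):
    """Malformed TPS stream; message carries the offending record/line."""


class TableParseError(LandmarkError):
    """Malformed delimited table; message carries the offending row."""


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One wing's ordered 2-D landmarks plus specimen metadata.

    Parameters
    ----------
    points
        ``(k, 2)`` array of coordinates in arbitrary but consistent length
        units.  At least 3 landmarks, not all collinear (otherwise the optimal
        rotation in superimposition is underdetermined).
    specimen_id
        Identifier of the individual the wing belongs to.
    taxon
        Training label; ``None`` for unknowns that are to be classified.
    side
        ``"left"``, ``"right"`` or ``"merged"`` (the left/right average used
        as the analysis unit).
    scale
        Optional digitization metadata (pixels per length unit).  Never used
        in the analysis: shape is scale-free.
    """

    points: np.ndarray
    specimen_id: str = ""
    taxon: str | None = None
    side: str = "right"
    scale: float | None = None

    def __post_init__(self):
        pts = as_points(self.points)
        if pts.shape[0] < 3:
            raise LandmarkError(
                f"configuration '{self.specimen_id}': need at least 3 landmarks, got {pts.shape[0]}"
            )
        if self.side not in SIDES:
            raise LandmarkError(f"side must be one of {SIDES}, got {self.side!r}")
        centred = pts - pts.mean(axis=0)
        svals = np.linalg.svd(centred, compute_uv=False)
        if svals[0] == 0.0 or svals[1] <= _COLLINEARITY_RTOL * svals[0]:
            raise DegenerateConfigurationError(
                f"configuration '{self.specimen_id}': landmarks are collinear or coincident; "
                "rotation would be underdetermined"
            )
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    @property
    def n_landmarks(self) -> int:
        return self.points.shape[0]

    def with_points(self, points: np.ndarray, **meta) -> "LandmarkConfiguration":
        """Copy of this configuration with new coordinates (and metadata overrides)."""
        kwargs = dict(
            specimen_id=self.specimen_id, taxon=self.taxon, side=self.side, scale=self.scale
        )
        kwargs.update(meta)
        return LandmarkConfiguration(points=np.array(points, dtype=float), **kwargs)


@dataclass
class SpecimenRecord:
    """Left/right wing pair of one specimen; ``merged`` is the analysis unit."""

    specimen_id: str
    taxon: str | None = None
    left: LandmarkConfiguration | None = None
    right: LandmarkConfiguration | None = None
    merged: LandmarkConfiguration | None = None

    def __post_init__(self):
        if self.left is None and self.right is None:
            raise LandmarkError(f"specimen '{self.specimen_id}': no wing configuration present")


# ---------------------------------------------------------------------------
# TPS dialect
# ---------------------------------------------------------------------------


def _open_maybe(source, mode="r"):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(os.fspath(source), mode), True


def read_tps(stream) -> list[LandmarkConfiguration]:
    """Parse a TPS stream into landmark configurations.

    Records start with ``LM=<k>`` followed by ``k`` whitespace-separated
    coordinate lines; ``ID=``, ``IMAGE=`` and ``SCALE=`` lines may follow.
    Coordinates are multiplied by SCALE when present.  ``ID=`` becomes the
    specimen id; records without one get sequential ids.
    """
    fh, should_close = _open_maybe(stream)
    try:
        lines = fh.read().splitlines()
    finally:
        if should_close:
            fh.close()

    configs: list[LandmarkConfiguration] = []
    i = 0
    n_lines = len(lines)
    record_index = 0
    while i < n_lines:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TpsParseError(f"line {i + 1}: expected 'LM=<count>' record header, got {line!r}")
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TpsParseError(f"line {i + 1}: malformed landmark count in {line!r}") from exc
        if k < 3:
            raise LandmarkError(f"record {record_index}: LM={k} but at least 3 landmarks required")
        i += 1
        coords = np.empty((k, 2), dtype=float)
        for j in range(k):
            if i >= n_lines or "=" in lines[i]:
                raise TpsParseError(
                    f"record {record_index}: LM={k} but only {j} coordinate lines found"
                )
            tokens = lines[i].split()
            if len(tokens) != 2:
                raise TpsParseError(
                    f"line {i + 1}: expected 2 coordinates, got {len(tokens)} tokens"
                )
            try:
                coords[j, 0] = float(tokens[0])
                coords[j, 1] = float(tokens[1])
            except ValueError as exc:
                raise TpsParseError(f"line {i + 1}: non-numeric coordinate in {lines[i]!r}") from exc
            i += 1
        specimen_id = None
        scale = None
        while i < n_lines:
            stripped = lines[i].strip()
            if not stripped:
                i += 1
                continue
            if stripped.upper().startswith("LM="):
                break
            if "=" not in stripped:
                raise TpsParseError(
                    f"line {i + 1}: unexpected extra coordinate line {stripped!r} "
                    f"(record {record_index} declared LM={k})"
                )
            key, value = stripped.split("=", 1)
            key = key.strip().upper()
            if key == "ID":
                specimen_id = value.strip()
            elif key == "SCALE":
                try:
                    scale = float(value)
                except ValueError as exc:
                    raise TpsParseError(f"line {i + 1}: non-numeric SCALE {value!r}") from exc
            elif key == "IMAGE":
                pass
            else:
                logger.debug("ignoring unsupported TPS key %s at line %d", key, i + 1)
            i += 1
        if scale is not None:
            coords = coords * scale
        if specimen_id is None:
            specimen_id = f"specimen_{record_index}"
        configs.append(
            LandmarkConfiguration(points=coords, specimen_id=specimen_id, scale=scale)
        )
        record_index += 1
    return configs


def write_tps(configs: Iterable[LandmarkConfiguration], stream) -> None:
    """Write configurations as TPS records.

    Coordinates are rendered with :func:`repr` so the round trip through
    :func:`read_tps` is bit-exact.  SCALE lines are never emitted: coordinates
    are already in length units after reading.
    """
    fh, should_close = _open_maybe(stream, "w")
    try:
        for config in configs:
            fh.write(f"LM={config.n_landmarks}\n")
            for x, y in config.points:
                fh.write(f"{float(x)!r} {float(y)!r}\n")
            fh.write(f"ID={config.specimen_id}\n")
    finally:
        if should_close:
            fh.close()


# ---------------------------------------------------------------------------
# Delimited table
# ---------------------------------------------------------------------------

_TABLE_META_COLS = ("specimen_id", "taxon", "side")


def write_table(
    configs: Iterable[LandmarkConfiguration],
    stream,
    delimiter: str = ",",
    aligned: bool = False,
) -> None:
    """Write one row per wing: ``specimen_id,taxon,side,x1,y1,...,xk,yk``.

    ``aligned=True`` adds a ``# aligned=true`` comment line for exported
    Procrustes shape coordinates.
    """
    configs = list(configs)
    fh, should_close = _open_maybe(stream, "w")
    try:
        if aligned:
            fh.write("# aligned=true\n")
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        if configs:
            k = configs[0].n_landmarks
            header = list(_TABLE_META_COLS)
            for j in range(1, k + 1):
                header += [f"x{j}", f"y{j}"]
            writer.writerow(header)
            for config in configs:
                if config.n_landmarks != k:
                    raise LandmarkError(
                        f"configuration '{config.specimen_id}' has {config.n_landmarks} "
                        f"landmarks but the table declares {k}"
                    )
                row = [config.specimen_id, config.taxon or "", config.side]
                for x, y in config.points:
                    row += [repr(float(x)), repr(float(y))]
                writer.writerow(row)
    finally:
        if should_close:
            fh.close()


def read_table(stream, delimiter: str = ",") -> list[LandmarkConfiguration]:
    """Read the delimited-table dialect written by :func:`write_table`."""
    fh, should_close = _open_maybe(stream)
    try:
        rows = [
            (lineno, row)
            for lineno, row in enumerate(csv.reader(fh, delimiter=delimiter), start=1)
            if row and not row[0].lstrip().startswith("#")
        ]
    finally:
        if should_close:
            fh.close()
    if not rows:
        return []
    header_lineno, header = rows[0]
    header = [h.strip() for h in header]
    if [h.lower() for h in header[:3]] != list(_TABLE_META_COLS):
        raise TableParseError(
            f"row {header_lineno}: header must start with {','.join(_TABLE_META_COLS)}"
        )
    n_coord_cols = len(header) - 3
    if n_coord_cols < 6 or n_coord_cols % 2:
        raise LandmarkError(
            f"table declares {n_coord_cols} coordinate columns; need an even count >= 6 "
            "(at least 3 landmarks)"
        )
    k = n_coord_cols // 2
    configs = []
    for lineno, row in rows[1:]:
        if len(row) != len(header):
            raise TableParseError(
                f"row {lineno}: expected {len(header)} fields, got {len(row)}"
            )
        try:
            coords = np.array([float(v) for v in row[3:]], dtype=float).reshape(k, 2)
        except ValueError as exc:
            raise TableParseError(f"row {lineno}: non-numeric coordinate") from exc
        taxon = row[1].strip() or None
        configs.append(
            LandmarkConfiguration(
                points=coords,
                specimen_id=row[0].strip(),
                taxon=taxon,
                side=row[2].strip() or "right",
            )
        )
    return configs


# ---------------------------------------------------------------------------
# Reflection and bilateral merging
# ---------------------------------------------------------------------------


def reflect(config: LandmarkConfiguration, axis: str = "y") -> LandmarkConfiguration:
    """Mirror a configuration about a coordinate axis.

    ``axis`` names the mirror axis: reflecting about the y axis negates x
    coordinates (turning a left wing into right-wing orientation when the
    wing long axis runs along x); reflecting about the x axis negates y.
    Landmark order is unchanged and the operation is an involution.
    """
    pts = np.array(config.points)
    if axis == "y":
        pts[:, 0] = -pts[:, 0]
    elif axis == "x":
        pts[:, 1] = -pts[:, 1]
    else:
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    return config.with_points(pts)


def merge_sides(record: SpecimenRecord, reflect_side: str = "left") -> LandmarkConfiguration:
    """Average the left and right wings of one specimen into a single shape.

    The wing named by ``reflect_side`` (default ``left``) is mirrored about
    the y axis so both wings share right-wing orientation.  Both wings are
    then reduced to preshape (centred, unit centroid size), one is optimally
    rotated onto the other, and the landmark-wise arithmetic mean of the two
    aligned preshapes is taken.  The mean is rescaled to the average centroid
    size of the two wings so the merged configuration keeps an interpretable
    size, and its shape is symmetric in the two sides by construction.

    With a single side present that wing is returned (mirrored if it is the
    reflected side) tagged ``side="merged"``, with a logged warning.
    """
    if reflect_side not in ("left", "right"):
        raise ValueError(f"reflect_side must be 'left' or 'right', got {reflect_side!r}")

    def oriented(config: LandmarkConfiguration) -> LandmarkConfiguration:
        return reflect(config, "y") if config.side == reflect_side else config

    if record.left is None or record.right is None:
        only = record.left if record.left is not None else record.right
        logger.warning(
            "specimen '%s': only the %s wing present; merged shape is that wing alone",
            record.specimen_id,
            only.side,
        )
        return oriented(only).with_points(
            oriented(only).points, side="merged", specimen_id=record.specimen_id,
            taxon=record.taxon if record.taxon is not None else only.taxon,
        )

    first = oriented(record.right)
    second = oriented(record.left)
    if first.n_landmarks != second.n_landmarks:
        raise LandmarkError(
            f"specimen '{record.specimen_id}': left and right wings have different "
            f"landmark counts ({second.n_landmarks} vs {first.n_landmarks})"
        )
    z1 = preshape(first.points)
    z2 = preshape(second.points)
    rot, _ = rotation_onto(z2, z1)
    mean = (z1 + z2 @ rot.T) / 2.0
    # renormalize the mean preshape, then restore an average physical size
    mean = mean - mean.mean(axis=0)
    norm = float(np.sqrt((mean**2).sum()))
    if norm == 0.0:
        raise DegenerateConfigurationError(
            f"specimen '{record.specimen_id}': sides cancel to a degenerate mean shape"
        )
    size = 0.5 * (centroid_size(first.points) + centroid_size(second.points))
    merged_pts = mean / norm * size
    return LandmarkConfiguration(
        points=merged_pts,
        specimen_id=record.specimen_id,
        taxon=record.taxon if record.taxon is not None else first.taxon,
        side="merged",
    )


def build_records(configs: Iterable[LandmarkConfiguration]) -> list[SpecimenRecord]:
    """Group wing configurations by specimen id into left/right records.

    Each specimen may contribute at most one left and one right wing; the
    merged analysis shape is computed immediately via :func:`merge_sides`.
    Input order of first appearance is preserved.
    """
    sides: dict[str, dict[str, LandmarkConfiguration]] = {}
    taxa: dict[str, str | None] = {}
    order: list[str] = []
    for config in configs:
        sid = config.specimen_id
        if sid not in sides:
            sides[sid] = {}
            taxa[sid] = None
            order.append(sid)
        if config.taxon is not None:
            if taxa[sid] is not None and taxa[sid] != config.taxon:
                raise LandmarkError(
                    f"specimen '{sid}': conflicting taxon labels {taxa[sid]!r} vs {config.taxon!r}"
                )
            taxa[sid] = config.taxon
        slot = "left" if config.side == "left" else "right"
        if slot in sides[sid]:
            raise LandmarkError(f"specimen '{sid}': duplicate {slot} wing")
        sides[sid][slot] = config
    records = []
    for sid in order:
        rec = SpecimenRecord(
            specimen_id=sid,
            taxon=taxa[sid],
            left=sides[sid].get("left"),
            right=sides[sid].get("right"),
        )
        rec.merged = merge_sides(rec)
        records.append(rec)
    return records
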