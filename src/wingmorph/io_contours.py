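"""Contour datasets: domain types, readers, writers and polygon metrics.

A :class:`Contour` is an ordered, closed polygon of pseudo-landmarks
digitized along the boundary of a wing element.  All coordinates are
stored in millimetres (the digitizer scale is applied on construction)
and all contours are normalized to counter-clockwise orientation, so
downstream code can rely on a positive signed area.

Three on-disk dialects are supported:

``xy_text``
    One specimen per block.  A header line
    ``>specimen_id element group [replicate] [scale]`` is followed by one
    ``x y`` pair per line.  Chosen for hand-editability.
``tps_curves``
    The de-facto TPS standard with ``CURVES=`` / ``POINTS=`` records; the
    first curve of each record is taken as the contour.  TPS files carry
    no group/element metadata, so a metadata table may be supplied.
``csv``
    Long format with columns
    ``specimen_id,group,element,replicate,point_index,x,y[,scale]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputValidationError

logger = logging.getLogger(__name__)

#: The four wing elements analysed in outline-based wing morphometrics.
WING_ELEMENTS = (
    "wing_contour",
    "second_submarginal",
    "first_posterior",
    "third_posterior",
)


def _signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon (closure implicit)."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _drop_consecutive_duplicates(points: np.ndarray) -> np.ndarray:
    """Remove points identical to their predecessor, including the
    wrap-around duplicate produced by digitizers that close the polygon
    explicitly."""
    d = np.linalg.norm(np.diff(points, axis=0), axis=1)
    keep = np.concatenate([[True], d > 0.0])
    points = points[keep]
    # wrap-around: last point equal to first
    while len(points) > 1 and np.linalg.norm(points[-1] - points[0]) == 0.0:
        points = points[:-1]
    return points


@dataclass(frozen=True)
class Contour:
    """Closed polygon of pseudo-landmarks for one wing element.

    ``points`` are in mm (scale already applied); orientation is
    counter-clockwise (signed area > 0).  Use :meth:`create` to build a
    validated instance from raw digitizer output.
    """

    specimen_id: str
    element: str
    points: np.ndarray  # (V, 2), mm, CCW
    scale_mm_per_unit: float = 1.0
    replicate: int = 1

    @classmethod
    def create(
        cls,
        specimen_id: str,
        element: str,
        points: Sequence[Sequence[float]] | np.ndarray,
        scale_mm_per_unit: float = 1.0,
        replicate: int = 1,
        image_coords: bool = False,
    ) -> "Contour":
        if element not in WING_ELEMENTS:
            raise InputValidationError(
                f"specimen {specimen_id!r}: unknown wing element {element!r}; "
                f"expected one of {WING_ELEMENTS}"
            )
        if not (scale_mm_per_unit > 0):
            raise InputValidationError(
                f"specimen {specimen_id!r}: scale must be positive, got "
                f"{scale_mm_per_unit}"
            )
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InputValidationError(
                f"specimen {specimen_id!r}: points must be an (V, 2) sequence"
            )
        if not np.all(np.isfinite(pts)):
            raise InputValidationError(
                f"specimen {specimen_id!r}: non-finite coordinates"
            )
        if image_coords:
            pts = pts * np.array([1.0, -1.0])
        pts = pts * scale_mm_per_unit
        before = len(pts)
        pts = _drop_consecutive_duplicates(pts)
        if len(pts) < before:
            logger.info(
                "specimen %s: dropped %d duplicate consecutive point(s)",
                specimen_id, before - len(pts),
            )
        if len(pts) < 3:
            raise InputValidationError(
                f"specimen {specimen_id!r}: contour has fewer than 3 distinct "
                f"points ({len(pts)})"
            )
        area = _signed_area(pts)
        if area == 0.0:
            raise InputValidationError(
                f"specimen {specimen_id!r}: degenerate (zero-area) contour"
            )
        if area < 0:
            pts = pts[::-1].copy()
            logger.info(
                "specimen %s: clockwise contour reversed to counter-clockwise",
                specimen_id,
            )
        return cls(
            specimen_id=str(specimen_id),
            element=element,
            points=pts,
            scale_mm_per_unit=float(scale_mm_per_unit),
            replicate=int(replicate),
        )

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def signed_area(self) -> float:
        return _signed_area(self.points)

    @property
    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))


def polygon_metrics(c: Contour) -> tuple[float, float, tuple[float, float]]:
    """Perimeter (mm), absolute area (mm^2) and polygon centroid of a contour.

    Diagnostic quantities only: the size variable used by the analyses is
    the first-harmonic semi-major axis, not the perimeter or sqrt(area).
    """
    pts = c.points
    nxt = np.roll(pts, -1, axis=0)
    cross = pts[:, 0] * nxt[:, 1] - nxt[:, 0] * pts[:, 1]
    area = 0.5 * np.sum(cross)
    cx = np.sum((pts[:, 0] + nxt[:, 0]) * cross) / (6.0 * area)
    cy = np.sum((pts[:, 1] + nxt[:, 1]) * cross) / (6.0 * area)
    return c.perimeter, abs(float(area)), (float(cx), float(cy))


@dataclass(frozen=True)
class SpecimenRecord:
    """One row of a :class:`SpecimenTable`."""

    specimen_id: str
    group: str
    element: str
    replicate: int
    contour: Contour


class SpecimenTable:
    """Validated collection of labeled contours.

    Invariants: group labels non-empty; ``(specimen_id, element,
    replicate)`` unique; statistical operations additionally require
    every group to hold at least two specimens.
    """

    def __init__(self, records: Iterable[SpecimenRecord]):
        self.records: list[SpecimenRecord] = list(records)
        seen = set()
        for r in self.records:
            if not r.group:
                raise InputValidationError(
                    f"specimen {r.specimen_id!r}: empty group label"
                )
            key = (r.specimen_id, r.element, r.replicate)
            if key in seen:
                raise InputValidationError(
                    f"duplicate record for specimen_id={r.specimen_id!r}, "
                    f"element={r.element!r}, replicate={r.replicate}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n_specimens(self) -> int:
        return len({r.specimen_id for r in self.records})

    @property
    def elements(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.element not in out:
                out.append(r.element)
        return out

    @property
    def group_labels(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.group not in out:
                out.append(r.group)
        return out

    def group_sizes(self, element: str | None = None) -> dict[str, int]:
        """Specimens per group (replicates counted once)."""
        sub = self.select(element=element, replicate=None)
        sizes: dict[str, set] = {}
        for r in sub.records:
            sizes.setdefault(r.group, set()).add(r.specimen_id)
        return {g: len(s) for g, s in sizes.items()}

    def select(
        self,
        element: str | None = None,
        replicate: int | None = 1,
        group: str | None = None,
    ) -> "SpecimenTable":
        """Subset by element / replicate / group.

        ``replicate=None`` keeps all replicates; the default keeps the
        first digitization only, which is what the statistical analyses
        use.
        """
        recs = [
            r
            for r in self.records
            if (element is None or r.element == element)
            and (replicate is None or r.replicate == replicate)
            and (group is None or r.group == group)
        ]
        return SpecimenTable(recs)

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "specimen_id": r.specimen_id,
                    "group": r.group,
                    "element": r.element,
                    "replicate": r.replicate,
                    "n_points": r.contour.n_points,
                    "scale_mm_per_unit": r.contour.scale_mm_per_unit,
                }
                for r in self.records
            ]
        )

    def require_min_group_size(self, k: int, element: str | None = None) -> None:
        sizes = self.group_sizes(element=element)
        small = {g: n for g, n in sizes.items() if n < k}
        if small:
            raise InputValidationError(
                f"groups below the minimum of {k} specimens: {small}"
            )


# ---------------------------------------------------------------------------
# readers


def _parse_xy_text(
    path: Path, image_coords: bool
) -> list[SpecimenRecord]:
    records: list[SpecimenRecord] = []
    header: list[str] | None = None
    pts: list[tuple[float, float]] = []
    header_line = 0

    def flush():
        if header is None:
            return
        sid, element, group = header[0], header[1], header[2]
        replicate, scale = 1, 1.0
        for tok in header[3:]:
            try:
                if "." in tok or "e" in tok.lower():
                    scale = float(tok)
                else:
                    replicate = int(tok)
            except ValueError as exc:
                raise InputValidationError(
                    f"{path}:{header_line}: bad header token {tok!r}"
                ) from exc
        contour = Contour.create(
            sid, element, pts, scale_mm_per_unit=scale,
            replicate=replicate, image_coords=image_coords,
        )
        records.append(SpecimenRecord(sid, group, element, replicate, contour))

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()
                header_line = lineno
                if len(header) < 3:
                    raise InputValidationError(
                        f"{path}:{lineno}: header needs at least "
                        "'specimen_id element group'"
                    )
                pts = []
            else:
                if header is None:
                    raise InputValidationError(
                        f"{path}:{lineno}: coordinate line before any header"
                    )
                parts = line.split()
                if len(parts) != 2:
                    raise InputValidationError(
                        f"{path}:{lineno}: expected 'x y', got {line!r}"
                    )
                try:
                    pts.append((float(parts[0]), float(parts[1])))
                except ValueError as exc:
                    raise InputValidationError(
                        f"{path}:{lineno}: non-numeric coordinate in {line!r}"
                    ) from exc
    flush()
    return records


def _parse_tps_curves(
    path: Path,
    image_coords: bool,
    metadata: Mapping[str, Mapping[str, object]] | None,
    default_element: str,
    default_group: str,
) -> list[SpecimenRecord]:
    """Parse TPS ``CURVES=``/``POINTS=`` records; first curve = contour."""
    records: list[SpecimenRecord] = []
    raw_records: list[dict] = []
    current: dict | None = None
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    i = 0
    n_record = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().upper()
        if key == "LM":
            n_record += 1
            current = {"curves": [], "id": None, "scale": 1.0, "record": n_record}
            raw_records.append(current)
            n_lm = int(value)
            i += n_lm  # landmarks are not used by the outline analyses
        elif key == "CURVES":
            if current is None:
                n_record += 1
                current = {"curves": [], "id": None, "scale": 1.0,
                           "record": n_record}
                raw_records.append(current)
            current["n_curves"] = int(value)
        elif key == "POINTS":
            if current is None:
                raise InputValidationError(
                    f"{path}: POINTS= outside a record near line {i}"
                )
            m = int(value)
            pts = []
            for _ in range(m):
                if i >= len(lines):
                    raise InputValidationError(
                        f"{path}: record {current['record']}: truncated curve"
                    )
                parts = lines[i].split()
                i += 1
                if len(parts) != 2:
                    raise InputValidationError(
                        f"{path}:{i}: expected 'x y', got {lines[i - 1]!r}"
                    )
                pts.append((float(parts[0]), float(parts[1])))
            current["curves"].append(pts)
        elif key == "ID":
            if current is not None:
                current["id"] = value.strip()
        elif key == "SCALE":
            if current is not None:
                current["scale"] = float(value)
        elif key == "IMAGE":
            continue
        else:
            raise InputValidationError(
                f"{path}:{i}: unrecognised TPS line {line!r}"
            )
    for rec in raw_records:
        if not rec["curves"]:
            raise InputValidationError(
                f"{path}: record {rec['record']}: no curve data"
            )
        sid = rec["id"] if rec["id"] is not None else f"tps_{rec['record']}"
        meta = dict(metadata.get(sid, {})) if metadata else {}
        element = str(meta.get("element", default_element))
        group = str(meta.get("group", default_group))
        replicate = int(meta.get("replicate", 1))
        scale = float(meta.get("scale", rec["scale"]))
        contour = Contour.create(
            sid, element, rec["curves"][0], scale_mm_per_unit=scale,
            replicate=replicate, image_coords=image_coords,
        )
        records.append(SpecimenRecord(sid, group, element, replicate, contour))
    return records


def _parse_csv(path: Path, image_coords: bool) -> list[SpecimenRecord]:
    df = pd.read_csv(path)
    required = {"specimen_id", "group", "element", "replicate",
                "point_index", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise InputValidationError(
            f"{path}: missing required columns {sorted(missing)}"
        )
    records = []
    keys = ["specimen_id", "group", "element", "replicate"]
    for (sid, group, element, replicate), sub in df.groupby(keys, sort=False):
        sub = sub.sort_values("point_index")
        scale = float(sub["scale"].iloc[0]) if "scale" in sub.columns else 1.0
        contour = Contour.create(
            str(sid), str(element), sub[["x", "y"]].to_numpy(),
            scale_mm_per_unit=scale, replicate=int(replicate),
            image_coords=image_coords,
        )
        records.append(
            SpecimenRecord(str(sid), str(group), str(element),
                           int(replicate), contour)
        )
    return records


def read_contours(
    path: str | Path,
    dialect: str = "xy_text",
    *,
    image_coords: bool = False,
    metadata: Mapping[str, Mapping[str, object]] | None = None,
    default_element: str = "wing_contour",
    default_group: str = "ungrouped",
) -> SpecimenTable:
    """Read a contour dataset and return a validated :class:`SpecimenTable`.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``xy_text``, ``tps_curves`` or ``csv`` (see module docstring).
    image_coords
        Flip the y axis for digitizations made in image coordinates
        (y grows downward); internally the package uses mathematical
        y-up axes.
    metadata
        Optional per-specimen metadata mapping used by the TPS dialect
        (``{specimen_id: {"group": ..., "element": ..., ...}}``).
    """
    path = Path(path)
    if not path.exists():
        raise InputValidationError(f"input file not found: {path}")
    if dialect == "xy_text":
        records = _parse_xy_text(path, image_coords)
    elif dialect == "tps_curves":
        records = _parse_tps_curves(
            path, image_coords, metadata, default_element, default_group
        )
    elif dialect == "csv":
        records = _parse_csv(path, image_coords)
    else:
        raise InputValidationError(
            f"unknown dialect {dialect!r}; expected xy_text, tps_curves or csv"
        )
    return SpecimenTable(records)


def write_contours_xy_text(table: SpecimenTable, path: str | Path) -> None:
    """Write a SpecimenTable in the ``xy_text`` dialect (mm coordinates,
    scale recorded as 1.0 since it has been applied)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for r in table.records:
            fh.write(f">{r.specimen_id} {r.element} {r.group} "
                     f"{r.replicate} 1.0\n")
            for x, y in r.contour.points:
                fh.write(f"{x:.17g} {y:.17g}\n")


def write_table(rows, path: str | Path) -> None:
    """Write a result table as CSV (UTF-8, '.' decimal, header row).

    ``rows`` may be a DataFrame or any sequence of dict-like records.
    Row order is preserved as given.  Empty input is an error — a result
    table with no rows almost always signals an upstream filtering bug.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows))
    if df.empty:
        raise InputValidationError(f"refusing to write empty table to {path}")
    path = Path(path)
    try:
        df.to_csv(path, index=False, encoding="utf-8", float_format="%.12g")
    except OSError as exc:
        raise InputValidationError(f"cannot write table to {path}: {exc}") from exc
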