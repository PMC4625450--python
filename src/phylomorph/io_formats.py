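"""Readers and writers for the formats the pipeline touches.

Covers the tps-DIG dialect of the TPS landmark format (``LM=`` /
``CURVES=`` / ``POINTS=`` / ``ID=`` / ``IMAGE=`` / ``SCALE=`` records),
long-format landmark CSV tables, specimen metadata tables, rooted newick
trees (via dendropy), and the JSON/CSV result bundle of a pipeline run.

Coordinates are kept exactly as stored in the TPS file (Cartesian, y up);
no image-row flipping is applied.  ``SCALE=`` factors are applied
multiplicatively when present — scale cancels in the Procrustes
superimposition anyway, so this only matters for raw-coordinate output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "FeedingType",
    "RawCurve",
    "SpecimenMeta",
    "TpsParseError",
    "MetadataError",
    "read_tps",
    "write_tps",
    "read_newick",
    "tree_has_branch_lengths",
    "read_metadata",
    "write_metadata",
    "read_landmark_csv",
    "write_landmark_csv",
    "write_results",
]


class FeedingType(str, Enum):
    """The three feeding-type groups: omnivory, phytophagy, coprophagy."""

    OM = "OM"
    PH = "PH"
    CO = "CO"

    @classmethod
    def parse(cls, text: str) -> "FeedingType":
        t = text.strip().upper()
        aliases = {
            "OM": cls.OM, "OMNIVORY": cls.OM, "OMNIVOROUS": cls.OM,
            "PH": cls.PH, "PHYTOPHAGY": cls.PH, "PHYTOPHAGOUS": cls.PH,
            "CO": cls.CO, "COPROPHAGY": cls.CO, "COPROPHAGOUS": cls.CO,
        }
        if t not in aliases:
            raise MetadataError(f"unknown feeding type: {text!r}")
        return aliases[t]


class TpsParseError(ValueError):
    pass


class MetadataError(ValueError):
    pass


@dataclass
class RawCurve:
    """One specimen's digitized outline: ordered 2D points in image units."""

    specimen_id: str
    points: np.ndarray  # (n, 2)
    scale: float | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if len(self.points) < 2:
            raise ValueError(f"curve {self.specimen_id!r} needs >= 2 points")
        seg = np.diff(self.points, axis=0)
        if not np.any(np.linalg.norm(seg, axis=1) > 0):
            raise ValueError(f"curve {self.specimen_id!r} has zero arc length")


@dataclass(frozen=True)
class SpecimenMeta:
    specimen_id: str
    taxon: str
    terminal: str
    feeding_type: FeedingType

    def __post_init__(self) -> None:
        if not self.terminal:
            raise MetadataError(f"specimen {self.specimen_id!r}: empty terminal")


# ---------------------------------------------------------------------------
# TPS

def _tps_key(line: str) -> tuple[str, str] | None:
    if "=" in line:
        key, _, val = line.partition("=")
        key = key.strip().upper()
        if key in {"LM", "CURVES", "POINTS", "ID", "IMAGE", "SCALE"}:
            return key, val.strip()
    return None


def read_tps(path: str | Path) -> list[RawCurve]:
    """Parse a TPS file into one :class:`RawCurve` per specimen record.

    Curve points (``CURVES=``/``POINTS=`` blocks, concatenated in order)
    take precedence over the ``LM=`` block when both are present, since the
    digitized object here is an outline curve.  Declared point counts are
    enforced; a mismatch raises :class:`TpsParseError` naming the record.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    curves: list[RawCurve] = []
    i, record_no = 0, 0

    def read_coords(start: int, n: int, what: str) -> tuple[np.ndarray, int]:
        pts = []
        j = start
        while j < len(lines) and len(pts) < n:
            stripped = lines[j].strip()
            if not stripped:
                j += 1
                continue
            if _tps_key(stripped) is not None:
                break
            fields = stripped.split()
            if len(fields) != 2:
                raise TpsParseError(
                    f"record {record_no} line {j + 1}: expected 'x y', got {stripped!r}")
            try:
                pts.append([float(fields[0]), float(fields[1])])
            except ValueError as exc:
                raise TpsParseError(
                    f"record {record_no} line {j + 1}: non-numeric coordinate") from exc
            j += 1
        if len(pts) != n:
            raise TpsParseError(
                f"record {record_no}: {what} declares {n} points but {len(pts)} found"
                f" (near line {start + 1})")
        return np.asarray(pts, dtype=float), j

    while i < len(lines):
        stripped = lines[i].strip()
        if not stripped:
            i += 1
            continue
        kv = _tps_key(stripped)
        if kv is None or kv[0] != "LM":
            raise TpsParseError(f"line {i + 1}: expected LM= record start, got {stripped!r}")
        record_no += 1
        try:
            n_lm = int(kv[1])
        except ValueError as exc:
            raise TpsParseError(f"record {record_no}: bad LM count {kv[1]!r}") from exc
        i += 1
        lm_pts, i = read_coords(i, n_lm, "LM=")
        curve_pts: list[np.ndarray] = []
        spec_id: str | None = None
        image: str | None = None
        scale: float | None = None
        while i < len(lines):
            stripped = lines[i].strip()
            if not stripped:
                i += 1
                continue
            kv = _tps_key(stripped)
            if kv is None:
                raise TpsParseError(
                    f"record {record_no} line {i + 1}: unexpected content {stripped!r}")
            key, val = kv
            if key == "LM":
                break  # next record
            i += 1
            if key == "CURVES":
                n_curves = int(val)
                for _ in range(n_curves):
                    while i < len(lines) and not lines[i].strip():
                        i += 1
                    pkv = _tps_key(lines[i].strip()) if i < len(lines) else None
                    if pkv is None or pkv[0] != "POINTS":
                        raise TpsParseError(
                            f"record {record_no} line {i + 1}: expected POINTS= after CURVES=")
                    n_pts = int(pkv[1])
                    i += 1
                    pts, i = read_coords(i, n_pts, "POINTS=")
                    curve_pts.append(pts)
            elif key == "ID":
                spec_id = val
            elif key == "IMAGE":
                image = val
            elif key == "SCALE":
                scale = float(val)
        if spec_id is None:
            spec_id = Path(image).stem if image else f"record{record_no}"
        pts = np.concatenate(curve_pts) if curve_pts else lm_pts
        if len(pts) < 2:
            raise TpsParseError(f"record {record_no} ({spec_id!r}): fewer than 2 points")
        if scale is not None:
            pts = pts * scale
        curves.append(RawCurve(specimen_id=spec_id, points=pts, scale=scale))
    return curves


def write_tps(curves: Iterable[RawCurve], path: str | Path) -> None:
    """Write curves as one-curve-per-specimen TPS records (no LM points)."""
    out = []
    for c in curves:
        out.append("LM=0")
        out.append("CURVES=1")
        out.append(f"POINTS={len(c.points)}")
        for x, y in c.points:
            out.append(f"{x:.12g} {y:.12g}")
        out.append(f"ID={c.specimen_id}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Trees

def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single rooted newick tree; tip labels must be unique.

    Branch lengths present in the file are retained on the returned tree
    but the downstream reconstruction replaces them with equal lengths;
    a warning is logged when originals are present.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except dendropy.utility.error.DataParseError as exc:
        raise ValueError(f"newick parse error in {path}: {exc}") from exc
    tree.is_rooted = True
    labels = [t.label for t in tree.taxon_namespace]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
    if tree_has_branch_lengths(tree):
        log.warning("input tree has branch lengths; they will be replaced by "
                    "equal lengths (1.0) for the ancestral reconstruction")
    return tree


def tree_has_branch_lengths(tree: dendropy.Tree) -> bool:
    return any(e.length is not None for e in tree.preorder_edge_iter()
               if e.head_node is not tree.seed_node)


# ---------------------------------------------------------------------------
# Metadata and landmark tables

_META_COLS = ["specimen_id", "taxon", "terminal", "feeding_type"]


def read_metadata(path: str | Path) -> list[SpecimenMeta]:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise MetadataError(f"metadata missing columns: {missing}")
    dupes = df.specimen_id[df.specimen_id.duplicated()].unique().tolist()
    if dupes:
        raise MetadataError(f"duplicate specimen_id values: {dupes}")
    records = []
    for row in df.itertuples(index=False):
        records.append(SpecimenMeta(
            specimen_id=row.specimen_id, taxon=row.taxon,
            terminal=row.terminal,
            feeding_type=FeedingType.parse(row.feeding_type)))
    return records


def write_metadata(meta: Iterable[SpecimenMeta], path: str | Path) -> None:
    pd.DataFrame([{
        "specimen_id": m.specimen_id, "taxon": m.taxon,
        "terminal": m.terminal, "feeding_type": m.feeding_type.value,
    } for m in meta]).to_csv(path, index=False)


def write_landmark_csv(configs, path: str | Path) -> None:
    """Long-format landmark table: specimen_id, point_index (0-based), x, y."""
    rows = []
    for c in configs:
        pts = np.asarray(c.coords if hasattr(c, "coords") else c.points)
        for idx, (x, y) in enumerate(pts):
            rows.append((c.specimen_id, idx, x, y))
    pd.DataFrame(rows, columns=["specimen_id", "point_index", "x", "y"]) \
        .to_csv(path, index=False, float_format="%.17g")


def read_landmark_csv(path: str | Path) -> list[RawCurve]:
    df = pd.read_csv(path)
    curves = []
    for sid, grp in df.groupby("specimen_id", sort=False):
        grp = grp.sort_values("point_index")
        curves.append(RawCurve(specimen_id=str(sid),
                               points=grp[["x", "y"]].to_numpy(float)))
    return curves


# ---------------------------------------------------------------------------
# Result bundle

def write_results(results: Mapping[str, object], outdir: str | Path) -> list[str]:
    """Write a pipeline result bundle and return the manifest (file names).

    ``results`` maps a short name to a pandas DataFrame (written as CSV at
    12 significant digits) or to a JSON-serializable object (written as
    ``<name>.json``).  A ``manifest.json`` listing every file is always
    written last.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            fname = f"{name}.csv"
            obj.to_csv(outdir / fname, index=False, float_format="%.12e")
        else:
            fname = f"{name}.json"
            (outdir / fname).write_text(json.dumps(obj, indent=2, sort_keys=True))
        manifest.append(fname)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest.append("manifest.json")
    return manifest
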