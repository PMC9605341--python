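"""Domain types and file I/O for per-cell biofilm data.

A biofilm microcolony is represented as a table of segmented (or simulated)
cells: one row per cell with centroid position, orientation and size. The
coordinate frame is right-handed with units of micrometres; the substrate is
the plane z = 0 and the colony occupies z >= 0. Orientations are nematic
directors (n and -n are equivalent) stored as full unit vectors.

On disk a sample is a CSV cell table (columns ``id,x,y,z,nx,ny,nz,length,
width`` plus optional extra scalar columns) with a JSON metadata sidecar
``<name>.meta.json`` carrying the group label, growth condition, replicate id
and provenance tag. A collection is a directory of such pairs listed by a
``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CellRecord",
    "SampleMetadata",
    "BiofilmSample",
    "BiofilmCollection",
    "CellTableError",
    "read_cell_table",
    "write_cell_table",
    "validate_sample",
    "read_collection",
    "write_collection",
]

REQUIRED_COLUMNS = ("id", "x", "y", "z", "nx", "ny", "nz", "length", "width")

#: tolerance for the unit-orientation and round-trip invariants
FIELD_TOL = 1e-9

#: float serialization format; 9 significant digits give a deterministic,
#: byte-stable round trip at FIELD_TOL
FLOAT_FMT = "%.9g"

PROVENANCE_TAGS = ("experiment", "simulation", "synthetic")


class CellTableError(ValueError):
    """Raised for malformed cell tables or invariant violations."""


@dataclass(frozen=True)
class CellRecord:
    """One segmented or simulated cell.

    Attributes
    ----------
    id : int
        Unique (within a sample) cell identifier.
    position : (3,) ndarray
        Centroid, micrometres; z >= 0 (substrate at z = 0).
    orientation : (3,) ndarray
        Unit director along the cell axis; nematic, so the sign carries no
        meaning.
    length : float
        Pole-to-pole length, micrometres; length >= width.
    width : float
        Cell diameter, micrometres; > 0.
    extras : dict
        Optional named scalar properties carried through from segmentation
        (e.g. convexity).
    """

    id: int
    position: np.ndarray
    orientation: np.ndarray
    length: float
    width: float
    extras: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "orientation", np.asarray(self.orientation, dtype=float))

    @property
    def aspect_ratio(self) -> float:
        return self.length / self.width

    def violations(self) -> list[str]:
        """Invariant violations for this cell (empty list if valid)."""
        out: list[str] = []
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            out.append("non-finite or malformed position")
        elif self.position[2] < 0:
            out.append("below substrate")
        if self.orientation.shape != (3,) or not np.all(np.isfinite(self.orientation)):
            out.append("non-finite or malformed orientation")
        elif abs(float(np.linalg.norm(self.orientation)) - 1.0) > FIELD_TOL:
            out.append("orientation not unit length")
        if not (math.isfinite(self.length) and math.isfinite(self.width)):
            out.append("non-finite size")
        elif not (self.length >= self.width > 0):
            out.append("size violates length >= width > 0")
        for name, val in self.extras.items():
            if not math.isfinite(val):
                out.append(f"non-finite extra '{name}'")
        return out


@dataclass(frozen=True)
class SampleMetadata:
    """Provenance and grouping metadata for one biofilm."""

    group: str = "unknown"
    condition: str = ""
    replicate: str = "0"
    provenance: str = "experiment"
    params: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if not d["params"]:
            d.pop("params")
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SampleMetadata":
        return cls(
            group=str(d.get("group", "unknown")),
            condition=str(d.get("condition", "")),
            replicate=str(d.get("replicate", "0")),
            provenance=str(d.get("provenance", "experiment")),
            params=dict(d.get("params", {})),
        )


class BiofilmSample:
    """A set of cells plus metadata: one biofilm microcolony.

    Provides array views (``positions``, ``orientations`` ...) used by all
    downstream feature and statistics code; the per-cell :class:`CellRecord`
    view is built lazily.
    """

    def __init__(self, cells: Iterable[CellRecord], metadata: SampleMetadata | None = None):
        self.cells: list[CellRecord] = list(cells)
        if not self.cells:
            raise CellTableError("a biofilm sample requires at least one cell")
        self.metadata = metadata or SampleMetadata()
        self._arrays: dict[str, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self) -> Iterator[CellRecord]:
        return iter(self.cells)

    def _build(self) -> dict[str, np.ndarray]:
        if self._arrays is None:
            self._arrays = {
                "ids": np.array([c.id for c in self.cells], dtype=int),
                "positions": np.array([c.position for c in self.cells], dtype=float),
                "orientations": np.array([c.orientation for c in self.cells], dtype=float),
                "lengths": np.array([c.length for c in self.cells], dtype=float),
                "widths": np.array([c.width for c in self.cells], dtype=float),
            }
        return self._arrays

    @property
    def ids(self) -> np.ndarray:
        return self._build()["ids"]

    @property
    def positions(self) -> np.ndarray:
        return self._build()["positions"]

    @property
    def orientations(self) -> np.ndarray:
        return self._build()["orientations"]

    @property
    def lengths(self) -> np.ndarray:
        return self._build()["lengths"]

    @property
    def widths(self) -> np.ndarray:
        return self._build()["widths"]

    @property
    def extra_names(self) -> list[str]:
        names: list[str] = []
        for c in self.cells:
            for k in c.extras:
                if k not in names:
                    names.append(k)
        return names

    def extra(self, name: str) -> np.ndarray:
        return np.array([c.extras[name] for c in self.cells], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Cell table as a DataFrame (required columns then extras)."""
        arr = self._build()
        df = pd.DataFrame(
            {
                "id": arr["ids"],
                "x": arr["positions"][:, 0],
                "y": arr["positions"][:, 1],
                "z": arr["positions"][:, 2],
                "nx": arr["orientations"][:, 0],
                "ny": arr["orientations"][:, 1],
                "nz": arr["orientations"][:, 2],
                "length": arr["lengths"],
                "width": arr["widths"],
            }
        )
        for name in self.extra_names:
            df[name] = self.extra(name)
        return df

    @classmethod
    def from_arrays(
        cls,
        positions: np.ndarray,
        orientations: np.ndarray,
        lengths: np.ndarray,
        widths: np.ndarray,
        metadata: SampleMetadata | None = None,
        ids: np.ndarray | None = None,
        extras: Mapping[str, np.ndarray] | None = None,
    ) -> "BiofilmSample":
        n = len(lengths)
        if ids is None:
            ids = np.arange(n)
        extras = extras or {}
        cells = [
            CellRecord(
                id=int(ids[i]),
                position=positions[i],
                orientation=orientations[i],
                length=float(lengths[i]),
                width=float(widths[i]),
                extras={k: float(v[i]) for k, v in extras.items()},
            )
            for i in range(n)
        ]
        return cls(cells, metadata)


@dataclass
class BiofilmCollection:
    """An ordered list of biofilm samples analysed together."""

    samples: list[BiofilmSample]

    def __post_init__(self) -> None:
        if not self.samples:
            raise CellTableError("empty collection")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[BiofilmSample]:
        return iter(self.samples)

    @property
    def labels(self) -> list[str]:
        return [s.metadata.group for s in self.samples]


def validate_sample(sample: BiofilmSample) -> list[str]:
    """Report all invariant violations; empty list iff the sample is valid.

    Each entry names the offending cell id, e.g. ``"cell 7: below substrate"``.
    """
    report: list[str] = []
    seen: set[int] = set()
    for c in sample.cells:
        for v in c.violations():
            report.append(f"cell {c.id}: {v}")
        if c.id in seen:
            report.append(f"cell {c.id}: duplicate id")
        seen.add(c.id)
    return report


def _meta_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(path.suffix).parent / (path.stem + ".meta.json")


def write_cell_table(sample: BiofilmSample, path: str | Path) -> None:
    """Write a sample as CSV + JSON metadata sidecar.

    Floats are serialized with 9 significant digits, which makes the output
    byte-stable and the read/write round trip an identity to 1e-9.
    """
    path = Path(path)
    df = sample.to_frame()
    try:
        df.to_csv(path, index=False, float_format=FLOAT_FMT)
        _meta_path(path).write_text(json.dumps(sample.metadata.to_dict(), indent=1, sort_keys=True))
    except OSError as exc:
        raise IOError(f"cannot write cell table at {path}: {exc}") from exc


def read_cell_table(path: str | Path, metadata: SampleMetadata | None = None) -> BiofilmSample:
    """Read and validate a cell-table CSV (+ sidecar metadata if present).

    Orientations are renormalized to unit length on read; a zero-length
    orientation, a missing required column, a non-finite value or any cell
    invariant violation raises :class:`CellTableError`.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such cell table: {path}")
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise CellTableError(f"missing required column '{col}' in {path}")
    values = df[list(REQUIRED_COLUMNS)].to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise CellTableError(
            f"non-finite value in row {int(r)}, column '{REQUIRED_COLUMNS[int(c)]}' of {path}"
        )
    ori = df[["nx", "ny", "nz"]].to_numpy(dtype=float)
    norms = np.linalg.norm(ori, axis=1)
    if np.any(norms == 0):
        row = int(np.argwhere(norms == 0)[0][0])
        raise CellTableError(f"zero-length orientation in row {row} of {path}")
    ori = ori / norms[:, None]

    if metadata is None:
        mpath = _meta_path(path)
        if mpath.exists():
            metadata = SampleMetadata.from_dict(json.loads(mpath.read_text()))

    extra_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    extras = {c: df[c].to_numpy(dtype=float) for c in extra_cols}
    sample = BiofilmSample.from_arrays(
        positions=df[["x", "y", "z"]].to_numpy(dtype=float),
        orientations=ori,
        lengths=df["length"].to_numpy(dtype=float),
        widths=df["width"].to_numpy(dtype=float),
        metadata=metadata,
        ids=df["id"].to_numpy(dtype=int),
        extras=extras,
    )
    report = validate_sample(sample)
    if report:
        raise CellTableError(f"invalid cell table {path}: " + "; ".join(report[:5]))
    return sample


def write_collection(collection: BiofilmCollection, outdir: str | Path) -> Path:
    """Write every sample plus a ``manifest.json`` listing the pairs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, s in enumerate(collection.samples):
        name = f"biofilm_{i:04d}.csv"
        write_cell_table(s, outdir / name)
        entries.append({"table": name, "metadata": name.replace(".csv", ".meta.json")})
    manifest = outdir / "manifest.json"
    manifest.write_text(json.dumps({"samples": entries}, indent=1))
    return manifest


def read_collection(indir: str | Path) -> BiofilmCollection:
    """Read a directory of cell tables (via manifest.json, else all ``*.csv``)."""
    indir = Path(indir)
    manifest = indir / "manifest.json"
    if manifest.exists():
        entries = json.loads(manifest.read_text())["samples"]
        paths = [indir / e["table"] for e in entries]
    else:
        paths = sorted(p for p in indir.glob("*.csv") if not p.name.endswith(".meta.csv"))
    if not paths:
        raise IOError(f"no cell tables found in {indir}")
    return BiofilmCollection([read_cell_table(p) for p in paths])
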