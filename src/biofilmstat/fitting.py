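"""Parameter scans of the growth simulator and best-fit selection by Cd.

A scan enumerates the Cartesian product of the four scanned mechanical
parameters (division length, repulsion range, attraction range, attraction
strength) times seeds, runs the simulator at each point and stores the
resulting cell tables with a manifest. Fitting compares target biofilms
(experimental or synthetic) against the simulation library using the
cumulative Chebyshev dissimilarity, with supports pooled jointly over targets
and library so coefficients are comparable; per target group the Cd to each
simulation is averaged over the group's replicates and the ``k`` smallest
entries are retained.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cells import BiofilmCollection, BiofilmSample, read_cell_table, write_cell_table
from .chebyshev import cd_biofilm, fit_collection
from .features import DEFAULT_RADIUS, compute_property_table
from .simulate import SimParams, run, with_params

__all__ = ["ScanGrid", "FitResult", "run_scan", "best_fit", "fit_samples"]

SCANNED = ("division_length", "repulsion_range", "attraction_range", "attraction_strength")

#: properties used for simulation-to-target comparison; width is excluded
#: because simulated and packed cells have a fixed diameter (degenerate
#: distribution), and substrate/centroid distances are kept to capture shape
DEFAULT_FIT_PROPERTIES = (
    "aspect_ratio",
    "length",
    "local_density",
    "local_nematic_order",
    "distance_to_surface",
    "distance_to_centroid",
)


@dataclass(frozen=True)
class ScanGrid:
    """Cartesian scan over the four mechanical parameters."""

    division_length: tuple[float, ...]
    repulsion_range: tuple[float, ...]
    attraction_range: tuple[float, ...]
    attraction_strength: tuple[float, ...]
    seeds: tuple[int, ...] = (0,)
    base: SimParams = field(default_factory=SimParams)

    def __post_init__(self) -> None:
        for name in SCANNED:
            if not getattr(self, name):
                raise ValueError(f"empty value list for {name}")
        if not self.seeds:
            raise ValueError("need at least one seed")

    def points(self) -> list[dict[str, float]]:
        return [
            dict(zip(SCANNED, combo))
            for combo in itertools.product(
                self.division_length, self.repulsion_range,
                self.attraction_range, self.attraction_strength,
            )
        ]

    def __len__(self) -> int:
        return len(self.points()) * len(self.seeds)


def _run_name(point: dict[str, float], seed: int) -> str:
    key = json.dumps({**point, "seed": seed}, sort_keys=True)
    return "run_" + hashlib.sha1(key.encode()).hexdigest()[:12]


def run_scan(grid: ScanGrid, outdir: str | Path, progress: bool = False) -> pd.DataFrame:
    """Run every (grid point, seed) and write cell tables plus a manifest.

    Resumable: runs whose output file already exists are skipped, so re-running
    a completed scan performs zero new simulations. A simulator failure is
    recorded in the manifest (``status`` column) and the scan continues.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "scan_manifest.csv"
    rows = []
    for point in grid.points():
        for seed in grid.seeds:
            name = _run_name(point, seed)
            table = outdir / f"{name}.csv"
            row = {**point, "seed": seed, "path": table.name}
            if table.exists():
                row["status"] = "cached"
            else:
                try:
                    params = with_params(grid.base, seed=seed, **point)
                    sample = run(params)
                    write_cell_table(sample, table)
                    row["status"] = "ok"
                except Exception as exc:  # recorded, scan continues
                    row["status"] = f"failed: {exc}"
            rows.append(row)
            if progress:
                print(f"{name}: {row['status']}", flush=True)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(manifest_path, index=False)
    return manifest


def load_library(outdir: str | Path) -> tuple[list[BiofilmSample], pd.DataFrame]:
    """Load the successful runs of a scan directory."""
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "scan_manifest.csv")
    ok = manifest[manifest["status"].isin(["ok", "cached"])]
    samples = [read_cell_table(outdir / p) for p in ok["path"]]
    return samples, ok.reset_index(drop=True)


@dataclass
class FitResult:
    """Top-k simulator matches for each target group, ranked by ascending Cd."""

    table: pd.DataFrame  # columns: group, rank, scanned params, seed, cd, library_index

    def best(self, group: str) -> pd.Series:
        sub = self.table[self.table["group"] == group]
        return sub.iloc[0]


def fit_samples(
    targets: BiofilmCollection,
    library: Sequence[BiofilmSample],
    library_info: pd.DataFrame | None = None,
    properties: Sequence[str] = DEFAULT_FIT_PROPERTIES,
    k: int = 5,
    radius: float = DEFAULT_RADIUS,
    per_replicate: bool = False,
) -> FitResult:
    """Rank library simulations against target biofilms by cumulative Cd.

    Chebyshev supports are pooled jointly over targets and library (so library
    Cd values depend on the targets they are fitted to). By default the Cd of
    a simulation to a target *group* is the arithmetic mean over the group's
    replicates; ``per_replicate`` ranks each target biofilm separately
    instead.
    """
    if k > len(library):
        raise ValueError(f"k={k} exceeds library size {len(library)}")
    n_t = len(targets.samples)
    all_samples = list(targets.samples) + list(library)
    tables = [compute_property_table(s, properties, radius) for s in all_samples]
    matrices, _ = fit_collection(tables, labels=[s.metadata.group for s in all_samples])
    t_mats, l_mats = matrices[:n_t], matrices[n_t:]

    if per_replicate:
        groups = {f"{s.metadata.group}/{s.metadata.replicate}": [i] for i, s in enumerate(targets.samples)}
    else:
        groups: dict[str, list[int]] = {}
        for i, s in enumerate(targets.samples):
            groups.setdefault(s.metadata.group, []).append(i)

    rows = []
    for gname, members in groups.items():
        cds = np.array(
            [np.mean([cd_biofilm(t_mats[i], lm) for i in members]) for lm in l_mats]
        )
        order = np.argsort(cds, kind="stable")[:k]
        for rank, li in enumerate(order, start=1):
            row = {"group": gname, "rank": rank, "cd": float(cds[li]), "library_index": int(li)}
            if library_info is not None:
                for col in (*SCANNED, "seed"):
                    if col in library_info.columns:
                        row[col] = library_info.iloc[li][col]
            rows.append(row)
    return FitResult(pd.DataFrame(rows))


def best_fit(
    targets: BiofilmCollection,
    library_dir: str | Path,
    properties: Sequence[str] = DEFAULT_FIT_PROPERTIES,
    k: int = 5,
) -> FitResult:
    """Convenience wrapper: fit targets against a scan directory on disk."""
    library, info = load_library(library_dir)
    return fit_samples(targets, library, info, properties, k)
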