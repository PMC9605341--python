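"""Per-cell architectural properties and per-biofilm emergent summaries.

Implements the observables used throughout the analysis: cell aspect ratio,
local number density (neighbours within a fixed radius, 2 um by default),
local nematic order from the 3-D Q-tensor, distances to the substrate and to
the colony centroid, the variance of the nematic order parameter, and the
biofilm surface area per volume estimated from an alpha shape of the cell
centroids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree

from .cells import BiofilmSample

__all__ = [
    "DEFAULT_PROPERTIES",
    "DEFAULT_RADIUS",
    "EmergentSummary",
    "aspect_ratio",
    "local_density",
    "local_nematic_order",
    "nematic_order_variance",
    "surface_area_per_volume",
    "compute_property_table",
    "emergent_summary",
]

#: neighbourhood radius (um) for local density and local nematic order
DEFAULT_RADIUS = 2.0

DEFAULT_PROPERTIES = (
    "aspect_ratio",
    "length",
    "width",
    "local_density",
    "local_nematic_order",
    "distance_to_surface",
    "distance_to_centroid",
)


def aspect_ratio(sample: BiofilmSample) -> np.ndarray:
    """Cell length divided by cell width, per cell (dimensionless, >= 1)."""
    return sample.lengths / sample.widths


def local_density(sample: BiofilmSample, radius: float = DEFAULT_RADIUS) -> np.ndarray:
    """Number of *other* cells with centroid within ``radius`` of each cell."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    tree = cKDTree(sample.positions)
    counts = np.zeros(len(sample), dtype=int)
    for i, j in tree.query_pairs(radius, output_type="ndarray"):
        counts[i] += 1
        counts[j] += 1
    return counts


def _neighbor_q_tensors(sample: BiofilmSample, radius: float) -> np.ndarray:
    """Per-cell Q-tensor averaged over the focal cell and its neighbours."""
    n = len(sample)
    ori = sample.orientations
    outer = np.einsum("ki,kj->kij", ori, ori)  # (n, 3, 3)
    acc = outer.copy()  # focal cell included in its own average
    count = np.ones(n)
    tree = cKDTree(sample.positions)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        np.add.at(acc, i, outer[j])
        np.add.at(acc, j, outer[i])
        np.add.at(count, i, 1)
        np.add.at(count, j, 1)
    mean_outer = acc / count[:, None, None]
    return 1.5 * mean_outer - 0.5 * np.eye(3)


def local_nematic_order(sample: BiofilmSample, radius: float = DEFAULT_RADIUS) -> np.ndarray:
    """Largest eigenvalue of the local Q-tensor, per cell.

    The Q-tensor for cell i is ``(3<n n^T> - I)/2`` averaged over cell i and
    its neighbours within ``radius``; the scalar order parameter S is its
    largest eigenvalue (1 for perfect alignment, 0 for isotropy, down to -1/2
    analytically). Nematic symmetry: flipping any director leaves S unchanged.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    q = _neighbor_q_tensors(sample, radius)
    return np.linalg.eigvalsh(q)[:, -1]


def nematic_order_variance(sample: BiofilmSample, radius: float = DEFAULT_RADIUS) -> float:
    """Population variance of the per-cell nematic order parameter."""
    if len(sample) < 2:
        raise ValueError("nematic order variance needs at least 2 cells")
    s = local_nematic_order(sample, radius)
    return float(np.var(s))


def _alpha_complex(points: np.ndarray, alpha: float) -> tuple[np.ndarray, Delaunay]:
    """Indices of Delaunay tetrahedra with circumradius below ``alpha``."""
    tri = Delaunay(points)
    tets = tri.simplices
    a, b, c, d = (points[tets[:, k]] for k in range(4))
    # circumcenter in coordinates relative to vertex a: 2 V . x = |V|^2
    rb, rc, rd = b - a, c - a, d - a
    m = np.stack([rb, rc, rd], axis=1)  # (n, 3, 3)
    rhs = 0.5 * np.stack(
        [
            np.einsum("ij,ij->i", rb, rb),
            np.einsum("ij,ij->i", rc, rc),
            np.einsum("ij,ij->i", rd, rd),
        ],
        axis=1,
    )
    det = np.linalg.det(m)
    ok = np.abs(det) > 1e-12
    center = np.full((len(tets), 3), np.inf)
    if ok.any():
        center[ok] = np.linalg.solve(m[ok], rhs[ok][..., None])[..., 0]
    radius = np.linalg.norm(center, axis=1)  # relative to vertex a
    keep = ok & (radius < alpha)
    return tets[keep], tri


def surface_area_per_volume(sample: BiofilmSample, alpha: float | None = None) -> float:
    """Surface area over volume of the centroid alpha shape, 1/um.

    ``alpha`` is the circumradius threshold of the underlying Delaunay filter;
    the default is three times the mean cell width. This is a point-cloud
    proxy for the segmented biofilm surface: tetrahedra with circumradius
    below alpha form the body, their once-used faces form the surface.
    """
    points = sample.positions
    if len(points) < 4:
        raise ValueError("alpha shape needs at least 4 centroids")
    if alpha is None:
        alpha = 3.0 * float(np.mean(sample.widths))
    try:
        tets, _ = _alpha_complex(points, alpha)
    except Exception as exc:  # Qhull degeneracy
        raise ValueError(f"degenerate centroid geometry: {exc}") from exc
    if len(tets) == 0:
        raise ValueError("alpha too small: empty alpha complex")

    verts = points[tets]  # (n, 4, 3)
    vol = np.abs(
        np.einsum(
            "ij,ij->i",
            verts[:, 1] - verts[:, 0],
            np.cross(verts[:, 2] - verts[:, 0], verts[:, 3] - verts[:, 0]),
        )
    ).sum() / 6.0
    if vol <= 0:
        raise ValueError("degenerate alpha complex (zero volume)")

    # boundary faces appear in exactly one kept tetrahedron
    faces = np.sort(
        np.concatenate([tets[:, [0, 1, 2]], tets[:, [0, 1, 3]], tets[:, [0, 2, 3]], tets[:, [1, 2, 3]]]),
        axis=1,
    )
    uniq, counts = np.unique(faces, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    p0, p1, p2 = points[boundary[:, 0]], points[boundary[:, 1]], points[boundary[:, 2]]
    area = 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1).sum()
    return float(area / vol)


def compute_property_table(
    sample: BiofilmSample,
    properties: Sequence[str] | None = None,
    radius: float = DEFAULT_RADIUS,
) -> pd.DataFrame:
    """Per-cell property table (one row per cell, indexed by cell id).

    ``properties`` defaults to :data:`DEFAULT_PROPERTIES`; names not in the
    computed set are looked up in the cells' extras and passed through
    verbatim. Unknown names raise ``KeyError``.
    """
    props = list(properties) if properties is not None else list(DEFAULT_PROPERTIES)
    cols: dict[str, np.ndarray] = {}
    centroid = sample.positions.mean(axis=0)
    extra_names = set(sample.extra_names)
    for name in props:
        if name == "aspect_ratio":
            cols[name] = aspect_ratio(sample)
        elif name == "length":
            cols[name] = sample.lengths
        elif name == "width":
            cols[name] = sample.widths
        elif name == "local_density":
            cols[name] = local_density(sample, radius).astype(float)
        elif name == "local_nematic_order":
            cols[name] = local_nematic_order(sample, radius)
        elif name == "distance_to_surface":
            cols[name] = sample.positions[:, 2]
        elif name == "distance_to_centroid":
            cols[name] = np.linalg.norm(sample.positions - centroid, axis=1)
        elif name in extra_names:
            cols[name] = sample.extra(name)
        else:
            raise KeyError(f"unknown property '{name}'")
    df = pd.DataFrame(cols, index=pd.Index(sample.ids, name="id"))
    return df


@dataclass(frozen=True)
class EmergentSummary:
    """Colony-level summary statistics for one biofilm."""

    mean_aspect_ratio: float
    mean_local_density: float
    nematic_order_variance: float
    surface_area_per_volume: float
    n_cells: int


def emergent_summary(sample: BiofilmSample, radius: float = DEFAULT_RADIUS) -> EmergentSummary:
    return EmergentSummary(
        mean_aspect_ratio=float(np.mean(aspect_ratio(sample))),
        mean_local_density=float(np.mean(local_density(sample, radius))),
        nematic_order_variance=nematic_order_variance(sample, radius),
        surface_area_per_volume=surface_area_per_volume(sample),
        n_cells=len(sample),
    )
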