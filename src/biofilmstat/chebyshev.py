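"""Chebyshev representation of property distributions and the Cd dissimilarity.

Each per-cell property distribution of a biofilm is smoothed by a Gaussian
kernel density estimate and interpolated by a degree-``d`` Chebyshev
polynomial (d = 20 by default, hence 21 coefficients) on a support shared by
the whole collection. A biofilm with m properties is thus compressed to a
(d+1) x m coefficient matrix — 273 numbers for m = 13 — while retaining
distribution shape beyond means and variances.

The Chebyshev dissimilarity between two fitted densities is

    Cd(A, B) = 2 * sum_k |c_k^A - c_k^B|,

a weighted-L1 metric on coefficient space. Because |T_k(x)| <= 1 on the
canonical interval [-1, 1] (length 2), Cd upper-bounds the L1 distance
between the reconstructed densities, and summed over properties it bounds the
cumulative L1 distance between two biofilms' histogram collections. Applied
across biofilms to single-property coefficient vectors, the same construction
measures redundancy between properties; average-linkage clustering with a
silhouette-selected cluster number then prunes near-duplicate properties to
one representative (medoid) each.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.fft import dct
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

__all__ = [
    "DEFAULT_DEGREE",
    "PropertySupport",
    "ChebyshevRep",
    "ChebyshevMatrix",
    "pooled_support",
    "fit_chebyshev",
    "reconstruct_density",
    "cd_property",
    "cd_biofilm",
    "cd_matrix",
    "property_dissimilarity",
    "reduce_properties",
    "fit_collection",
    "save_coefficients",
    "load_coefficients",
]

DEFAULT_DEGREE = 20
_BANDWIDTH_FLOOR = 0.01  # canonical units
MIN_SAMPLE = 10


@dataclass(frozen=True)
class PropertySupport:
    """Affine map of one property's value range onto the canonical [-1, 1]."""

    name: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"degenerate support for '{self.name}': [{self.lower}, {self.upper}]")

    def to_canonical(self, values: np.ndarray) -> np.ndarray:
        """Clamp to the support, then map affinely onto [-1, 1]."""
        v = np.clip(np.asarray(values, float), self.lower, self.upper)
        return 2.0 * (v - self.lower) / (self.upper - self.lower) - 1.0

    def matches(self, other: "PropertySupport", tol: float = 1e-9) -> bool:
        return (
            self.name == other.name
            and abs(self.lower - other.lower) <= tol
            and abs(self.upper - other.upper) <= tol
        )


@dataclass(frozen=True)
class ChebyshevRep:
    """Chebyshev expansion of one property's KDE density for one biofilm."""

    support: PropertySupport
    coefficients: np.ndarray  # c_0 .. c_d of the first-kind expansion
    n: int  # sample size behind the fit

    @property
    def name(self) -> str:
        return self.support.name

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1


@dataclass(frozen=True)
class ChebyshevMatrix:
    """(d+1) x m coefficient matrix for one biofilm; columns ordered as ``names``."""

    names: tuple[str, ...]
    supports: tuple[PropertySupport, ...]
    values: np.ndarray  # shape (d+1, m)
    label: str = ""

    def rep(self, name: str) -> ChebyshevRep:
        j = self.names.index(name)
        return ChebyshevRep(self.supports[j], self.values[:, j], n=-1)


def pooled_support(
    values_per_sample: Sequence[np.ndarray],
    name: str,
    q_lo: float = 0.005,
    q_hi: float = 0.995,
    margin: float = 0.05,
) -> PropertySupport:
    """Shared support from pooled quantiles over all biofilms of a collection.

    The [q_lo, q_hi] pooled quantile interval is widened by ``margin`` (a
    fraction of its width) on each side so that KDE mass near the edges stays
    inside the canonical interval. A zero-spread property has no usable
    support and raises ``ValueError``.
    """
    pooled = np.concatenate([np.asarray(v, float) for v in values_per_sample])
    lo, hi = np.quantile(pooled, [q_lo, q_hi])
    if hi <= lo:
        raise ValueError(f"degenerate support for '{name}' (zero spread)")
    pad = margin * (hi - lo)
    return PropertySupport(name, float(lo - pad), float(hi + pad))


def _silverman_bandwidth(t: np.ndarray) -> float:
    """Silverman's rule on canonical-coordinate data, floored at 0.01."""
    n = len(t)
    std = float(np.std(t, ddof=1)) if n > 1 else 0.0
    iqr = float(np.subtract(*np.quantile(t, [0.75, 0.25])))
    scale = min(x for x in (std, iqr / 1.34) if x > 0) if (std > 0 or iqr > 0) else 0.0
    return max(0.9 * scale * n ** (-0.2), _BANDWIDTH_FLOOR)


def chebyshev_nodes(degree: int) -> np.ndarray:
    """Chebyshev–Gauss–Lobatto nodes cos(pi*j/d), j = 0..d (from +1 to -1)."""
    return np.cos(np.pi * np.arange(degree + 1) / degree)


def _interpolate_at_lobatto(node_values: np.ndarray) -> np.ndarray:
    """Chebyshev coefficients of the degree-d interpolant through Lobatto nodes.

    Uses the type-I discrete cosine transform; c_0 and c_d carry the usual
    half weights.
    """
    d = len(node_values) - 1
    coeffs = dct(node_values, type=1) / d
    coeffs[0] /= 2.0
    coeffs[-1] /= 2.0
    return coeffs


def fit_chebyshev(
    values: np.ndarray,
    support: PropertySupport,
    degree: int = DEFAULT_DEGREE,
    bandwidth: float | None = None,
) -> ChebyshevRep:
    """Fit the Chebyshev representation of one property sample.

    The sample is clamped to the support, mapped to canonical coordinates,
    smoothed by a Gaussian KDE (Silverman bandwidth with a 0.01 floor unless
    ``bandwidth`` is given) with reflection boundary correction at the
    interval edges, evaluated at the d+1 Gauss–Lobatto nodes and interpolated
    exactly. Reflection keeps edge-concentrated distributions (e.g. neighbour
    counts piling up at zero) unbiased and the density mass inside the
    canonical interval. Deterministic: identical inputs give identical
    coefficients bit for bit.
    """
    values = np.asarray(values, float)
    if values.ndim != 1 or len(values) < MIN_SAMPLE:
        raise ValueError(f"insufficient sample for '{support.name}': need >= {MIN_SAMPLE} values")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"non-finite values in property '{support.name}'")
    t = support.to_canonical(values)
    h = bandwidth if bandwidth is not None else _silverman_bandwidth(t)
    nodes = chebyshev_nodes(degree)
    dens = _reflected_kde(nodes, t, h)
    return ChebyshevRep(support, _interpolate_at_lobatto(dens), n=len(values))


def _reflected_kde(x: np.ndarray, t: np.ndarray, h: float) -> np.ndarray:
    """Gaussian KDE of canonical data with mirror reflection at -1 and +1."""
    acc = np.zeros_like(x, dtype=float)
    for data in (t, -2.0 - t, 2.0 - t):
        z = (x[:, None] - data[None, :]) / h
        acc += np.exp(-0.5 * z * z).sum(axis=1)
    return acc / (len(t) * h * np.sqrt(2.0 * np.pi))


def reconstruct_density(rep: ChebyshevRep, x: np.ndarray | float) -> np.ndarray | float:
    """Evaluate the fitted expansion at canonical coordinate(s) x in [-1, 1].

    Clenshaw evaluation; truncation can make values slightly negative, which
    is reported as-is.
    """
    x = np.asarray(x, float)
    if np.any(x < -1.0) or np.any(x > 1.0):
        raise ValueError("canonical coordinate outside [-1, 1]")
    out = np.polynomial.chebyshev.chebval(x, rep.coefficients)
    return float(out) if out.ndim == 0 else out


def cd_property(rep_a: ChebyshevRep, rep_b: ChebyshevRep) -> float:
    """Cd between two fitted densities of the same property: 2 * sum |delta c_k|."""
    if rep_a.degree != rep_b.degree:
        raise ValueError("degree mismatch")
    if not rep_a.support.matches(rep_b.support):
        raise ValueError(f"support mismatch for '{rep_a.name}' vs '{rep_b.name}'")
    return 2.0 * float(np.abs(rep_a.coefficients - rep_b.coefficients).sum())


def cd_biofilm(
    mat_a: ChebyshevMatrix,
    mat_b: ChebyshevMatrix,
    properties: Sequence[str] | None = None,
) -> float:
    """Cumulative Cd between two biofilms over the selected properties."""
    if mat_a.names != mat_b.names:
        raise ValueError("property lists differ")
    props = list(properties) if properties is not None else list(mat_a.names)
    if not props:
        raise ValueError("empty property subset")
    total = 0.0
    for name in props:
        j = mat_a.names.index(name)
        if not mat_a.supports[j].matches(mat_b.supports[j]):
            raise ValueError(f"support mismatch for '{name}'")
        total += 2.0 * float(np.abs(mat_a.values[:, j] - mat_b.values[:, j]).sum())
    return total


def cd_matrix(
    matrices: Sequence[ChebyshevMatrix],
    properties: Sequence[str] | None = None,
) -> np.ndarray:
    """Symmetric pairwise biofilm-to-biofilm Cd matrix (zero diagonal)."""
    if len(matrices) < 2:
        raise ValueError("need at least 2 biofilms")
    n = len(matrices)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = cd_biofilm(matrices[i], matrices[j], properties)
    return out


def property_dissimilarity(matrices: Sequence[ChebyshevMatrix]) -> np.ndarray:
    """m x m cross-property Cd matrix over a biofilm collection.

    Each property's coefficient vector across biofilms (length B*(d+1)) is
    z-normalized per coefficient index across the biofilms before comparison,
    so properties with different units and scales become comparable; the
    dissimilarity is then the Cd form 2 * sum |delta| between normalized
    vectors. Exact duplicate properties come out at distance 0.
    """
    names = matrices[0].names
    stack = np.stack([m.values for m in matrices])  # (B, d+1, m)
    v = np.transpose(stack, (2, 0, 1))  # (m, B, d+1)
    mean = v.mean(axis=1, keepdims=True)
    std = v.std(axis=1, keepdims=True)
    z = np.where(std > 0, (v - mean) / np.where(std > 0, std, 1.0), 0.0)
    flat = z.reshape(len(names), -1)
    diff = np.abs(flat[:, None, :] - flat[None, :, :]).sum(axis=2)
    return 2.0 * diff


def reduce_properties(
    prop_cd: np.ndarray,
    names: Sequence[str],
    k_range: Sequence[int] | None = None,
) -> tuple[list[str], np.ndarray, int]:
    """Prune redundant properties by Cd clustering.

    Average-linkage hierarchical clustering on the property Cd matrix; the
    cluster number k maximizes the mean silhouette coefficient over
    ``k_range`` (default 2..m-1, ties broken toward the smallest k); each
    cluster is represented by its medoid (minimal summed Cd to members, ties
    toward the earliest input position).

    Returns ``(selected names in input order, cluster labels, k)``.
    """
    m = len(names)
    if m < 3:
        raise ValueError("need at least 3 properties to reduce")
    prop_cd = np.asarray(prop_cd, float)
    ks = list(k_range) if k_range is not None else list(range(2, m))
    z = linkage(squareform(prop_cd, checks=False), method="average")
    best_k, best_score, best_labels = None, -np.inf, None
    for k in sorted(ks):
        labels = fcluster(z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2 or len(np.unique(labels)) >= m:
            continue
        score = silhouette_score(prop_cd, labels, metric="precomputed")
        if score > best_score + 1e-12:
            best_k, best_score, best_labels = len(np.unique(labels)), score, labels
    if best_labels is None:
        raise ValueError("no valid clustering found in k_range")
    selected: list[int] = []
    for lab in np.unique(best_labels):
        members = np.flatnonzero(best_labels == lab)
        sums = prop_cd[np.ix_(members, members)].sum(axis=1)
        selected.append(int(members[int(np.argmin(sums))]))
    selected.sort()
    return [names[i] for i in selected], best_labels, int(best_k)


def fit_collection(
    tables: Sequence["pd.DataFrame"],  # noqa: F821 - typed loosely to avoid a hard pandas import
    degree: int = DEFAULT_DEGREE,
    q_lo: float = 0.005,
    q_hi: float = 0.995,
    labels: Sequence[str] | None = None,
    drop_degenerate: bool = True,
) -> tuple[list[ChebyshevMatrix], list[str]]:
    """Fit ChebyshevMatrix per biofilm from per-cell property tables.

    Supports are pooled over the whole collection so coefficients are
    comparable across biofilms. Properties with degenerate (zero-spread)
    pooled support are dropped with a note when ``drop_degenerate`` is set,
    otherwise raise.

    Returns the matrices and the list of dropped property names.
    """
    names = list(tables[0].columns)
    for t in tables[1:]:
        if list(t.columns) != names:
            raise ValueError("property sets differ across biofilms")
    supports: list[PropertySupport] = []
    dropped: list[str] = []
    for name in names:
        try:
            supports.append(pooled_support([t[name].to_numpy() for t in tables], name, q_lo, q_hi))
        except ValueError:
            if not drop_degenerate:
                raise
            dropped.append(name)
    kept = [s.name for s in supports]
    matrices = []
    for i, t in enumerate(tables):
        values = np.column_stack(
            [fit_chebyshev(t[s.name].to_numpy(), s, degree).coefficients for s in supports]
        )
        label = labels[i] if labels is not None else str(i)
        matrices.append(ChebyshevMatrix(tuple(kept), tuple(supports), values, label=label))
    return matrices, dropped


def save_coefficients(matrices: Sequence[ChebyshevMatrix], path: str | Path) -> None:
    """Serialize a collection of coefficient matrices to a single JSON file."""
    first = matrices[0]
    doc = {
        "properties": list(first.names),
        "supports": [[s.lower, s.upper] for s in first.supports],
        "degree": first.values.shape[0] - 1,
        "biofilms": [{"label": m.label, "coefficients": m.values.tolist()} for m in matrices],
    }
    Path(path).write_text(json.dumps(doc))


def load_coefficients(path: str | Path) -> list[ChebyshevMatrix]:
    doc = json.loads(Path(path).read_text())
    names = tuple(doc["properties"])
    supports = tuple(
        PropertySupport(n, lo, hi) for n, (lo, hi) in zip(names, doc["supports"])
    )
    return [
        ChebyshevMatrix(names, supports, np.asarray(b["coefficients"], float), label=b["label"])
        for b in doc["biofilms"]
    ]
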