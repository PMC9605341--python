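"""PCA on Chebyshev coefficient vectors, the biofilm architecture index, and
the aspect-ratio / density phase diagram.

Each biofilm's (d+1) x p coefficient matrix is flattened to a single vector;
the collection of vectors is centred per dimension and decomposed by SVD.
The coefficients are values of canonical probability densities on the shared
interval [-1, 1], so all dimensions are already unit-free and on a common
scale; centring without per-dimension rescaling preserves the variance
structure (rescaling every coefficient to unit variance would inflate
noise-dominated dimensions and bury the architectural signal). The first
principal-component score is the biofilm architecture index (BAI), a scalar
summary of architecture; its sign is fixed so that BAI increases with the
mean of the local-density distribution (computed from the density coefficient
block), making "denser -> larger BAI" a convention rather than an accident of
the SVD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cells import BiofilmCollection
from .chebyshev import ChebyshevMatrix
from .features import DEFAULT_RADIUS, aspect_ratio, local_density

__all__ = ["PhaseEmbedding", "pca_embed", "property_contributions", "phase_diagram"]

COLOR_METRICS = ("BAI", "nematic_order_variance", "surface_area_per_volume")


@dataclass
class PhaseEmbedding:
    """PCA of a biofilm collection in Chebyshev coefficient space."""

    scores: np.ndarray  # (B, K) per-biofilm component scores
    loadings: np.ndarray  # (K, D) orthonormal rows in the full (kept) space
    explained_variance_ratio: np.ndarray  # (K,), sums to 1
    property_names: tuple[str, ...]
    block_size: int  # d+1 coefficients per property
    kept: np.ndarray  # boolean mask over the D_full flattened dims
    means: np.ndarray  # preprocessing record over kept dims
    scales: np.ndarray
    labels: list[str] = field(default_factory=list)

    @property
    def bai(self) -> np.ndarray:
        """Biofilm architecture index: signed first-component score."""
        return self.scores[:, 0]

    def block_slice(self, name: str) -> slice:
        j = self.property_names.index(name)
        return slice(j * self.block_size, (j + 1) * self.block_size)


def _canonical_mean_weights(degree: int) -> np.ndarray:
    """Weights m_k = integral of x*T_k(x) over [-1, 1].

    The canonical-coordinate mean of a fitted density is linear in its
    coefficients: mean_b = sum_k c_bk * m_k. Used to anchor the BAI sign.
    """
    k = np.arange(degree + 1)
    # int x T_k dx = -2k / (k^2 - 4)*... closed form: 0 for even k except via
    # parity; for odd k: ((-1)^((k-1)/2) style sums are error-prone, so
    # integrate numerically on a fine Gauss grid instead (exact to quadrature)
    x, w = np.polynomial.legendre.leggauss(4 * (degree + 2))
    t = np.polynomial.chebyshev.chebvander(x, degree)
    return (w * x) @ t


def pca_embed(matrices: list[ChebyshevMatrix]) -> PhaseEmbedding:
    """PCA on flattened, per-dimension centred (d+1) x p coefficient vectors.

    Requires at least 3 biofilms. Coefficient dimensions are centred but not
    rescaled (canonical densities share scale and units already; per-dimension
    z-scoring would amplify noise dimensions). Zero-variance dimensions are
    dropped from the decomposition (recorded in ``kept``); all non-trivial
    components are retained so the explained-variance ratios sum to one.
    Loadings are embedded back into the full flattened space with zeros at
    dropped dimensions, so per-property blocks stay addressable.
    """
    if len(matrices) < 3:
        raise ValueError("PCA needs at least 3 biofilms")
    names = matrices[0].names
    for m in matrices[1:]:
        if m.names != names:
            raise ValueError("property lists differ across biofilms")
    block = matrices[0].values.shape[0]
    # flatten property-major: [prop0 c0..cd, prop1 c0..cd, ...]
    x_full = np.stack([m.values.T.reshape(-1) for m in matrices])  # (B, p*(d+1))
    std = x_full.std(axis=0)
    kept = std > 1e-12
    x = x_full[:, kept]
    means = x.mean(axis=0)
    xc = x - means
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    nontrivial = s > max(s[0], 1.0) * 1e-12
    u, s, vt = u[:, nontrivial], s[nontrivial], vt[nontrivial]
    scores = u * s
    evr = s**2 / np.sum(s**2)

    loadings_full = np.zeros((len(s), x_full.shape[1]))
    loadings_full[:, kept] = vt

    emb = PhaseEmbedding(
        scores=scores,
        loadings=loadings_full,
        explained_variance_ratio=evr,
        property_names=names,
        block_size=block,
        kept=kept,
        means=means,
        scales=np.ones_like(means),
        labels=[m.label for m in matrices],
    )
    # sign convention: denser -> larger BAI. The canonical-coordinate mean of
    # the local-density distribution is linear in its coefficient block, so
    # anchor the sign on the covariance between PC1 score and that mean.
    anchor = "local_density" if "local_density" in names else names[0]
    j = names.index(anchor)
    mk = _canonical_mean_weights(block - 1)
    dens_mean = np.stack([m.values[:, j] for m in matrices]) @ mk
    cov = float(np.cov(emb.scores[:, 0], dens_mean)[0, 1])
    if cov < 0:
        emb.scores[:, 0] *= -1.0
        emb.loadings[0] *= -1.0
    return emb


def property_contributions(embedding: PhaseEmbedding) -> pd.Series:
    """Per-property contribution to the BAI, descending.

    Contribution of property j = sum of squared first-component loadings over
    its coefficient block, normalized to sum to 1. Dimensions dropped as
    zero-variance contribute 0.
    """
    pc1 = embedding.loadings[0]
    contrib = {
        name: float(np.sum(pc1[embedding.block_slice(name)] ** 2))
        for name in embedding.property_names
    }
    s = pd.Series(contrib)
    total = s.sum()
    if total > 0:
        s = s / total
    return s.sort_values(ascending=False)


def phase_diagram(
    collection: BiofilmCollection,
    color: str = "BAI",
    embedding: PhaseEmbedding | None = None,
    radius: float = DEFAULT_RADIUS,
) -> pd.DataFrame:
    """Per-biofilm points in the mean aspect-ratio vs mean local-density plane.

    ``color`` selects the third, color-coding metric: the BAI (requires the
    embedding), the variance of the nematic order parameter, or the surface
    area per biofilm volume.
    """
    if color not in COLOR_METRICS:
        raise ValueError(f"unknown color metric '{color}'; choose from {COLOR_METRICS}")
    rows = []
    for i, sample in enumerate(collection):
        if color == "BAI":
            if embedding is None:
                raise ValueError("color='BAI' requires the PCA embedding")
            cval = float(embedding.bai[i])
        elif color == "nematic_order_variance":
            from .features import nematic_order_variance

            cval = nematic_order_variance(sample, radius)
        else:
            from .features import surface_area_per_volume

            cval = surface_area_per_volume(sample)
        rows.append(
            {
                "group": sample.metadata.group,
                "mean_aspect_ratio": float(np.mean(aspect_ratio(sample))),
                "mean_local_density": float(np.mean(local_density(sample, radius))),
                "color_metric": color,
                "color_value": cval,
            }
        )
    return pd.DataFrame(rows)
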