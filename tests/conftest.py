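import numpy as np
import pytest

from biofilmstat.cells import BiofilmSample, CellRecord, SampleMetadata
from biofilmstat.chebyshev import ChebyshevMatrix, fit_collection, property_dissimilarity, reduce_properties
from biofilmstat.features import compute_property_table
from biofilmstat.phase import pca_embed
from biofilmstat.synthetic import generate_collection, phase_reference_specs


def make_sample(positions, orientations, lengths=None, widths=None, group="test", **meta):
    positions = np.atleast_2d(np.asarray(positions, float))
    orientations = np.atleast_2d(np.asarray(orientations, float))
    orientations = orientations / np.linalg.norm(orientations, axis=1, keepdims=True)
    n = len(positions)
    lengths = np.full(n, 2.0) if lengths is None else np.asarray(lengths, float)
    widths = np.full(n, 0.8) if widths is None else np.asarray(widths, float)
    return BiofilmSample.from_arrays(
        positions, orientations, lengths, widths,
        metadata=SampleMetadata(group=group, **meta),
    )


def random_sample(rng, n=50, box=6.0, group="rand"):
    pos = rng.uniform(0, box, size=(n, 3))
    ori = rng.standard_normal((n, 3))
    ar = rng.uniform(1.0, 4.0, n)
    w = np.full(n, 0.8)
    return make_sample(pos, ori, lengths=w * ar, widths=w, group=group)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def reference_collection():
    """The 2x2 density-by-aspect-ratio synthetic collection (5 x 500 cells)."""
    return generate_collection(phase_reference_specs(n_biofilms=5, n_cells=500, seed=1))


@pytest.fixture(scope="session")
def reference_analysis(reference_collection):
    """Full pipeline artifacts on the reference collection."""
    coll = reference_collection
    tables = [compute_property_table(s) for s in coll]
    matrices, dropped = fit_collection(tables, labels=coll.labels)
    names = list(matrices[0].names)
    prop_cd = property_dissimilarity(matrices)
    selected, clusters, k = reduce_properties(prop_cd, names)
    idx = [names.index(s) for s in selected]
    sub = [
        ChebyshevMatrix(tuple(selected), tuple(m.supports[i] for i in idx), m.values[:, idx], m.label)
        for m in matrices
    ]
    embedding = pca_embed(sub)
    return {
        "collection": coll,
        "tables": tables,
        "matrices": matrices,
        "dropped": dropped,
        "property_cd": prop_cd,
        "selected": selected,
        "clusters": clusters,
        "k": k,
        "embedding": embedding,
    }
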