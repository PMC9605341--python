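"""Chebyshev-KDE representation, the Cd dissimilarity, redundancy reduction."""

import itertools

import numpy as np
import pytest

from biofilmstat.chebyshev import (
    ChebyshevRep,
    PropertySupport,
    cd_biofilm,
    cd_matrix,
    cd_property,
    chebyshev_nodes,
    fit_chebyshev,
    fit_collection,
    load_coefficients,
    pooled_support,
    property_dissimilarity,
    reduce_properties,
    reconstruct_density,
    save_coefficients,
)


def quadrature_l1(rep_a, rep_b, n=20001):
    x = np.linspace(-1.0, 1.0, n)
    return np.trapezoid(np.abs(reconstruct_density(rep_a, x) - reconstruct_density(rep_b, x)), x)


def random_rep(rng, support, scale=0.3):
    c = scale * rng.standard_normal(21) / (1.0 + np.arange(21))
    return ChebyshevRep(support, c, n=100)


class TestSupports:
    def test_uniform_quantile_oracle(self, rng):
        vals = rng.uniform(0, 10, 200_000)
        sup = pooled_support([vals], "u")
        assert sup.lower == pytest.approx(-0.45, abs=0.02)
        assert sup.upper == pytest.approx(10.45, abs=0.02)

    def test_identical_samples_share_support(self, rng):
        v = rng.normal(3, 1, 5000)
        s1 = pooled_support([v], "p")
        s2 = pooled_support([v, v.copy()], "p")
        assert s1.matches(s2)

    def test_integer_counts_spanned(self, rng):
        vals = rng.integers(0, 31, 20000).astype(float)
        sup = pooled_support([vals], "local_density")
        assert sup.lower <= 0 and sup.upper >= 30

    def test_degenerate_support_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pooled_support([np.full(100, 0.8)], "width")


class TestFit:
    def test_degree20_gives_21_coefficients(self, rng):
        rep = fit_chebyshev(rng.normal(0, 1, 500), PropertySupport("p", -4, 4))
        assert len(rep.coefficients) == 21
        assert rep.degree == 20

    def test_uniform_constant_density(self, rng):
        sup = PropertySupport("u", 0.0, 1.0)
        rep = fit_chebyshev(rng.uniform(0, 1, 10_000), sup, bandwidth=0.01)
        assert rep.coefficients[0] == pytest.approx(0.5, abs=0.03)
        assert np.all(np.abs(rep.coefficients[1:]) < 0.05)

    def test_density_normalized(self, rng):
        vals = rng.normal(2.0, 0.5, 3000)
        sup = pooled_support([vals], "g")
        rep = fit_chebyshev(vals, sup)
        x = np.linspace(-1, 1, 10001)
        assert np.trapezoid(reconstruct_density(rep, x), x) == pytest.approx(1.0, abs=0.05)

    def test_mixture_reconstruction_error(self, rng):
        # two-component Gaussian mixture: reconstruction close in L1
        mu, sd = np.array([2.0, 6.0]), np.array([0.8, 1.0])
        comp = rng.integers(0, 2, 2000)
        vals = rng.normal(mu[comp], sd[comp])
        sup = PropertySupport("mix", -1.0, 9.0)
        rep = fit_chebyshev(vals, sup)
        x = np.linspace(-1, 1, 20001)
        orig = 0.5 * (sup.upper - sup.lower) * 0.5 * (
            np.exp(-0.5 * ((x * 5 + 4 - mu[0]) / sd[0]) ** 2) / (sd[0] * np.sqrt(2 * np.pi))
            + np.exp(-0.5 * ((x * 5 + 4 - mu[1]) / sd[1]) ** 2) / (sd[1] * np.sqrt(2 * np.pi))
        )
        l1 = np.trapezoid(np.abs(reconstruct_density(rep, x) - orig), x)
        assert l1 < 0.15

    def test_deterministic_bit_for_bit(self, rng):
        vals = rng.normal(0, 1, 500)
        sup = PropertySupport("p", -4, 4)
        c1 = fit_chebyshev(vals, sup).coefficients
        c2 = fit_chebyshev(vals.copy(), sup).coefficients
        assert np.array_equal(c1, c2)

    def test_insufficient_sample(self):
        with pytest.raises(ValueError, match="insufficient"):
            fit_chebyshev(np.arange(9, dtype=float), PropertySupport("p", 0, 10))

    def test_values_outside_support_clamped(self, rng):
        sup = PropertySupport("p", 0.0, 1.0)
        vals = np.concatenate([rng.uniform(0, 1, 500), [50.0, -50.0]])
        rep = fit_chebyshev(vals, sup)  # should not raise
        assert np.all(np.isfinite(rep.coefficients))


class TestReconstruct:
    def test_constant_rep(self):
        rep = ChebyshevRep(PropertySupport("p", 0, 1), np.array([0.5] + [0.0] * 20), n=10)
        x = np.linspace(-1, 1, 7)
        np.testing.assert_allclose(reconstruct_density(rep, x), 0.5)

    def test_interpolates_kde_at_nodes(self, rng):
        vals = rng.normal(0, 1, 1000)
        sup = PropertySupport("p", -4, 4)
        rep = fit_chebyshev(vals, sup, bandwidth=0.1)
        nodes = chebyshev_nodes(20)
        t = sup.to_canonical(vals)
        kde = sum(
            np.exp(-0.5 * ((nodes[:, None] - d[None]) / 0.1) ** 2).sum(axis=1)
            for d in (t, -2 - t, 2 - t)
        ) / (len(t) * 0.1 * np.sqrt(2 * np.pi))
        np.testing.assert_allclose(reconstruct_density(rep, nodes), kde, atol=1e-9)

    def test_matches_direct_summation(self, rng):
        rep = random_rep(rng, PropertySupport("p", 0, 1))
        x = rng.uniform(-1, 1, 50)
        direct = sum(
            c * np.cos(k * np.arccos(x)) for k, c in enumerate(rep.coefficients)
        )
        np.testing.assert_allclose(reconstruct_density(rep, x), direct, atol=1e-10)

    def test_out_of_interval_rejected(self, rng):
        rep = random_rep(rng, PropertySupport("p", 0, 1))
        with pytest.raises(ValueError):
            reconstruct_density(rep, 1.001)


class TestCd:
    def test_identity_and_symmetry(self, rng):
        sup = PropertySupport("p", 0, 1)
        a, b = random_rep(rng, sup), random_rep(rng, sup)
        assert cd_property(a, a) == 0.0
        assert cd_property(a, b) == pytest.approx(cd_property(b, a))

    def test_metric_axioms_random_triples(self, rng):
        sup = PropertySupport("p", 0, 1)
        for _ in range(200):
            a, b, c = (random_rep(rng, sup) for _ in range(3))
            ab, bc, ac = cd_property(a, b), cd_property(b, c), cd_property(a, c)
            assert ab >= 0
            assert ac <= ab + bc + 1e-12

    def test_upper_bounds_l1_distance(self, rng):
        sup = PropertySupport("p", -1.5, 1.5)
        a = fit_chebyshev(rng.normal(-0.5, 0.15, 2000), sup)
        b = fit_chebyshev(rng.normal(0.6, 0.2, 2000), sup)
        assert cd_property(a, b) >= quadrature_l1(a, b) - 1e-6

    def test_mismatched_support_rejected(self, rng):
        a = random_rep(rng, PropertySupport("p", 0, 1))
        b = random_rep(rng, PropertySupport("p", 0, 2))
        with pytest.raises(ValueError):
            cd_property(a, b)


class TestCdBiofilm:
    def _matrices(self, rng, n_props=13, n_biofilms=2):
        from biofilmstat.chebyshev import ChebyshevMatrix

        names = tuple(f"p{i}" for i in range(n_props))
        sups = tuple(PropertySupport(n, 0, 1) for n in names)
        return [
            ChebyshevMatrix(
                names, sups, 0.2 * rng.standard_normal((21, n_props)), label=str(b)
            )
            for b in range(n_biofilms)
        ]

    def test_identical_matrices_zero(self, rng):
        a, _ = self._matrices(rng)
        assert cd_biofilm(a, a) == 0.0

    def test_single_property_restriction(self, rng):
        a, b = self._matrices(rng)
        assert cd_biofilm(a, b, ["p3"]) == pytest.approx(cd_property(a.rep("p3"), b.rep("p3")))

    def test_sum_decomposition(self, rng):
        a, b = self._matrices(rng)
        total = sum(cd_property(a.rep(n), b.rep(n)) for n in a.names)
        assert cd_biofilm(a, b) == pytest.approx(total)

    def test_empty_subset_rejected(self, rng):
        a, b = self._matrices(rng)
        with pytest.raises(ValueError):
            cd_biofilm(a, b, [])

    def test_compression_size(self, rng):
        a, _ = self._matrices(rng, n_props=13)
        assert a.values.size == 273

    def test_cd_matrix_symmetric_zero_diagonal(self, rng):
        mats = self._matrices(rng, n_props=4, n_biofilms=5)
        m = cd_matrix(mats)
        np.testing.assert_allclose(m, m.T)
        np.testing.assert_allclose(np.diag(m), 0.0)

    def test_serialization_round_trip(self, rng, tmp_path):
        mats = self._matrices(rng, n_props=4, n_biofilms=3)
        save_coefficients(mats, tmp_path / "c.json")
        back = load_coefficients(tmp_path / "c.json")
        assert back[0].names == mats[0].names
        np.testing.assert_allclose(back[2].values, mats[2].values, atol=1e-12)


def brute_force_silhouette(dist, labels):
    """Direct per-point silhouette from the definition (s = 0 for singletons)."""
    labels = np.asarray(labels)
    n = len(labels)
    svals = np.zeros(n)
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        if not same.any():
            continue  # Rousseeuw convention: singleton clusters score 0
        a = dist[i, same].mean()
        b = min(
            dist[i, labels == other].mean() for other in np.unique(labels) if other != labels[i]
        )
        svals[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return svals.mean()


class TestPropertyReduction:
    def test_duplicate_property_distance_zero(self, rng):
        import pandas as pd

        vals = [rng.normal(0, 1, 400) for _ in range(3)]
        tables = [
            pd.DataFrame({"a": v, "a_copy": v, "b": rng.uniform(0, 1, 400)}) for v in vals
        ]
        mats, _ = fit_collection(tables)
        d = property_dissimilarity(mats)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert d[0, 2] > 1.0

    def test_correlated_properties_closest(self, rng):
        import pandas as pd

        # fixed-width cells: length is a scaled copy of aspect ratio
        tables = []
        for b in range(4):
            ar = rng.lognormal(np.log(2.0 + 0.3 * b), 0.2, 400)
            tables.append(
                pd.DataFrame(
                    {"aspect_ratio": ar, "length": 0.8 * ar, "noise": rng.uniform(0, 1, 400)}
                )
            )
        mats, _ = fit_collection(tables)
        d = property_dissimilarity(mats)
        assert d[0, 1] < d[0, 2] and d[0, 1] < d[1, 2]

    def test_duplicate_merged(self, rng):
        import pandas as pd

        # distinct properties follow anti-correlated across-biofilm designs so
        # only the exact duplicate pair clusters together
        x_loc = [1.0, 1.0, 1.0, -1.0, -1.0, -1.0]
        py = [1, -0.5, -0.5, 1, -0.5, -0.5]
        pz = [-0.5, 1, -0.5, -0.5, 1, -0.5]
        pw = [-0.5, -0.5, 1, -0.5, -0.5, 1]
        tables = []
        for b in range(6):
            x = rng.normal(x_loc[b], 1, 300)
            tables.append(pd.DataFrame({
                "x": x, "x_dup": x,
                "y": rng.exponential(1.25 + 0.75 * py[b], 300),
                "z": rng.exponential(1.25 + 0.75 * pz[b], 300),
                "w": rng.exponential(1.25 + 0.75 * pw[b], 300),
            }))
        mats, _ = fit_collection(tables)
        d = property_dissimilarity(mats)
        selected, labels, k = reduce_properties(d, list(mats[0].names))
        assert len(selected) == 4  # p = m - 1
        assert labels[0] == labels[1]  # duplicate pair shares a cluster
        assert "x" in selected and "x_dup" not in selected  # earliest medoid kept

    def test_planted_blocks_recovered_vs_bruteforce(self, rng):
        # 9 properties in 3 planted blocks: small within-, large between-distance
        m, planted = 9, np.repeat([0, 1, 2], 3)
        d = np.where(planted[:, None] == planted[None], 1.0, 10.0)
        d += 0.05 * rng.uniform(size=(m, m))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        names = [f"p{i}" for i in range(m)]
        selected, labels, k = reduce_properties(d, names)
        assert k == 3
        # same partition as planted
        _, inv = np.unique(labels, return_inverse=True)
        _, inv_true = np.unique(planted, return_inverse=True)
        assert len({(a, b) for a, b in zip(inv, inv_true)}) == 3
        # chosen k maximizes the brute-force silhouette over all k
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        z = linkage(squareform(d, checks=False), method="average")
        scores = {
            kk: brute_force_silhouette(d, fcluster(z, t=kk, criterion="maxclust"))
            for kk in range(2, m)
        }
        assert max(scores, key=scores.get) == k
        # medoids match exhaustive search within each planted block
        for lab in np.unique(labels):
            members = np.flatnonzero(labels == lab)
            best = members[np.argmin([d[i, members].sum() for i in members])]
            assert names[best] in selected

    def test_too_few_properties_rejected(self):
        with pytest.raises(ValueError):
            reduce_properties(np.zeros((2, 2)), ["a", "b"])
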