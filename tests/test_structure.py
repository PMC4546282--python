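"""Φst/AMOVA variance components, Mantel, MDS and shared haplotypes."""

from itertools import combinations, permutations

import numpy as np
import pytest

from conftest import random_sequences
from mesodemog.diversity import pairwise_difference_matrix
from mesodemog.structure import (
    AmovaResult,
    DistanceMatrix,
    StructureError,
    amova,
    centroid_diversity_correlation,
    corrected_pairwise_diff,
    geographic_distance_matrix,
    mantel,
    mds,
    pairwise_phist,
    phist_from_distances,
    shared_haplotype_matrix,
    two_level_components,
)


def brute_force_two_level(d2, labels):
    """Independent variance-component computation straight from the sums."""
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_w += sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)
    P = len(groups)
    sigma_w = (ss_w) / (n - P)
    sizes = [labels.count(g) for g in groups]
    n_c = (n - sum(s * s for s in sizes) / n) / (P - 1)
    sigma_a = ((ss_total - ss_w) / (P - 1) - sigma_w) / n_c
    return sigma_a, sigma_w


class TestPhist:
    def test_identical_populations(self):
        pop = ["ACGTACGT", "ACGAACGT", "ACGTACGA"]
        phist, p, neg = pairwise_phist(pop, list(pop), n_perm=200, seed=1)
        assert phist <= 0.0
        assert neg or phist == 0.0
        assert p > 0.5

    def test_fixed_difference_gives_one(self):
        a = ["AAAAAAAA"] * 4
        b = ["AAAATTTT"] * 4
        phist, p, _ = pairwise_phist(a, b, n_perm=500, seed=2)
        assert phist == pytest.approx(1.0)
        assert p < 0.05

    def test_matches_brute_force_components(self):
        rng = np.random.default_rng(5)
        seqs = random_sequences(rng, 12, 30)
        d2 = pairwise_difference_matrix(seqs)
        labels = [0] * 6 + [1] * 6
        sa, sw = two_level_components(d2, np.array(labels))
        sa2, sw2 = brute_force_two_level(d2, labels)
        assert sa == pytest.approx(sa2, abs=1e-10)
        assert sw == pytest.approx(sw2, abs=1e-10)
        obs = phist_from_distances(d2, np.array(labels))
        assert obs == pytest.approx(sa2 / (sa2 + sw2), abs=1e-10)

    def test_needs_permutations(self):
        with pytest.raises(StructureError):
            pairwise_phist(["AC", "AG"], ["AC", "AG"], n_perm=0)


class TestCorrectedPairwiseDiff:
    def test_same_distribution_centres_on_zero(self):
        """Splitting one panmictic pool in two: corrected distance has mean 0."""
        rng = np.random.default_rng(12)
        vals = []
        for _ in range(50):
            pool = random_sequences(rng, 12, 60)
            vals.append(corrected_pairwise_diff(pool[:6], pool[6:]))
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 1e-9

    def test_identical_monomorphic_demes_are_zero(self):
        pop = ["ACGTAC"] * 3
        assert corrected_pairwise_diff(pop, list(pop)) == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_demes_three_sites(self):
        a = ["AAAAAA"] * 3
        b = ["TTTAAA"] * 3
        assert corrected_pairwise_diff(a, b) == pytest.approx(3.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(6)
        a = random_sequences(rng, 4, 20)
        b = random_sequences(rng, 5, 20)

        def mean_diff(x, y, same):
            pairs = combinations(range(len(x)), 2) if same else \
                [(i, j) for i in range(len(x)) for j in range(len(y))]
            vals = []
            for i, j in pairs:
                vals.append(sum(1 for u, v in zip(x[i], y[j]) if u != v))
            return sum(vals) / len(vals)

        expected = mean_diff(a, b, False) - (mean_diff(a, a, True) + mean_diff(b, b, True)) / 2
        assert corrected_pairwise_diff(a, b) == pytest.approx(expected, abs=1e-10)


def brute_force_three_level(d2, pop_of, group_of_pop):
    """Oracle for the hierarchical decomposition, written from the definitions."""
    n = len(pop_of)
    pops = sorted(set(pop_of))
    groups = sorted({group_of_pop[p] for p in pops})

    def ss(idx):
        return sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)

    ss_t = ss(range(n))
    ss_wp = sum(ss([i for i in range(n) if pop_of[i] == p]) for p in pops)
    ss_g = sum(ss([i for i in range(n) if group_of_pop[pop_of[i]] == g]) for g in groups)
    P, G = len(pops), len(groups)
    df_wp, df_ap, df_ag = n - P, P - G, G - 1
    sigma_w = ss_wp / df_wp
    n_of = {p: pop_of.count(p) for p in pops}
    size_g = {g: sum(n_of[p] for p in pops if group_of_pop[p] == g) for g in groups}
    sum_n2_g = {g: sum(n_of[p] ** 2 for p in pops if group_of_pop[p] == g) for g in groups}
    n1 = (n - sum(sum_n2_g[g] / size_g[g] for g in groups)) / df_ap
    sigma_b = ((ss_g - ss_wp) / df_ap - sigma_w) / n1
    n2 = (sum(sum_n2_g[g] / size_g[g] for g in groups) - sum(n_of[p] ** 2 for p in pops) / n) / df_ag
    n3 = (n - sum(s * s for s in size_g.values()) / n) / df_ag
    sigma_a = ((ss_t - ss_g) / df_ag - sigma_w - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_w


class TestAmova:
    def test_components_match_brute_force(self):
        rng = np.random.default_rng(7)
        pops = {f"P{i}": random_sequences(rng, 4 + i, 25) for i in range(4)}
        grouping = {"P0": "G1", "P1": "G1", "P2": "G2", "P3": "G2"}
        res = amova(pops, grouping, n_perm=50, seed=3)
        seqs, pop_of = [], []
        for i, name in enumerate(sorted(pops)):
            seqs.extend(pops[name])
            pop_of.extend([i] * len(pops[name]))
        d2 = pairwise_difference_matrix(seqs)
        gmap = {0: 0, 1: 0, 2: 1, 3: 1}
        sa, sb, sw = brute_force_three_level(d2, pop_of, gmap)
        assert res.sigma_among_groups == pytest.approx(sa, abs=1e-10)
        assert res.sigma_among_pops == pytest.approx(sb, abs=1e-10)
        assert res.sigma_within == pytest.approx(sw, abs=1e-10)

    def test_mutually_distinct_internally_identical_demes(self):
        """All variance between groups: F_CT approaches 1."""
        between = "T" * 20 + "A" * 4
        pops = {
            "P1": ["A" * 24] * 4, "P2": ["A" * 23 + "T"] * 4,
            "P3": [between] * 4, "P4": [between[:-1] + "T"] * 4,
        }
        grouping = {"P1": "G1", "P2": "G1", "P3": "G2", "P4": "G2"}
        res = amova(pops, grouping, n_perm=100, seed=1)
        assert res.f_ct > 0.9
        # only 3 distinct 2+2 splits of 4 populations exist, so p floors at ~1/3
        assert res.p_ct == pytest.approx(1 / 3, abs=0.1)

    def test_null_grouping_fct_near_zero(self):
        """Identically distributed demes: F_CT fluctuates around 0 and its
        permutation p-values spread over (0,1)."""
        rng = np.random.default_rng(11)
        fcts, ps = [], []
        for rep in range(30):
            base = random_sequences(rng, 20, 30)
            pops = {f"P{i}": base[5 * i : 5 * (i + 1)] for i in range(4)}
            grouping = {"P0": "G1", "P1": "G1", "P2": "G2", "P3": "G2"}
            res = amova(pops, grouping, n_perm=60, seed=rep)
            fcts.append(res.f_ct)
            ps.append(res.p_ct)
        assert abs(np.mean(fcts)) < 0.05
        assert 0.2 < np.mean(ps) < 0.8
        assert max(ps) > 0.5 and min(ps) < 0.5

    def test_degenerate_design_rejected(self):
        pops = {"P1": ["AC"] * 3, "P2": ["AG"] * 3}
        with pytest.raises(StructureError):
            amova(pops, {"P1": "G1", "P2": "G1"}, n_perm=10)


class TestMantel:
    @staticmethod
    def random_dm(rng, labels):
        n = len(labels)
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        return DistanceMatrix(tuple(labels), m)

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        d = self.random_dm(rng, "ABCDEF")
        r, p = mantel(d, d, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_affine_transform_correlation_is_one(self):
        rng = np.random.default_rng(2)
        d = self.random_dm(rng, "ABCDEF")
        d2 = DistanceMatrix(d.labels, 3.0 * d.values + (1 - np.eye(d.n)) * 2.0)
        r, _ = mantel(d, d2, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_permutation_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        dA = self.random_dm(rng, "ABCDEF")
        dB = self.random_dm(rng, "ABCDEF")
        iu = np.triu_indices(6, k=1)
        a = dA.values[iu]
        obs = np.corrcoef(a, dB.values[iu])[0, 1]
        count = 0
        total = 0
        for perm in permutations(range(6)):
            b = dB.values[np.ix_(perm, perm)][iu]
            if abs(np.corrcoef(a, b)[0, 1]) >= abs(obs) - 1e-12:
                count += 1
            total += 1
        p_exact = count / total
        n_perm = 10_000
        _, p_mc = mantel(dA, dB, n_perm=n_perm, seed=4)
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_mc - p_exact) < max(2 * se, 2 / 720)

    def test_against_skbio(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(5)
        dA = self.random_dm(rng, "ABCDEFGH")
        dB = self.random_dm(rng, "ABCDEFGH")
        r_mine, _ = mantel(dA, dB, n_perm=10, seed=0)
        r_ref, _, _ = skbio_mantel(SkbioDM(dA.values), SkbioDM(dB.values),
                                   permutations=0)
        assert r_mine == pytest.approx(r_ref, abs=1e-10)

    def test_constant_matrix_rejected(self):
        ones = DistanceMatrix(("a", "b", "c"), np.ones((3, 3)) - np.eye(3))
        with pytest.raises(StructureError):
            mantel(ones, ones, n_perm=10)


class TestMds:
    def test_collinear_points_recovered(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        d = np.abs(x[:, None] - x[None, :])
        sol = mds(DistanceMatrix(("a", "b", "c", "d"), d))
        rec = np.linalg.norm(sol.coordinates[:, None] - sol.coordinates[None], axis=2)
        assert np.allclose(rec, d, atol=1e-9)
        assert np.allclose(sol.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_equilateral_from_equal_distances(self):
        d = np.ones((3, 3)) - np.eye(3)
        sol = mds(DistanceMatrix(("a", "b", "c"), d))
        rec = np.linalg.norm(sol.coordinates[:, None] - sol.coordinates[None], axis=2)
        off = rec[np.triu_indices(3, k=1)]
        assert np.allclose(off, off[0], atol=1e-9)

    def test_label_order_invariance_up_to_rotation(self):
        rng = np.random.default_rng(8)
        pts = rng.random((8, 2))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        labels = tuple("abcdefgh")
        sol1 = mds(DistanceMatrix(labels, d))
        perm = rng.permutation(8)
        sol2 = mds(DistanceMatrix(tuple(labels[i] for i in perm), d[np.ix_(perm, perm)]))
        # align sol2 rows back to sol1's label order, then Procrustes
        inv = np.argsort(perm)
        from scipy.linalg import orthogonal_procrustes

        a, b = sol1.coordinates, sol2.coordinates[inv]
        rot, _ = orthogonal_procrustes(b, a)
        assert np.linalg.norm(b @ rot - a) < 1e-9

    def test_against_skbio_pcoa(self):
        from skbio.stats.ordination import pcoa

        rng = np.random.default_rng(9)
        m = rng.random((8, 8)) * 0.09
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        sol = mds(DistanceMatrix(tuple("abcdefgh"), m))
        ref = pcoa(m, number_of_dimensions=2)
        rec_m = np.linalg.norm(sol.coordinates[:, None] - sol.coordinates[None], axis=2)
        ref_c = ref.samples.to_numpy()
        rec_r = np.linalg.norm(ref_c[:, None] - ref_c[None], axis=2)
        assert np.allclose(rec_m, rec_r, atol=1e-8)

    def test_dims_bound(self):
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(StructureError):
            mds(DistanceMatrix(("a", "b", "c"), d), dims=3)


class TestCentroidDiversityCorrelation:
    @staticmethod
    def solution_from_points(pts, labels):
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        return mds(DistanceMatrix(tuple(labels), d))

    def test_constant_diversity_rejected(self):
        rng = np.random.default_rng(1)
        sol = self.solution_from_points(rng.random((5, 2)), "abcde")
        with pytest.raises(StructureError):
            centroid_diversity_correlation(sol, {lab: 0.9 for lab in "abcde"})

    def test_sign_for_decreasing_diversity(self):
        rng = np.random.default_rng(2)
        pts = rng.random((6, 2))
        sol = self.solution_from_points(pts, "abcdef")
        centroid = sol.coordinates.mean(axis=0)
        dist = np.linalg.norm(sol.coordinates - centroid, axis=1)
        h = {lab: 1.0 - d for lab, d in zip("abcdef", dist)}
        r, _ = centroid_diversity_correlation(sol, h)
        assert r < -0.99

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(3)
        pts = rng.random((10, 2))
        labels = [f"p{i}" for i in range(10)]
        sol = self.solution_from_points(pts, labels)
        h = {lab: float(v) for lab, v in zip(labels, rng.random(10))}
        r, _ = centroid_diversity_correlation(sol, h)
        centroid = sol.coordinates.mean(axis=0)
        x = np.linalg.norm(sol.coordinates - centroid, axis=1)
        y = np.array([h[lab] for lab in labels])
        mx, my = x.mean(), y.mean()
        r_oracle = ((x - mx) * (y - my)).sum() / np.sqrt(
            ((x - mx) ** 2).sum() * ((y - my) ** 2).sum()
        )
        assert r == pytest.approx(r_oracle, abs=1e-12)


class TestSharedHaplotypes:
    def test_disjoint_identical_and_overlap(self):
        sets = {
            "A": {"h1", "h2", "h3"},
            "B": {"h4", "h5"},
            "C": {"h1", "h2", "h3"},
            "D": {"h2", "h3", "h6", "h7"},
        }
        m = shared_haplotype_matrix(sets)
        assert m.loc["A", "B"] == 0
        assert m.loc["A", "C"] == 3
        assert m.loc["A", "D"] == 2
        assert (m.values == m.values.T).all()


def test_geographic_distances_are_haversine():
    import pandas as pd

    meta = pd.DataFrame({
        "sample": ["a", "b"], "population": ["P1", "P2"],
        "lat": [20.0, 21.0], "lon": [-89.0, -89.0],
    })
    d = geographic_distance_matrix(meta)
    assert d.values[0, 1] == pytest.approx(111.19, abs=0.5)  # 1 degree latitude
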