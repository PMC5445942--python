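"""Pairwise distances, group means, net distances and bootstrap SEs."""

import numpy as np
import pytest

from specdelim.distmat import (
    DistanceMatrix,
    bootstrap_se,
    distance_matrix,
    group_mean_distances,
    net_between,
)
from specdelim.errors import IncomparablePairError
from specdelim.seqio import GroupingScheme

from conftest import make_alignment, random_alignment


def _mutated_pair(seed, p, L=300):
    """One ancestral sequence and a copy with ~p*L substituted sites."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    s1 = rng.integers(0, 4, L)
    s2 = s1.copy()
    hits = rng.random(L) < p
    s2[hits] = (s2[hits] + rng.integers(1, 4, hits.sum())) % 4
    return make_alignment([("a", "".join(bases[s1])), ("b", "".join(bases[s2]))])


class TestPDistance:
    def test_single_difference(self):
        a = make_alignment([("a", "ACGTACGT"), ("b", "ACGTACGA")])
        assert distance_matrix(a, "p").values[0, 1] == pytest.approx(0.125)

    def test_identical_sequences_zero(self):
        a = make_alignment([("a", "ACGT"), ("b", "ACGT")])
        for model in ("p", "tn93_gamma"):
            assert distance_matrix(a, model).values[0, 1] == 0.0

    def test_matches_brute_force_site_count(self):
        rng = np.random.default_rng(7)
        a = random_alignment(rng, n=5, L=200)
        m = distance_matrix(a, "p")
        for i in range(5):
            for j in range(5):
                expected = (
                    sum(x != y for x, y in zip(a.seqs[i], a.seqs[j])) / 200
                )
                assert m.values[i, j] == pytest.approx(expected, abs=0)

    def test_pairwise_deletion_uses_shared_sites(self):
        a = make_alignment([("a", "A-GT"), ("b", "ACGA"), ("c", "ACGT")])
        m = distance_matrix(a, "p", policy="pairwise")
        assert m.values[0, 1] == pytest.approx(1 / 3)  # sites 0,2,3; one diff
        assert m.values[0, 2] == 0.0

    def test_incomparable_pair_raises(self):
        a = make_alignment([("a", "AC--"), ("b", "--GT"), ("c", "ACGT")])
        with pytest.raises(IncomparablePairError):
            distance_matrix(a, "p", policy="pairwise")

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        a = random_alignment(rng, n=6, L=100)
        m1 = distance_matrix(a, "p")
        perm = [4, 2, 0, 5, 1, 3]
        b = make_alignment([(a.ids[i], a.seqs[i]) for i in perm])
        m2 = distance_matrix(b, "p")
        for x in a.ids:
            for y in a.ids:
                assert m1.get(x, y) == m2.get(x, y)


class TestTN93Gamma:
    def test_matches_ape_reference_values(self):
        """Frozen cross-check against ape::dist.dna(model='TN93', gamma=1)."""
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        expected = [
            (0.0433333333, 0.0460063246),
            (0.1733333333, 0.2279146762),
            (0.3000000000, 0.5032291686),
        ]
        for p, (exp_p, exp_g) in zip([0.05, 0.15, 0.30], expected):
            L = 300
            s1 = rng.integers(0, 4, L)
            s2 = s1.copy()
            hits = rng.random(L) < p
            s2[hits] = (s2[hits] + rng.integers(1, 4, hits.sum())) % 4
            a = make_alignment(
                [("a", "".join(bases[s1])), ("b", "".join(bases[s2]))]
            )
            got_p = distance_matrix(a, "p").values[0, 1]
            got_g = distance_matrix(a, "tn93_gamma", gamma_shape=1.0).values[0, 1]
            assert got_p == pytest.approx(exp_p, abs=1e-9)
            assert got_g == pytest.approx(exp_g, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_correction_inflates_p_distance(self, seed):
        a = _mutated_pair(seed, p=0.2)
        p = distance_matrix(a, "p").values[0, 1]
        g = distance_matrix(a, "tn93_gamma", gamma_shape=1.0).values[0, 1]
        assert g >= p

    def test_saturated_pair_flagged_infinite(self):
        a = make_alignment([("a", "AAAAAAAAAA"), ("b", "GGGGGGGGGG")])
        with pytest.warns(UserWarning, match="diverged"):
            m = distance_matrix(a, "tn93_gamma")
        assert np.isinf(m.values[0, 1])


class TestGroupMeans:
    def test_worked_example(self):
        values = np.array(
            [[0.0, 0.02, 0.10], [0.02, 0.0, 0.12], [0.10, 0.12, 0.0]]
        )
        m = DistanceMatrix(("x1", "x2", "y1"), values, "p", "complete", 100)
        g = GroupingScheme(
            "g", {"x1": ("X", "px"), "x2": ("X", "px"), "y1": ("Y", "py")}
        )
        with pytest.warns(UserWarning, match="singleton"):
            s = group_mean_distances(m, g)
        assert s.within["X"] == pytest.approx(0.02)
        assert s.within["Y"] == 0.0
        assert s.between[("X", "Y")] == pytest.approx(0.11)
        assert s.net_between("X", "Y") == pytest.approx(0.10)

    def test_fixed_differences_net_equals_raw(self, two_group_scheme):
        aln, scheme = two_group_scheme
        m = distance_matrix(aln, "p")
        s = group_mean_distances(m, scheme)
        assert s.within == {"X": 0.0, "Y": 0.0}
        assert s.net_between("X", "Y") == pytest.approx(0.5)

    def test_same_group_net_zero(self, two_group_scheme):
        aln, scheme = two_group_scheme
        m = distance_matrix(aln, "p")
        assert group_mean_distances(m, scheme).net_between("X", "X") == 0.0

    def test_net_can_be_negative(self):
        # high within diversity, low between divergence
        a = make_alignment(
            [
                ("x1", "AAAAAAAAAA"),
                ("x2", "GGGGGGGGGG"),
                ("y1", "AAAAAGGGGG"),
                ("y2", "GGGGGAAAAA"),
            ]
        )
        g = GroupingScheme(
            "g",
            {
                "x1": ("X", "px"),
                "x2": ("X", "px"),
                "y1": ("Y", "py"),
                "y2": ("Y", "py"),
            },
        )
        net = net_between(distance_matrix(a, "p"), g, "X", "Y")
        assert net < 0


class TestBootstrap:
    @staticmethod
    def _net_stat(m, g):
        return {"net": net_between(m, g, "X", "Y")}

    def test_invariant_alignment_zero_se(self):
        a = make_alignment([(f"s{i}", "ACGTACGTAC") for i in range(4)])
        g = GroupingScheme(
            "g",
            {
                "s0": ("X", "p0"),
                "s1": ("X", "p0"),
                "s2": ("Y", "p1"),
                "s3": ("Y", "p1"),
            },
        )
        se = bootstrap_se(a, g, self._net_stat, replicates=50, seed=1)
        assert se["net"] == 0.0

    def test_seed_determinism(self, two_group_scheme):
        aln, scheme = two_group_scheme
        kw = dict(replicates=100, seed=9)
        se1 = bootstrap_se(aln, scheme, self._net_stat, **kw)
        se2 = bootstrap_se(aln, scheme, self._net_stat, **kw)
        assert se1 == se2

    def test_se_tracks_monte_carlo_truth(self):
        """Bootstrap SE of the net distance approximates the sampling SD
        of the statistic over independent re-simulations."""
        from specdelim.synth import LineageConfig, LocusConfig, SimConfig, simulate_dataset

        def one_net(seed):
            cfg = SimConfig(
                seed=seed,
                loci=(LocusConfig("l", 400, 1.0),),
                lineages=(
                    LineageConfig("X", {"px": 8}, 0.004),
                    LineageConfig("Y", {"py": 8}, 0.004),
                ),
                divergence=np.array([[0.0, 0.06], [0.06, 0.0]]),
            )
            sim = simulate_dataset(cfg)
            m = distance_matrix(sim.alignments["l"], "p")
            return sim, net_between(m, sim.truth, "X", "Y")

        nets = [one_net(s)[1] for s in range(60)]
        mc_sd = float(np.std(nets, ddof=1))
        sim, _ = one_net(0)
        se = bootstrap_se(
            sim.alignments["l"], sim.truth, self._net_stat, replicates=300, seed=2
        )["net"]
        assert se == pytest.approx(mc_sd, rel=0.6)
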