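"""AMOVA variance components, candidate arrangements and plateau rule."""

import math

import numpy as np
import pytest

from specdelim.amova import (
    amova_components,
    enumerate_candidate_arrangements,
    published_phi_ct_series,
    read_arrangement_table,
    select_plateau,
)
from specdelim.distmat import distance_matrix
from specdelim.errors import (
    InvalidHierarchyError,
    NoCandidatesError,
    NoMolecularVariationError,
)
from specdelim.seqio import GroupingScheme

from conftest import make_alignment, random_structured_instance


# ---------------------------------------------------------------------------
# independent straight-line oracle: explicit double loops + linear solve


def amova_oracle(d2, structure):
    """Brute-force nested AMOVA.

    ``d2``: full squared-distance matrix.  ``structure``: list of groups,
    each a list of populations, each a list of row indices.  Forms the
    sums of squares by explicit double loops and solves the 3x3
    mean-square expectation system with numpy.linalg.solve.
    """
    all_idx = [i for grp in structure for pop in grp for i in pop]
    N = len(all_idx)
    G = len(structure)
    P = sum(len(grp) for grp in structure)

    def ssd(idx):
        total = 0.0
        for i in idx:
            for j in idx:
                total += d2[i, j]
        return total / (2 * len(idx))

    ssd_total = ssd(all_idx)
    ssd_wp = sum(ssd(pop) for grp in structure for pop in grp)
    ssd_wg = sum(ssd([i for pop in grp for i in pop]) for grp in structure)
    ssd_ap = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg

    sizes = [[len(pop) for pop in grp] for grp in structure]
    ng = [sum(s) for s in sizes]
    sum_np2_over_ng = sum(
        sum(n * n for n in grp) / ng[g] for g, grp in enumerate(sizes)
    )
    sum_np2_over_n = sum(n * n for grp in sizes for n in grp) / N
    sum_ng2_over_n = sum(n * n for n in ng) / N
    n1 = (N - sum_np2_over_ng) / (P - G)
    n2 = (sum_np2_over_ng - sum_np2_over_n) / (G - 1)
    n3 = (N - sum_ng2_over_n) / (G - 1)

    msd = np.array([ssd_ag / (G - 1), ssd_ap / (P - G), ssd_wp / (N - P)])
    coeff = np.array([[n3, n2, 1.0], [0.0, n1, 1.0], [0.0, 0.0, 1.0]])
    sigma_a, sigma_b, sigma_c = np.linalg.solve(coeff, msd)
    total = sigma_a + sigma_b + sigma_c
    return {
        "sigma": (sigma_a, sigma_b, sigma_c),
        "phi_st": (sigma_a + sigma_b) / total,
        "phi_sc": sigma_b / (sigma_b + sigma_c),
        "phi_ct": sigma_a / total,
    }


class TestAmovaComponents:
    def test_all_variation_among_groups(self, two_group_scheme):
        aln, scheme = two_group_scheme
        m = distance_matrix(aln, "p")
        res = amova_components(m, scheme)
        assert res.sigma_b == pytest.approx(0.0, abs=1e-12)
        assert res.sigma_c == pytest.approx(0.0, abs=1e-12)
        assert res.phi_ct == pytest.approx(1.0)
        assert math.isnan(res.phi_sc)  # 0/0

    def test_all_identical_raises(self):
        a = make_alignment([(f"s{i}", "ACGT") for i in range(4)])
        g = GroupingScheme(
            "g",
            {
                "s0": ("X", "p0"),
                "s1": ("X", "p0"),
                "s2": ("Y", "p1"),
                "s3": ("Y", "p1"),
            },
        )
        with pytest.raises(NoMolecularVariationError):
            amova_components(distance_matrix(a, "p"), g)

    def test_single_group_phi_ct_nan(self):
        a = make_alignment(
            [("s0", "AAAA"), ("s1", "AAAT"), ("s2", "AATT"), ("s3", "ATTT")]
        )
        g = GroupingScheme(
            "one",
            {
                "s0": ("X", "p0"),
                "s1": ("X", "p0"),
                "s2": ("X", "p1"),
                "s3": ("X", "p1"),
            },
        )
        res = amova_components(distance_matrix(a, "p"), g)
        assert math.isnan(res.phi_ct)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_oracle(self, seed):
        """50 random unequal-sample-size instances agree with the
        double-loop oracle to 1e-10 relative tolerance."""
        rng = np.random.default_rng(seed)
        aln, scheme = random_structured_instance(rng)
        m = distance_matrix(aln, "p")
        res = amova_components(m, scheme, delta_sq="count_of_differences")

        pos = {sid: i for i, sid in enumerate(m.ids)}
        structure = [
            [[pos[s] for s in members] for members in pops.values()]
            for pops in scheme.populations_by_group().values()
        ]
        d2 = m.values * m.sites_used
        oracle = amova_oracle(d2, structure)
        assert res.sigma_a == pytest.approx(oracle["sigma"][0], rel=1e-10, abs=1e-12)
        assert res.sigma_b == pytest.approx(oracle["sigma"][1], rel=1e-10, abs=1e-12)
        assert res.sigma_c == pytest.approx(oracle["sigma"][2], rel=1e-10, abs=1e-12)
        assert res.phi_ct == pytest.approx(oracle["phi_ct"], rel=1e-10)
        assert res.phi_st == pytest.approx(oracle["phi_st"], rel=1e-10)
        assert res.phi_sc == pytest.approx(oracle["phi_sc"], rel=1e-10)

    def test_invariant_to_relabeling_and_order(self):
        rng = np.random.default_rng(11)
        aln, scheme = random_structured_instance(rng)
        m = distance_matrix(aln, "p")
        base = amova_components(m, scheme)

        relabeled = GroupingScheme(
            "relabel",
            {
                sid: (f"Z{grp}", f"q{pop}")
                for sid, (grp, pop) in scheme.mapping.items()
            },
        )
        perm = list(range(aln.n))
        rng.shuffle(perm)
        shuffled = make_alignment([(aln.ids[i], aln.seqs[i]) for i in perm])
        res2 = amova_components(distance_matrix(shuffled, "p"), relabeled)
        assert res2.phi_ct == pytest.approx(base.phi_ct, rel=1e-12)
        assert res2.phi_st == pytest.approx(base.phi_st, rel=1e-12)

    def test_variance_components_sum_to_total(self):
        rng = np.random.default_rng(23)
        aln, scheme = random_structured_instance(rng)
        res = amova_components(distance_matrix(aln, "p"), scheme)
        assert res.phi_ct + res.sigma_b / res.total_variance == pytest.approx(
            res.phi_st, rel=1e-9
        )


class TestArrangements:
    POPS = {"p1": ["s1"], "p2": ["s2"], "p3": ["s3"], "p4": ["s4"]}

    def test_levels_pass_through(self):
        levels = [
            {"p1": "A", "p2": "A", "p3": "B", "p4": "B"},
            {"p1": "a1", "p2": "a2", "p3": "b1", "p4": "b2"},
        ]
        schemes = enumerate_candidate_arrangements(levels, self.POPS)
        assert [s.k for s in schemes] == [2, 4]

    def test_non_nested_rejected(self):
        levels = [
            {"p1": "A", "p2": "A", "p3": "B", "p4": "B"},
            {"p1": "x", "p2": "y", "p3": "x", "p4": "y"},  # x spans A and B
        ]
        with pytest.raises(InvalidHierarchyError):
            enumerate_candidate_arrangements(levels, self.POPS)

    def test_arrangement_table_round_trip(self, tmp_path):
        p = tmp_path / "arr.tsv"
        p.write_text(
            "population_id\tk2\tk4\n"
            "p1\tA\ta1\np2\tA\ta2\np3\tB\tb1\np4\tB\tb2\n"
        )
        schemes = read_arrangement_table(p, self.POPS)
        assert [s.name for s in schemes] == ["k2", "k4"]
        assert [s.k for s in schemes] == [2, 4]
        assert schemes[0].group_of("s3") == "B"


class TestPlateau:
    def test_published_series_selects_six_lineages(self):
        sel = select_plateau(published_phi_ct_series(), tau=0.02)
        assert sel.per_locus_k == {"coi": 6, "16s": 6}
        assert sel.selected_k == 6
        assert not sel.discordant
        assert not any(sel.no_plateau.values())

    def test_constant_series_selects_smallest(self):
        sel = select_plateau({"l": {2: 0.5, 4: 0.5, 6: 0.5}}, tau=0.02)
        assert sel.per_locus_k["l"] == 2

    def test_steep_series_flags_no_plateau(self):
        sel = select_plateau({"l": {2: 0.1, 3: 0.3, 4: 0.5}}, tau=0.02)
        assert sel.per_locus_k["l"] == 4
        assert sel.no_plateau["l"]

    def test_discordant_loci_flagged(self):
        sel = select_plateau(
            {
                "fast": {2: 0.1, 3: 0.6, 4: 0.61},
                "slow": {2: 0.6, 3: 0.61, 4: 0.62},
            },
            tau=0.02,
        )
        assert sel.discordant
        assert sel.selected_k is None

    def test_empty_series_raises(self):
        with pytest.raises(NoCandidatesError):
            select_plateau({}, tau=0.02)
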