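"""Clonotype building, diversity indices, downsampling, clone classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clonomosaic import clonality
from clonomosaic.clonality import Repertoire
from clonomosaic.io_formats import ClonotypeRecord


def _rec(cell, chain, v="V1", j="J1", cdr3="TGTGCC", umis=1, productive=True):
    return ClonotypeRecord(cell, chain, v, j, cdr3, "CA", umis, productive)


class TestBuildRepertoire:
    def test_identical_trb_collapse(self):
        records = [_rec(f"c{i}", "TRB") for i in range(3)]
        rep = clonality.build_repertoire(records)
        assert len(rep.clonotypes) == 1
        assert rep.clonotypes[0].n_c == 3

    def test_paired_vs_beta_scheme(self):
        # same TRB, different TRA: 2 clonotypes paired, 1 clonotype beta-only
        records = [
            _rec("c1", "TRB"), _rec("c1", "TRA", cdr3="TGTAAA"),
            _rec("c2", "TRB"), _rec("c2", "TRA", cdr3="TGTCCC"),
        ]
        paired = clonality.build_repertoire(records, scheme="paired")
        beta = clonality.build_repertoire(records, scheme="beta")
        assert len(paired.clonotypes) == 2
        assert len(beta.clonotypes) == 1 and beta.clonotypes[0].n_c == 2

    def test_nonproductive_cell_excluded(self):
        records = [_rec("c1", "TRB"), _rec("c2", "TRB", productive=False)]
        rep = clonality.build_repertoire(records)
        assert rep.N == 1 and rep.n_excluded_cells == 1

    def test_all_excluded_is_error(self):
        with pytest.raises(ValueError, match="empty repertoire"):
            clonality.build_repertoire([_rec("c1", "TRB", productive=False)])

    def test_multichain_keeps_highest_umi(self):
        records = [
            _rec("c1", "TRB", cdr3="TGTAAA", umis=5),
            _rec("c1", "TRB", cdr3="TGTCCC", umis=2),
        ]
        rep = clonality.build_repertoire(records)
        assert rep.clonotypes[0].key.cdr3_nt_trb == "TGTAAA"

    def test_multichain_umi_tie_breaks_lexicographically(self):
        records = [
            _rec("c1", "TRB", cdr3="TGTCCC", umis=3),
            _rec("c1", "TRB", cdr3="TGTAAA", umis=3),
        ]
        rep = clonality.build_repertoire(records)
        assert rep.clonotypes[0].key.cdr3_nt_trb == "TGTAAA"


class TestInverseSimpson:
    @pytest.mark.parametrize("k", [1, 4, 100])
    def test_uniform_repertoire_equals_clone_count(self, k):
        rep = Repertoire.from_counts("s", [1] * k)
        assert clonality.inverse_simpson(rep) == pytest.approx(k, abs=1e-12)

    def test_skewed_hand_value(self):
        rep = Repertoire.from_counts("s", [50, 30, 20])
        assert clonality.inverse_simpson(rep) == pytest.approx(1 / 0.38, abs=1e-9)

    def test_uniform_maximizes_and_perturbation_decreases(self):
        k = 10
        uniform = Repertoire.from_counts("s", [5] * k)
        assert clonality.inverse_simpson(uniform) == pytest.approx(k, abs=1e-12)
        perturbed = Repertoire.from_counts("s", [6, 4] + [5] * (k - 2))
        assert clonality.inverse_simpson(perturbed) < k


class TestDownsampledDiversity:
    def test_full_depth_is_identity_with_zero_width_ci(self):
        rep = Repertoire.from_counts("s", [50, 30, 20])
        est = clonality.downsampled_diversity(rep, depth=100, n_boot=200, seed=0)
        assert est.point == pytest.approx(clonality.inverse_simpson(rep), abs=1e-12)
        assert est.ci_high - est.ci_low == pytest.approx(0, abs=1e-12)

    def test_all_singlet_repertoire_is_degenerate(self):
        rep = Repertoire.from_counts("s", [1] * 1000)
        est = clonality.downsampled_diversity(rep, depth=100, n_boot=50, seed=1)
        assert est.point == pytest.approx(100, abs=1e-12)
        assert est.ci_high - est.ci_low == pytest.approx(0, abs=1e-12)

    def test_depth_exceeding_n_instructs_common_depth(self):
        rep = Repertoire.from_counts("s", [5, 5])
        with pytest.raises(ValueError, match="minimum sample size"):
            clonality.downsampled_diversity(rep, depth=11)

    def test_seed_reproducibility_and_seed_stability(self):
        rep = Repertoire.from_counts("s", [500, 300, 200])
        a = clonality.downsampled_diversity(rep, depth=50, n_boot=1000, seed=3)
        b = clonality.downsampled_diversity(rep, depth=50, n_boot=1000, seed=3)
        assert a == b
        c = clonality.downsampled_diversity(rep, depth=50, n_boot=1000, seed=4)
        # different seeds agree within 4x combined Monte-Carlo SE
        rng = np.random.default_rng(0)
        draws = rng.multivariate_hypergeometric([500, 300, 200], 50, size=2000)
        sd = (1.0 / np.square(draws / 50).sum(axis=1)).std()
        se = sd * np.sqrt(2.0 / 1000.0)
        assert abs(a.point - c.point) < 4 * se


class TestOccupancy:
    def test_single_clone_all_in_top_bin(self):
        rep = Repertoire.from_counts("s", [7])
        occ = clonality.occupancy_profile(rep, (0, 0.5, 1))
        assert occ[(0.5, 1.0)] == pytest.approx(1.0)
        assert occ[(0.0, 0.5)] == 0

    def test_right_closed_boundary(self):
        rep = Repertoire.from_counts("s", [1] * 100)  # every p = 0.01
        occ = clonality.occupancy_profile(rep, (0, 0.01, 1))
        assert occ[(0.0, 0.01)] == pytest.approx(1.0)

    def test_hand_assignment(self):
        rep = Repertoire.from_counts("s", [60, 30, 10])
        occ = clonality.occupancy_profile(rep, (0, 0.2, 0.5, 1))
        assert occ[(0.0, 0.2)] == pytest.approx(0.1)
        assert occ[(0.2, 0.5)] == pytest.approx(0.3)
        assert occ[(0.5, 1.0)] == pytest.approx(0.6)

    def test_unordered_bins_rejected(self):
        rep = Repertoire.from_counts("s", [3, 2])
        with pytest.raises(ValueError):
            clonality.occupancy_profile(rep, (0, 0.5, 0.3, 1))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=500), min_size=1, max_size=60))
    def test_occupancy_and_proportions_sum_to_one(self, counts):
        rep = Repertoire.from_counts("s", counts)
        assert rep.proportions.sum() == pytest.approx(1.0, abs=1e-9)
        occ = clonality.occupancy_profile(rep)
        assert sum(occ.values()) == pytest.approx(1.0, abs=1e-9)


class TestClassifyClones:
    @pytest.mark.parametrize(
        "n,total,expect_class,expect_dominant",
        [
            (60, 4000, "expanded", True),   # p = 1.5% > 1%, n = 60 > 50
            (40, 1000, "expanded", False),  # p = 4% but n = 40 fails n > 50
            (51, 5200, "expanded", False),  # p = 0.98% fails p > 1%
            (1, 100, "singlet", False),
        ],
    )
    def test_dominance_rule(self, n, total, expect_class, expect_dominant):
        rest = total - n
        rep = Repertoire.from_counts("s", {"focal": n, **{f"bg{i}": 1 for i in range(rest)}})
        classes = {c.n_c: c for c in clonality.classify_clones(rep)}
        focal = classes[n] if n > 1 else next(iter(classes.values()))
        assert focal.clone_class == expect_class
        assert focal.dominant is expect_dominant

    def test_singlet_iff_count_one(self):
        rep = Repertoire.from_counts("s", [1, 2, 5, 1])
        for c in clonality.classify_clones(rep):
            assert (c.clone_class == "singlet") == (c.n_c == 1)

    def test_cell_class_table_covers_all_cells(self):
        rep = Repertoire.from_counts("s", [3, 2, 1])
        table = clonality.cell_class_table(rep)
        assert len(table) == rep.N
        assert set(table["clone_class"]) == {"singlet", "expanded"}
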