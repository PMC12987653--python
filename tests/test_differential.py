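"""DGE statistics, preranked GSEA, proportion comparisons, contrast assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_bh, brute_force_es
from clonomosaic import differential
from clonomosaic.differential import ContrastSpec
from clonomosaic.mosaicism import CellVariantCall


class TestNormalize:
    def test_hand_value(self):
        raw = pd.DataFrame([[10, 0]], index=["c1"], columns=["g1", "g2"])
        x = differential.normalize_counts(raw, scale=1e4)
        assert x.loc["c1", "g1"] == pytest.approx(np.log1p(1e4))
        assert x.loc["c1", "g2"] == 0.0

    def test_equal_cells_identical_rows(self):
        raw = pd.DataFrame([[5, 3, 2]] * 4, index=list("abcd"), columns=["g1", "g2", "g3"])
        x = differential.normalize_counts(raw)
        assert (x.nunique(axis=0) == 1).all()

    def test_zero_total_cell_excluded(self):
        raw = pd.DataFrame([[5, 3], [0, 0]], index=["a", "b"], columns=["g1", "g2"])
        x = differential.normalize_counts(raw)
        assert list(x.index) == ["a"]

    def test_all_zero_matrix_is_error(self):
        raw = pd.DataFrame([[0, 0]], index=["a"], columns=["g1", "g2"])
        with pytest.raises(ValueError):
            differential.normalize_counts(raw)


class TestDGE:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        vals = rng.poisson(3.0, size=(6, 20))
        raw = pd.DataFrame(np.vstack([vals, vals]),
                           index=[f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)],
                           columns=[f"g{i}" for i in range(20)])
        x = differential.normalize_counts(raw)
        spec = ContrastSpec(tuple(f"a{i}" for i in range(6)),
                            tuple(f"b{i}" for i in range(6)), "blood", "self")
        res = differential.dge(spec, x)
        assert np.allclose(res.table["lfc"], 0.0, atol=1e-12)
        assert (res.table["p"] > 0.9).all()

    def test_underpowered_contrast_rejected(self):
        raw = pd.DataFrame([[3, 1]] * 4, index=list("abcd"), columns=["g1", "g2"])
        x = differential.normalize_counts(raw)
        spec = ContrastSpec(("a", "b"), ("c", "d"), "blood", "tiny")
        with pytest.raises(ValueError, match="underpowered"):
            differential.dge(spec, x)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=100))
    def test_bh_matches_brute_force_stepup(self, pvals):
        got = differential.benjamini_hochberg(pvals)
        expected = brute_force_bh(pvals)
        assert np.allclose(got, expected, atol=1e-12, rtol=0)


class TestGSEA:
    def _random_ranking(self, rng, n):
        scores = rng.normal(size=n)
        return pd.Series(scores, index=[f"g{i}" for i in range(n)])

    def test_top_block_set_hand_fixture(self):
        ranking = pd.Series(np.arange(10, 0, -1, dtype=float), index=[f"g{i}" for i in range(10)])
        es, le = differential.enrichment_score(ranking, {"g0", "g1", "g2"})
        assert es == pytest.approx(brute_force_es(ranking, {"g0", "g1", "g2"}), abs=1e-12)
        assert es > 0 and set(le) == {"g0", "g1", "g2"}

    def test_set_of_all_genes_degenerate_zero(self):
        ranking = pd.Series([3.0, 2.0, 1.0], index=["a", "b", "c"])
        es, le = differential.enrichment_score(ranking, {"a", "b", "c"})
        assert es == 0.0 and le == ()

    @pytest.mark.parametrize("n,seed", [(5, 0), (10, 1), (15, 2), (20, 3), (20, 4)])
    def test_matches_running_sum_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        ranking = self._random_ranking(rng, n)
        for trial in range(20):
            k = int(rng.integers(1, n))
            members = set(rng.choice(ranking.index, size=k, replace=False))
            es, _ = differential.enrichment_score(ranking, members)
            assert es == pytest.approx(brute_force_es(ranking, members), abs=1e-12)

    def test_reversed_ranking_negates_es(self):
        # whenever the positive and negative extremes do not tie in
        # magnitude (the degenerate sign-ambiguous case), reversal negates
        # the ES exactly
        from conftest import es_extremes_tied

        rng = np.random.default_rng(5)
        ranking = self._random_ranking(rng, 50)
        n_checked = 0
        for trial in range(10):
            members = set(rng.choice(ranking.index, size=8, replace=False))
            if es_extremes_tied(ranking, members):
                continue
            es, _ = differential.enrichment_score(ranking, members)
            es_rev, _ = differential.enrichment_score(-ranking, members)
            assert es_rev == pytest.approx(-es, abs=1e-12)
            n_checked += 1
        assert n_checked >= 8

    def test_planted_set_detected_with_small_q(self):
        rng = np.random.default_rng(6)
        ranking = self._random_ranking(rng, 400).sort_values(ascending=False)
        planted = set(ranking.index[:15])
        null_sets = {
            f"N{i}": set(rng.choice(ranking.index, size=15, replace=False)) for i in range(8)
        }
        results = differential.gsea_preranked(
            ranking, {"planted": planted, **null_sets}, n_perm=500, seed=1
        )
        by_name = {r.set_name: r for r in results}
        assert by_name["planted"].es > 0.9
        assert by_name["planted"].p < 0.01
        assert by_name["planted"].fdr_q < 0.1

    def test_nominal_p_uniform_under_null(self):
        rng = np.random.default_rng(7)
        ranking = self._random_ranking(rng, 500)
        sets = {f"S{i}": set(rng.choice(ranking.index, size=20, replace=False)) for i in range(200)}
        results = differential.gsea_preranked(ranking, sets, n_perm=1000, seed=2)
        pvals = np.sort([r.p for r in results])
        ks = np.max(np.abs(pvals - (np.arange(1, len(pvals) + 1)) / len(pvals)))
        assert ks < 1.63 / np.sqrt(len(pvals))  # 1% KS critical value


class TestProportions:
    def _ann(self, spec):
        rows = []
        for (sample, group), type_counts in spec.items():
            for ct, n in type_counts.items():
                for i in range(n):
                    rows.append(
                        {
                            "cell_barcode": f"{sample}-{ct}-{i}",
                            "sample_id": sample,
                            "tissue": "blood",
                            "cell_type": ct,
                            "group": group,
                        }
                    )
        return pd.DataFrame(rows)

    def test_equal_proportions_zero_delta(self):
        ann = self._ann({("s1", "A"): {"x": 25, "y": 75}, ("r1", "R"): {"x": 25, "y": 75}})
        res = differential.proportion_forest(ann, reference_group="R")
        assert all(r.delta == pytest.approx(0.0, abs=1e-12) for r in res)

    def test_one_sided_quarter_proportion(self):
        ann = self._ann({("s1", "A"): {"x": 25, "y": 75}, ("r1", "R"): {"y": 100}})
        res = differential.proportion_forest(ann, reference_group="R")
        x = next(r for r in res if r.cell_type == "x")
        assert x.delta == pytest.approx(np.pi / 6, abs=1e-12)

    def test_ci_width_shrinks_as_inverse_sqrt_n(self):
        widths = []
        for n in (100, 10_000, 1_000_000):
            ann = self._ann({("s1", "A"): {"x": n // 4, "y": 3 * n // 4},
                             ("r1", "R"): {"x": n // 4, "y": 3 * n // 4}})
            res = differential.proportion_forest(ann, reference_group="R")
            x = next(r for r in res if r.cell_type == "x")
            widths.append(x.ci_high - x.ci_low)
        assert widths[0] / widths[1] == pytest.approx(10.0, rel=1e-6)
        assert widths[1] / widths[2] == pytest.approx(10.0, rel=1e-6)

    def test_antisymmetric_under_group_swap(self):
        ann = self._ann({("s1", "A"): {"x": 30, "y": 70}, ("r1", "R"): {"x": 10, "y": 90}})
        fwd = differential.proportion_forest(ann, reference_group="R")
        rev = differential.proportion_forest(ann, reference_group="A")
        fx = next(r for r in fwd if r.cell_type == "x")
        rx = next(r for r in rev if r.cell_type == "x")
        assert fx.delta == pytest.approx(-rx.delta, abs=1e-12)


class TestBuildContrasts:
    def _fixture(self):
        ann = pd.DataFrame(
            [
                {"cell_barcode": b, "sample_id": s, "tissue": t, "cell_type": "CD8 TEM", "group": g}
                for b, s, t, g in [
                    ("p1", "P_bl", "blood", "AGLCD"), ("p2", "P_bl", "blood", "AGLCD"),
                    ("p3", "P_bl", "blood", "AGLCD"), ("p4", "P_gut", "gut", "AGLCD"),
                    ("h1", "HD_bl", "blood", "HD"), ("h2", "HD_bl", "blood", "HD"),
                    ("cd1", "CD_gut", "gut", "CD"),
                ]
            ]
        )
        cell_classes = pd.DataFrame(
            {
                "cell_barcode": ["p1", "p2", "p3", "p4"],
                "clone_class": ["expanded", "expanded", "singlet", "expanded"],
                "dominant": [True, True, False, False],
            }
        )
        calls = [
            CellVariantCall("p1", "l", 0, 2, 0, "mutant"),
            CellVariantCall("p2", "l", 3, 0, 0, "wildtype_covered"),
            CellVariantCall("p3", "l", 1, 0, 0, "wildtype_covered"),
        ]
        return cell_classes, calls, ann

    def test_families_and_disjointness(self):
        cell_classes, calls, ann = self._fixture()
        specs = differential.build_contrasts(cell_classes, calls, ann)
        labels = {s.label for s in specs}
        assert "expanded_vs_HD_blood" in labels
        assert "mutant_vs_nonmutant_blood" in labels
        assert "mutant_vs_HD_blood" in labels
        for s in specs:
            assert not (set(s.group_a) & set(s.group_b))
        mvn = next(s for s in specs if s.label == "mutant_vs_nonmutant_blood")
        assert set(mvn.group_a) == {"p1"}
        assert set(mvn.group_b) == {"p2", "p3"}

    def test_cell_can_join_both_families(self):
        cell_classes, calls, ann = self._fixture()
        specs = differential.build_contrasts(cell_classes, calls, ann)
        exp = next(s for s in specs if s.label == "expanded_vs_HD_blood")
        mut = next(s for s in specs if s.label == "mutant_vs_HD_blood")
        assert "p1" in exp.group_a and "p1" in mut.group_a

    def test_empty_groups_skipped(self):
        cell_classes, calls, ann = self._fixture()
        specs = differential.build_contrasts(
            cell_classes, [], ann
        )  # no variant calls -> mutant contrasts skipped
        labels = {s.label for s in specs}
        assert labels == {"expanded_vs_HD_blood", "expanded_vs_CD_gut"}
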