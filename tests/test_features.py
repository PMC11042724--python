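import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pathpsn import features as fs
from pathpsn.io import PathwayRecord
from pathpsn.preprocess import OmicsMatrix


def make_ome(values, index=None, columns=None, kind="expression"):
    arr = np.asarray(values, dtype=float)
    index = index or [f"g{i}" for i in range(arr.shape[0])]
    columns = columns or [f"s{j}" for j in range(arr.shape[1])]
    return OmicsMatrix(pd.DataFrame(arr, index=index, columns=columns), kind)


def two_class_labels(n_case, n_control):
    idx = ([f"s{j}" for j in range(n_case + n_control)])
    return pd.Series(["case"] * n_case + ["control"] * n_control, index=idx)


class TestFoldChanges:
    def test_pure_mean_shift(self):
        # case mean 8, control mean 2, equal CVs -> elfc = 2, vlfc = 0
        ome = make_ome([[8, 8 + 8e-9, 8 - 8e-9, 2, 2 + 2e-9, 2 - 2e-9]])
        labels = two_class_labels(3, 3)
        t = fs.compute_fold_changes(ome, labels, epsilon=0.0)
        assert t["elfc"].iloc[0] == pytest.approx(2.0, abs=1e-6)
        assert t["vlfc"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_hand_computed_cv_case(self):
        # case {2,4,6}: mean 4, sd 2, CV 0.5; control {3,4,5}: CV 0.25
        ome = make_ome([[2, 4, 6, 3, 4, 5]])
        labels = two_class_labels(3, 3)
        t = fs.compute_fold_changes(ome, labels, epsilon=0.0)
        assert t["elfc"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert t["vlfc"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert t["stability"].iloc[0] == pytest.approx(-1.0, abs=1e-12)

    def test_identical_classes_all_zero(self):
        ome = make_ome([[1, 2, 3, 1, 2, 3], [5, 6, 7, 5, 6, 7]])
        labels = two_class_labels(3, 3)
        t = fs.compute_fold_changes(ome, labels)
        np.testing.assert_allclose(t["elfc"], 0.0, atol=1e-9)
        np.testing.assert_allclose(t["vlfc"], 0.0, atol=1e-9)

    def test_antisymmetric_under_class_swap(self):
        rng = np.random.default_rng(0)
        ome = make_ome(rng.lognormal(3, 1, size=(20, 12)))
        labels = two_class_labels(6, 6)
        fwd = fs.compute_fold_changes(ome, labels, case_class="case")
        rev = fs.compute_fold_changes(ome, labels, case_class="control")
        np.testing.assert_allclose(fwd["elfc"], -rev["elfc"], atol=1e-9)
        np.testing.assert_allclose(fwd["vlfc"], -rev["vlfc"], atol=1e-9)

    def test_single_sample_class_rejected(self):
        ome = make_ome([[1, 2, 3]])
        labels = pd.Series(["case", "control", "control"],
                           index=["s0", "s1", "s2"])
        with pytest.raises(ValueError, match="2 samples"):
            fs.compute_fold_changes(ome, labels)


class TestSelectMolecules:
    def _run(self, ome, labels, **kw):
        table = fs.compute_fold_changes(ome, labels)
        return fs.select_molecules(table, ome, labels, **kw)

    def test_null_data_type_i_error_controlled(self):
        fractions = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ome = make_ome(rng.lognormal(3, 0.5, size=(100, 20)))
            labels = two_class_labels(10, 10)
            out = self._run(ome, labels, alpha=0.05)
            fractions.append(out["selected"].mean())
        assert np.mean(fractions) <= 0.05 + 0.02

    def test_planted_effects_recovered(self):
        recalls = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 40
            base = rng.lognormal(3, 0.3, size=(60, 2 * n))
            # first 10 molecules: 4x mean, half the CV in cases
            base[:10, :n] = rng.normal(4 * 20, 0.2 * 4 * 20, size=(10, n))
            base[:10, n:] = rng.normal(20, 0.4 * 20, size=(10, n))
            ome = make_ome(np.abs(base))
            labels = two_class_labels(n, n)
            out = self._run(ome, labels, alpha=0.05)
            recalls.append(out["selected"].iloc[:10].mean())
        assert np.mean(recalls) >= 0.9

    def test_adjusted_p_not_below_raw(self):
        rng = np.random.default_rng(1)
        ome = make_ome(rng.lognormal(3, 0.5, size=(50, 12)))
        labels = two_class_labels(6, 6)
        out = self._run(ome, labels)
        assert (out["adjusted_p"] >= out["moderated_p"] - 1e-12).all()

    def test_large_elfc_without_significance_not_selected(self):
        rng = np.random.default_rng(2)
        values = rng.lognormal(3, 0.5, size=(40, 8))
        # huge fold change but huge within-class variance on one molecule
        values[0, :4] = [1, 4000, 1, 4000]
        values[0, 4:] = [10, 10.5, 9.5, 10]
        ome = make_ome(values)
        labels = two_class_labels(4, 4)
        out = self._run(ome, labels, alpha=0.05)
        row = out.iloc[0]
        if row["adjusted_p"] > 0.05:
            assert not row["selected"]

    def test_top_n_truncates_by_rank_product(self):
        rng = np.random.default_rng(3)
        n = 30
        values = rng.lognormal(3, 0.1, size=(20, 2 * n))
        values[:5, :n] *= 8.0  # strong, clean effects
        ome = make_ome(values)
        labels = two_class_labels(n, n)
        out = self._run(ome, labels, alpha=0.05, top_n=3)
        assert out["selected"].sum() <= 3

    def test_alpha_out_of_range_rejected(self):
        ome = make_ome([[1, 2, 3, 4]])
        labels = two_class_labels(2, 2)
        table = fs.compute_fold_changes(ome, labels)
        with pytest.raises(ValueError, match="alpha"):
            fs.select_molecules(table, ome, labels, alpha=1.5)


class TestNcrnaLink:
    def _setup(self, seed, anti=True, n=40, n_targets=8):
        rng = np.random.default_rng(seed)
        x = pd.Series(rng.normal(0, 1, n), index=[f"s{j}" for j in range(n)])
        if anti:
            targets = np.array([-x.to_numpy() + rng.normal(0, 0.05, n)
                                for _ in range(n_targets)])
        else:
            targets = rng.normal(0, 1, size=(n_targets, n))
        background = rng.normal(0, 1, size=(50, n))
        tm = make_ome(targets - targets.min() + 1.0,
                      index=[f"t{i}" for i in range(n_targets)],
                      columns=list(x.index))
        bm = make_ome(background - background.min() + 1.0,
                      index=[f"b{i}" for i in range(50)],
                      columns=list(x.index))
        return x - x.min() + 1.0, tm, bm

    def test_perfect_anticorrelation_kept(self):
        x, tm, bm = self._setup(0, anti=True)
        keep, p, _ = fs.test_ncrna_target_link(x, tm, bm, alpha=0.05)
        assert keep and p < 0.01

    def test_null_false_positive_rate(self):
        hits = 0
        for seed in range(100):
            x, tm, bm = self._setup(seed, anti=False)
            keep, _, _ = fs.test_ncrna_target_link(x, tm, bm, alpha=0.05)
            hits += keep
        assert hits <= 7

    def test_positive_correlation_rejected_by_sign_gate(self):
        rng = np.random.default_rng(5)
        n = 40
        x = pd.Series(rng.normal(0, 1, n), index=[f"s{j}" for j in range(n)])
        targets = np.array([x.to_numpy() + rng.normal(0, 0.05, n)
                            for _ in range(8)])
        tm = make_ome(targets - targets.min() + 1.0,
                      index=[f"t{i}" for i in range(8)], columns=list(x.index))
        background = rng.normal(0, 1, size=(50, n))
        bm = make_ome(background - background.min() + 1.0,
                      index=[f"b{i}" for i in range(50)],
                      columns=list(x.index))
        keep, _, _ = fs.test_ncrna_target_link(x - x.min() + 1.0, tm, bm)
        assert not keep

    def test_too_few_targets_reports_reason(self):
        x, tm, bm = self._setup(0, anti=True, n_targets=3)
        keep, p, reason = fs.test_ncrna_target_link(x, tm, bm)
        assert not keep and reason == "insufficient targets"


class TestOra:
    def test_closed_form_full_overlap(self):
        # universe 20, pathway 5, selected 5, overlap 5:
        # p = C(5,5) C(15,0) / C(20,5) = 1 / 15504
        universe = {f"g{i}" for i in range(20)}
        pathway = PathwayRecord("P", "P", "t", frozenset(f"g{i}" for i in range(5)))
        selected = {f"g{i}" for i in range(5)}
        out = fs.enrich_pathways(selected, universe, [pathway], alpha=0.05)
        assert len(out) == 1
        assert out[0].ora_p == pytest.approx(1 / 15504, rel=1e-9)

    def test_zero_overlap_p_is_one_and_dropped(self):
        universe = {f"g{i}" for i in range(20)}
        pathway = PathwayRecord("P", "P", "t", frozenset(f"g{i}" for i in range(5)))
        selected = {f"g{i}" for i in range(15, 20)}
        out = fs.enrich_pathways(selected, universe, [pathway], alpha=0.05)
        assert out == []

    def test_matches_exhaustive_enumeration(self):
        # brute-force oracle: enumerate all C(20,5) selected sets and count
        # those with overlap >= observed
        universe = [f"g{i}" for i in range(20)]
        members = set(universe[:6])
        selected = set(universe[:3]) | set(universe[10:12])  # overlap 3
        observed = len(members & selected)
        count = 0
        total = 0
        for combo in itertools.combinations(universe, len(selected)):
            total += 1
            if len(members & set(combo)) >= observed:
                count += 1
        oracle_p = count / total
        pathway = PathwayRecord("P", "P", "t", frozenset(members))
        out = fs.enrich_pathways(selected, set(universe), [pathway],
                                 alpha=1.0 - 1e-12, min_overlap=1)
        assert len(out) == 1
        assert out[0].ora_p == pytest.approx(oracle_p, rel=1e-9)

    def test_selected_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            fs.enrich_pathways({"x"}, {"a", "b"}, [], alpha=0.05)

    def test_empty_selected_warns_empty_result(self, caplog):
        with caplog.at_level("WARNING", logger="pathpsn.features"):
            out = fs.enrich_pathways(set(), {"a", "b"}, [], alpha=0.05)
        assert out == []


def _enriched(members):
    rec = PathwayRecord("P", "P", "t", frozenset(members))
    return fs.EnrichedPathway(pathway=rec, significant_members=frozenset(members),
                              ora_p=0.01, ora_adjusted_p=0.01)


def _stats(rows):
    df = pd.DataFrame(rows, columns=["elfc", "stability"])
    df.index = [f"m{i}" for i in range(len(rows))]
    df["vlfc"] = -df["stability"]
    return df


class TestCategorize:
    @pytest.mark.parametrize("elfc,stab,expected", [
        (1.0, 1.0, "activated_case"),
        (-1.0, -1.0, "activated_control"),
        (-1.0, 1.0, "inhibited_case"),
        (1.0, -1.0, "inhibited_control"),
    ])
    def test_pure_quadrants(self, elfc, stab, expected):
        stats = _stats([[elfc, stab]] * 4)
        ep = _enriched(stats.index)
        assert fs.categorize_pathway(ep, stats) == expected

    def test_plurality_wins(self):
        stats = _stats([[1, 1], [1, 1], [1, 1], [-1, -1], [-1, -1]])
        ep = _enriched(stats.index)
        assert fs.categorize_pathway(ep, stats) == "activated_case"

    def test_tie_broken_by_mean_abs_elfc(self):
        stats = _stats([[0.5, 1], [0.5, 1], [-3, -1], [-3, -1]])
        ep = _enriched(stats.index)
        assert fs.categorize_pathway(ep, stats) == "activated_control"

    def test_zero_zero_members_abstain(self):
        stats = _stats([[0, 0], [0, 0], [-1, 1]])
        ep = _enriched(stats.index)
        assert fs.categorize_pathway(ep, stats) == "inhibited_case"

    def test_class_swap_maps_categories(self):
        rng = np.random.default_rng(0)
        rows = rng.normal(0, 1, size=(9, 2))
        stats = _stats(rows.tolist())
        ep = _enriched(stats.index)
        fwd = fs.categorize_pathway(ep, stats)
        swapped = stats.copy()
        swapped["elfc"] *= -1
        swapped["stability"] *= -1
        swapped["vlfc"] *= -1
        rev = fs.categorize_pathway(ep, swapped)
        mapping = {"activated_case": "activated_control",
                   "activated_control": "activated_case",
                   "inhibited_case": "inhibited_control",
                   "inhibited_control": "inhibited_case"}
        assert rev == mapping[fwd]


class TestFlagMutated:
    def test_empty_mutated_set_all_false(self):
        eps = [_enriched(["m0", "m1", "m2"])]
        out = fs.flag_mutated_pathways(eps, set())
        assert [e.contains_mutated_gene for e in out] == [False]

    def test_single_hit_flags_exactly_one(self):
        a = _enriched(["m0", "m1", "m2"])
        b = fs.EnrichedPathway(
            pathway=PathwayRecord("Q", "Q", "t", frozenset(["x1", "x2"])),
            significant_members=frozenset(["x1"]), ora_p=0.01,
            ora_adjusted_p=0.01)
        out = fs.flag_mutated_pathways([a, b], {"m1"})
        assert [e.contains_mutated_gene for e in out] == [True, False]
        out_rev = fs.flag_mutated_pathways([b, a], {"m1"})
        assert [e.contains_mutated_gene for e in out_rev] == [False, True]
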