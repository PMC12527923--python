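"""Missingness filters, detection-limit exclusion, imputation, test splits."""

import numpy as np
import pandas as pd
import pytest

from timbertrace import (
    ElementTable,
    GeneticMatrix,
    IsotopeTable,
    ValidationError,
    eligible_trees,
    filter_elements_by_detection,
    filter_genetic_matrix,
    impute_isotopes_site_mean,
    impute_snps_site_mode,
    select_test_set,
)

from conftest import fast_config, toy_dataset
from timbertrace import generate_dataset

M = -1  # missing call


def matrix(rows, trees=None, loci=None):
    arr = np.array(rows, dtype=np.int8)
    trees = trees or [f"t{i}" for i in range(arr.shape[0])]
    loci = loci or [f"L{j}" for j in range(arr.shape[1])]
    return GeneticMatrix(trees, loci, arr)


class TestGeneticFilter:
    def test_hand_counted_fixture_individuals_then_loci(self):
        # t3 has 3/4 missing -> removed; then L3 is missing in 2/3 of the
        # remaining trees (66% > 25%) -> removed; result is 3 x 3
        m = matrix(
            [
                [0, 1, 0, M],
                [1, 1, 0, 0],
                [0, 0, 1, M],
                [M, M, M, 0],
            ]
        )
        out, report = filter_genetic_matrix(m)
        assert report.removed_trees == ["t3"]
        assert report.removed_loci == ["L3"]
        assert out.shape == (3, 3)
        assert out.trees == ["t0", "t1", "t2"]

    def test_clean_matrix_unchanged(self):
        m = matrix([[0, 1], [1, 0]])
        out, report = filter_genetic_matrix(m)
        assert out == m
        assert not report.removed_trees and not report.removed_loci

    def test_exactly_half_missing_individual_is_retained(self):
        m = matrix([[0, 1, M, M], [0, 1, 0, 1], [1, 0, 1, 0]])
        out, _ = filter_genetic_matrix(m)
        assert "t0" in out.trees  # 50% is not > 50%

    def test_filter_is_idempotent(self):
        rng = np.random.default_rng(3)
        arr = rng.integers(0, 2, (12, 30)).astype(np.int8)
        arr[rng.uniform(size=arr.shape) < 0.3] = M
        m = matrix(arr.tolist())
        once, _ = filter_genetic_matrix(m)
        twice, rep = filter_genetic_matrix(once)
        assert twice == once
        assert not rep.removed_trees and not rep.removed_loci

    def test_everything_removed_raises(self):
        m = matrix([[M, M], [M, M]])
        with pytest.raises(ValidationError, match="survive"):
            filter_genetic_matrix(m)


class TestElementFilter:
    def _table(self, counts, n_samples=234):
        data = {}
        flags = {}
        for name, k in counts.items():
            vals = np.full(n_samples, 1.0)
            flag = np.zeros(n_samples, dtype=bool)
            flag[:k] = True
            data[name] = vals
            flags[name] = flag
        idx = [f"t{i}" for i in range(n_samples)]
        limits = pd.Series(0.2, index=list(counts))
        return ElementTable(pd.DataFrame(data, index=idx),
                            pd.DataFrame(flags, index=idx), limits)

    def test_more_than_100_below_detection_dropped(self):
        t = self._table({"A": 101, "B": 100})
        out, report = filter_elements_by_detection(t)
        assert report.removed_elements == ["A"]
        assert out.elements == ["B"]  # 100 is not > 100

    def test_fixture_counts_0_50_150_keeps_two(self):
        t = self._table({"A": 0, "B": 50, "C": 150})
        out, _ = filter_elements_by_detection(t, max_below_detection=100)
        assert out.elements == ["A", "B"]

    def test_clean_element_kept_unchanged(self):
        t = self._table({"A": 0})
        out, _ = filter_elements_by_detection(t)
        assert (out.data["A"] == 1.0).all()

    def test_below_detection_cells_substituted_at_half_limit(self):
        t = self._table({"A": 5})
        out, _ = filter_elements_by_detection(t)
        assert (out.data["A"].iloc[:5] == 0.1).all()  # DL/2 = 0.2/2
        assert (out.data["A"].iloc[5:] == 1.0).all()

    def test_filter_is_idempotent(self):
        t = self._table({"A": 40, "B": 120})
        once, _ = filter_elements_by_detection(t)
        twice, rep = filter_elements_by_detection(once)
        pd.testing.assert_frame_equal(once.data, twice.data)
        assert not rep.removed_elements


class TestSnpImputation:
    def test_site_mode_fills_missing(self):
        m = matrix([[0], [0], [1], [M]])
        sites = pd.Series(["A", "A", "A", "A"], index=m.trees)
        out = impute_snps_site_mode(m, sites)
        assert out.calls[3, 0] == 0  # mode of [0, 0, 1]

    def test_no_missing_is_identity(self):
        m = matrix([[0, 1], [1, 0]])
        sites = pd.Series(["A", "B"], index=m.trees)
        out = impute_snps_site_mode(m, sites)
        assert out == m

    def test_tie_breaks_to_lowest_allele_code(self):
        m = matrix([[0], [1], [M]])
        sites = pd.Series(["A", "A", "A"], index=m.trees)
        out = impute_snps_site_mode(m, sites)
        assert out.calls[2, 0] == 0

    def test_observed_calls_never_modified(self):
        rng = np.random.default_rng(5)
        arr = rng.integers(0, 2, (20, 15)).astype(np.int8)
        mask = rng.uniform(size=arr.shape) < 0.2
        arr2 = arr.copy()
        arr2[mask] = M
        m = matrix(arr2.tolist())
        sites = pd.Series(rng.choice(["A", "B"], 20), index=m.trees)
        out = impute_snps_site_mode(m, sites)
        assert (out.calls != M).all()
        assert np.array_equal(out.calls[~mask], arr2[~mask])

    def test_global_mode_fallback_when_site_unobserved(self):
        m = matrix([[1], [1], [M]])
        sites = pd.Series(["A", "A", "B"], index=m.trees)
        out = impute_snps_site_mode(m, sites)
        assert out.calls[2, 0] == 1

    def test_locus_missing_everywhere_raises(self):
        m = matrix([[M], [M]])
        sites = pd.Series(["A", "A"], index=m.trees)
        with pytest.raises(ValidationError, match="entirely missing"):
            impute_snps_site_mode(m, sites)


class TestIsotopeImputation:
    def _table(self, d18O, index):
        df = pd.DataFrame({"d18O": d18O, "d2H": 10.0, "d34S": 7.0}, index=index)
        return IsotopeTable(df)

    def test_missing_cell_gets_site_mean(self):
        t = self._table([26.0, 28.0, np.nan], ["a", "b", "c"])
        sites = pd.Series(["S", "S", "S"], index=["a", "b", "c"])
        out, flags = impute_isotopes_site_mean(t, sites)
        assert out.data.loc["c", "d18O"] == pytest.approx(27.0)
        assert flags.loc["c", "d18O"] and not flags.loc["a", "d18O"]

    def test_fully_measured_is_identity(self):
        t = self._table([26.0, 28.0], ["a", "b"])
        sites = pd.Series(["S", "S"], index=["a", "b"])
        out, flags = impute_isotopes_site_mean(t, sites)
        pd.testing.assert_frame_equal(out.data, t.data)
        assert not flags.any().any()

    def test_means_from_excludes_test_trees(self):
        # imputed value must not depend on the excluded tree's measurement
        t1 = self._table([26.0, 28.0, 99.0, np.nan], ["a", "b", "test", "c"])
        t2 = self._table([26.0, 28.0, -50.0, np.nan], ["a", "b", "test", "c"])
        sites = pd.Series(["S"] * 4, index=["a", "b", "test", "c"])
        out1, _ = impute_isotopes_site_mean(t1, sites, means_from=["a", "b"])
        out2, _ = impute_isotopes_site_mean(t2, sites, means_from=["a", "b"])
        assert out1.data.loc["c", "d18O"] == out2.data.loc["c", "d18O"] == pytest.approx(27.0)

    def test_isotope_without_any_measurement_raises(self):
        df = pd.DataFrame({"d18O": [np.nan], "d2H": [1.0], "d34S": [1.0]}, index=["a"])
        with pytest.raises(ValidationError, match="d18O"):
            impute_isotopes_site_mean(IsotopeTable(df), pd.Series(["S"], index=["a"]))


class TestTestSetSelection:
    @pytest.mark.parametrize("n_eligible, expected", [(10, 5), (7, 3)])
    def test_floor_of_fraction_times_pool(self, n_eligible, expected):
        d = toy_dataset(n_sites=2, trees_per_site=n_eligible // 2 + n_eligible % 2)
        # trim to exactly n_eligible trees
        keep = list(d.trees.index)[:n_eligible]
        d.trees = d.trees.loc[keep]
        d.genetics = d.genetics.subset(trees=keep)
        d.isotopes.data = d.isotopes.data.loc[keep]
        d.elements.data = d.elements.data.loc[keep]
        split = select_test_set(d, fraction=0.5, repeat_index=0, seed=1)
        assert len(split.test_ids) == expected

    def test_fifty_percent_of_83_gives_41(self):
        from timbertrace import GeneratorConfig

        d = generate_dataset(GeneratorConfig(seed=21))
        pool = eligible_trees(d)
        assert len(pool) >= 83  # the study design yields a pool of this order
        # shrink the pool to exactly 83 by dropping element completeness
        d.elements.data.loc[pool[83:]] = np.nan
        assert len(eligible_trees(d)) == 83
        split = select_test_set(d, fraction=0.5, repeat_index=0, seed=1)
        assert len(split.test_ids) == 41

    def test_partition_and_train_site_coverage(self, small_dataset):
        split = select_test_set(small_dataset, repeat_index=2, seed=9)
        assert set(split.test_ids) | set(split.train_ids) == set(small_dataset.trees.index)
        assert not set(split.test_ids) & set(split.train_ids)
        train_sites = set(small_dataset.trees.loc[list(split.train_ids), "site_id"])
        assert train_sites == set(small_dataset.sites.index)

    def test_stratification_covers_every_site_with_eligible_trees(self, small_dataset):
        split = select_test_set(small_dataset, repeat_index=0, seed=4)
        pool_sites = set(small_dataset.trees.loc[eligible_trees(small_dataset), "site_id"])
        test_sites = set(small_dataset.trees.loc[list(split.test_ids), "site_id"])
        assert test_sites == pool_sites

    def test_reproducible_and_repeat_dependent(self, small_dataset):
        a = select_test_set(small_dataset, repeat_index=1, seed=5)
        b = select_test_set(small_dataset, repeat_index=1, seed=5)
        c = select_test_set(small_dataset, repeat_index=2, seed=5)
        assert a.test_ids == b.test_ids
        assert a.test_ids != c.test_ids
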