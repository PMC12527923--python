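"""Statistical structure and determinism of the synthetic-data generator."""

import numpy as np
import pandas as pd
import pytest

from timbertrace import GeneratorConfig, generate_dataset, haversine_km
from timbertrace.ordination import psa_distance_matrix
from timbertrace.simulate import (
    ConfigurationError,
    apply_missingness,
    assign_clusters,
    generate_elements,
    generate_genetics,
    generate_isotopes,
    generate_sites,
)

from conftest import fast_config, null_config


class TestSites:
    def test_minimum_pairwise_separation_enforced(self):
        cfg = fast_config(n_sites=5, min_site_separation_km=15.0, extent_km=200.0)
        sites, _ = generate_sites(cfg)
        ids = list(sites.index)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                d = haversine_km(sites.loc[a, "lat"], sites.loc[a, "lon"],
                                 sites.loc[b, "lat"], sites.loc[b, "lon"])
                assert d >= 15.0 - 0.5  # centroid jitter from tree scatter

    def test_single_site_has_no_pairwise_constraint(self):
        sites, trees = generate_sites(fast_config(n_sites=1, n_genetic_clusters=1))
        assert len(sites) == 1
        assert (trees["site_id"] == sites.index[0]).all()

    def test_same_seed_reproduces_site_table(self):
        s1, t1 = generate_sites(fast_config(seed=3))
        s2, t2 = generate_sites(fast_config(seed=3))
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_impossible_packing_raises_configuration_error(self):
        cfg = fast_config(n_sites=40, extent_km=20.0, min_site_separation_km=15.0)
        with pytest.raises(ConfigurationError):
            generate_sites(cfg)

    def test_trees_scattered_within_5km_of_centroid(self):
        sites, trees = generate_sites(fast_config())
        for sid, grp in trees.groupby("site_id"):
            for _, row in grp.iterrows():
                d = haversine_km(row["lat"], row["lon"],
                                 sites.loc[sid, "lat"], sites.loc[sid, "lon"])
                assert d <= 5.0 + 5.0  # radius + centroid offset


class TestGenetics:
    def test_forced_divergence_gives_psa_distance_one_between_clusters(self):
        cfg = fast_config(n_sites=4, n_genetic_clusters=2, cluster_divergence=1.0,
                          snp_missing_rate=0.0)
        sites, trees = generate_sites(cfg)
        m = generate_genetics(sites, trees, cfg)
        clusters = assign_clusters(sites, 2)
        tree_cluster = trees["site_id"].map(clusters)
        d = psa_distance_matrix(m).to_frame()
        for a in trees.index[:6]:
            for b in trees.index[-6:]:
                if tree_cluster[a] != tree_cluster[b]:
                    assert d.loc[a, b] == pytest.approx(1.0)

    def test_no_structure_when_divergence_zero_and_ibd_flat(self):
        # expected between-site distance equals within-site distance
        cfg = null_config(n_sites=6, n_trees_per_site=(12, 12), n_loci=200,
                          snp_missing_rate=0.0, seed=11)
        sites, trees = generate_sites(cfg)
        m = generate_genetics(sites, trees, cfg)
        d = psa_distance_matrix(m).to_frame()
        same = trees["site_id"]
        within, between = [], []
        ids = list(trees.index)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                (within if same[a] == same[b] else between).append(d.loc[a, b])
        assert np.mean(between) == pytest.approx(np.mean(within), rel=0.03)

    def test_default_clusters_separate_in_psa_distance(self):
        # between-cluster 1-PSA exceeds within-cluster, averaged over seeds
        margins = []
        for seed in range(10):
            cfg = fast_config(seed=seed, snp_missing_rate=0.0)
            sites, trees = generate_sites(cfg)
            m = generate_genetics(sites, trees, cfg)
            clusters = assign_clusters(sites, cfg.n_genetic_clusters)
            tc = trees["site_id"].map(clusters).to_numpy()
            d = psa_distance_matrix(m).values
            iu = np.triu_indices(len(tc), k=1)
            same = tc[iu[0]] == tc[iu[1]]
            margins.append(d[iu][~same].mean() - d[iu][same].mean())
        assert np.mean(margins) > 0
        assert np.mean(margins) > 2 * np.std(margins) / np.sqrt(len(margins))


class TestIsotopes:
    def test_within_site_sd_comparable_to_sd_of_site_means(self):
        cfg = GeneratorConfig(seed=5)
        sites, trees = generate_sites(cfg)
        iso = generate_isotopes(sites, trees, cfg)
        labels = trees["site_id"]
        for col in iso.data.columns:
            site_means = iso.data[col].groupby(labels).mean()
            within = iso.data[col].groupby(labels).std(ddof=1).mean()
            ratio = within / site_means.std(ddof=1)
            assert 0.5 <= ratio <= 2.0, col

    def test_zero_within_sd_collapses_trees_to_site_mean(self):
        cfg = fast_config(isotope_within_sd={"d18O": 0.0, "d2H": 0.0, "d34S": 0.0})
        sites, trees = generate_sites(cfg)
        iso = generate_isotopes(sites, trees, cfg)
        spread = iso.data.groupby(trees["site_id"]).std(ddof=0)
        assert (spread.to_numpy() < 1e-9).all()

    def test_pooled_values_comparable_to_configured_range(self):
        cfg = GeneratorConfig(seed=2)
        sites, trees = generate_sites(cfg)
        iso = generate_isotopes(sites, trees, cfg)
        for col, (lo, hi) in cfg.isotope_ranges.items():
            width = hi - lo
            vals = iso.data[col]
            assert vals.between(lo - width, hi + width).all()
            assert lo <= vals.median() <= hi


class TestElements:
    def test_concentrations_positive_and_finite_for_any_seed(self):
        for seed in (0, 1, 99):
            cfg = fast_config(seed=seed)
            sites, trees = generate_sites(cfg)
            el = generate_elements(sites, trees, cfg)
            vals = el.data.to_numpy()
            assert np.isfinite(vals).all()
            assert (vals > 0).all()

    def test_default_span_covers_configured_concentration_range(self):
        cfg = GeneratorConfig(seed=4)
        sites, trees = generate_sites(cfg)
        el = generate_elements(sites, trees, cfg)
        medians = el.data.median()
        assert medians.max() > 1.0  # potassium-like
        assert medians.min() < 0.01  # ytterbium-like
        assert list(el.data.columns[:1]) == ["K"]
        assert "Yb" in el.data.columns

    def test_discriminant_elements_carry_the_site_signal(self):
        cfg = fast_config(n_elements=41, n_discriminant_elements=5, element_site_sigma=2.0)
        sites, trees = generate_sites(cfg)
        el = generate_elements(sites, trees, cfg)
        logged = np.log(el.data)
        f_ratios = {}
        labels = trees["site_id"]
        for col in logged.columns:
            gm = logged[col].groupby(labels)
            f_ratios[col] = gm.mean().var(ddof=1) / gm.var(ddof=1).mean()
        ranked = sorted(f_ratios, key=f_ratios.get, reverse=True)
        # the configured discriminant trace elements dominate the site signal
        assert len(set(ranked[:5]) & {"W", "Ba", "Mo", "K", "Cr"}) >= 4


class TestMissingness:
    def test_zero_rates_leave_dataset_unchanged(self):
        cfg = fast_config(snp_missing_rate=0.0,
                          isotope_trees_per_site={})
        d = generate_dataset(cfg)
        assert not d.genetics.missing_mask.any()
        assert d.isotopes.data.notna().all().all()

    def test_per_site_measured_isotope_counts_within_configured_range(self):
        d = generate_dataset(GeneratorConfig(seed=3))
        counts = d.isotopes.measured.groupby(d.trees["site_id"]).sum()
        assert counts["d18O"].between(6, 10).all()
        assert counts["d2H"].between(2, 10).all()
        assert counts["d34S"].between(2, 4).all()

    def test_d34S_trees_nested_in_d2H_trees(self):
        d = generate_dataset(GeneratorConfig(seed=3))
        m = d.isotopes.measured
        assert not (m["d34S"] & ~m["d2H"]).any()
        assert not (m["d2H"] & ~m["d18O"]).any()

    def test_mask_reproducible_from_seed(self):
        d1 = generate_dataset(fast_config(seed=9, snp_missing_rate=0.1))
        d2 = generate_dataset(fast_config(seed=9, snp_missing_rate=0.1))
        assert np.array_equal(d1.genetics.calls, d2.genetics.calls)

    def test_excessive_missingness_raises(self):
        cfg = fast_config(snp_missing_rate=0.0, element_missing_rate=0.999)
        with pytest.raises(ConfigurationError, match="zero complete trees"):
            generate_dataset(cfg)


class TestComposition:
    def test_default_dataset_matches_study_shape(self):
        d = generate_dataset(GeneratorConfig(seed=1))
        assert d.n_sites == 13
        assert 195 <= len(d.trees) <= 260
        assert len(d.genetics.loci) == 238
        assert list(d.isotopes.data.columns) == ["d18O", "d2H", "d34S"]
        assert len(d.elements.elements) == 41

    def test_same_seed_bit_identical_different_seed_differs(self):
        a = generate_dataset(fast_config(seed=5))
        b = generate_dataset(fast_config(seed=5))
        c = generate_dataset(fast_config(seed=6))
        assert np.array_equal(a.genetics.calls, b.genetics.calls)
        pd.testing.assert_frame_equal(a.isotopes.data, b.isotopes.data)
        pd.testing.assert_frame_equal(a.elements.data, b.elements.data)
        assert not np.array_equal(a.genetics.calls, c.genetics.calls)

    def test_provenance_records_seed_and_config(self):
        d = generate_dataset(fast_config(seed=42))
        assert d.provenance["seed"] == 42
        assert d.provenance["config"]["n_sites"] == 6
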