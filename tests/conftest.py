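import numpy as np
import pandas as pd
import pytest

from timbertrace import (
    ElementTable,
    GeneticMatrix,
    IsotopeTable,
    TraceDataset,
    generate_dataset,
)
from timbertrace.simulate import GeneratorConfig


def fast_config(seed: int = 7, **overrides) -> GeneratorConfig:
    """A small but structurally faithful study design for unit tests."""
    base = dict(
        n_sites=6,
        n_trees_per_site=(8, 10),
        extent_km=600.0,
        n_loci=60,
        n_genetic_clusters=3,
        n_elements=12,
        n_discriminant_elements=3,
        isotope_trees_per_site={"d18O": (5, 7), "d2H": (4, 6), "d34S": (2, 3)},
        seed=seed,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def null_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """No signal in any proxy: flat fields, zero divergence, no discriminant
    elements, and no missingness (site-mean isotope imputation would otherwise
    leak site identity into otherwise signal-free features). Downstream
    accuracy should be at chance."""
    base = dict(
        cluster_divergence=0.0,
        ibd_sigma=0.0,
        isotope_gradient_fraction=0.0,
        isotope_within_sd={"d18O": 1.0, "d2H": 5.0, "d34S": 1.0},
        n_discriminant_elements=0,
        snp_missing_rate=0.0,
        isotope_trees_per_site={},
        seed=seed,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_dataset() -> TraceDataset:
    return generate_dataset(fast_config())


@pytest.fixture(scope="session")
def small_preprocessed(small_dataset):
    from timbertrace import preprocess_dataset

    d, _ = preprocess_dataset(small_dataset)
    return d


def toy_dataset(n_sites=2, trees_per_site=4, n_loci=6, seed=0) -> TraceDataset:
    """A tiny fully deterministic dataset built by hand (no generator)."""
    rng = np.random.default_rng(seed)
    site_rows, tree_rows = [], []
    for s in range(n_sites):
        site_id = f"S{s + 1}"
        lat, lon = 1.0 + s, 10.0 + s
        site_rows.append({"site_id": site_id, "country": "XX", "lat": lat, "lon": lon,
                          "n_trees": trees_per_site})
        for k in range(trees_per_site):
            tree_rows.append({"tree_id": f"{site_id}_T{k + 1}", "site_id": site_id,
                              "lat": lat, "lon": lon, "dbh_cm": 50.0})
    sites = pd.DataFrame(site_rows).set_index("site_id")
    trees = pd.DataFrame(tree_rows).set_index("tree_id")
    calls = rng.integers(0, 2, size=(len(trees), n_loci)).astype(np.int8)
    gen = GeneticMatrix(list(trees.index), [f"L{j}" for j in range(n_loci)], calls)
    iso = IsotopeTable(pd.DataFrame(
        {
            "d18O": rng.normal(27, 1, len(trees)),
            "d2H": rng.normal(10, 5, len(trees)),
            "d34S": rng.normal(7, 1, len(trees)),
        },
        index=trees.index,
    ))
    el = ElementTable(pd.DataFrame(
        rng.lognormal(0, 0.3, size=(len(trees), 3)),
        index=trees.index,
        columns=["K", "Ba", "W"],
    ))
    return TraceDataset(sites=sites, trees=trees, genetics=gen, isotopes=iso, elements=el)
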