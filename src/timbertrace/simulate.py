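"""Synthetic multi-proxy tracing datasets.

The generator emulates the statistical structure of a Central-African timber
reference collection: ~13 logging sites 15 to >1000 km apart, 15-20 trees per
site, a haploid plastid SNP matrix whose sites fall into a few spatially
contiguous genetic clusters with isolation-by-distance inside each cluster,
three stable isotopes whose within-site spread is comparable to the spread of
site means (weak site signal), and a multi-element profile in which a handful
of trace elements carry a fine-scale, site-specific soil signal that is
deliberately uncorrelated with the genetic clusters. Per-method missingness
mimics the unequal sampling effort of the three laboratory methods.

Randomness is driven by a single seed fanned out into named substreams, so
each proxy can be regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datamodel import (
    ISOTOPES,
    MISSING,
    ElementTable,
    GeneticMatrix,
    IsotopeTable,
    TraceDataset,
    haversine_km,
    site_centroid,
)

__all__ = [
    "GeneratorConfig",
    "ConfigurationError",
    "generate_sites",
    "generate_genetics",
    "generate_isotopes",
    "generate_elements",
    "apply_missingness",
    "generate_dataset",
]


class ConfigurationError(ValueError):
    """Generator configuration cannot produce a valid dataset."""


# 41 elements reported for dense hardwood, ordered by typical abundance so the
# log-spaced concentration ladder puts K at ~4 g/kg and Yb at ~0.001 g/kg.
ELEMENTS_BY_ABUNDANCE: tuple[str, ...] = (
    "K", "Ca", "Mg", "Na", "Mn", "Al", "Fe", "Si", "P", "Sr",
    "Ba", "Zn", "Rb", "Ti", "Cu", "Ni", "Cr", "Pb", "Zr", "Co",
    "Sn", "La", "Ce", "Y", "Cs", "Ga", "As", "Mo", "W", "Nd",
    "Cd", "Li", "Pr", "Sm", "Gd", "Bi", "Dy", "Eu", "Er", "Tb",
    "Yb",
)

DEFAULT_DISCRIMINANT_ELEMENTS: tuple[str, ...] = ("W", "Ba", "Mo", "K", "Cr")

#: per mil ranges observed across trees, used to scale the synthetic fields
DEFAULT_ISOTOPE_RANGES: dict[str, tuple[float, float]] = {
    "d18O": (24.7, 30.4),
    "d2H": (-9.5, 36.55),
    "d34S": (4.6, 10.9),
}

#: measured trees per site per isotope (lo, hi), mirroring unequal lab effort
DEFAULT_ISOTOPE_TREES_PER_SITE: dict[str, tuple[int, int]] = {
    "d18O": (6, 10),
    "d2H": (4, 10),
    "d34S": (2, 4),
}

_SUBSTREAMS = {"sites": 0, "genetics": 1, "isotopes": 2, "elements": 3, "missingness": 4}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study design; defaults emulate the field campaign."""

    n_sites: int = 13
    n_trees_per_site: tuple[int, int] = (15, 20)
    extent_km: float = 1100.0
    min_site_separation_km: float = 15.0
    tree_scatter_km: float = 5.0
    center_lat: float = 1.0
    center_lon: float = 12.0

    # genetics
    n_loci: int = 238
    n_genetic_clusters: int = 3
    cluster_divergence: float = 0.30  # Balding-Nichols-style F between clusters
    ibd_scale_km: float = 300.0  # e-folding distance of within-cluster structure
    ibd_sigma: float = 0.45  # logit-scale SD of site-level allele-freq shifts
    locus_block_size: int = 8  # loci per correlated block (no recombination)

    # isotopes (per mil)
    isotope_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ISOTOPE_RANGES)
    )
    isotope_site_sd: dict[str, float] | None = None  # smooth-noise SD on site means
    isotope_within_sd: dict[str, float] | None = None  # tree-level SD within a site
    isotope_gradient_fraction: float = 0.6  # share of the range spanned by site means

    # elements (g/kg)
    n_elements: int = 41
    n_discriminant_elements: int = 5
    element_conc_range: tuple[float, float] = (0.001, 4.0)
    element_lognormal_sigma: float = 0.4  # within-site log-scale SD
    element_site_sigma: float = 0.8  # site-offset log-scale SD, discriminant only
    element_detection_ratio: float = 0.01  # detection limit / baseline median
    # restrict element site offsets to sites of one genetic cluster (None = all
    # sites); realizes strict method complementarity: elements then separate
    # sites only inside that cluster while genetics separates the clusters
    element_discriminant_cluster: int | None = None

    # missingness
    snp_missing_rate: float = 0.05
    element_missing_rate: float = 0.0
    isotope_trees_per_site: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_ISOTOPE_TREES_PER_SITE)
    )

    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 1 or self.n_loci < 1 or self.n_elements < 1:
            raise ConfigurationError("counts must be >= 1")
        lo, hi = self.n_trees_per_site
        if lo < 1 or hi < lo:
            raise ConfigurationError("n_trees_per_site must be an ordered pair >= 1")
        if not 1 <= self.n_genetic_clusters <= self.n_sites:
            raise ConfigurationError("n_genetic_clusters must be in [1, n_sites]")
        for rate in (self.snp_missing_rate, self.element_missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError("missingness rates must be in [0, 1]")
        if not 0.0 <= self.cluster_divergence <= 1.0:
            raise ConfigurationError("cluster_divergence must be in [0, 1]")
        for name, (a, b) in self.isotope_ranges.items():
            if b <= a:
                raise ConfigurationError(f"isotope range for {name} must be ordered")
        if self.element_conc_range[1] <= self.element_conc_range[0]:
            raise ConfigurationError("element_conc_range must be ordered")
        if not 0 <= self.n_discriminant_elements <= self.n_elements:
            raise ConfigurationError("n_discriminant_elements must be in [0, n_elements]")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream of the global seed."""
        return np.random.default_rng([int(self.seed), _SUBSTREAMS[stream]])

    def isotope_names(self) -> tuple[str, ...]:
        return tuple(self.isotope_ranges)

    def resolved_isotope_sds(self) -> tuple[dict[str, float], dict[str, float]]:
        """(site-level smooth-noise SD, within-site SD) per isotope.

        Defaults make the within-site SD comparable to the SD of site means:
        site means span ``isotope_gradient_fraction`` of the range (a uniform
        spread of width w has SD w/sqrt(12)), and the within-site SD is set to
        that same value.
        """
        site_sd, within_sd = {}, {}
        for name, (lo, hi) in self.isotope_ranges.items():
            width = (hi - lo) * self.isotope_gradient_fraction
            between = width / math.sqrt(12.0)
            site_sd[name] = between / 4.0
            within_sd[name] = between
        if self.isotope_site_sd:
            site_sd.update(self.isotope_site_sd)
        if self.isotope_within_sd:
            within_sd.update(self.isotope_within_sd)
        return site_sd, within_sd


def _km_offsets_to_lat_lon(lat0: float, lon0: float, dx_km: np.ndarray, dy_km: np.ndarray):
    """Local flat-earth conversion of east/north km offsets to degrees."""
    km_per_deg = 2.0 * math.pi * 6371.0 / 360.0
    lat = lat0 + dy_km / km_per_deg
    lon = lon0 + dx_km / (km_per_deg * math.cos(math.radians(lat0)))
    return lat, lon


def _country_of(lat: float, lon: float, center_lat: float, center_lon: float) -> str:
    # coarse partition of the study box into the three exporting countries
    if lat > center_lat + 1.0:
        return "CAM"
    return "GAB" if lon < center_lon else "CON"


def generate_sites(config: GeneratorConfig, rng: np.random.Generator | None = None):
    """Place sites (>= min separation apart) and scatter trees around them.

    Returns (sites, trees) DataFrames shaped like :class:`TraceDataset` fields;
    site locations are the centroids of their trees' coordinates.
    """
    config.validate()
    rng = rng or config.rng("sites")
    half = config.extent_km / 2.0

    centers: list[tuple[float, float]] = []  # east/north km offsets
    attempts = 0
    max_attempts = 10_000 * config.n_sites
    while len(centers) < config.n_sites:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigurationError(
                f"could not place {config.n_sites} sites >= "
                f"{config.min_site_separation_km} km apart in a {config.extent_km} km box"
            )
        x, y = rng.uniform(-half, half, size=2)
        if all(
            math.hypot(x - cx, y - cy) >= config.min_site_separation_km
            for cx, cy in centers
        ):
            centers.append((x, y))

    lo, hi = config.n_trees_per_site
    counts = rng.integers(lo, hi + 1, size=config.n_sites)

    site_rows = []
    tree_rows = []
    country_counter: dict[str, int] = {}
    for (x, y), n_trees in zip(centers, counts):
        lat0, lon0 = _km_offsets_to_lat_lon(config.center_lat, config.center_lon, np.array(x), np.array(y))
        country = _country_of(float(lat0), float(lon0), config.center_lat, config.center_lon)
        country_counter[country] = country_counter.get(country, 0) + 1
        site_id = f"{country}{country_counter[country]}"

        r = config.tree_scatter_km * np.sqrt(rng.uniform(size=n_trees))
        theta = rng.uniform(0.0, 2.0 * math.pi, size=n_trees)
        tlat, tlon = _km_offsets_to_lat_lon(
            config.center_lat, config.center_lon, x + r * np.cos(theta), y + r * np.sin(theta)
        )
        for k in range(n_trees):
            tree_rows.append(
                {
                    "tree_id": f"{site_id}_T{k + 1:02d}",
                    "site_id": site_id,
                    "lat": float(tlat[k]),
                    "lon": float(tlon[k]),
                    "dbh_cm": float(np.round(rng.uniform(30.0, 150.0), 1)),
                }
            )
        site_rows.append(
            {
                "site_id": site_id,
                "country": country,
                "lat": float(np.mean(tlat)),
                "lon": float(np.mean(tlon)),
                "n_trees": int(n_trees),
            }
        )

    sites = pd.DataFrame(site_rows).set_index("site_id")
    trees = pd.DataFrame(tree_rows).set_index("tree_id")
    return sites, trees


def _site_distance_matrix(sites: pd.DataFrame) -> np.ndarray:
    n = len(sites)
    lat = sites["lat"].to_numpy()
    lon = sites["lon"].to_numpy()
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = haversine_km(lat[i], lon[i], lat[j], lon[j])
    return d


def assign_clusters(sites: pd.DataFrame, n_clusters: int) -> pd.Series:
    """Spatially contiguous cluster labels from a 1-D split on longitude."""
    order = sites["lon"].sort_values().index
    labels = pd.Series(0, index=sites.index, dtype=int)
    for c, chunk in enumerate(np.array_split(np.asarray(order), n_clusters)):
        labels.loc[chunk] = c
    return labels


def generate_genetics(
    sites: pd.DataFrame,
    trees: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> GeneticMatrix:
    """Haploid biallelic calls with cluster divergence and isolation by distance.

    Sites are grouped into spatially contiguous clusters; per-locus cluster
    allele frequencies diverge from a common ancestral frequency with a
    Balding-Nichols-style parameter F = ``cluster_divergence``; within a
    cluster, site frequencies receive logit-scale shifts that are spatially
    correlated with e-folding distance ``ibd_scale_km`` and are shared across
    consecutive blocks of loci (the plastid genome does not recombine, so loci
    travel together).
    """
    config.validate()
    rng = rng or config.rng("genetics")
    clusters = assign_clusters(sites, config.n_genetic_clusters)
    site_ids = list(sites.index)
    n_sites = len(site_ids)
    L = config.n_loci
    F = config.cluster_divergence

    p0 = rng.uniform(0.1, 0.9, size=L)
    n_clu = config.n_genetic_clusters
    if F >= 1.0:
        # fixed alternating alleles: adjacent clusters carry opposite alleles
        p_cluster = np.tile((np.arange(n_clu) % 2).astype(float)[:, None], (1, L))
    elif F <= 0.0:
        p_cluster = np.tile(p0, (n_clu, 1))
    else:
        a = p0 * (1.0 - F) / F
        b = (1.0 - p0) * (1.0 - F) / F
        p_cluster = rng.beta(np.tile(a, (n_clu, 1)), np.tile(b, (n_clu, 1)))

    # site-level logit shifts: one draw per (block, cluster), spatially correlated
    dist = _site_distance_matrix(sites)
    n_blocks = max(1, math.ceil(L / config.locus_block_size))
    block_of_locus = np.minimum(np.arange(L) // config.locus_block_size, n_blocks - 1)
    shifts = np.zeros((n_sites, n_blocks))
    if config.ibd_sigma > 0:
        for c in range(n_clu):
            members = np.flatnonzero(clusters.loc[site_ids].to_numpy() == c)
            if members.size == 0:
                continue
            sub = dist[np.ix_(members, members)]
            if np.isinf(config.ibd_scale_km):
                corr = np.ones_like(sub)
            else:
                corr = np.exp(-sub / config.ibd_scale_km)
            cov = (config.ibd_sigma**2) * corr + 1e-9 * np.eye(members.size)
            chol = np.linalg.cholesky(cov)
            z = rng.standard_normal(size=(members.size, n_blocks))
            shifts[members, :] = chol @ z

    site_cluster = clusters.loc[site_ids].to_numpy()
    logit_pc = np.where(
        (p_cluster <= 0) | (p_cluster >= 1), np.nan, logit(np.clip(p_cluster, 1e-12, 1 - 1e-12))
    )
    p_site = np.empty((n_sites, L))
    for s in range(n_sites):
        base = p_cluster[site_cluster[s]]
        lp = logit_pc[site_cluster[s]] + shifts[s, block_of_locus]
        p_site[s] = np.where(np.isnan(lp), base, expit(lp))

    site_index = {sid: i for i, sid in enumerate(site_ids)}
    tree_site_idx = trees["site_id"].map(site_index).to_numpy()
    u = rng.uniform(size=(len(trees), L))
    calls = (u < p_site[tree_site_idx]).astype(np.int8)
    loci = [f"pSNP{j + 1:04d}" for j in range(L)]
    positions = np.sort(rng.choice(np.arange(1, 160_000), size=L, replace=False))
    return GeneticMatrix(list(trees.index), loci, calls, positions)


def _smooth_site_field(
    sites: pd.DataFrame, rng: np.random.Generator, site_sd: float, scale_km: float
) -> np.ndarray:
    """Low-frequency spatial noise on site locations (exponential covariance)."""
    if site_sd <= 0:
        return np.zeros(len(sites))
    dist = _site_distance_matrix(sites)
    cov = (site_sd**2) * np.exp(-dist / scale_km) + 1e-9 * np.eye(len(sites))
    return np.linalg.cholesky(cov) @ rng.standard_normal(len(sites))


def generate_isotopes(
    sites: pd.DataFrame,
    trees: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> IsotopeTable:
    """Site means on a linear spatial gradient plus smooth noise; trees = mean + noise.

    Site means are rescaled to span ``isotope_gradient_fraction`` of the
    configured per-mil range, centred in it; the default within-site SD equals
    the SD of the site means, reproducing the weak-site-signal regime in which
    local variation rivals the across-site variation.
    """
    config.validate()
    rng = rng or config.rng("isotopes")
    site_sd, within_sd = config.resolved_isotope_sds()
    lat = sites["lat"].to_numpy()
    lon = sites["lon"].to_numpy()
    values = {}
    tree_sites = trees["site_id"].to_numpy()
    site_pos = {sid: i for i, sid in enumerate(sites.index)}
    for name, (lo, hi) in config.isotope_ranges.items():
        theta = rng.uniform(0.0, 2.0 * math.pi)
        score = lat * math.sin(theta) + lon * math.cos(theta)
        score = score + _smooth_site_field(sites, rng, site_sd[name], config.extent_km / 2.0)
        span = score.max() - score.min()
        if span <= 0:
            scaled = np.full_like(score, (lo + hi) / 2.0)
        else:
            width = (hi - lo) * config.isotope_gradient_fraction
            mid = (lo + hi) / 2.0
            scaled = mid + (score - score.mean()) / span * width
        idx = np.array([site_pos[s] for s in tree_sites])
        values[name] = scaled[idx] + rng.normal(0.0, within_sd[name], size=len(trees))
    return IsotopeTable(pd.DataFrame(values, index=trees.index))


def _element_names(config: GeneratorConfig) -> list[str]:
    if config.n_elements <= len(ELEMENTS_BY_ABUNDANCE):
        return list(ELEMENTS_BY_ABUNDANCE[: config.n_elements])
    extra = [f"E{k:02d}" for k in range(config.n_elements - len(ELEMENTS_BY_ABUNDANCE))]
    return list(ELEMENTS_BY_ABUNDANCE) + extra


def generate_elements(
    sites: pd.DataFrame,
    trees: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> ElementTable:
    """Log-normal element concentrations with a few site-discriminant elements.

    Baseline medians are log-spaced across the configured g/kg range. The
    discriminant elements get an independent multiplicative site offset per
    site (a fine-scale soil mosaic, uncorrelated with the genetic clusters);
    all other elements carry no site information.
    """
    config.validate()
    rng = rng or config.rng("elements")
    names = _element_names(config)
    lo, hi = config.element_conc_range
    medians = np.geomspace(hi, lo, num=len(names))
    discr = [e for e in DEFAULT_DISCRIMINANT_ELEMENTS if e in names]
    discr = discr[: config.n_discriminant_elements]
    while len(discr) < config.n_discriminant_elements:
        for e in names:
            if e not in discr:
                discr.append(e)
                break
    site_ids = list(sites.index)
    site_pos = {sid: i for i, sid in enumerate(site_ids)}
    if config.element_discriminant_cluster is None:
        informative = np.ones(len(site_ids), dtype=bool)
    else:
        clusters = assign_clusters(sites, config.n_genetic_clusters)
        informative = (
            clusters.loc[site_ids].to_numpy() == config.element_discriminant_cluster
        )
    offsets = np.zeros((len(site_ids), len(names)))
    for j, e in enumerate(names):
        if e in discr:
            draw = rng.normal(0.0, config.element_site_sigma, size=len(site_ids))
            offsets[:, j] = np.where(informative, draw, 0.0)
    idx = np.array([site_pos[s] for s in trees["site_id"]])
    noise = rng.normal(0.0, config.element_lognormal_sigma, size=(len(trees), len(names)))
    conc = medians[None, :] * np.exp(offsets[idx] + noise)
    data = pd.DataFrame(conc, index=trees.index, columns=names)
    limits = pd.Series(medians * config.element_detection_ratio, index=names)
    below = data.lt(limits, axis=1)
    return ElementTable(data, below, limits)


def apply_missingness(
    d: TraceDataset,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> TraceDataset:
    """Mask cells to emulate per-method sampling effort; reproducible from seed.

    SNP and element cells are masked independently at the configured rates.
    Isotopes are masked per (site, isotope): each site keeps a random nested
    subset of measured trees sized within the configured per-isotope range, so
    trees measured for the scarcest isotope are also measured for the others.
    """
    config.validate()
    rng = rng or config.rng("missingness")
    out = d.copy()

    if config.snp_missing_rate > 0:
        mask = rng.uniform(size=out.genetics.calls.shape) < config.snp_missing_rate
        out.genetics.calls[mask] = MISSING

    if config.element_missing_rate > 0:
        emask = rng.uniform(size=out.elements.data.shape) < config.element_missing_rate
        out.elements.data = out.elements.data.mask(emask)

    iso_names = [n for n in out.isotopes.data.columns]
    ranges = config.isotope_trees_per_site
    if any(n in ranges for n in iso_names):
        # draw nested measured subsets per site, most-sampled isotope first
        order = sorted(
            [n for n in iso_names if n in ranges], key=lambda n: ranges[n][1], reverse=True
        )
        keep = pd.DataFrame(False, index=out.isotopes.data.index, columns=iso_names)
        for site_id, grp in out.trees.groupby("site_id"):
            ids = np.asarray(grp.index)
            perm = rng.permutation(ids)
            prev_k = len(ids)
            for name in order:
                klo, khi = ranges[name]
                k = int(rng.integers(klo, khi + 1))
                k = min(k, prev_k, len(ids))
                k = max(k, 1)
                keep.loc[perm[:k], name] = True
                prev_k = k
        for name in iso_names:
            if name in ranges:
                out.isotopes.data[name] = out.isotopes.data[name].where(keep[name])

    _check_sites_have_complete_trees(out)
    return out


def _check_sites_have_complete_trees(d: TraceDataset) -> None:
    """Every site must retain >= 1 tree usable as a training anchor."""
    from .preprocess import eligible_trees

    complete = pd.Series(d.trees.index.isin(eligible_trees(d)), index=d.trees.index)
    per_site = complete.groupby(d.trees["site_id"]).sum()
    empty = per_site[per_site == 0].index.tolist()
    if empty:
        raise ConfigurationError(
            f"missingness left site(s) {empty} with zero complete trees"
        )


def generate_dataset(config: GeneratorConfig | None = None, seed: int | None = None) -> TraceDataset:
    """Compose the four generators into a validated TraceDataset.

    ``seed`` overrides ``config.seed``; the config and seed are recorded in the
    dataset's provenance so a run manifest can reproduce it.
    """
    config = config or GeneratorConfig()
    if seed is not None:
        config = GeneratorConfig(**{**asdict(config), "seed": int(seed)})
    config.validate()
    sites, trees = generate_sites(config)
    genetics = generate_genetics(sites, trees, config)
    isotopes = generate_isotopes(sites, trees, config)
    elements = generate_elements(sites, trees, config)
    d = TraceDataset(
        sites=sites,
        trees=trees,
        genetics=genetics,
        isotopes=isotopes,
        elements=elements,
        provenance={"generator": "timbertrace.simulate", "seed": int(config.seed), "config": asdict(config)},
    )
    return apply_missingness(d, config)
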