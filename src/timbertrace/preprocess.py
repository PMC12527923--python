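"""Data hygiene: missingness filters, detection-limit exclusion, imputation,
and test-set selection.

The genetic filter removes individuals with more than 50% missing calls, then
loci with more than 25% missing calls (strict inequalities, individuals
first). Elements below the detection limit in more than 100 samples are
excluded; below-detection cells of retained elements are set to half the
detection limit. Missing SNPs are imputed with the most common allele at the
tree's site; missing isotopes with the site mean over measured trees — by
default computed from training trees only, so no information flows from test
to train.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING,
    ElementTable,
    GeneticMatrix,
    IsotopeTable,
    TraceDataset,
    ValidationError,
)

__all__ = [
    "TestSplit",
    "FilterReport",
    "filter_genetic_matrix",
    "filter_elements_by_detection",
    "impute_snps_site_mode",
    "impute_isotopes_site_mean",
    "eligible_trees",
    "select_test_set",
]


@dataclass(frozen=True)
class TestSplit:
    """One repeated hold-out draw; test and train partition the tree universe."""

    test_ids: tuple[str, ...]
    train_ids: tuple[str, ...]
    repeat_index: int
    seed: int

    def __post_init__(self) -> None:
        if set(self.test_ids) & set(self.train_ids):
            raise ValidationError("test and train sets overlap")


@dataclass
class FilterReport:
    removed_trees: list[str] = field(default_factory=list)
    removed_loci: list[str] = field(default_factory=list)
    removed_elements: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [("tree", t) for t in self.removed_trees]
            + [("locus", l) for l in self.removed_loci]
            + [("element", e) for e in self.removed_elements]
        )
        return pd.DataFrame(rows, columns=["kind", "id"])


def filter_genetic_matrix(
    m: GeneticMatrix,
    max_ind_missing: float = 0.50,
    max_locus_missing: float = 0.25,
) -> tuple[GeneticMatrix, FilterReport]:
    """Drop individuals with > max_ind_missing missing calls, then loci with
    > max_locus_missing (computed on the remaining individuals)."""
    report = FilterReport()
    tree_frac = m.tree_missing_fraction()
    keep_trees = [t for t in m.trees if tree_frac[t] <= max_ind_missing]
    report.removed_trees = [t for t in m.trees if tree_frac[t] > max_ind_missing]
    if not keep_trees:
        raise ValidationError("no individuals survive the missingness filter")
    m2 = m.subset(trees=keep_trees)
    locus_frac = m2.locus_missing_fraction()
    keep_loci = [l for l in m2.loci if locus_frac[l] <= max_locus_missing]
    report.removed_loci = [l for l in m2.loci if locus_frac[l] > max_locus_missing]
    if not keep_loci:
        raise ValidationError("no loci survive the missingness filter")
    return m2.subset(loci=keep_loci), report


def filter_elements_by_detection(
    t: ElementTable, max_below_detection: int = 100
) -> tuple[ElementTable, FilterReport]:
    """Exclude elements below the detection limit in more than
    ``max_below_detection`` samples; substitute DL/2 in retained elements'
    below-detection cells."""
    report = FilterReport()
    counts = t.below_detection_counts()
    keep = [e for e in t.elements if counts[e] <= max_below_detection]
    report.removed_elements = [e for e in t.elements if counts[e] > max_below_detection]
    data = t.data[keep].copy()
    flags = t.below_detection[keep]
    limits = t.detection_limits[keep]
    half_dl = pd.DataFrame(
        np.tile((limits / 2.0).to_numpy(), (len(data), 1)), index=data.index, columns=keep
    )
    data = data.mask(flags, half_dl)
    return ElementTable(data, flags, limits), report


def _as_site_series(site_labels, index: Sequence[str]) -> pd.Series:
    s = pd.Series(site_labels) if not isinstance(site_labels, pd.Series) else site_labels
    missing = [t for t in index if t not in s.index]
    if missing:
        raise ValidationError(f"no site label for tree(s): {missing[:5]}")
    return s.loc[list(index)]


def impute_snps_site_mode(
    m: GeneticMatrix,
    site_labels,
    mode_from: Iterable[str] | None = None,
) -> GeneticMatrix:
    """Replace missing calls with the most common allele at the tree's site.

    Modes are computed over ``mode_from`` trees only (default: all trees) —
    pass the training ids to keep test trees out of the statistics. Ties break
    to the lowest allele code; a site with no observed call at a locus falls
    back to the global mode. A locus with no observed call anywhere is an
    error.
    """
    sites = _as_site_series(site_labels, m.trees)
    calls = m.calls.copy()
    obs = calls != MISSING
    if mode_from is None:
        stat_rows = np.ones(len(m.trees), dtype=bool)
    else:
        mode_set = set(mode_from)
        stat_rows = np.array([t in mode_set for t in m.trees])

    def _mode(counts0: np.ndarray, counts1: np.ndarray) -> np.ndarray:
        # ties (equal counts) resolve to allele 0 via >=
        return np.where(counts0 >= counts1, 0, 1).astype(np.int8)

    stat_obs = obs & stat_rows[:, None]
    g0 = (stat_obs & (calls == 0)).sum(axis=0)
    g1 = (stat_obs & (calls == 1)).sum(axis=0)
    # loci never observed anywhere (not just within mode_from) are unusable
    never = ~obs.any(axis=0)
    if never.any():
        bad = [m.loci[j] for j in np.flatnonzero(never)]
        raise ValidationError(f"locus entirely missing in all individuals: {bad[:5]}")
    # global fallback where mode_from has no observation: widen to all rows
    no_stat = (g0 + g1) == 0
    if no_stat.any():
        g0 = np.where(no_stat, (obs & (calls == 0)).sum(axis=0), g0)
        g1 = np.where(no_stat, (obs & (calls == 1)).sum(axis=0), g1)
    global_mode = _mode(g0, g1)

    site_arr = sites.to_numpy()
    out = calls.copy()
    for site in np.unique(site_arr):
        rows = site_arr == site
        srows = rows & stat_rows
        s_obs = obs[srows]
        s_calls = calls[srows]
        c0 = ((s_calls == 0) & s_obs).sum(axis=0)
        c1 = ((s_calls == 1) & s_obs).sum(axis=0)
        site_mode = _mode(c0, c1)
        unseen = (c0 + c1) == 0
        fill = np.where(unseen, global_mode, site_mode)
        block = out[rows]
        block[block == MISSING] = np.broadcast_to(fill, block.shape)[block == MISSING]
        out[rows] = block
    return GeneticMatrix(m.trees, m.loci, out, m.positions)


def impute_isotopes_site_mean(
    t: IsotopeTable,
    site_labels,
    means_from: Iterable[str] | None = None,
) -> tuple[IsotopeTable, pd.DataFrame]:
    """Replace missing isotope values with site means over measured trees.

    Means use only trees in ``means_from`` (default: all) — pass training ids
    so imputed training statistics never depend on test-tree measurements.
    Returns the completed table and a boolean frame flagging imputed cells
    (global-mean fallbacks included).
    """
    sites = _as_site_series(site_labels, t.data.index)
    data = t.data.copy()
    stat = data if means_from is None else data.loc[data.index.intersection(list(means_from))]
    stat_sites = sites.loc[stat.index]
    imputed = data.isna()
    for col in data.columns:
        col_stat = stat[col]
        if col_stat.notna().sum() == 0:
            raise ValidationError(f"no measured values at all for isotope {col}")
        site_means = col_stat.groupby(stat_sites).mean()
        global_mean = col_stat.mean()
        fill = sites.map(site_means).fillna(global_mean)
        data[col] = data[col].fillna(fill)
    return IsotopeTable(data), imputed


def eligible_trees(d: TraceDataset) -> list[str]:
    """Trees with complete element and genetic data and measured d2H and d18O —
    the pool from which test sets are drawn."""
    idx = d.trees.index
    in_gen = idx.isin(d.genetics.trees)
    el = d.elements.data.reindex(idx)
    el_ok = el.notna().all(axis=1).to_numpy()
    iso = d.isotopes.data.reindex(idx)
    iso_ok = np.ones(len(idx), dtype=bool)
    for name in ("d2H", "d18O"):
        if name in iso.columns:
            iso_ok &= iso[name].notna().to_numpy()
    return list(idx[in_gen & el_ok & iso_ok])


def select_test_set(
    d: TraceDataset,
    fraction: float = 0.5,
    repeat_index: int = 0,
    seed: int = 0,
) -> TestSplit:
    """Draw a stratified test set from the eligible pool.

    n_test = floor(fraction x |eligible|), allocated across sites
    proportionally to their eligible counts with largest-remainder rounding
    and at least one test tree per represented site where the pool and budget
    allow. Reproducible from (seed, repeat_index); different repeat indices
    give different draws.
    """
    pool = eligible_trees(d)
    if not pool:
        raise ValidationError("no eligible trees to draw a test set from")
    n_test = int(np.floor(fraction * len(pool)))
    sites = d.trees.loc[pool, "site_id"]
    counts = sites.value_counts().sort_index()
    all_sites = d.sites.index
    missing_sites = [s for s in all_sites if s not in counts.index]
    if missing_sites:
        warnings.warn(
            f"site(s) {missing_sites} have no eligible trees and are absent from the test set"
        )
    quotas = counts / counts.sum() * n_test
    alloc = np.floor(quotas).astype(int)
    alloc = np.minimum(alloc, counts)
    # largest-remainder distribution of the leftover budget
    rem = n_test - int(alloc.sum())
    frac_order = (quotas - np.floor(quotas)).sort_values(ascending=False).index
    for s in list(frac_order) * 2:  # second pass in case of caps
        if rem <= 0:
            break
        if alloc[s] < counts[s]:
            alloc[s] += 1
            rem -= 1
    # minimum one per represented site, funded by the largest allocations
    if n_test >= len(counts):
        for s in counts.index:
            if alloc[s] == 0:
                donor = alloc.idxmax()
                if alloc[donor] > 1:
                    alloc[donor] -= 1
                    alloc[s] = 1
    rng = np.random.default_rng([int(seed), int(repeat_index), 0x5E1EC7])
    test: list[str] = []
    for s in counts.index:
        members = sorted(sites.index[sites == s])
        take = int(alloc[s])
        if take > 0:
            test.extend(rng.choice(members, size=take, replace=False))
    test_set = set(test)
    train = [t for t in d.trees.index if t not in test_set]
    train_sites = set(d.trees.loc[train, "site_id"])
    absent = set(d.trees.loc[list(test_set), "site_id"]) - train_sites
    if absent:
        raise ValidationError(f"site(s) {sorted(absent)} left without training trees")
    return TestSplit(tuple(sorted(test_set)), tuple(train), int(repeat_index), int(seed))
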