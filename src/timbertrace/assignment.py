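"""The site-identification experiment.

Fuses the per-method reference databases into feature tables, trains one
random-forest classifier per method set (SNP, ISO, EL and their
combinations) on repeated stratified hold-out draws, assigns each held-out
tree to its most likely site, and summarizes accuracy, confusion and the
distance between true and predicted site centroids — against a
random-assignment (RDM) baseline derived from the pairwise site distances
occurring in the reference dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .datamodel import (
    ALL_METHOD_SETS,
    ISOTOPES,
    MethodSet,
    TraceDataset,
    ValidationError,
)
from .preprocess import (
    impute_isotopes_site_mean,
    impute_snps_site_mode,
    select_test_set,
)

__all__ = [
    "DEFAULT_BIN_EDGES",
    "FeatureTable",
    "Classifier",
    "build_feature_table",
    "fit_classifier",
    "predict_site",
    "SiteIdentificationModel",
    "IdentificationResults",
    "run_identification_experiment",
    "distance_bin_summary",
    "random_assignment_distance_baseline",
    "variable_importance_report",
]

#: Upper edges (km) of the distance-to-predicted-origin bins after the exact
#: bin; intervals are half-open (lo, hi].
DEFAULT_BIN_EDGES: tuple[float, ...] = (50.0, 100.0, 300.0, 500.0, 1000.0)


@dataclass
class FeatureTable:
    """Fused numeric features for one method set; no missing cells."""

    data: pd.DataFrame
    method_set: MethodSet

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValidationError(f"feature table has missing cells in {bad[:5]}")

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)


def build_feature_table(
    d: TraceDataset,
    method_set: MethodSet | Iterable[str],
    train_ids: Sequence[str],
    test_ids: Sequence[str] | None = None,
) -> tuple[FeatureTable, FeatureTable]:
    """Build train/test feature tables for one method set.

    The tree universe is the intersection of the genetic matrix and the
    complete-element trees. Missing SNPs are imputed with the site mode and
    missing isotopes with the site mean, both computed from training trees
    only, so no statistic flows from test to train. Columns are prefixed
    ``SNP:``/``ISO:``/``EL:`` and ordered identically for train and test.
    """
    method_set = MethodSet(method_set)
    el_complete = d.elements.data.dropna()
    universe = [t for t in d.trees.index if t in d.genetics.trees and t in el_complete.index]
    train = [t for t in train_ids if t in universe]
    test = [t for t in (test_ids or []) if t in universe]
    if test_ids is not None and len(test) != len(test_ids):
        lost = sorted(set(test_ids) - set(test))
        raise ValidationError(f"test tree(s) lack complete genetic/element data: {lost[:5]}")
    sites = d.trees["site_id"]

    blocks: list[pd.DataFrame] = []
    if "SNP" in method_set:
        sub = d.genetics.subset(trees=universe)
        imputed = impute_snps_site_mode(sub, sites, mode_from=train)
        snp = pd.DataFrame(
            imputed.calls.astype(float),
            index=imputed.trees,
            columns=[f"SNP:{l}" for l in imputed.loci],
        )
        blocks.append(snp)
    if "ISO" in method_set:
        iso_all = d.isotopes.data.reindex(universe)
        from .datamodel import IsotopeTable

        filled, _ = impute_isotopes_site_mean(IsotopeTable(iso_all), sites, means_from=train)
        iso = filled.data.rename(columns={c: f"ISO:{c}" for c in filled.data.columns})
        blocks.append(iso)
    if "EL" in method_set:
        el = el_complete.reindex(universe)
        el = el.rename(columns={c: f"EL:{c}" for c in el.columns})
        blocks.append(el)

    fused = pd.concat(blocks, axis=1)
    return (
        FeatureTable(fused.loc[train], method_set),
        FeatureTable(fused.loc[test], method_set),
    )


class Classifier:
    """A fitted multiclass random forest with a documented tie-break.

    Prediction takes the class with the highest mean vote; exact ties resolve
    to the lexicographically smallest site label.
    """

    def __init__(self, model: RandomForestClassifier, columns: list[str]) -> None:
        self._model = model
        self.columns = columns
        self.classes_ = list(model.classes_)  # sklearn sorts labels

    def predict(self, table: FeatureTable | pd.DataFrame) -> pd.Series:
        data = table.data if isinstance(table, FeatureTable) else table
        if list(data.columns) != self.columns:
            extra = sorted(set(data.columns) - set(self.columns))
            missing = sorted(set(self.columns) - set(data.columns))
            raise ValidationError(
                f"feature schema mismatch: missing {missing[:5]}, unexpected {extra[:5]}"
            )
        if len(data) == 0:
            return pd.Series([], dtype=object, index=data.index)
        proba = self._model.predict_proba(data.to_numpy())
        # argmax returns the first maximum; classes_ are sorted, so ties fall
        # to the lexicographically smallest label
        idx = np.argmax(proba, axis=1)
        return pd.Series([self.classes_[i] for i in idx], index=data.index)

    @property
    def feature_importances_(self) -> pd.Series:
        return pd.Series(self._model.feature_importances_, index=self.columns)


def fit_classifier(
    train: FeatureTable,
    labels: Sequence[str] | pd.Series,
    n_trees: int = 500,
    seed: int | None = 0,
) -> Classifier:
    """Train a random forest (default 500 trees, sqrt(p) features per split)."""
    labels = pd.Series(list(labels), index=train.data.index) if not isinstance(labels, pd.Series) else labels.loc[train.data.index]
    if labels.nunique() < 2:
        raise ValidationError("training set contains a single class")
    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=None if seed is None else int(seed),
        n_jobs=1,
    )
    model.fit(train.data.to_numpy(), labels.to_numpy())
    return Classifier(model, list(train.data.columns))


def predict_site(c: Classifier, test: FeatureTable) -> pd.Series:
    """Assign each test tree to its most likely site."""
    return c.predict(test)


def _bin_labels(edges: Sequence[float]) -> list[str]:
    labels = ["0"]
    lo = 0.0
    for hi in edges:
        labels.append(f"({lo:g},{hi:g}]")
        lo = hi
    labels.append(f"({lo:g},inf)")
    return labels


def distance_bin_summary(
    results: pd.DataFrame, edges: Sequence[float] = DEFAULT_BIN_EDGES
) -> pd.Series:
    """Percentage of assignments per distance-to-predicted-origin bin.

    Bin "0" holds correct-site assignments; the rest are half-open (lo, hi]
    intervals in km. Percentages sum to 100.
    """
    if len(results) == 0:
        raise ValidationError("no assignments to bin")
    labels = _bin_labels(edges)
    correct = results["predicted_site"] == results["true_site"]
    counts = pd.Series(0.0, index=labels)
    counts["0"] = correct.sum()
    dists = results.loc[~correct, "distance_km"].to_numpy()
    cut_edges = [0.0, *edges, np.inf]
    binned = pd.cut(dists, bins=cut_edges, right=True, labels=labels[1:])
    vc = binned.value_counts()
    for lab in labels[1:]:
        counts[lab] += vc.get(lab, 0)
    return counts / counts.sum() * 100.0


def random_assignment_distance_baseline(
    d: TraceDataset,
    edges: Sequence[float] = DEFAULT_BIN_EDGES,
    weight: str = "counts",
) -> pd.Series:
    """Distance-bin percentages expected under fully random assignment (RDM).

    Every tree is "assigned" to the site of every reference tree, so each
    candidate site is weighted by its reference tree count (``weight="counts"``)
    or uniformly (``weight="uniform"``). Percentages sum to 100.
    """
    if d.n_sites < 1:
        raise ValidationError("dataset has no sites")
    labels = _bin_labels(edges)
    site_counts = d.trees["site_id"].value_counts()
    sdm = d.site_distance_matrix()
    counts = pd.Series(0.0, index=labels)
    cut_edges = [0.0, *edges, np.inf]
    for true_site, n_true in site_counts.items():
        for cand_site in d.site_ids:
            w_cand = site_counts.get(cand_site, 0) if weight == "counts" else 1.0
            w = float(n_true) * float(w_cand)
            if w == 0:
                continue
            if cand_site == true_site:
                counts["0"] += w
            else:
                dist = sdm.loc[true_site, cand_site]
                lab = pd.cut([dist], bins=cut_edges, right=True, labels=labels[1:])[0]
                counts[lab] += w
    return counts / counts.sum() * 100.0


def variable_importance_report(c: Classifier, top_k: int | None = None) -> pd.DataFrame:
    """Features ranked by impurity importance, descending; ties by name."""
    imp = c.feature_importances_
    df = (
        imp.rename("importance")
        .rename_axis("feature")
        .reset_index()
        .sort_values(["importance", "feature"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return df.head(top_k) if top_k else df


@dataclass
class IdentificationResults:
    """Pooled assignments of the repeated identification experiment.

    ``assignments`` has one row per (repeat, method set, test tree) with the
    true and predicted sites and the great-circle distance between their
    centroids.
    """

    assignments: pd.DataFrame
    method_sets: tuple[MethodSet, ...]
    n_repeats: int
    bin_edges: tuple[float, ...]
    rdm_bins: pd.Series
    importances: dict[str, pd.DataFrame] = field(default_factory=dict)

    def _per_repeat_accuracy(self, label: str) -> pd.Series:
        sub = self.assignments[self.assignments["method_set"] == label]
        correct = sub["predicted_site"] == sub["true_site"]
        return correct.groupby(sub["repeat_index"]).mean() * 100.0

    def accuracy_summary(self) -> pd.DataFrame:
        """Mean and SD (over repeats) of % correctly assigned, per method set."""
        rows = []
        for ms in self.method_sets:
            acc = self._per_repeat_accuracy(ms.label)
            rows.append(
                {
                    "method_set": ms.label,
                    "accuracy_mean": acc.mean(),
                    "accuracy_sd": acc.std(ddof=1) if len(acc) > 1 else 0.0,
                }
            )
        return pd.DataFrame(rows).set_index("method_set")

    def per_site_accuracy(self, method_set: MethodSet | str) -> pd.Series:
        label = method_set if isinstance(method_set, str) else method_set.label
        sub = self.assignments[self.assignments["method_set"] == label]
        correct = sub["predicted_site"] == sub["true_site"]
        return correct.groupby(sub["true_site"]).mean() * 100.0

    def confusion(self, method_set: MethodSet | str) -> pd.DataFrame:
        """Counts of true site (rows) x predicted site (columns), pooled."""
        label = method_set if isinstance(method_set, str) else method_set.label
        sub = self.assignments[self.assignments["method_set"] == label]
        return pd.crosstab(sub["true_site"], sub["predicted_site"]).astype(int)

    def distance_bins(self, method_set: MethodSet | str | None = None) -> pd.DataFrame:
        """Distance-bin percentages per method set (plus the RDM baseline)."""
        out = {}
        targets = (
            [method_set] if method_set is not None else [ms.label for ms in self.method_sets]
        )
        for t in targets:
            label = t if isinstance(t, str) else t.label
            sub = self.assignments[self.assignments["method_set"] == label]
            out[label] = distance_bin_summary(sub, self.bin_edges)
        out["RDM"] = self.rdm_bins
        return pd.DataFrame(out)

    def within_km(self, km: float, method_set: MethodSet | str) -> float:
        """% of assignments within ``km`` of the true site (correct included)."""
        label = method_set if isinstance(method_set, str) else method_set.label
        sub = self.assignments[self.assignments["method_set"] == label]
        ok = (sub["predicted_site"] == sub["true_site"]) | (sub["distance_km"] <= km)
        return float(ok.mean() * 100.0)

    def summary(self) -> str:
        acc = self.accuracy_summary()
        lines = [
            "Site identification experiment",
            "------------------------------",
            f"repeats: {self.n_repeats}; assignments per method set: "
            f"{(self.assignments['method_set'] == self.method_sets[0].label).sum()}",
            "",
            f"{'method set':<12} {'accuracy %':>12} {'sd':>6} {'<=100 km %':>11}",
        ]
        for ms in self.method_sets:
            row = acc.loc[ms.label]
            lines.append(
                f"{ms.label:<12} {row['accuracy_mean']:>12.1f} {row['accuracy_sd']:>6.1f} "
                f"{self.within_km(100.0, ms):>11.1f}"
            )
        rdm0 = self.rdm_bins.iloc[0]
        lines.append(f"{'RDM':<12} {rdm0:>12.1f} {'':>6} "
                     f"{self.rdm_bins.iloc[:3].sum():>11.1f}")
        return "\n".join(lines)


class SiteIdentificationModel:
    """Repeated hold-out site identification over the seven method sets.

    Parameters
    ----------
    dataset : TraceDataset
        Preprocessed (filtered) multi-proxy reference database.
    method_sets : sequence of MethodSet
        Model categories to evaluate; default all seven.
    n_repeats : int
        Number of random test-set draws (default 25).
    test_fraction : float
        Fraction of the eligible pool held out per repeat (default 0.5).
    n_trees : int
        Random-forest size (default 500).
    """

    def __init__(
        self,
        dataset: TraceDataset,
        method_sets: Sequence[MethodSet] = ALL_METHOD_SETS,
        n_repeats: int = 25,
        test_fraction: float = 0.5,
        n_trees: int = 500,
        bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    ) -> None:
        self.dataset = dataset
        self.method_sets = tuple(MethodSet(ms) for ms in method_sets)
        if not self.method_sets:
            raise ValidationError("need at least one method set")
        self.n_repeats = int(n_repeats)
        self.test_fraction = float(test_fraction)
        self.n_trees = int(n_trees)
        self.bin_edges = tuple(float(e) for e in bin_edges)

    def fit(self, seed: int = 0, collect_importances: bool = False) -> IdentificationResults:
        """Run the experiment; deterministic given ``seed``."""
        d = self.dataset
        sdm = d.site_distance_matrix()
        sites = d.trees["site_id"]
        rows = []
        importances: dict[str, pd.DataFrame] = {}
        for r in range(self.n_repeats):
            split = select_test_set(d, self.test_fraction, repeat_index=r, seed=seed)
            for k, ms in enumerate(self.method_sets):
                train_ft, test_ft = build_feature_table(d, ms, split.train_ids, split.test_ids)
                rf_seed = int(
                    np.random.SeedSequence([int(seed), r, k]).generate_state(1)[0] % (2**31)
                )
                clf = fit_classifier(train_ft, sites.loc[train_ft.ids], self.n_trees, rf_seed)
                pred = clf.predict(test_ft)
                for tree_id, p in pred.items():
                    true = sites[tree_id]
                    rows.append(
                        {
                            "tree_id": tree_id,
                            "true_site": true,
                            "predicted_site": p,
                            "distance_km": 0.0 if p == true else float(sdm.loc[true, p]),
                            "repeat_index": r,
                            "method_set": ms.label,
                        }
                    )
                if collect_importances and r == 0:
                    importances[ms.label] = variable_importance_report(clf)
        assignments = pd.DataFrame(rows)
        rdm = random_assignment_distance_baseline(d, self.bin_edges)
        return IdentificationResults(
            assignments=assignments,
            method_sets=self.method_sets,
            n_repeats=self.n_repeats,
            bin_edges=self.bin_edges,
            rdm_bins=rdm,
            importances=importances,
        )


def run_identification_experiment(
    d: TraceDataset,
    n_repeats: int = 25,
    seed: int = 0,
    method_sets: Sequence[MethodSet] = ALL_METHOD_SETS,
    **kwargs,
) -> IdentificationResults:
    """Functional wrapper over SiteIdentificationModel(...).fit(seed)."""
    return SiteIdentificationModel(
        d, method_sets=method_sets, n_repeats=n_repeats, **kwargs
    ).fit(seed=seed)
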