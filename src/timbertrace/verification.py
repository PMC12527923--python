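"""Origin-claim verification.

Two forensic scenarios, both argmax-based like the identification models:

* Scenario A (true claim): the claimed origin is the tree's real site; the
  model is trained on every tree except the focal one (reference trees from
  the claimed = true origin included). The claim is confirmed iff the
  predicted site equals the claim.
* Scenario B (false claim): the claim is a randomly drawn wrong site, and all
  reference trees of the tree's *true* origin are removed from training — the
  true origin is unknown and absent from the database. The claim is rejected
  iff the predicted site differs from the claim.

Analytic chance baselines for K sites: a random assignment confirms a true
claim with probability 1/K and rejects a false claim with probability
(K-2)/(K-1), since after removing the true origin K-1 candidate sites remain
of which K-2 differ from the claim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import ALL_METHOD_SETS, MethodSet, TraceDataset, ValidationError
from .preprocess import eligible_trees
from .assignment import build_feature_table, fit_classifier

__all__ = [
    "VerificationOutcome",
    "VerificationResults",
    "SiteVerificationModel",
    "verify_true_claim",
    "reject_false_claim",
    "run_verification_experiment",
    "random_baseline_confirm",
    "random_baseline_reject",
]


@dataclass(frozen=True)
class VerificationOutcome:
    tree_id: str
    true_site: str
    claimed_site: str
    scenario: str  # "A" or "B"
    predicted_site: str
    decision: str  # "confirmed" or "rejected"
    method_set: str

    def __post_init__(self) -> None:
        if self.scenario == "A" and self.claimed_site != self.true_site:
            raise ValidationError("scenario A requires claimed = true site")
        if self.scenario == "B" and self.claimed_site == self.true_site:
            raise ValidationError("scenario B requires claimed != true site")
        expected = "confirmed" if self.predicted_site == self.claimed_site else "rejected"
        if self.decision != expected:
            raise ValidationError("decision inconsistent with prediction")


def random_baseline_confirm(K: int) -> float:
    """Chance % of confirming a true claim among K sites: 100/K, 1 decimal."""
    if K < 2:
        raise ValidationError("need at least 2 sites")
    return round(100.0 / K, 1)


def random_baseline_reject(K: int) -> float:
    """Chance % of rejecting a false claim: 100 (K-2)/(K-1), 1 decimal.

    The true origin is removed from the reference, leaving K-1 sites of which
    K-2 differ from the claimed one.
    """
    if K < 2:
        raise ValidationError("need at least 2 sites")
    return round(100.0 * (K - 2) / (K - 1), 1)


def _predict_one(
    d: TraceDataset,
    tree_id: str,
    method_set: MethodSet,
    train_ids: list[str],
    n_trees: int,
    seed: int,
) -> str:
    train_ft, test_ft = build_feature_table(d, method_set, train_ids, [tree_id])
    sites = d.trees["site_id"]
    labels = sites.loc[train_ft.ids]
    if labels.nunique() == 1:
        # only one candidate site remains; the assignment is forced
        return str(labels.iloc[0])
    clf = fit_classifier(train_ft, labels, n_trees=n_trees, seed=seed)
    return str(clf.predict(test_ft).iloc[0])


def verify_true_claim(
    d: TraceDataset,
    tree_id: str,
    method_set: MethodSet | Sequence[str],
    seed: int = 0,
    n_trees: int = 500,
) -> VerificationOutcome:
    """Scenario A: train without the focal tree, confirm iff predicted = true."""
    method_set = MethodSet(method_set)
    if tree_id not in d.trees.index:
        raise ValidationError(f"unknown tree {tree_id!r}")
    true_site = d.trees.loc[tree_id, "site_id"]
    train = [t for t in d.trees.index if t != tree_id]
    if true_site not in set(d.trees.loc[train, "site_id"]):
        raise ValidationError(
            f"site {true_site!r} has no other trees; cannot train scenario A"
        )
    pred = _predict_one(d, tree_id, method_set, train, n_trees, seed)
    return VerificationOutcome(
        tree_id=tree_id,
        true_site=true_site,
        claimed_site=true_site,
        scenario="A",
        predicted_site=pred,
        decision="confirmed" if pred == true_site else "rejected",
        method_set=method_set.label,
    )


def reject_false_claim(
    d: TraceDataset,
    tree_id: str,
    claimed_site: str,
    method_set: MethodSet | Sequence[str],
    seed: int = 0,
    n_trees: int = 500,
) -> VerificationOutcome:
    """Scenario B: drop the true origin's trees from training, reject iff
    predicted differs from the claim."""
    method_set = MethodSet(method_set)
    if tree_id not in d.trees.index:
        raise ValidationError(f"unknown tree {tree_id!r}")
    true_site = d.trees.loc[tree_id, "site_id"]
    if claimed_site == true_site:
        raise ValidationError("claimed site equals true site; use scenario A")
    if claimed_site not in d.sites.index:
        raise ValidationError(f"unknown claimed site {claimed_site!r}")
    train = [
        t
        for t in d.trees.index
        if t != tree_id and d.trees.loc[t, "site_id"] != true_site
    ]
    pred = _predict_one(d, tree_id, method_set, train, n_trees, seed)
    assert pred != true_site, "scenario B predicted the excluded true origin"
    return VerificationOutcome(
        tree_id=tree_id,
        true_site=true_site,
        claimed_site=claimed_site,
        scenario="B",
        predicted_site=pred,
        decision="confirmed" if pred == claimed_site else "rejected",
        method_set=method_set.label,
    )


@dataclass
class VerificationResults:
    """Outcomes of both scenarios for the same test-tree subset."""

    outcomes: pd.DataFrame  # one row per (tree, scenario, method set)
    method_sets: tuple[MethodSet, ...]
    n_sites: int

    def rates(self) -> pd.DataFrame:
        """% confirmed (A) and % rejected (B) per method set, plus baselines."""
        rows = []
        for ms in self.method_sets:
            sub = self.outcomes[self.outcomes["method_set"] == ms.label]
            a = sub[sub["scenario"] == "A"]
            b = sub[sub["scenario"] == "B"]
            rows.append(
                {
                    "method_set": ms.label,
                    "pct_confirmed_A": float((a["decision"] == "confirmed").mean() * 100.0)
                    if len(a)
                    else float("nan"),
                    "pct_rejected_B": float((b["decision"] == "rejected").mean() * 100.0)
                    if len(b)
                    else float("nan"),
                }
            )
        rows.append(
            {
                "method_set": "RDM",
                "pct_confirmed_A": random_baseline_confirm(self.n_sites),
                "pct_rejected_B": random_baseline_reject(self.n_sites),
            }
        )
        return pd.DataFrame(rows).set_index("method_set")

    def summary(self) -> str:
        rates = self.rates()
        n = self.outcomes[self.outcomes["scenario"] == "A"]["tree_id"].nunique()
        lines = [
            "Origin verification experiment",
            "------------------------------",
            f"test trees: {n}; sites: {self.n_sites}",
            "",
            f"{'method set':<12} {'% confirmed (A)':>16} {'% rejected (B)':>15}",
        ]
        for label, row in rates.iterrows():
            lines.append(
                f"{label:<12} {row['pct_confirmed_A']:>16.1f} {row['pct_rejected_B']:>15.1f}"
            )
        return "\n".join(lines)


class SiteVerificationModel:
    """Both verification scenarios over a random subset of eligible trees.

    The same ``n_test`` trees are evaluated under scenario A (true claim) and
    scenario B (false claim drawn uniformly from the other sites) for every
    method set.
    """

    def __init__(
        self,
        dataset: TraceDataset,
        method_sets: Sequence[MethodSet] = ALL_METHOD_SETS,
        n_test: int = 41,
        n_trees: int = 500,
        scenarios: Sequence[str] = ("A", "B"),
    ) -> None:
        self.dataset = dataset
        self.method_sets = tuple(MethodSet(ms) for ms in method_sets)
        self.n_test = int(n_test)
        self.n_trees = int(n_trees)
        if not set(scenarios) <= {"A", "B"} or not scenarios:
            raise ValidationError("scenarios must be a non-empty subset of {'A', 'B'}")
        self.scenarios = tuple(scenarios)

    def fit(self, seed: int = 0) -> VerificationResults:
        d = self.dataset
        pool = eligible_trees(d)
        if len(pool) < self.n_test:
            raise ValidationError(
                f"only {len(pool)} eligible trees; cannot draw {self.n_test}"
            )
        rng = np.random.default_rng([int(seed), 0x5EED])
        chosen = sorted(rng.choice(pool, size=self.n_test, replace=False))
        site_ids = list(d.sites.index)
        rows = []
        for i, tree_id in enumerate(chosen):
            true_site = d.trees.loc[tree_id, "site_id"]
            others = [s for s in site_ids if s != true_site]
            claimed = str(rng.choice(others))
            for k, ms in enumerate(self.method_sets):
                rf_seed = int(
                    np.random.SeedSequence([int(seed), i, k]).generate_state(1)[0] % (2**31)
                )
                if "A" in self.scenarios:
                    rows.append(
                        vars(verify_true_claim(d, tree_id, ms, seed=rf_seed, n_trees=self.n_trees))
                    )
                if "B" in self.scenarios:
                    rows.append(
                        vars(
                            reject_false_claim(
                                d, tree_id, claimed, ms, seed=rf_seed + 1, n_trees=self.n_trees
                            )
                        )
                    )
        return VerificationResults(
            outcomes=pd.DataFrame(rows),
            method_sets=self.method_sets,
            n_sites=d.n_sites,
        )


def run_verification_experiment(
    d: TraceDataset,
    n_test: int = 41,
    seed: int = 0,
    method_sets: Sequence[MethodSet] = ALL_METHOD_SETS,
    n_trees: int = 500,
) -> VerificationResults:
    """Functional wrapper over SiteVerificationModel(...).fit(seed)."""
    return SiteVerificationModel(
        d, method_sets=method_sets, n_test=n_test, n_trees=n_trees
    ).fit(seed=seed)
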