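"""Between-site variation: genetic and chemical distance matrices and
distance-based redundancy analysis (db-RDA) with a permutation test.

For the haploid SNP matrix the distance is 1 minus the proportion of shared
alleles, which with one allele per locus is the mismatch proportion over
jointly observed loci (pairwise deletion). Chemical tables use the chord
distance: Euclidean distance between rows scaled to unit Euclidean norm.
Isotope tables contain negative per-mil values, for which the chord norm has
no compositional meaning, so they are range-standardized to [0, 1] per
variable first (configurable).

db-RDA: principal-coordinate decomposition of the Gower-centred squared
distance matrix (axes with positive eigenvalues retained), least-squares
projection of the coordinates onto site indicator variables, pseudo-F from
the constrained vs residual sums of squares, and a free permutation of rows
for the p-value with the add-one convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import GeneticMatrix, MISSING, ValidationError

__all__ = [
    "DistanceMatrix",
    "DbRDAResults",
    "DbRDA",
    "psa_distance_matrix",
    "chord_distance_matrix",
    "dbrda_site_test",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal, indexed by id."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValidationError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.all(np.isfinite(v)):
            raise ValidationError("distance matrix contains non-finite entries")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise ValidationError("distance matrix has negative entries")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path: str | os.PathLike) -> None:
        df = self.to_frame()
        df.index.name = "id"
        df.to_csv(path)

    def to_phylip(self, path: str | os.PathLike) -> None:
        """PHYLIP-style lower-triangle text export."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{self.values[i, j]:.6f}" for j in range(i))
                fh.write(f"{name} {row}".rstrip() + "\n")


def psa_distance_matrix(m: GeneticMatrix) -> DistanceMatrix:
    """1 - proportion of shared alleles between haploid profiles.

    Computed over jointly observed loci only; a pair with no jointly observed
    locus is an error naming the pair.
    """
    calls = m.calls
    obs = (calls != MISSING).astype(np.int32)
    joint = obs @ obs.T  # jointly observed locus counts
    if (joint == 0).any():
        i, j = np.argwhere(joint == 0)[0]
        raise ValidationError(
            f"trees {m.trees[i]!r} and {m.trees[j]!r} share no observed loci"
        )
    masked = np.where(calls == MISSING, 0, calls).astype(np.int32)
    # matches at jointly observed loci: both 1, or both 0
    both1 = masked @ masked.T
    inv = np.where(calls == MISSING, 0, 1 - calls).astype(np.int32)
    both0 = inv @ inv.T
    d = (joint - (both0 + both1)) / joint  # mismatch proportion, exact
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(m.trees), d)


def chord_distance_matrix(
    t: pd.DataFrame, range_standardize: bool = False
) -> DistanceMatrix:
    """Euclidean distance between rows scaled to unit norm.

    With ``range_standardize`` each column is first mapped to [0, 1] over its
    observed range — required for tables with negative values such as delta
    2H — plus a uniform 1e-6 shift so a row at the minimum of every variable
    does not degenerate to the (un-normalizable) zero vector.
    """
    x = t.astype(float).to_numpy()
    if np.isnan(x).any():
        raise ValidationError("chord distance requires a complete table")
    if range_standardize:
        lo = x.min(axis=0)
        rng = x.max(axis=0) - lo
        rng[rng == 0] = 1.0
        x = (x - lo) / rng + 1e-6
    norms = np.linalg.norm(x, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValidationError(f"all-zero row(s) at index {[t.index[i] for i in zero[:5]]}")
    u = x / norms[:, None]
    gram = np.clip(u @ u.T, -1.0, 1.0)
    d2 = np.maximum(0.0, 2.0 - 2.0 * gram)
    d = np.sqrt(d2)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix([str(i) for i in t.index], d)


@dataclass
class DbRDAResults:
    """Fitted db-RDA site test.

    pseudo_F is the ratio of constrained to residual mean squares in the
    principal-coordinate space; p_value is the add-one permutation p; the
    axis_variance entries are the proportions of total (retained) variance
    explained by each constrained axis.
    """

    pseudo_F: float
    p_value: float
    n_permutations: int
    axis_variance: np.ndarray
    df_constrained: int
    df_residual: int
    constrained_proportion: float

    def summary(self) -> str:
        lines = [
            "db-RDA site test",
            "----------------",
            f"pseudo-F ({self.df_constrained}, {self.df_residual} df): {self.pseudo_F:.4f}",
            f"permutation p ({self.n_permutations} permutations): {self.p_value:.4g}",
            f"constrained variance proportion: {self.constrained_proportion:.4f}",
        ]
        for k, v in enumerate(self.axis_variance[:5], start=1):
            lines.append(f"  CAP{k}: {v * 100:.1f}% of total variance")
        return "\n".join(lines)


class DbRDA:
    """Distance-based redundancy analysis of a distance matrix on site labels.

    Parameters
    ----------
    distance : DistanceMatrix
        Pairwise distances between observations.
    labels : sequence of str
        Site identity per observation, aligned with ``distance.ids``.
    """

    def __init__(self, distance: DistanceMatrix, labels) -> None:
        self.distance = distance
        labels = pd.Series(list(labels), index=distance.ids)
        if len(labels) != len(distance.ids):
            raise ValidationError("labels length does not match distance matrix")
        self.labels = labels
        groups = labels.unique()
        if len(groups) < 2:
            raise ValidationError("db-RDA needs at least two sites")
        if len(labels) < 3:
            raise ValidationError("db-RDA needs at least three observations")
        sizes = labels.value_counts()
        if (sizes == 1).any():
            import warnings

            warnings.warn(
                f"site(s) {sizes[sizes == 1].index.tolist()} have a single "
                "observation; residual degrees of freedom are small"
            )
        self._groups = sorted(groups)

    def _pcoa_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Coordinates on PCoA axes with eigenvalues > 1e-8 x the largest."""
        d = self.distance.values
        n = d.shape[0]
        a = -0.5 * d**2
        j = np.eye(n) - np.ones((n, n)) / n
        g = j @ a @ j
        eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        keep = eigval > 1e-8 * max(eigval.max(), 0.0)
        if not keep.any():
            raise ValidationError("no positive PCoA eigenvalues; distances degenerate")
        coords = eigvec[:, keep] * np.sqrt(eigval[keep])
        return coords, eigval[keep]

    def fit(self, n_permutations: int = 999, seed: int | None = 0) -> DbRDAResults:
        """Run the site test with ``n_permutations`` free row permutations."""
        coords, eigvals = self._pcoa_coordinates()
        n = coords.shape[0]
        groups = np.asarray(self.labels)
        g = len(self._groups)
        df_c, df_r = g - 1, n - g
        if df_r <= 0:
            raise ValidationError("no residual degrees of freedom")
        y = coords - coords.mean(axis=0)
        ss_total = float((y**2).sum())
        # one-hot site indicator; constrained SS = sum_g n_g ||group mean||^2
        gindex = np.searchsorted(np.array(self._groups), groups)
        onehot = np.zeros((g, n))
        onehot[gindex, np.arange(n)] = 1.0
        inv_ng = 1.0 / onehot.sum(axis=1)

        def constrained_ss(rows: np.ndarray) -> float:
            m = onehot @ y[rows]
            return float(((m**2) * inv_ng[:, None]).sum())

        identity = np.arange(n)
        ss_c = constrained_ss(identity)
        ss_r = ss_total - ss_c
        f_obs = (ss_c / df_c) / (ss_r / df_r)

        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            ss_cp = constrained_ss(perm)
            f_p = (ss_cp / df_c) / ((ss_total - ss_cp) / df_r)
            if f_p >= f_obs:
                exceed += 1
        p = (1 + exceed) / (1 + n_permutations)

        # constrained axes: eigen-decomposition of the fitted values
        x = pd.get_dummies(pd.Series(groups)).to_numpy(dtype=float)
        x = x - x.mean(axis=0)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        fitted = x @ beta
        sv = np.linalg.svd(fitted, compute_uv=False)
        axis_var = (sv**2) / ss_total
        axis_var = axis_var[axis_var > 1e-12]

        return DbRDAResults(
            pseudo_F=float(f_obs),
            p_value=float(p),
            n_permutations=int(n_permutations),
            axis_variance=axis_var,
            df_constrained=df_c,
            df_residual=df_r,
            constrained_proportion=float(ss_c / ss_total),
        )


def dbrda_site_test(
    d: DistanceMatrix, site_labels, n_permutations: int = 999, seed: int | None = 0
) -> DbRDAResults:
    """Convenience wrapper: DbRDA(d, labels).fit(...)."""
    return DbRDA(d, site_labels).fit(n_permutations=n_permutations, seed=seed)
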