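"""Core domain types for multi-proxy timber tracing.

A tracing dataset joins, on a shared universe of tree ids, three reference
databases measured on geolocated trees: a haploid biallelic SNP matrix from
the plastid genome, a stable-isotope table (delta 18O, delta 2H, delta 34S in
per mil), and a multi-element concentration table (g/kg). Sites are groups of
trees; a site's location is the centroid of its trees' GPS coordinates, and
all between-site distances are great-circle distances on those centroids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "ISOTOPES",
    "METHODS",
    "ALL_METHOD_SETS",
    "ValidationError",
    "FormatError",
    "Site",
    "TreeRecord",
    "GeneticMatrix",
    "IsotopeTable",
    "ElementTable",
    "TraceDataset",
    "MethodSet",
    "haversine_km",
    "site_centroid",
]

#: Sentinel for a missing haploid allele call.
MISSING: int = -1

#: Canonical isotope column order (per mil vs V-SMOW, V-SMOW, CDT).
ISOTOPES: tuple[str, ...] = ("d18O", "d2H", "d34S")

#: The three forensic methods.
METHODS: tuple[str, ...] = ("SNP", "ISO", "EL")

EARTH_RADIUS_KM = 6371.0


class ValidationError(ValueError):
    """A domain invariant is violated (duplicate ids, broken references...)."""


class FormatError(ValueError):
    """An input file does not meet the declared format contract."""


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km between two WGS84 points (R = 6371 km).

    Raises
    ------
    ValidationError
        If any coordinate is outside [-90, 90] latitude / [-180, 180] longitude.
    """
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValidationError(f"latitude {lat!r} outside [-90, 90]")
    for lon in (lon1, lon2):
        if not -180.0 <= lon <= 180.0:
            raise ValidationError(f"longitude {lon!r} outside [-180, 180]")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def site_centroid(lats: Sequence[float], lons: Sequence[float]) -> tuple[float, float]:
    """Arithmetic-mean centroid of tree coordinates, used as the site location."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if lats.size == 0 or lats.size != lons.size:
        raise ValidationError("centroid requires at least one (lat, lon) pair")
    return float(lats.mean()), float(lons.mean())


@dataclass(frozen=True)
class Site:
    site_id: str
    country: str
    lat: float
    lon: float
    n_trees: int = 0

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"site {self.site_id}: latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValidationError(f"site {self.site_id}: longitude {self.lon} outside [-180, 180]")


@dataclass(frozen=True)
class TreeRecord:
    tree_id: str
    site_id: str
    lat: float
    lon: float
    dbh_cm: float | None = None


class MethodSet(frozenset):
    """A non-empty subset of {SNP, ISO, EL}; exactly seven values exist."""

    def __new__(cls, methods: Iterable[str]):
        obj = super().__new__(cls, methods)
        unknown = obj - set(METHODS)
        if unknown:
            raise ValidationError(f"unknown methods: {sorted(unknown)}")
        if not obj:
            raise ValidationError("method set must be non-empty")
        return obj

    @property
    def label(self) -> str:
        return "+".join(m for m in METHODS if m in self)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MethodSet({self.label})"


#: The seven model categories, singles first, then pairs, then all three.
ALL_METHOD_SETS: tuple[MethodSet, ...] = (
    MethodSet({"SNP"}),
    MethodSet({"ISO"}),
    MethodSet({"EL"}),
    MethodSet({"SNP", "ISO"}),
    MethodSet({"SNP", "EL"}),
    MethodSet({"ISO", "EL"}),
    MethodSet({"SNP", "ISO", "EL"}),
)


class GeneticMatrix:
    """Haploid biallelic SNP calls: trees x loci, values in {0, 1, MISSING}."""

    def __init__(
        self,
        trees: Sequence[str],
        loci: Sequence[str],
        calls: np.ndarray,
        positions: Sequence[int] | None = None,
    ) -> None:
        self.trees = list(trees)
        self.loci = list(loci)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(self.trees), len(self.loci)):
            raise ValidationError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(self.trees)} trees x {len(self.loci)} loci"
            )
        bad = ~np.isin(calls, (0, 1, MISSING))
        if bad.any():
            raise ValidationError("allele calls must be 0, 1 or MISSING")
        if len(set(self.trees)) != len(self.trees):
            raise ValidationError("duplicate tree_id in genetic matrix")
        if len(set(self.loci)) != len(self.loci):
            raise ValidationError("duplicate locus id in genetic matrix")
        self.calls = calls
        self.positions = (
            np.asarray(positions, dtype=np.int64)
            if positions is not None
            else np.arange(1, len(self.loci) + 1, dtype=np.int64)
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    @property
    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def tree_missing_fraction(self) -> pd.Series:
        return pd.Series(self.missing_mask.mean(axis=1), index=self.trees)

    def locus_missing_fraction(self) -> pd.Series:
        return pd.Series(self.missing_mask.mean(axis=0), index=self.loci)

    def subset(self, trees: Sequence[str] | None = None, loci: Sequence[str] | None = None) -> "GeneticMatrix":
        trees = self.trees if trees is None else list(trees)
        loci = self.loci if loci is None else list(loci)
        ti = [self.trees.index(t) for t in trees]
        li = [self.loci.index(l) for l in loci]
        return GeneticMatrix(trees, loci, self.calls[np.ix_(ti, li)], self.positions[li])

    def to_frame(self) -> pd.DataFrame:
        """0/1 calls as a DataFrame with NaN for missing."""
        df = pd.DataFrame(self.calls.astype(float), index=self.trees, columns=self.loci)
        return df.mask(df < 0)

    def copy(self) -> "GeneticMatrix":
        return GeneticMatrix(self.trees, self.loci, self.calls.copy(), self.positions.copy())

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GeneticMatrix)
            and self.trees == other.trees
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
            and np.array_equal(self.positions, other.positions)
        )


class IsotopeTable:
    """Per-tree stable-isotope ratios in per mil; NaN marks an unmeasured cell."""

    def __init__(self, data: pd.DataFrame) -> None:
        missing_cols = [c for c in ISOTOPES if c not in data.columns]
        if missing_cols:
            raise ValidationError(f"isotope table lacks columns {missing_cols}")
        if data.index.has_duplicates:
            raise ValidationError("duplicate tree_id in isotope table")
        data = data.loc[:, list(ISOTOPES)].astype(float)
        if np.isinf(data.to_numpy()).any():
            raise ValidationError("isotope values must be finite where measured")
        self.data = data

    @property
    def measured(self) -> pd.DataFrame:
        return self.data.notna()

    def copy(self) -> "IsotopeTable":
        return IsotopeTable(self.data.copy())


class ElementTable:
    """Per-tree element concentrations (g/kg) with per-cell below-detection flags.

    ``data`` holds measured concentrations (NaN = not measured), ``below_detection``
    flags cells reported under the element's detection limit, and
    ``detection_limits`` gives that limit per element.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        below_detection: pd.DataFrame | None = None,
        detection_limits: pd.Series | None = None,
    ) -> None:
        if data.index.has_duplicates:
            raise ValidationError("duplicate tree_id in element table")
        if data.columns.has_duplicates:
            raise ValidationError("duplicate element name in element table")
        data = data.astype(float)
        vals = data.to_numpy()
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError("element concentrations must be >= 0")
        self.data = data
        if below_detection is None:
            below_detection = pd.DataFrame(False, index=data.index, columns=data.columns)
        self.below_detection = below_detection.reindex_like(data).fillna(False).astype(bool)
        if detection_limits is None:
            detection_limits = pd.Series(0.0, index=data.columns)
        self.detection_limits = detection_limits.reindex(data.columns).fillna(0.0).astype(float)

    @property
    def elements(self) -> list[str]:
        return list(self.data.columns)

    def below_detection_counts(self) -> pd.Series:
        return self.below_detection.sum(axis=0)

    def copy(self) -> "ElementTable":
        return ElementTable(self.data.copy(), self.below_detection.copy(), self.detection_limits.copy())


@dataclass
class TraceDataset:
    """Aligned multi-proxy reference database plus site metadata.

    Every proxy table is indexed by tree ids drawn from ``trees``; a tree may be
    absent from a proxy (not every tree was measured with every method) but a
    proxy may not mention a tree unknown to the tree table.
    """

    sites: pd.DataFrame  # index site_id; columns country, lat, lon, n_trees
    trees: pd.DataFrame  # index tree_id; columns site_id, lat, lon, dbh_cm
    genetics: GeneticMatrix
    isotopes: IsotopeTable
    elements: ElementTable
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.sites.index.has_duplicates:
            raise ValidationError("duplicate site_id")
        if self.trees.index.has_duplicates:
            dups = self.trees.index[self.trees.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate tree_id: {dups}")
        unknown_sites = set(self.trees["site_id"]) - set(self.sites.index)
        if unknown_sites:
            raise ValidationError(f"trees reference unknown sites: {sorted(unknown_sites)}")
        universe = set(self.trees.index)
        for name, ids in (
            ("genetics", self.genetics.trees),
            ("isotopes", self.isotopes.data.index),
            ("elements", self.elements.data.index),
        ):
            orphans = set(ids) - universe
            if orphans:
                raise ValidationError(f"{name} table contains unknown tree_id(s): {sorted(orphans)}")
        for site_id, lat, lon in self.sites[["lat", "lon"]].itertuples():
            Site(site_id, "", float(lat), float(lon))  # range check

    @property
    def site_ids(self) -> list[str]:
        return list(self.sites.index)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_of(self, tree_ids: Iterable[str]) -> pd.Series:
        return self.trees.loc[list(tree_ids), "site_id"]

    def site_labels(self) -> pd.Series:
        return self.trees["site_id"]

    def site_distance_km(self, a: str, b: str) -> float:
        ra, rb = self.sites.loc[a], self.sites.loc[b]
        return haversine_km(ra["lat"], ra["lon"], rb["lat"], rb["lon"])

    def site_distance_matrix(self) -> pd.DataFrame:
        ids = self.site_ids
        out = pd.DataFrame(0.0, index=ids, columns=ids)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                d = self.site_distance_km(a, b)
                out.loc[a, b] = out.loc[b, a] = d
        return out

    def recompute_site_centroids(self) -> None:
        """Set each site's location to the centroid of its trees' coordinates."""
        for site_id, grp in self.trees.groupby("site_id"):
            lat, lon = site_centroid(grp["lat"].to_numpy(), grp["lon"].to_numpy())
            self.sites.loc[site_id, ["lat", "lon"]] = (lat, lon)
            self.sites.loc[site_id, "n_trees"] = len(grp)

    def copy(self) -> "TraceDataset":
        return TraceDataset(
            self.sites.copy(),
            self.trees.copy(),
            self.genetics.copy(),
            self.isotopes.copy(),
            self.elements.copy(),
            dict(self.provenance),
        )
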