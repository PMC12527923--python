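"""Reading and writing tracing datasets.

On disk a dataset is a directory of plain-text files: ``sites.csv``,
``trees.csv``, ``isotopes.csv``, ``elements.csv`` (plus the element
below-detection flag matrix and detection limits), and the SNP matrix either
as a haploid VCF (``genetics.vcf``, biallelic records only, genotypes ``0``,
``1`` or ``.``) or as a 0/1/empty CSV. CSVs are UTF-8, comma-separated, with a
header row; an empty cell means missing.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam
import yaml

from .datamodel import (
    ISOTOPES,
    MISSING,
    ElementTable,
    FormatError,
    GeneticMatrix,
    IsotopeTable,
    TraceDataset,
    ValidationError,
)

__all__ = [
    "load_dataset",
    "load_dataset_from_config",
    "save_dataset",
    "read_genetics_vcf",
    "write_genetics_vcf",
    "read_genetics_csv",
    "write_genetics_csv",
]

_CONTIG = "plastid"
_CONTIG_LEN = 1_000_000


def read_genetics_vcf(path: str | os.PathLike) -> GeneticMatrix:
    """Read a haploid, biallelic-only VCF into a GeneticMatrix.

    Raises FormatError naming the offending record for multiallelic or diploid
    entries; allele codes are 0-based (0 = REF, 1 = ALT), ``.`` = missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        loci: list[str] = []
        positions: list[int] = []
        columns: list[np.ndarray] = []
        for rec in vcf:
            name = rec.id or f"{rec.chrom}:{rec.pos}"
            if rec.alts is None or len(rec.alts) != 1:
                raise FormatError(f"record {name} is not biallelic")
            col = np.empty(len(samples), dtype=np.int8)
            for i, sample in enumerate(samples):
                gt = rec.samples[sample].get("GT", (None,))
                alleles = [a for a in gt if a is not None]
                if len(alleles) > 1:
                    raise FormatError(f"record {name}, sample {sample}: diploid genotype")
                col[i] = alleles[0] if alleles else MISSING
            loci.append(name)
            positions.append(rec.pos)
            columns.append(col)
    if not loci:
        raise FormatError(f"{path}: VCF contains no variant records")
    calls = np.column_stack(columns)
    return GeneticMatrix(samples, loci, calls, positions)


def write_genetics_vcf(m: GeneticMatrix, path: str | os.PathLike) -> None:
    """Write a GeneticMatrix as an uncompressed haploid VCF (REF=A, ALT=T)."""
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={_CONTIG},length={_CONTIG_LEN}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for tree in m.trees:
        header.add_sample(tree)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, locus in enumerate(m.loci):
            rec = vcf.new_record(
                contig=_CONTIG,
                start=int(m.positions[j]) - 1,
                alleles=("A", "T"),
                id=locus,
            )
            for i, tree in enumerate(m.trees):
                call = int(m.calls[i, j])
                rec.samples[tree]["GT"] = (None,) if call == MISSING else (call,)
            vcf.write(rec)


def read_genetics_csv(path: str | os.PathLike) -> GeneticMatrix:
    """Read a 0/1/empty SNP matrix CSV (rows = trees, columns = loci)."""
    df = pd.read_csv(path, index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate tree_id in {path}: {dups}")
    calls = np.full(df.shape, MISSING, dtype=np.int8)
    vals = df.to_numpy()
    for code in (0, 1):
        calls[vals == str(code)] = code
    known = pd.isna(vals) | (vals == "") | (vals == "0") | (vals == "1")
    if not known.all():
        bad = vals[~known][0]
        raise FormatError(f"{path}: allele call {bad!r} is not 0, 1 or empty")
    return GeneticMatrix(list(df.index), list(df.columns), calls)


def write_genetics_csv(m: GeneticMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        np.where(m.calls == MISSING, "", m.calls.astype(str)),
        index=pd.Index(m.trees, name="tree_id"),
        columns=m.loci,
    )
    df.to_csv(path)


def _read_csv_indexed(path: str | os.PathLike, index_name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if index_name not in df.columns:
        raise FormatError(f"{path}: missing required column {index_name!r}")
    if df[index_name].duplicated().any():
        dups = df.loc[df[index_name].duplicated(), index_name].unique().tolist()
        raise ValidationError(f"duplicate {index_name} in {path}: {dups}")
    return df.set_index(index_name)


def load_dataset(
    sites: str | os.PathLike,
    trees: str | os.PathLike,
    genetics: str | os.PathLike,
    isotopes: str | os.PathLike,
    elements: str | os.PathLike,
    element_flags: str | os.PathLike | None = None,
    element_limits: str | os.PathLike | None = None,
    provenance: Mapping | None = None,
) -> TraceDataset:
    """Assemble a TraceDataset from its on-disk parts.

    The genetics path may be a VCF (``.vcf``) or a 0/1 CSV. Trees appearing in
    a proxy table but absent from the tree table are rejected with a
    ValidationError listing the offending ids.
    """
    sites_df = _read_csv_indexed(sites, "site_id")
    for col in ("lat", "lon"):
        if col not in sites_df.columns:
            raise FormatError(f"{sites}: missing required column {col!r}")
    if "country" not in sites_df.columns:
        sites_df["country"] = ""
    trees_df = _read_csv_indexed(trees, "tree_id")
    for col in ("site_id", "lat", "lon"):
        if col not in trees_df.columns:
            raise FormatError(f"{trees}: missing required column {col!r}")
    if "dbh_cm" not in trees_df.columns:
        trees_df["dbh_cm"] = np.nan

    genetics = Path(genetics)
    if genetics.suffix.lower() == ".vcf":
        gmat = read_genetics_vcf(genetics)
    else:
        gmat = read_genetics_csv(genetics)

    iso = IsotopeTable(_read_csv_indexed(isotopes, "tree_id"))

    el_df = _read_csv_indexed(elements, "tree_id")
    flags = None
    if element_flags is not None and Path(element_flags).exists():
        flags = _read_csv_indexed(element_flags, "tree_id").astype(bool)
    limits = None
    if element_limits is not None and Path(element_limits).exists():
        lim_df = pd.read_csv(element_limits)
        limits = lim_df.set_index("element")["detection_limit"]
    el = ElementTable(el_df, flags, limits)

    if "n_trees" not in sites_df.columns:
        sites_df["n_trees"] = trees_df.groupby("site_id").size().reindex(sites_df.index).fillna(0).astype(int)

    return TraceDataset(
        sites=sites_df,
        trees=trees_df,
        genetics=gmat,
        isotopes=iso,
        elements=el,
        provenance=dict(provenance or {}),
    )


def load_dataset_from_config(config_path: str | os.PathLike) -> TraceDataset:
    """Load a dataset from a YAML file mapping table names to paths.

    Relative paths are resolved against the YAML file's directory.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    base = config_path.parent

    def _resolve(key: str, required: bool = True):
        val = cfg.get(key)
        if val is None:
            if required:
                raise FormatError(f"{config_path}: missing required key {key!r}")
            return None
        return base / val

    return load_dataset(
        sites=_resolve("sites"),
        trees=_resolve("trees"),
        genetics=_resolve("genetics"),
        isotopes=_resolve("isotopes"),
        elements=_resolve("elements"),
        element_flags=_resolve("element_flags", required=False),
        element_limits=_resolve("element_limits", required=False),
        provenance={"config": str(config_path)},
    )


def save_dataset(
    d: TraceDataset, outdir: str | os.PathLike, genetics_format: str = "vcf"
) -> dict[str, Path]:
    """Write a TraceDataset to a directory of CSV/VCF files.

    Returns the mapping of table name to file path; a ``dataset.yaml`` config
    usable by :func:`load_dataset_from_config` is written alongside.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    sites = d.sites.copy()
    sites.index.name = "site_id"
    paths["sites"] = outdir / "sites.csv"
    sites.to_csv(paths["sites"])

    trees = d.trees.copy()
    trees.index.name = "tree_id"
    paths["trees"] = outdir / "trees.csv"
    trees.to_csv(paths["trees"])

    if genetics_format == "vcf":
        paths["genetics"] = outdir / "genetics.vcf"
        write_genetics_vcf(d.genetics, paths["genetics"])
    elif genetics_format == "csv":
        paths["genetics"] = outdir / "genetics.csv"
        write_genetics_csv(d.genetics, paths["genetics"])
    else:
        raise ValueError(f"unknown genetics format {genetics_format!r}")

    iso = d.isotopes.data.copy()
    iso.index.name = "tree_id"
    paths["isotopes"] = outdir / "isotopes.csv"
    iso.to_csv(paths["isotopes"])

    el = d.elements.data.copy()
    el.index.name = "tree_id"
    paths["elements"] = outdir / "elements.csv"
    el.to_csv(paths["elements"])

    flags = d.elements.below_detection.astype(int).copy()
    flags.index.name = "tree_id"
    paths["element_flags"] = outdir / "elements_below_detection.csv"
    flags.to_csv(paths["element_flags"])

    limits = d.elements.detection_limits.rename("detection_limit").copy()
    limits.index.name = "element"
    paths["element_limits"] = outdir / "element_detection_limits.csv"
    limits.to_csv(paths["element_limits"])

    cfg = {name: p.name for name, p in paths.items()}
    with open(outdir / "dataset.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    paths["config"] = outdir / "dataset.yaml"
    return paths
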