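"""One reproducible run: simulate/load -> preprocess -> ordination ->
identification -> verification, with every table written as CSV and a run
manifest (seed, config, versions) that suffices to reproduce the outputs.

A single global seed fans out into named substreams per stage, so each stage
is independently reproducible. Numeric CSV output uses 6 significant digits;
percentage tables one decimal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datamodel import ALL_METHOD_SETS, MethodSet, TraceDataset
from .io import load_dataset_from_config, save_dataset
from .ordination import chord_distance_matrix, dbrda_site_test, psa_distance_matrix
from .preprocess import filter_elements_by_detection, filter_genetic_matrix
from .assignment import (
    DEFAULT_BIN_EDGES,
    IdentificationResults,
    SiteIdentificationModel,
)
from .simulate import GeneratorConfig, generate_dataset
from .verification import SiteVerificationModel, VerificationResults

__all__ = ["RunConfig", "run_pipeline", "export_figures", "preprocess_dataset"]

logger = logging.getLogger("timbertrace")

_STAGE_SEEDS = {"simulate": 0, "ordinate": 1, "identify": 2, "verify": 3}


def _stage_seed(seed: int, stage: str) -> int:
    return int(
        np.random.SeedSequence([int(seed), _STAGE_SEEDS[stage]]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    outdir: str = "timbertrace_run"
    seed: int = 0
    simulate: dict | None = None  # GeneratorConfig overrides; None -> load data
    data: str | None = None  # path to a dataset.yaml; ignored if simulate is set
    n_repeats: int = 25
    test_fraction: float = 0.5
    n_test: int = 41
    n_trees: int = 500
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    method_sets: tuple[str, ...] = tuple(ms.label for ms in ALL_METHOD_SETS)
    dbrda_permutations: int = 999
    max_ind_missing: float = 0.50
    max_locus_missing: float = 0.25
    max_below_detection: int = 100
    figures: bool = False

    def __post_init__(self) -> None:
        if self.simulate is None and self.data is None:
            self.simulate = {}
        self.bin_edges = tuple(float(e) for e in self.bin_edges)
        self.method_sets = tuple(self.method_sets)
        for label in self.method_sets:
            MethodSet(label.split("+"))
        if self.n_repeats < 1 or self.n_trees < 1:
            raise ValueError("n_repeats and n_trees must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(**cfg)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bin_edges"] = list(self.bin_edges)
        d["method_sets"] = list(self.method_sets)
        return d

    def resolved_method_sets(self) -> tuple[MethodSet, ...]:
        return tuple(MethodSet(label.split("+")) for label in self.method_sets)


def preprocess_dataset(d: TraceDataset, config: RunConfig | None = None):
    """Apply the dataset-level hygiene filters; returns (dataset, audit frame)."""
    config = config or RunConfig()
    gmat, greport = filter_genetic_matrix(
        d.genetics, config.max_ind_missing, config.max_locus_missing
    )
    etab, ereport = filter_elements_by_detection(d.elements, config.max_below_detection)
    out = TraceDataset(
        sites=d.sites.copy(),
        trees=d.trees.copy(),
        genetics=gmat,
        isotopes=d.isotopes.copy(),
        elements=etab,
        provenance=dict(d.provenance),
    )
    audit = pd.concat([greport.to_frame(), ereport.to_frame()], ignore_index=True)
    return out, audit


def _write_csv(df: pd.DataFrame, path: Path, float_format: str = "%.6g") -> None:
    df.to_csv(path, float_format=float_format)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages and write artifacts; returns the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)

    # --- load or simulate -------------------------------------------------
    if config.simulate is not None:
        gen_cfg = GeneratorConfig(**{**config.simulate, "seed": _stage_seed(config.seed, "simulate")})
        dataset = generate_dataset(gen_cfg)
        logger.info("simulated dataset: %d sites, %d trees, %d loci, %d elements",
                    dataset.n_sites, len(dataset.trees), len(dataset.genetics.loci),
                    len(dataset.elements.elements))
        save_dataset(dataset, outdir / "dataset")
    else:
        dataset = load_dataset_from_config(config.data)
        logger.info("loaded dataset from %s: %d sites, %d trees", config.data,
                    dataset.n_sites, len(dataset.trees))

    # --- preprocess -------------------------------------------------------
    dataset, audit = preprocess_dataset(dataset, config)
    _write_csv(audit.set_index("kind"), outdir / "filter_audit.csv")
    logger.info("after filters: %d x %d genetic matrix, %d elements",
                *dataset.genetics.shape, len(dataset.elements.elements))

    # --- ordination -------------------------------------------------------
    ord_seed = _stage_seed(config.seed, "ordinate")
    ord_rows = []
    labels = dataset.site_labels()
    psa = psa_distance_matrix(dataset.genetics)
    psa.to_csv(outdir / "distance_psa.csv")
    res = dbrda_site_test(psa, labels.loc[psa.ids], config.dbrda_permutations, ord_seed)
    ord_rows.append({"proxy": "SNP", "pseudo_F": res.pseudo_F, "p_value": res.p_value,
                     "constrained_proportion": res.constrained_proportion})
    iso_complete = dataset.isotopes.data.dropna()
    if len(iso_complete) >= 3 and labels.loc[iso_complete.index].nunique() >= 2:
        chord_iso = chord_distance_matrix(iso_complete, range_standardize=True)
        res = dbrda_site_test(chord_iso, labels.loc[iso_complete.index],
                              config.dbrda_permutations, ord_seed + 1)
        ord_rows.append({"proxy": "ISO", "pseudo_F": res.pseudo_F, "p_value": res.p_value,
                         "constrained_proportion": res.constrained_proportion})
    el_complete = dataset.elements.data.dropna()
    chord_el = chord_distance_matrix(el_complete)
    res = dbrda_site_test(chord_el, labels.loc[el_complete.index],
                          config.dbrda_permutations, ord_seed + 2)
    ord_rows.append({"proxy": "EL", "pseudo_F": res.pseudo_F, "p_value": res.p_value,
                     "constrained_proportion": res.constrained_proportion})
    _write_csv(pd.DataFrame(ord_rows).set_index("proxy"), outdir / "dbrda.csv")
    logger.info("ordination: %d db-RDA tests", len(ord_rows))

    # --- identification ---------------------------------------------------
    model = SiteIdentificationModel(
        dataset,
        method_sets=config.resolved_method_sets(),
        n_repeats=config.n_repeats,
        test_fraction=config.test_fraction,
        n_trees=config.n_trees,
        bin_edges=config.bin_edges,
    )
    ident = model.fit(seed=_stage_seed(config.seed, "identify"), collect_importances=True)
    _write_csv(ident.assignments.set_index("tree_id"), outdir / "assignments.csv")
    _write_csv(ident.accuracy_summary(), outdir / "accuracy.csv", "%.1f")
    _write_csv(ident.distance_bins().rename_axis("bin"), outdir / "distance_bins.csv", "%.1f")
    for ms in ident.method_sets:
        _write_csv(ident.confusion(ms), outdir / f"confusion_{ms.label.replace('+', '-')}.csv")
        if ms.label in ident.importances:
            _write_csv(ident.importances[ms.label].set_index("feature"),
                       outdir / f"importance_{ms.label.replace('+', '-')}.csv")
    logger.info("identification: %d repeats x %d method sets = %d model fits, %d assignments",
                config.n_repeats, len(ident.method_sets),
                config.n_repeats * len(ident.method_sets), len(ident.assignments))

    # --- verification -----------------------------------------------------
    verifier = SiteVerificationModel(
        dataset,
        method_sets=config.resolved_method_sets(),
        n_test=config.n_test,
        n_trees=config.n_trees,
    )
    verif = verifier.fit(seed=_stage_seed(config.seed, "verify"))
    _write_csv(verif.outcomes.set_index("tree_id"), outdir / "verification_outcomes.csv")
    _write_csv(verif.rates(), outdir / "verification_rates.csv", "%.1f")
    logger.info("verification: %d outcomes", len(verif.outcomes))

    # --- manifest ---------------------------------------------------------
    cfg_dict = config.to_dict()
    manifest = {
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "versions": _versions(),
        "stage_seeds": {k: _stage_seed(config.seed, k) for k in _STAGE_SEEDS},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    if config.figures:
        export_figures(ident, verif, outdir / "figures")
    return outdir


def _versions() -> dict:
    import sklearn

    return {
        "timbertrace": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers = [h for h in logger.handlers if not isinstance(h, logging.FileHandler)]
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler) and not isinstance(h, logging.FileHandler)
               for h in logger.handlers):
        logger.addHandler(logging.StreamHandler())


def export_figures(
    ident: IdentificationResults | None,
    verif: VerificationResults | None,
    outdir: str | Path,
) -> list[Path]:
    """Write the distance-bin stacked bars and confusion heatmaps as PNGs.

    Returns the written paths; empty results produce no files and a warning.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    written: list[Path] = []
    if ident is None or len(ident.assignments) == 0:
        logger.warning("no identification results; skipping figures")
        return written
    outdir.mkdir(parents=True, exist_ok=True)

    bins = ident.distance_bins()
    fig, ax = plt.subplots(figsize=(1.2 * len(bins.columns) + 2, 4.5))
    bottom = np.zeros(len(bins.columns))
    cmap = plt.get_cmap("viridis", len(bins.index))
    for i, bin_label in enumerate(bins.index):
        vals = bins.loc[bin_label].to_numpy()
        ax.bar(bins.columns, vals, bottom=bottom, label=str(bin_label), color=cmap(i))
        bottom += vals
    ax.axhline(90, linestyle=":", color="black", linewidth=1)
    ax.set_ylabel("% of test assignments")
    ax.set_title("Distance to predicted origin by method set")
    ax.legend(title="distance bin (km)", fontsize=7)
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    fig.tight_layout()
    path = outdir / "distance_bins.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written.append(path)

    for ms in ident.method_sets:
        conf = ident.confusion(ms)
        fig, ax = plt.subplots(figsize=(5.5, 5))
        im = ax.imshow(conf.to_numpy(), cmap="Blues")
        ax.set_xticks(range(len(conf.columns)), conf.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(len(conf.index)), conf.index, fontsize=7)
        ax.set_xlabel("predicted site")
        ax.set_ylabel("true site")
        ax.set_title(f"Confusion: {ms.label}")
        fig.colorbar(im, ax=ax, shrink=0.8)
        fig.tight_layout()
        path = outdir / f"confusion_{ms.label.replace('+', '-')}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)

    if verif is not None and len(verif.outcomes) > 0:
        rates = verif.rates()
        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        for ax, col, title in zip(
            axes, ["pct_confirmed_A", "pct_rejected_B"],
            ["A: % true claims confirmed", "B: % false claims rejected"],
        ):
            ax.bar(rates.index, rates[col], color="tab:green")
            ax.set_title(title)
            ax.set_ylim(0, 100)
            plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
        fig.tight_layout()
        path = outdir / "verification_rates.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
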