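"""Dataset I/O, pipeline configuration and the end-to-end pipeline.

The canonical interchange format is a single long-format CSV with one
row per measured time point:

    cell_model, ligand, readout, log10_conc_M, time_min, replicate, signal

Concentrations are log10 molar (a positive value is almost certainly a
molar concentration that was not log-transformed and is rejected with a
hint), times are minutes.  ``run_pipeline`` chains kinetic fitting, AUC
normalization, empirical 4PL / endpoint profiling, the all-pairs bias
sweep and the PCA/clustering stage, writing tidy CSV tables plus a
machine-readable run manifest; identical configurations reproduce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bias_engine import all_pairs_bias
from .dose_response import endpoint_profiles, fit_hill, normalize_to_reference
from .kinetics import fit_rise_fall
from .multivariate import build_bias_matrix, cluster_pca, run_pca
from .synthetic import CSV_COLUMNS, StudyDataset
from .types import FitConfig

__all__ = ["read_long_table", "write_long_table", "PipelineConfig", "run_pipeline"]

logger = logging.getLogger("biasquant")


def read_long_table(path) -> StudyDataset:
    """Read and validate a long-format CSV into a :class:`StudyDataset`."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty file")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: schema mismatch, missing columns {missing} "
                         f"(expected {CSV_COLUMNS})")
    num_cols = ["log10_conc_M", "time_min", "signal"]
    for c in num_cols:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    if df["log10_conc_M"].max() > 0:
        bad = df.index[df["log10_conc_M"] > 0][0]
        raise ValueError(
            f"{path}: row {bad + 2}: positive concentration "
            f"{df.loc[bad, 'log10_conc_M']} — expected log10 molar (e.g. -7 for 100 nM)")
    nonfinite = ~np.isfinite(df["signal"])
    if nonfinite.any():
        bad = df.index[nonfinite][0]
        raise ValueError(f"{path}: row {bad + 2}: non-finite signal")
    key_cols = ["cell_model", "ligand", "readout", "log10_conc_M", "replicate", "time_min"]
    dup = df.duplicated(subset=key_cols)
    if dup.any():
        bad = df.index[dup][0]
        raise ValueError(f"{path}: row {bad + 2}: duplicate well/time key "
                         f"{tuple(df.loc[bad, key_cols])}")
    well_cols = key_cols[:-1]
    for key, sub in df.groupby(well_cols, sort=False):
        t = sub["time_min"].to_numpy()
        if np.any(np.diff(np.sort(t)) <= 0):
            raise ValueError(f"{path}: well {key}: non-monotone time grid")
    return StudyDataset(df, provenance="imported")


def write_long_table(ds: StudyDataset, path) -> None:
    ds.to_csv(path)


@dataclass
class PipelineConfig:
    """Everything needed to rerun the full analysis deterministically."""

    input_path: str
    output_dir: str
    reference: str
    readouts: list[str] | None = None  # None: all readouts, dataset order
    cell_models: list[str] | None = None
    endpoints: list[float] = field(default_factory=lambda: [2.0, 7.0, 20.0])
    auc_endpoint: float | None = None  # None: full recorded window
    seed: int = 0
    n_starts: int = 50
    alpha: float = 0.05
    impute: str = "zero"
    k_clusters: int = 3
    scale_pca: bool = False
    kinetic_mode: str = "replicate"  # or "mean"

    def fit_config(self) -> FitConfig:
        return FitConfig(n_starts=self.n_starts, seed=self.seed, alpha=self.alpha)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _kinetic_fit_table(ds: StudyDataset, mode: str, seed: int) -> pd.DataFrame:
    rows = []
    if mode == "mean":
        df = (ds.df.groupby(["cell_model", "ligand", "readout", "log10_conc_M", "time_min"],
                            as_index=False)["signal"].mean())
        df["replicate"] = 0
        ds = StudyDataset(df[CSV_COLUMNS], provenance="imported")
    for tr in ds.traces():
        try:
            kf = fit_rise_fall(tr, seed=seed)
        except ValueError as exc:
            rows.append(dict(cell_model=tr.cell_model, ligand=tr.ligand, readout=tr.readout,
                             log10_conc_M=tr.log10_conc, replicate=tr.replicate,
                             C=math.nan, K1=math.nan, K2=math.nan, T_half=math.nan,
                             rss=math.nan, converged=False, degenerate=True, note=str(exc)))
            continue
        rows.append(dict(
            cell_model=tr.cell_model, ligand=tr.ligand, readout=tr.readout,
            log10_conc_M=tr.log10_conc, replicate=tr.replicate,
            C=kf.params.c if kf.params else math.nan,
            K1=kf.params.k1 if kf.params else math.nan,
            K2=kf.params.k2 if kf.params else math.nan,
            T_half=kf.t_half if kf.t_half is not None else math.nan,
            rss=kf.rss, converged=kf.converged, degenerate=kf.degenerate, note=kf.message))
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig, ds: StudyDataset | None = None) -> dict:
    """Execute the full analysis; returns the manifest dictionary.

    Stages: rise-and-fall kinetic fits -> AUC normalization -> 4PL and
    endpoint profiles -> all-pairs bias sweep (profile CIs + LRT) ->
    bias matrices, PCA and Ward clustering per cell model.  Stage
    failures are recorded in the manifest and downstream outputs for the
    affected keys are masked, not fatal.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if ds is None:
        ds = read_long_table(cfg.input_path)
    failures: list[str] = []
    outputs: list[str] = []

    readouts = cfg.readouts or list(dict.fromkeys(ds.df["readout"]))
    cell_models = cfg.cell_models or list(dict.fromkeys(ds.df["cell_model"]))

    logger.info("stage 1/5: kinetic fits")
    kin = _kinetic_fit_table(ds, cfg.kinetic_mode, cfg.seed)
    _write_csv(kin, out / "kinetic_fits.csv")
    outputs.append("kinetic_fits.csv")

    logger.info("stage 2/5: normalization + 4PL fits")
    curves = normalize_to_reference(ds, endpoint=cfg.auc_endpoint, reference=cfg.reference)
    curve_rows, hill_rows = [], []
    for (cell, lig, readout), c in curves.items():
        for i, dose in enumerate(c.doses):
            for rep in range(c.responses.shape[1]):
                curve_rows.append(dict(cell_model=cell, ligand=lig, readout=readout,
                                       endpoint_min=c.endpoint_min, log10_conc_M=dose,
                                       replicate=rep, response_pct=c.responses[i, rep]))
        try:
            hf = fit_hill(c)
            hill_rows.append(dict(cell_model=cell, ligand=lig, readout=readout,
                                  basal=hf.basal, emax=hf.emax, log_ec50=hf.log_ec50,
                                  hill_n=hf.hill_n, rss=hf.rss, degenerate=hf.degenerate,
                                  descending=hf.descending, extrapolated=hf.extrapolated))
        except ValueError as exc:
            failures.append(f"hill fit {cell}/{lig}/{readout}: {exc}")
    _write_csv(pd.DataFrame(curve_rows), out / "curves.csv")
    _write_csv(pd.DataFrame(hill_rows), out / "hill_fits.csv")
    outputs += ["curves.csv", "hill_fits.csv"]

    logger.info("stage 3/5: endpoint profiles at %s min", cfg.endpoints)
    try:
        prof = endpoint_profiles(ds, cfg.endpoints, reference=cfg.reference)
        _write_csv(prof, out / "endpoint_profiles.csv")
        outputs.append("endpoint_profiles.csv")
    except ValueError as exc:
        failures.append(f"endpoint profiles: {exc}")

    logger.info("stage 4/5: all-pairs bias sweep")
    fit_cfg = cfg.fit_config()
    tables = []
    for cell in cell_models:
        try:
            tables.append(all_pairs_bias(ds, readouts, cell, reference=cfg.reference,
                                         config=fit_cfg, endpoint=cfg.auc_endpoint))
        except Exception as exc:
            failures.append(f"bias sweep {cell}: {exc}")
    bias_table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    _write_csv(bias_table, out / "bias_table.csv")
    outputs.append("bias_table.csv")

    logger.info("stage 5/5: PCA + clustering")
    pca_rows, cluster_rows = [], []
    for cell in cell_models:
        try:
            bm = build_bias_matrix(bias_table, cell, impute=cfg.impute, reference=cfg.reference)
            p = run_pca(bm, scale=cfg.scale_pca)
            labels, _, newick = cluster_pca(p, k=min(cfg.k_clusters, len(bm.ligands)))
            (out / f"dendrogram_{cell}.nwk").write_text(newick + "\n")
            outputs.append(f"dendrogram_{cell}.nwk")
            for i, lig in enumerate(p.ligands):
                row = dict(cell_model=cell, ligand=lig, cluster=int(labels[i]))
                for k in range(p.scores.shape[1]):
                    row[f"pc{k + 1}"] = p.scores[i, k]
                pca_rows.append(row)
            cluster_rows.append(dict(cell_model=cell,
                                     explained_pc1=p.explained_variance_ratio[0],
                                     explained_pc2=(p.explained_variance_ratio[1]
                                                    if p.explained_variance_ratio.size > 1 else 0.0),
                                     degenerate=p.degenerate))
        except Exception as exc:
            failures.append(f"multivariate {cell}: {exc}")
    _write_csv(pd.DataFrame(pca_rows), out / "pca_scores.csv")
    _write_csv(pd.DataFrame(cluster_rows), out / "pca_variance.csv")
    outputs += ["pca_scores.csv", "pca_variance.csv"]

    import scipy
    import sklearn

    manifest = dict(
        package="biasquant", version=__version__,
        numpy=np.__version__, scipy=scipy.__version__,
        pandas=pd.__version__, sklearn=sklearn.__version__,
        seed=cfg.seed, config=cfg.to_dict(), config_hash=_config_hash(cfg),
        outputs=sorted(set(outputs)), failures=failures,
        n_traces=ds.n_traces(),
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
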