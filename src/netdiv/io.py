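"""Readers, writers, run configuration and the end-to-end pipeline.

Count tables are TSV/CSV with a header row of taxon names and a first
column of sample identifiers; samples are rows by default and a transposed
file must be declared explicitly with ``orientation="taxa"`` (never guessed
silently).  Covariate tables are keyed by the same sample identifiers;
categorical columns are expanded to indicator coding with the first level
as reference and an intercept is prepended unless disabled.

``run_pipeline`` chains the whole method — perturb, choose base taxon, fit,
fitted compositions, alpha/beta estimates, bootstrap variance — and writes
TSV/JSON results plus a machine-readable manifest recording every seed and
flag, sufficient to reproduce the run bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .estimate import (
    ALPHA_INDICES,
    BETA_INDICES,
    alpha_estimates,
    beta_estimates,
    fitted_compositions,
)
from .logratio import choose_base_taxon
from .mcem import EMConfig, MHConfig, fit
from .variance import BootstrapConfig, nonparametric_bootstrap, parametric_bootstrap

__all__ = [
    "RunConfig",
    "read_count_table",
    "write_count_table",
    "read_covariates",
    "run_pipeline",
]

log = logging.getLogger("netdiv")


def read_count_table(path, orientation: str = "samples") -> pd.DataFrame:
    """Read a sample-by-taxon count table from TSV/CSV.

    ``orientation`` is ``"samples"`` (rows are samples, the default) or
    ``"taxa"`` (file stores taxa as rows and is transposed on read).
    """
    if orientation not in ("samples", "taxa"):
        raise ValueError("orientation must be 'samples' or 'taxa'")
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.EmptyDataError:
        raise ValueError(f"count table {path} is empty") from None
    if df.empty:
        raise ValueError(f"count table {path} has no data rows")
    if orientation == "taxa":
        df = df.T
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample names in {path}: {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric count at sample {df.index[r]!r}, taxon {df.columns[c]!r}"
        )
    if (numeric < 0).any().any():
        r, c = np.argwhere((numeric < 0).to_numpy())[0]
        raise ValueError(
            f"negative count at sample {df.index[r]!r}, taxon {df.columns[c]!r}"
        )
    if not np.allclose(numeric, numeric.round()):
        raise ValueError(f"count table {path} contains non-integer entries")
    return numeric.astype(np.int64)


def write_count_table(df: pd.DataFrame, path) -> None:
    """Write a count table as TSV (CSV if the suffix is .csv)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep)


def read_covariates(
    path,
    sample_ids=None,
    intercept: bool = True,
) -> pd.DataFrame:
    """Read covariates keyed by sample identifier into a design matrix.

    Rows are aligned to ``sample_ids`` (typically the count table's index),
    not file order; categorical columns become 0/1 indicators with the
    first level as reference; an intercept column is prepended unless
    ``intercept=False``.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    meta = pd.read_csv(path, sep=sep, index_col=0)
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in meta.index]
        if missing:
            raise ValueError(f"samples missing from covariate table: {missing}")
        meta = meta.loc[list(sample_ids)]
    design = pd.get_dummies(meta, drop_first=True, dtype=float)
    design = design.astype(float)
    if intercept:
        design.insert(0, "intercept", 1.0)
    return design


@dataclass
class RunConfig:
    """All knobs for one end-to-end run; serialized into the manifest."""

    counts: str
    covariates: str | None = None
    orientation: str = "samples"
    base_taxon: str | int | None = None  # taxon name, index, or None for AUTO
    rho: float = 0.5
    indices: tuple = ("shannon", "simpson", "bray_curtis", "euclidean")
    em_iter: int = 6
    precision_method: str = "naive"
    mc_iter: int = 500
    mc_burn: int = 500
    mc_step: float = 0.01
    variance: str = "parametric"  # parametric | nonparametric | none
    b_reps: int = 5
    n_sub: int | None = None
    seed: int = 1
    out: str = "netdiv_out"
    no_intercept: bool = False
    verbosity: int = 1


def _resolve_base(cfg: RunConfig, counts: pd.DataFrame) -> int:
    if cfg.base_taxon is None or str(cfg.base_taxon).upper() == "AUTO":
        return choose_base_taxon(counts.to_numpy())
    if isinstance(cfg.base_taxon, str) and cfg.base_taxon in counts.columns:
        return int(counts.columns.get_loc(cfg.base_taxon))
    try:
        idx = int(cfg.base_taxon)
    except (TypeError, ValueError):
        raise ValueError(f"unknown base taxon {cfg.base_taxon!r}") from None
    if not 0 <= idx < counts.shape[1]:
        raise ValueError(f"base taxon index {idx} out of range")
    return idx


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the full estimation pipeline and write results under ``cfg.out``.

    Outputs: ``alpha.tsv`` (per-sample alpha estimates with standard
    errors), ``beta_<index>.tsv`` (profile-by-profile matrices),
    ``profiles.tsv`` (sample-to-profile map), ``fit.json`` (gamma, sigma,
    diagnostics), ``manifest.json``.
    """
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO if cfg.verbosity else logging.WARNING)

    counts = read_count_table(cfg.counts, orientation=cfg.orientation)
    if cfg.covariates:
        design = read_covariates(
            cfg.covariates, sample_ids=counts.index, intercept=not cfg.no_intercept
        )
    else:
        design = pd.DataFrame(
            {"intercept": np.ones(len(counts))}, index=counts.index
        )
    W = counts.to_numpy()
    X = design.to_numpy()
    d = _resolve_base(cfg, counts)
    log.info("base taxon: %s (column %d)", counts.columns[d], d)

    mh_cfg = MHConfig(v=cfg.mc_step, burn=cfg.mc_burn, r_draws=cfg.mc_iter,
                      seed=cfg.seed)
    em_cfg = EMConfig(n_iter=cfg.em_iter, precision_method=cfg.precision_method)
    params, diagnostics = fit(W, X, d=d, rho=cfg.rho, mh_cfg=mh_cfg, em_cfg=em_cfg)
    log.info("MH acceptance by iteration: %s",
             [round(a, 3) for a in diagnostics["acceptance_rate"]])

    fc = fitted_compositions(params, X, d)
    alpha_names = [i for i in cfg.indices if i in ALPHA_INDICES]
    beta_names = [i for i in cfg.indices if i in BETA_INDICES]
    unknown = [i for i in cfg.indices if i not in ALPHA_INDICES and i not in BETA_INDICES]
    if unknown:
        raise ValueError(f"unknown indices: {unknown}")

    variances = None
    if cfg.variance != "none":
        bcfg = BootstrapConfig(scheme=cfg.variance, b_reps=cfg.b_reps,
                               n_sub=cfg.n_sub, seed=cfg.seed)
        if cfg.variance == "parametric":
            variances = parametric_bootstrap(
                params, W, X, d, rho=cfg.rho, mh_cfg=mh_cfg, em_cfg=em_cfg,
                cfg=bcfg, index_names=tuple(cfg.indices))
        else:
            variances = nonparametric_bootstrap(
                W, X, d, rho=cfg.rho, mh_cfg=mh_cfg, em_cfg=em_cfg,
                cfg=bcfg, index_names=tuple(cfg.indices))

    # alpha table: one row per sample and index
    rows = []
    for name in alpha_names:
        est = alpha_estimates(fc, name)
        se = (np.sqrt(variances[name]) if variances is not None else
              np.full(est.values.shape, np.nan))
        for s, sample in enumerate(counts.index):
            k = fc.profile_index[s]
            rows.append({
                "sample": sample, "profile": int(k), "index": name,
                "estimate": est.values[k], "std_error": se[k],
            })
    alpha_df = pd.DataFrame(rows)
    alpha_df.to_csv(out / "alpha.tsv", sep="\t", index=False)

    for name in beta_names:
        est = beta_estimates(fc, name)
        mat = pd.DataFrame(est.values)
        mat.to_csv(out / f"beta_{name}.tsv", sep="\t")
        if variances is not None:
            pd.DataFrame(np.sqrt(variances[name])).to_csv(
                out / f"beta_{name}_se.tsv", sep="\t")

    pd.DataFrame({
        "sample": counts.index, "profile": fc.profile_index,
    }).to_csv(out / "profiles.tsv", sep="\t", index=False)

    with open(out / "fit.json", "w") as fh:
        json.dump({
            "gamma": params.gamma.tolist(),
            "sigma": params.sigma.tolist(),
            "base_taxon": int(d),
            "base_taxon_name": str(counts.columns[d]),
            "diagnostics": diagnostics,
        }, fh, indent=1)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"netdiv_version": __version__, "config": asdict(cfg)}, fh, indent=1)
    log.info("results written to %s", out)
    return out
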