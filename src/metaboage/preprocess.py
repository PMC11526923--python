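"""Technical normalization of targeted LC-MS intensity tables.

The normalization ledger runs, in this order and only this order:

    raw -> filtered -> logged -> batch_corrected -> scaled -> imputed -> tech_adjusted

1. drop metabolites missing in more than ``max_missing`` of samples (strict >)
2. drop samples whose hemolysis grade exceeds ``max_grade`` (strict >)
3. natural-log transform, then mean-center each sample over its non-missing
   metabolites
4. per metabolite, take residuals of a batch-specific intercept plus
   batch-specific linear run-order slope fit (the batch x run-order
   interaction model); batches with < 3 non-missing values fall back to
   intercept-only
5. scale each metabolite to unit variance within each batch (sample SD,
   denominator n-1)
6. k-nearest-neighbour mean imputation (Euclidean distance over metabolites
   observed in both samples, scaled by the shared count; ties broken by
   sample identifier order)
7. per metabolite, residuals of an additive linear fit on the remaining
   technical covariates (travel time, arrival temperature, hemolysis grade)

Missing cells are excluded from every fit before imputation, never
zero-filled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STATES = (
    "raw",
    "filtered",
    "logged",
    "batch_corrected",
    "scaled",
    "imputed",
    "tech_adjusted",
)

META_COLUMNS = ("batch", "run", "run_order", "hemolysis", "travel_time", "arrival_temp")

TECH_COVARIATES = ("travel_time", "arrival_temp", "hemolysis")


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites intensity table with per-sample technical metadata.

    ``values`` and ``sample_meta`` share an index of sample identifiers.
    ``state`` tracks progress through the normalization ledger and operations
    refuse to run out of order.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if not self.values.index.equals(self.sample_meta.index):
            raise ValueError("values and sample_meta must share a sample index")
        missing_cols = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing_cols:
            raise ValueError(f"sample_meta lacks columns {missing_cols}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def _require(self, *states: str) -> None:
        if self.state not in states:
            raise ValueError(
                f"operation requires state in {states}, matrix is {self.state!r}"
            )

    def _step(self, values: pd.DataFrame, state: str, meta: pd.DataFrame | None = None) -> "MetaboliteMatrix":
        if STATES.index(state) < STATES.index(self.state):
            raise ValueError(f"cannot move backwards from {self.state!r} to {state!r}")
        return MetaboliteMatrix(values, self.sample_meta if meta is None else meta, state)


def filter_missingness(
    matrix: MetaboliteMatrix, max_missing: float = 0.10
) -> tuple[MetaboliteMatrix, pd.DataFrame]:
    """Drop metabolites missing in strictly more than ``max_missing`` of samples."""
    matrix._require("raw", "filtered")
    frac = matrix.values.isna().mean(axis=0)
    drop = frac.index[frac > max_missing]
    report = pd.DataFrame({"metabolite": drop, "missing_fraction": frac[drop].to_numpy()})
    kept = matrix.values.drop(columns=drop)
    if kept.shape[1] == 0:
        raise ValueError(
            f"all {matrix.n_metabolites} metabolites exceed missingness {max_missing}"
        )
    if len(drop):
        log.info("filter_missingness: dropped %d metabolites", len(drop))
    return matrix._step(kept, "filtered"), report


def filter_hemolysis(
    matrix: MetaboliteMatrix, max_grade: int = 3
) -> tuple[MetaboliteMatrix, pd.DataFrame]:
    """Drop samples with hemolysis grade strictly above ``max_grade``."""
    matrix._require("raw", "filtered")
    grade = matrix.sample_meta["hemolysis"]
    if grade.isna().any():
        bad = grade.index[grade.isna()][:5].tolist()
        raise ValueError(f"samples without a hemolysis grade: {bad}")
    drop = grade.index[grade > max_grade]
    report = pd.DataFrame({"sample_id": drop, "hemolysis": grade[drop].to_numpy()})
    if len(drop) == matrix.n_samples:
        raise ValueError("all samples removed by the hemolysis filter")
    keep = grade.index[grade <= max_grade]
    if len(drop):
        log.info("filter_hemolysis: removed %d samples", len(drop))
    return (
        matrix._step(matrix.values.loc[keep], "filtered", matrix.sample_meta.loc[keep]),
        report,
    )


def log_center(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Natural-log transform and mean-center each sample over non-missing cells."""
    matrix._require("raw", "filtered")
    vals = matrix.values.to_numpy(dtype=float)
    nonpos = (vals <= 0) & ~np.isnan(vals)
    if nonpos.any():
        i, j = np.argwhere(nonpos)[0]
        raise ValueError(
            f"non-positive intensity {vals[i, j]!r} at sample "
            f"{matrix.values.index[i]!r}, metabolite {matrix.values.columns[j]!r}"
        )
    logged = np.log(vals)
    row_mean = np.nanmean(logged, axis=1, keepdims=True)
    centered = pd.DataFrame(
        logged - row_mean, index=matrix.values.index, columns=matrix.values.columns
    )
    return matrix._step(centered, "logged")


def batch_runorder_correct(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Residualize each metabolite on batch-specific intercepts and run-order slopes.

    Run order is the within-batch processing index.  A batch with fewer than 3
    non-missing values for a metabolite falls back to intercept-only for that
    batch (logged).
    """
    matrix._require("logged")
    out = matrix.values.to_numpy(dtype=float).copy()
    order = matrix.sample_meta["run_order"].to_numpy(dtype=float)
    batches = matrix.sample_meta["batch"].to_numpy()
    n_fallback = 0
    for b in pd.unique(batches):
        rows = np.flatnonzero(batches == b)
        t = order[rows]
        block = out[rows, :]
        for j in range(block.shape[1]):
            y = block[:, j]
            obs = ~np.isnan(y)
            n_obs = int(obs.sum())
            if n_obs == 0:
                continue
            if n_obs < 3 or np.ptp(t[obs]) == 0:
                block[obs, j] = y[obs] - y[obs].mean()
                n_fallback += 1
                continue
            X = np.column_stack([np.ones(n_obs), t[obs]])
            coef, *_ = np.linalg.lstsq(X, y[obs], rcond=None)
            block[obs, j] = y[obs] - X @ coef
        out[rows, :] = block
    if n_fallback:
        log.warning(
            "batch_runorder_correct: %d batch/metabolite cells fell back to intercept-only",
            n_fallback,
        )
    corrected = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix._step(corrected, "batch_corrected")


def scale_by_batch(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Scale each metabolite to unit variance within each batch (SD with n-1).

    Batches with <= 1 non-missing value, or zero variance, are left unscaled
    with a warning.
    """
    matrix._require("batch_corrected")
    out = matrix.values.to_numpy(dtype=float).copy()
    batches = matrix.sample_meta["batch"].to_numpy()
    n_skipped = 0
    for b in pd.unique(batches):
        rows = np.flatnonzero(batches == b)
        block = out[rows, :]
        with np.errstate(invalid="ignore"):
            sd = np.array([
                np.std(col[~np.isnan(col)], ddof=1) if (~np.isnan(col)).sum() > 1 else np.nan
                for col in block.T
            ])
        usable = np.isfinite(sd) & (sd > 0)
        n_skipped += int((~usable).sum())
        block[:, usable] = block[:, usable] / sd[usable]
        out[rows, :] = block
    if n_skipped:
        log.warning("scale_by_batch: %d batch/metabolite cells left unscaled", n_skipped)
    scaled = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix._step(scaled, "scaled")


def _pairwise_distances(X: np.ndarray) -> np.ndarray:
    """Squared Euclidean distance over shared observed cells, per shared count.

    Entries with no shared observed metabolites are +inf.
    """
    obs = ~np.isnan(X)
    X0 = np.where(obs, X, 0.0)
    sq = X0**2
    shared = obs.astype(float) @ obs.T.astype(float)
    cross = X0 @ X0.T
    s_i = sq @ obs.T.astype(float)
    d2 = s_i + s_i.T - 2.0 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = np.where(shared > 0, d2 / shared, np.inf)
    return np.maximum(d2, 0.0)


def knn_impute(matrix: MetaboliteMatrix, k: int = 10) -> MetaboliteMatrix:
    """Replace missing cells by the metabolite mean over the k nearest samples.

    Neighbours are the k samples closest in scaled shared-cell Euclidean
    distance among those that observe the metabolite; ties are broken by
    sample identifier order.
    """
    matrix._require("scaled")
    X = matrix.values.to_numpy(dtype=float).copy()
    obs = ~np.isnan(X)
    if obs.all():
        return matrix._step(matrix.values.copy(), "imputed")
    d2 = _pairwise_distances(X)
    np.fill_diagonal(d2, np.inf)
    isolated = np.isinf(d2).all(axis=1)
    if isolated.any():
        bad = matrix.values.index[isolated][:5].tolist()
        raise ValueError(f"samples sharing no observed metabolites with any other: {bad}")
    id_rank = np.argsort(np.argsort(matrix.values.index.astype(str)))
    for i, j in np.argwhere(~obs):
        donors = np.flatnonzero(obs[:, j] & np.isfinite(d2[i]))
        if donors.size == 0:
            raise ValueError(
                f"metabolite {matrix.values.columns[j]!r} has no donor for sample "
                f"{matrix.values.index[i]!r}"
            )
        order = donors[np.lexsort((id_rank[donors], d2[i, donors]))]
        X[i, j] = X[order[: min(k, order.size)], j].mean()
    imputed = pd.DataFrame(X, index=matrix.values.index, columns=matrix.values.columns)
    return matrix._step(imputed, "imputed")


def regress_technical(
    matrix: MetaboliteMatrix, covariates: tuple[str, ...] = TECH_COVARIATES
) -> MetaboliteMatrix:
    """Residualize every metabolite on an additive fit of technical covariates.

    Constant covariates are dropped from the design with a warning; the fit
    is a rank-revealing least-squares solve, so collinear covariates cannot
    crash it.
    """
    matrix._require("imputed")
    cols = []
    names = []
    for c in covariates:
        v = matrix.sample_meta[c].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            log.warning("regress_technical: covariate %r is constant, dropped", c)
            continue
        cols.append(v)
        names.append(c)
    X = np.column_stack([np.ones(matrix.n_samples)] + cols)
    Y = matrix.values.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = pd.DataFrame(
        Y - X @ coef, index=matrix.values.index, columns=matrix.values.columns
    )
    return matrix._step(resid, "tech_adjusted")


def normalize(
    matrix: MetaboliteMatrix,
    max_missing: float = 0.10,
    max_hemolysis_grade: int = 3,
    knn_k: int = 10,
    tech_covariates: tuple[str, ...] = TECH_COVARIATES,
) -> tuple[MetaboliteMatrix, dict]:
    """Run the full ledger raw -> tech_adjusted; returns matrix and filter reports."""
    m, dropped_mets = filter_missingness(matrix, max_missing)
    m, dropped_samples = filter_hemolysis(m, max_hemolysis_grade)
    m = log_center(m)
    m = batch_runorder_correct(m)
    m = scale_by_batch(m)
    m = knn_impute(m, k=knn_k)
    m = regress_technical(m, tech_covariates)
    reports = {"dropped_metabolites": dropped_mets, "dropped_samples": dropped_samples}
    return m, reports
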