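"""PCA of the normalized metabolome, Tracy-Widom component selection,
Type III ANCOVA variance partitioning, and per-PC SNP-heritability.

The Tracy-Widom test standardizes each leading eigenvalue with the
moment-matched effective-size normalization used in population-structure
testing (remaining-eigenvalue moments estimate the effective dimension),
and evaluates the TW(beta=1) tail through a shifted-gamma approximation
accurate to ~1e-4 in probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .kinship import KinshipMatrix
from .lmm import LMMFit, build_design, eigendecompose, fit_lmm
from .preprocess import MetaboliteMatrix

log = logging.getLogger(__name__)

# shifted-gamma approximation to the Tracy-Widom beta=1 law (Chiani-style
# moment matching): TW1 =d= Gamma(k, theta) - shift
_TW1_K = 46.44604884387132
_TW1_THETA = 0.18605402228279682
_TW1_SHIFT = 9.848007781128567


def tw1_sf(x: float | np.ndarray) -> np.ndarray:
    """Upper tail probability of the Tracy-Widom beta=1 distribution."""
    z = (np.asarray(x, dtype=float) + _TW1_SHIFT) / _TW1_THETA
    return special.gammaincc(_TW1_K, np.maximum(z, 0.0))


@dataclass
class PCADecomposition:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # metabolites x components
    eigenvalues: np.ndarray  # descending
    var_explained: np.ndarray
    tw_p: np.ndarray | None = None
    n_significant: int | None = None


def pca(matrix: MetaboliteMatrix | pd.DataFrame) -> PCADecomposition:
    """Exact SVD of the column-standardized (per-metabolite unit variance) matrix.

    Sign convention: the largest-magnitude loading of each component is
    positive, so the decomposition is bit-stable across runs.
    """
    values = matrix.values if isinstance(matrix, MetaboliteMatrix) else matrix
    if isinstance(matrix, MetaboliteMatrix) and matrix.state != "tech_adjusted":
        raise ValueError(f"pca requires a tech_adjusted matrix, got {matrix.state!r}")
    X = values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("pca input contains missing values; impute first")
    n = X.shape[0]
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = values.columns[sd == 0][:5].tolist()
        raise ValueError(f"zero-variance metabolites: {bad}")
    X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    U = U * flip
    Vt = Vt * flip[:, None]
    eig = s**2 / (n - 1)
    comp = [f"PC{i + 1}" for i in range(len(s))]
    return PCADecomposition(
        scores=pd.DataFrame(U * s, index=values.index, columns=comp),
        loadings=pd.DataFrame(Vt.T, index=values.columns, columns=comp),
        eigenvalues=eig,
        var_explained=eig / eig.sum(),
    )


def tracy_widom_select(
    eigenvalues: np.ndarray, n_samples: int, alpha: float = 0.05
) -> tuple[np.ndarray, int]:
    """Sequential Tracy-Widom p-values for leading eigenvalues.

    Returns per-component p-values and the count of leading components
    significant at ``alpha``, stopping at the first non-significant one.
    Components past the point where the effective-size estimate degenerates
    get p = NaN.
    """
    if n_samples <= 2:
        raise ValueError("Tracy-Widom selection needs more than 2 samples")
    ev = np.asarray(eigenvalues, dtype=float)
    if np.any(np.diff(ev) > 1e-10):
        raise ValueError("eigenvalues must be non-increasing")
    ev = np.maximum(ev, 0.0)
    m = ev.size
    pvals = np.full(m, np.nan)
    for i in range(m):
        tail = ev[i:]
        mp = float(tail.size)
        s1 = tail.sum()
        if s1 <= 0 or mp < 2:
            break
        s2 = mp**2 * (tail**2).sum() / s1**2
        denom = s2 - mp
        if denom <= 0:
            break
        n_eff = mp * (mp + 2.0) / denom
        if n_eff <= 1:
            break
        stat = mp * ev[i] / s1
        a, b = np.sqrt(n_eff - 1.0), np.sqrt(mp)
        mu = (a + b) ** 2 / n_eff
        sigma = (a + b) / n_eff * (1.0 / a + 1.0 / b) ** (1.0 / 3.0)
        pvals[i] = float(tw1_sf((stat - mu) / sigma))
    n_sig = 0
    for p in pvals:
        if np.isnan(p) or p >= alpha:
            break
        n_sig += 1
    return pvals, n_sig


@dataclass
class VariancePartition:
    """Type III ANCOVA fractions per PC x covariate (plus residual)."""

    table: pd.DataFrame  # long: pc, term, sum_sq, F, p, fraction
    dropped: list[str] = field(default_factory=list)

    def fractions(self, pc: str) -> pd.Series:
        t = self.table[self.table["pc"] == pc]
        return t.set_index("term")["fraction"]


def _sum_code(series: pd.Series) -> tuple[pd.DataFrame, list[str]]:
    """Sum-to-zero (deviation) coding, last level as the dropped reference."""
    levels = sorted(series.astype(str).unique())
    cols = {}
    for lv in levels[:-1]:
        v = (series.astype(str) == lv).astype(float) - (
            series.astype(str) == levels[-1]
        ).astype(float)
        cols[lv] = v.to_numpy()
    return pd.DataFrame(cols, index=series.index), levels


def ancova_partition(
    scores: pd.DataFrame,
    cohort: pd.DataFrame,
    covariates: list[str],
) -> VariancePartition:
    """Type III (marginal) sums of squares per covariate for each PC.

    Factors use sum-to-zero contrasts.  Each term's SS is the RSS increase
    from deleting the term from the full model; fractions are computed
    against (sum of term SS + residual SS), so they add to 1 per PC.
    Aliased covariates are dropped with a report.
    """
    n = len(cohort)
    blocks: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for cov in covariates:
        col = cohort[cov]
        if pd.api.types.is_numeric_dtype(col):
            block = col.to_numpy(dtype=float)[:, None]
        else:
            block, _ = _sum_code(col)
            block = block.to_numpy(dtype=float)
        blocks[cov] = block
    # drop aliased terms greedily
    X_cols = [np.ones((n, 1))]
    kept: list[str] = []
    rank = 1
    for cov, block in blocks.items():
        cand = np.hstack(X_cols + [block])
        r = np.linalg.matrix_rank(cand)
        if r == rank + block.shape[1]:
            X_cols.append(block)
            kept.append(cov)
            rank = r
        else:
            dropped.append(cov)
            log.warning("ancova_partition: covariate %r aliased, dropped", cov)
    X_full = np.hstack(X_cols)

    def rss(X: np.ndarray, y: np.ndarray) -> float:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float(r @ r)

    p_full = X_full.shape[1]
    rows = []
    for pc in scores.columns:
        y = scores[pc].to_numpy(dtype=float)
        rss_full = rss(X_full, y)
        df_res = n - p_full
        ms_res = rss_full / df_res
        term_ss = {}
        for cov in kept:
            X_red = np.hstack(
                [np.ones((n, 1))] + [blocks[c] for c in kept if c != cov]
            )
            ss = rss(X_red, y) - rss_full
            df_t = blocks[cov].shape[1]
            F = (ss / df_t) / ms_res
            pval = stats.f.sf(F, df_t, df_res)
            term_ss[cov] = (ss, df_t, F, pval)
        denom = sum(v[0] for v in term_ss.values()) + rss_full
        for cov, (ss, df_t, F, pval) in term_ss.items():
            rows.append(
                {"pc": pc, "term": cov, "sum_sq": ss, "df": df_t, "F": F, "p": pval,
                 "fraction": ss / denom}
            )
        rows.append(
            {"pc": pc, "term": "residual", "sum_sq": rss_full, "df": df_res,
             "F": np.nan, "p": np.nan, "fraction": rss_full / denom}
        )
    return VariancePartition(pd.DataFrame(rows), dropped)


def pc_heritability(
    scores: pd.DataFrame,
    cohort: pd.DataFrame,
    K: KinshipMatrix,
    design_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Fit each PC with the kinship mixed model; report h_snp and log-likelihoods.

    Also refits against the identity matrix so the contribution of
    relatedness (never negative, nested at sigma_g2 = 0) is reported.
    """
    design = build_design(cohort, **(design_kwargs or {}))
    eig = eigendecompose(K)
    eye = KinshipMatrix.identity(list(scores.index.astype(str)))
    eig_i = eigendecompose(eye)
    rows = []
    fits: dict[str, LMMFit] = {}
    for pc in scores.columns:
        y = scores[pc].to_numpy(dtype=float)
        fit = fit_lmm(y, design, eig=eig)
        fit_id = fit_lmm(y, design, eig=eig_i)
        fits[pc] = fit
        rows.append(
            {
                "pc": pc,
                "h_snp": fit.h_snp,
                "sigma_g2": fit.sigma_g2,
                "sigma_e2": fit.sigma_e2,
                "loglik": fit.loglik,
                "loglik_identity": fit_id.loglik,
                "converged": fit.converged,
            }
        )
    table = pd.DataFrame(rows).set_index("pc")
    table.attrs["fits"] = fits
    return table
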