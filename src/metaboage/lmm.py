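"""Kinship-structured linear mixed models and panel-wide association.

Model per response: y ~ N(X b, sg2 * K + se2 * I).  The fit eigendecomposes
K once and maximizes the 1-D profile likelihood in the variance ratio
lam = sg2 / se2: with K = U diag(d) U', rotating by U' gives independent
observations with weights w_i = lam * d_i + 1, so each candidate lam costs
one weighted least squares solve.

REML is the default criterion.  Full ML is available (``reml=False``) but is
degenerate whenever a design column lies in the null space of K -- a
variance-standardized GRM always has the intercept in its null space (centered
genotype columns), and there the ML profile diverges as se2 -> 0.  REML works
on error contrasts orthogonal to X and is well-posed.

SNP-heritability is sg2 / (sg2 + se2) = lam / (1 + lam).  BLUPs are
u = lam K (lam K + I)^-1 (y - X b), computed in the eigenbasis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .kinship import KinshipMatrix
from .preprocess import MetaboliteMatrix

log = logging.getLogger(__name__)

LIFE_STAGE_BINS = (1.0, 3.0, 7.0, 11.0)
LIFE_STAGE_LABELS = ("puppy", "adolescent", "young_adult", "mature_adult", "senior")

_LOGLAM_LO, _LOGLAM_HI = -14.0, 14.0


def life_stage(age: pd.Series) -> pd.Series:
    """Five-level life-stage category from age in years (<1, 1-3, 3-7, 7-11, 11+)."""
    idx = np.digitize(age.to_numpy(dtype=float), LIFE_STAGE_BINS)
    return pd.Series(
        pd.Categorical.from_codes(idx, categories=list(LIFE_STAGE_LABELS)),
        index=age.index,
        name="life_stage",
    )


# ---------------------------------------------------------------------------
# design matrix


@dataclass
class DesignMatrix:
    """Fixed-effect design with a ledger of applied transforms and prunings."""

    X: pd.DataFrame
    ledger: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def values(self) -> np.ndarray:
        return self.X.to_numpy(dtype=float)


def _prune_to_full_rank(X: pd.DataFrame, ledger: list[str]) -> pd.DataFrame:
    """Greedy left-to-right pruning of linearly dependent columns."""
    A = X.to_numpy(dtype=float)
    keep: list[int] = []
    rank = 0
    for j in range(A.shape[1]):
        cand = A[:, keep + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(j)
            rank = r
        else:
            ledger.append(f"pruned collinear column {X.columns[j]!r}")
    return X.iloc[:, keep]


def build_design(
    cohort: pd.DataFrame,
    cbc_cols: list[str] | None = None,
    interactions: tuple[str, ...] = ("age:weight", "sex:sterilized"),
    diet_reference: str | None = None,
    extra_numeric: list[str] | None = None,
    standardize_numeric: bool = False,
) -> DesignMatrix:
    """Standard fixed-effect design from a cohort covariate table.

    Columns: intercept, sqrt(age), sqrt(weight), sex, sterilized, fasting,
    the CBC covariates, the requested interactions, optional diet dummies
    against ``diet_reference``, and optional standardized numeric extras
    (urinalysis or mediator columns).  Factors are coded 0/1.  Collinear
    columns are pruned greedily with a ledger entry.
    """
    ledger: list[str] = []
    cols: dict[str, np.ndarray] = {"(Intercept)": np.ones(len(cohort))}
    cols["sqrt_age"] = np.sqrt(cohort["age"].to_numpy(dtype=float))
    cols["sqrt_weight"] = np.sqrt(cohort["weight"].to_numpy(dtype=float))
    ledger.append("age, weight square-root transformed")
    for fac in ("sex", "sterilized"):
        v = cohort[fac]
        if v.dtype == object or str(v.dtype) == "category":
            levels = sorted(v.astype(str).unique())
            if len(levels) > 2:
                raise ValueError(f"{fac} has more than two levels: {levels}")
            cols[fac] = (v.astype(str) == levels[-1]).to_numpy(dtype=float)
            ledger.append(f"{fac} coded 0/1 with {levels[-1]!r}=1")
        else:
            cols[fac] = v.to_numpy(dtype=float)
    cols["fasting"] = np.round(cohort["fasting"].to_numpy(dtype=float))
    if cbc_cols is None:
        cbc_cols = [c for c in cohort.columns if c.startswith("cbc_")]
    for c in cbc_cols:
        cols[c] = cohort[c].to_numpy(dtype=float)
    if "age:weight" in interactions:
        cols["sqrt_age:sqrt_weight"] = cols["sqrt_age"] * cols["sqrt_weight"]
    if "sex:sterilized" in interactions:
        cols["sex:sterilized"] = cols["sex"] * cols["sterilized"]
    if diet_reference is not None:
        diet = cohort["diet"].astype(str)
        if diet_reference not in set(diet):
            raise ValueError(f"diet reference level {diet_reference!r} absent from cohort")
        for level in sorted(set(diet) - {diet_reference}):
            cols[f"diet[{level}]"] = (diet == level).to_numpy(dtype=float)
        ledger.append(f"diet dummy-coded against {diet_reference!r}")
    for c in extra_numeric or []:
        v = cohort[c].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"extra numeric covariate {c!r} is constant")
        cols[c] = (v - v.mean()) / sd
        ledger.append(f"{c} mean-centered, unit variance")
    if standardize_numeric:
        for name in ("sqrt_age", "sqrt_weight", "fasting"):
            v = cols[name]
            cols[name] = (v - v.mean()) / v.std(ddof=1)
        ledger.append("numeric base covariates standardized")
    X = pd.DataFrame(cols, index=cohort.index)
    X = _prune_to_full_rank(X, ledger)
    return DesignMatrix(X, ledger)


# ---------------------------------------------------------------------------
# single-response fit


@dataclass
class LMMFit:
    """Maximum-likelihood fit of one response under y ~ N(Xb, sg2 K + se2 I)."""

    beta: pd.Series
    se: pd.Series
    p: pd.Series
    sigma_g2: float
    sigma_e2: float
    h_snp: float
    blups: np.ndarray
    loglik: float
    converged: bool
    n: int
    df: int
    identifiable: bool = True


def eigendecompose(K: KinshipMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition with tiny negative eigenvalues floored at zero."""
    d, U = np.linalg.eigh(K.K)
    n_neg = int((d < 0).sum())
    if d.min() < -1e-8 * max(d.max(), 1.0):
        raise ValueError(f"kinship matrix is not PSD (min eigenvalue {d.min():.3g})")
    if n_neg:
        log.info("eigendecompose: floored %d negative eigenvalues at 0", n_neg)
    return np.maximum(d, 0.0), U


def _profile(lam: float, yr: np.ndarray, Xr: np.ndarray, d: np.ndarray, reml: bool):
    """Profile log-likelihood and GLS pieces at variance ratio lam = sg2/se2."""
    n, p = Xr.shape
    w = lam * d + 1.0
    wi = 1.0 / w
    XtWX = Xr.T @ (Xr * wi[:, None])
    XtWy = Xr.T @ (yr * wi)
    beta = np.linalg.solve(XtWX, XtWy)
    r = yr - Xr @ beta
    rss = float(r @ (r * wi))
    if reml:
        se2 = rss / (n - p)
        ll = -0.5 * (
            (n - p) * (np.log(2 * np.pi * se2) + 1.0)
            + np.sum(np.log(w))
            + np.linalg.slogdet(XtWX)[1]
        )
    else:
        se2 = rss / n
        ll = -0.5 * (n * (np.log(2 * np.pi * se2) + 1.0) + np.sum(np.log(w)))
    return ll, beta, se2, XtWX, r, wi


def fit_lmm(
    y: np.ndarray | pd.Series,
    X: DesignMatrix | pd.DataFrame,
    K: KinshipMatrix | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    reml: bool = True,
    n_grid: int = 64,
) -> LMMFit:
    """Exact REML (or ML) fit via the eigen-rotation profile likelihood.

    ``eig`` may carry a precomputed ``eigendecompose(K)`` so that panel-wide
    scans factor K only once.
    """
    Xdf = X.X if isinstance(X, DesignMatrix) else X
    labels = list(Xdf.columns)
    Xv = Xdf.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    n, p = Xv.shape
    if yv.shape != (n,):
        raise ValueError(f"response length {yv.shape} does not match design rows {n}")
    if np.linalg.matrix_rank(Xv) < p:
        raise ValueError("design matrix is rank deficient; prune before fitting")
    if eig is None:
        if K is None:
            raise ValueError("provide K or its eigendecomposition")
        eig = eigendecompose(K)
    d, U = eig
    yr = U.T @ yv
    Xr = U.T @ Xv

    def nll(loglam: float) -> float:
        return -_profile(np.exp(loglam), yr, Xr, d, reml)[0]

    grid = np.linspace(_LOGLAM_LO, _LOGLAM_HI, n_grid)
    vals = np.array([nll(g) for g in grid])
    best = int(np.argmin(vals))
    converged = True
    if best in (0, n_grid - 1):
        loglam_hat = grid[best]
    else:
        try:
            res = optimize.minimize_scalar(
                nll,
                bracket=(grid[best - 1], grid[best], grid[best + 1]),
                method="brent",
                options={"xtol": 1e-10},
            )
            converged = bool(res.success) if res.success is not None else True
            loglam_hat = float(res.x)
            if res.fun > vals[best]:  # keep the grid point if Brent drifted
                loglam_hat = grid[best]
        except ValueError:
            # flat profile (e.g. K = I): no strict bracket exists
            loglam_hat = grid[best]
    # explicit sg2 = 0 boundary (pure OLS)
    ll_zero, *_ = _profile(0.0, yr, Xr, d, reml)
    lam_hat = np.exp(loglam_hat)
    ll_hat = -nll(loglam_hat)
    if ll_zero >= ll_hat - 1e-10:
        lam_hat, ll_hat = 0.0, ll_zero

    ll, beta, se2, XtWX, r, wi = _profile(lam_hat, yr, Xr, d, reml)
    sg2 = lam_hat * se2
    h = lam_hat / (1.0 + lam_hat)
    cov = se2 * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    dfree = n - p
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.nan)
    pvals = np.where(np.isnan(t), np.nan, 2.0 * stats.t.sf(np.abs(t), dfree))
    if np.isnan(t).any():
        log.warning("fit_lmm: zero standard error, p set to NA")
    shrink = lam_hat * d / (lam_hat * d + 1.0)
    blups = U @ (shrink * (r))
    # flat profile (e.g. K = I): heritability is unidentifiable by construction
    identifiable = bool(np.ptp(d) > 1e-12)
    return LMMFit(
        beta=pd.Series(beta, index=labels),
        se=pd.Series(se, index=labels),
        p=pd.Series(pvals, index=labels),
        sigma_g2=sg2,
        sigma_e2=se2,
        h_snp=h,
        blups=blups,
        loglik=ll_hat,
        converged=converged,
        n=n,
        df=dfree,
        identifiable=identifiable,
    )


def wald_ci(fit: LMMFit, coef: str, level: float = 0.95) -> tuple[float, float]:
    half = stats.t.ppf(0.5 + level / 2.0, fit.df) * fit.se[coef]
    return fit.beta[coef] - half, fit.beta[coef] + half


def fdr_adjust(p: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up q-values; NA p-values propagate as NA."""
    arr = np.asarray(p, dtype=float)
    q = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    pv = arr[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m:
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        q[ok] = out
    if isinstance(p, pd.Series):
        return pd.Series(q, index=p.index)
    return q


# ---------------------------------------------------------------------------
# panel-wide association


@dataclass
class AssociationTable:
    """Per-metabolite mixed-model fits plus a long results table.

    ``table`` has one row per metabolite x coefficient with columns
    beta, se, p, q (BH-FDR per coefficient across metabolites), sigma_g2,
    sigma_e2, h_snp, loglik, converged.
    """

    fits: dict[str, LMMFit]
    table: pd.DataFrame
    design: DesignMatrix
    alpha: float = 0.05
    interaction_kept: bool | None = None

    def significant(self, coefficient: str, alpha: float | None = None) -> list[str]:
        a = self.alpha if alpha is None else alpha
        t = self.table
        hit = t[(t["coefficient"] == coefficient) & (t["q"] <= a)]
        return hit["metabolite"].tolist()

    def coefficient_frame(self, coefficient: str) -> pd.DataFrame:
        t = self.table[self.table["coefficient"] == coefficient]
        return t.set_index("metabolite")


def _fit_panel(
    values: pd.DataFrame, design: DesignMatrix, eig, alpha: float
) -> tuple[dict[str, LMMFit], pd.DataFrame]:
    fits: dict[str, LMMFit] = {}
    rows = []
    for met in values.columns:
        try:
            fit = fit_lmm(values[met].to_numpy(), design, eig=eig)
        except Exception as exc:  # pragma: no cover - defensive
            log.warning("fit failed for %r: %s", met, exc)
            continue
        if not fit.converged:
            log.warning("fit for %r did not converge; excluded from FDR", met)
        fits[met] = fit
        for coef in fit.beta.index:
            rows.append(
                {
                    "metabolite": met,
                    "coefficient": coef,
                    "beta": fit.beta[coef],
                    "se": fit.se[coef],
                    "p": fit.p[coef] if fit.converged else np.nan,
                    "sigma_g2": fit.sigma_g2,
                    "sigma_e2": fit.sigma_e2,
                    "h_snp": fit.h_snp,
                    "loglik": fit.loglik,
                    "converged": fit.converged,
                }
            )
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    for coef in design.X.columns:
        sel = table["coefficient"] == coef
        table.loc[sel, "q"] = fdr_adjust(table.loc[sel, "p"])
    return fits, table


def mwas(
    matrix: MetaboliteMatrix | pd.DataFrame,
    cohort: pd.DataFrame,
    K: KinshipMatrix,
    alpha: float = 0.05,
    interaction_screen: str = "sqrt_age:sqrt_weight",
    design_kwargs: dict | None = None,
) -> AssociationTable:
    """Metabolome-wide association with the two-stage interaction rule.

    Stage 1 fits every metabolite with the age x weight interaction; if no
    metabolite's interaction coefficient survives FDR ``alpha``, every
    metabolite is refit without that term.
    """
    values = matrix.values if isinstance(matrix, MetaboliteMatrix) else matrix
    if isinstance(matrix, MetaboliteMatrix) and matrix.state != "tech_adjusted":
        raise ValueError(f"mwas requires a tech_adjusted matrix, got {matrix.state!r}")
    kwargs = dict(design_kwargs or {})
    design = build_design(cohort, **kwargs)
    eig = eigendecompose(K)
    interaction_kept: bool | None = None
    if interaction_screen and interaction_screen in design.X.columns:
        fits, table = _fit_panel(values, design, eig, alpha)
        inter_q = table.loc[table["coefficient"] == interaction_screen, "q"]
        interaction_kept = bool((inter_q <= alpha).any())
        if not interaction_kept:
            log.info(
                "mwas: no %s interaction at FDR %.3g; refitting without it",
                interaction_screen,
                alpha,
            )
            kwargs["interactions"] = tuple(
                i
                for i in kwargs.get("interactions", ("age:weight", "sex:sterilized"))
                if i != "age:weight"
            )
            design = build_design(cohort, **kwargs)
            fits, table = _fit_panel(values, design, eig, alpha)
    else:
        fits, table = _fit_panel(values, design, eig, alpha)
    return AssociationTable(fits, table, design, alpha, interaction_kept)


def contrast_covariate(
    matrix: MetaboliteMatrix | pd.DataFrame,
    cohort: pd.DataFrame,
    K: KinshipMatrix,
    covariate: str,
    reference: str | None = None,
    alpha: float = 0.05,
    design_kwargs: dict | None = None,
) -> AssociationTable:
    """Add one covariate (factor vs reference, or standardized numeric) and refit.

    Covers the diet-type, uSG and bilirubin analyses with one mechanism; the
    added coefficients get their own FDR across metabolites.
    """
    kwargs = dict(design_kwargs or {})
    kwargs.setdefault("interactions", ("sex:sterilized",))
    if reference is not None:
        kwargs["diet_reference"] = reference if covariate == "diet" else None
        if covariate != "diet":
            raise ValueError("reference levels are supported for the diet factor")
    else:
        if not pd.api.types.is_numeric_dtype(cohort[covariate]):
            raise ValueError(f"covariate {covariate!r} is not numeric; give a reference")
        kwargs["extra_numeric"] = list(kwargs.get("extra_numeric", [])) + [covariate]
    return mwas(
        matrix, cohort, K, alpha=alpha, interaction_screen="", design_kwargs=kwargs
    )


def subset_refit(
    matrix: MetaboliteMatrix | pd.DataFrame,
    cohort: pd.DataFrame,
    K: KinshipMatrix,
    predicate: pd.Series,
    alpha: float = 0.05,
    min_margin: int = 5,
    design_kwargs: dict | None = None,
    interaction_screen: str = "sqrt_age:sqrt_weight",
) -> AssociationTable:
    """Refit the panel on the rows where ``predicate`` is True.

    The metabolite matrix, cohort table and K are subset consistently;
    the subset must keep at least p + ``min_margin`` dogs.
    """
    values = matrix.values if isinstance(matrix, MetaboliteMatrix) else matrix
    keep = predicate.reindex(values.index)
    if keep.isna().any():
        raise ValueError("predicate does not cover every sample")
    ids = values.index[keep.astype(bool)]
    sub_design = build_design(cohort.loc[ids], **(design_kwargs or {}))
    if len(ids) < sub_design.p + min_margin:
        raise ValueError(
            f"subset keeps {len(ids)} dogs; need at least {sub_design.p + min_margin}"
        )
    return mwas(
        values.loc[ids],
        cohort.loc[ids],
        K.subset(list(ids)),
        alpha=alpha,
        interaction_screen=interaction_screen,
        design_kwargs=design_kwargs,
    )
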