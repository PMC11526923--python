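"""Genetic relatedness from biallelic dosages and breed classification.

The relatedness matrix is the variance-standardized GRM

    K_ij = (1/m) * sum_k z_ik z_jk,   z_ik = (g_ik - 2 p_k) / sqrt(2 p_k (1 - p_k))

with ``p_k`` the sample allele frequency of marker ``k``.  Residual missing
dosages after call-rate filtering are imputed with the marker mean ``2 p_k``
before standardization.  Allele frequencies always come from the analyzed
sample itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io

log = logging.getLogger(__name__)

REMAINING = "remaining"


@dataclass
class KinshipMatrix:
    """Variance-standardized relatedness among dogs."""

    K: np.ndarray
    dog_ids: list[str]
    n_markers: int = 0

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        self.dog_ids = [str(d) for d in self.dog_ids]
        n = len(self.dog_ids)
        if self.K.shape != (n, n):
            raise ValueError(f"K has shape {self.K.shape}, expected ({n}, {n})")
        asym = np.max(np.abs(self.K - self.K.T)) if n else 0.0
        if asym > 1e-10:
            raise ValueError(f"K is not symmetric (max |K - K'| = {asym:.3g})")

    @property
    def n(self) -> int:
        return len(self.dog_ids)

    def is_psd(self, rtol: float = 1e-8) -> bool:
        w = np.linalg.eigvalsh(self.K)
        return w.min() >= -rtol * max(w.max(), 1.0)

    def subset(self, ids: list[str]) -> "KinshipMatrix":
        """Principal submatrix for ``ids`` (kept in the given order)."""
        pos = {d: i for i, d in enumerate(self.dog_ids)}
        missing = [d for d in ids if str(d) not in pos]
        if missing:
            raise KeyError(f"ids not in kinship matrix: {missing[:5]}")
        idx = np.array([pos[str(d)] for d in ids])
        return KinshipMatrix(self.K[np.ix_(idx, idx)], list(map(str, ids)), self.n_markers)

    def to_rel(self, path) -> None:
        io.write_rel(self.K, self.dog_ids, path)

    @classmethod
    def from_rel(cls, path) -> "KinshipMatrix":
        K, ids = io.read_rel(path)
        return cls(K, ids)

    @classmethod
    def identity(cls, dog_ids: list[str]) -> "KinshipMatrix":
        return cls(np.eye(len(dog_ids)), list(dog_ids))


def filter_snps(
    genotypes: pd.DataFrame,
    min_maf: float = 0.01,
    min_callrate: float = 0.95,
) -> pd.DataFrame:
    """Keep SNPs with MAF > ``min_maf`` and call rate > ``min_callrate``.

    ``genotypes`` is dogs x SNPs with dosages in {0, 1, 2} and NaN for missing.
    Both thresholds are strict inequalities.
    """
    G = genotypes.to_numpy(dtype=float)
    bad = ~(np.isnan(G) | np.isin(G, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"dosage {G[i, j]!r} at dog {genotypes.index[i]!r}, "
            f"SNP {genotypes.columns[j]!r} is not in {{0, 1, 2, NaN}}"
        )
    callrate = 1.0 - np.isnan(G).mean(axis=0)
    p = np.nanmean(G, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = (maf > min_maf) & (callrate > min_callrate)
    if not keep.any():
        raise ValueError(
            f"no SNPs pass MAF > {min_maf} and call rate > {min_callrate}"
        )
    dropped = int((~keep).sum())
    if dropped:
        log.info("filter_snps: dropped %d of %d SNPs", dropped, len(keep))
    return genotypes.loc[:, keep]


def compute_grm(genotypes: pd.DataFrame) -> KinshipMatrix:
    """Variance-standardized GRM from filtered dosages.

    Missing dosages are mean-imputed per SNP; a zero-variance SNP at this
    stage is an internal error (the filter removes them).
    """
    G = genotypes.to_numpy(dtype=float)
    p = np.nanmean(G, axis=0) / 2.0
    var = 2.0 * p * (1.0 - p)
    if (var <= 0).any():
        raise RuntimeError("zero-variance SNP reached compute_grm; filter first")
    G = np.where(np.isnan(G), 2.0 * p, G)
    Z = (G - 2.0 * p) / np.sqrt(var)
    m = Z.shape[1]
    K = (Z @ Z.T) / m
    K = (K + K.T) / 2.0
    return KinshipMatrix(K, list(genotypes.index.astype(str)), n_markers=m)


@dataclass
class AncestryTable:
    """Per-dog breed ancestry proportions (rows sum to 1)."""

    proportions: pd.DataFrame  # dogs x breeds
    tol: float = 1e-6

    def __post_init__(self) -> None:
        P = self.proportions.to_numpy(dtype=float)
        if (P < -self.tol).any() or (P > 1 + self.tol).any():
            raise ValueError("ancestry proportions must lie in [0, 1]")
        rs = P.sum(axis=1)
        off = np.abs(rs - 1.0)
        if off.max() > self.tol:
            bad = self.proportions.index[int(off.argmax())]
            raise ValueError(f"ancestry rows must sum to 1; dog {bad!r} sums to {rs[off.argmax()]:.6f}")

    @property
    def max_breed(self) -> pd.Series:
        return self.proportions.idxmax(axis=1)

    @property
    def max_proportion(self) -> pd.Series:
        return self.proportions.max(axis=1)


def classify_purebred(
    ancestry: AncestryTable,
    threshold: float = 0.85,
    min_dogs: int = 8,
    require_both_sexes: bool = False,
    sex: pd.Series | None = None,
) -> pd.Series:
    """Label each dog with its majority breed or ``"remaining"``.

    A dog is purebred when its maximum ancestry proportion is >= ``threshold``
    (inclusive).  A breed is kept as an analysis level only when at least
    ``min_dogs`` qualifying dogs carry it and, if ``require_both_sexes``,
    both sexes are represented among them; otherwise its dogs fall back to
    ``"remaining"``.
    """
    labels = ancestry.max_breed.where(ancestry.max_proportion >= threshold, REMAINING)
    if require_both_sexes and sex is None:
        raise ValueError("require_both_sexes needs a per-dog sex series")
    for breed, members in labels[labels != REMAINING].groupby(labels):
        ok = len(members) >= min_dogs
        if ok and require_both_sexes:
            ok = sex.loc[members.index].nunique() >= 2
        if not ok:
            labels.loc[members.index] = REMAINING
    return labels.rename("breed")
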