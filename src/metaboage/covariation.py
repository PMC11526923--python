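"""Residual covariation among metabolites after full mixed-model adjustment.

Adjusted values are y' = y - X beta_hat - u_hat (fixed effects and BLUPs both
removed).  Pairwise Pearson correlations on y' get exact-t p-values and
BH-FDR across all unordered pairs, and the correlation structure is clustered
by UPGMA on the distance 1 - r (signed: positive covariation is close).

UPGMA convention: merge height is the full average distance between the two
clusters (not the half-height); ties are broken by lexicographic label order,
so the agglomeration is deterministic under input permutation.  Newick branch
lengths are ultrametric (height / 2 minus the child's half-height).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import AssociationTable, fdr_adjust
from .preprocess import MetaboliteMatrix

log = logging.getLogger(__name__)

METABOLITE_CLASSES = ("ptmAA", "parent_AA", "ambiguous", "N_waste", "other")


@dataclass
class AdjustedMatrix:
    """Fully adjusted residual values with provenance to the fits used."""

    values: pd.DataFrame
    provenance: AssociationTable | None = None


def adjust(
    matrix: MetaboliteMatrix | pd.DataFrame, fits: AssociationTable
) -> AdjustedMatrix:
    """y' = y - X beta_hat - u_hat per metabolite; unfitted metabolites dropped."""
    values = matrix.values if isinstance(matrix, MetaboliteMatrix) else matrix
    X = fits.design.values()
    out = {}
    for met in values.columns:
        fit = fits.fits.get(met)
        if fit is None or not fit.converged:
            log.warning("adjust: no converged fit for %r, excluded", met)
            continue
        out[met] = values[met].to_numpy(dtype=float) - X @ fit.beta.to_numpy() - fit.blups
    if not out:
        raise ValueError("no metabolite had a converged fit")
    return AdjustedMatrix(pd.DataFrame(out, index=values.index), fits)


@dataclass
class Node:
    """Dendrogram node; ``height`` is the full merge distance (0 for leaves)."""

    label: str
    height: float = 0.0
    children: tuple["Node", "Node"] | None = None

    @property
    def min_leaf(self) -> str:
        if self.children is None:
            return self.label
        return min(c.min_leaf for c in self.children)

    def newick(self) -> str:
        return self._newick(parent_height=self.height) + ";"

    def _newick(self, parent_height: float) -> str:
        bl = (parent_height - self.height) / 2.0
        if self.children is None:
            return f"{self.label}:{bl:.10g}"
        inner = ",".join(c._newick(self.height) for c in self.children)
        return f"({inner}):{bl:.10g}"


@dataclass
class UPGMATree:
    root: Node
    merges: list[tuple[str, str, float]]  # (cluster label, cluster label, height)

    def newick(self) -> str:
        return self.root.newick()

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]


def upgma(distance: pd.DataFrame) -> UPGMATree:
    """Unweighted pair-group agglomeration on a symmetric distance matrix.

    Ties in the minimum distance are broken by the lexicographically
    smallest (label, label) pair.  Merge heights are non-decreasing.
    """
    D = distance.to_numpy(dtype=float)
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if distance.shape[0] != distance.shape[1]:
        raise ValueError("distance matrix must be square")
    labels = [str(c) for c in distance.columns]
    if len(labels) < 2:
        raise ValueError("need at least two items to cluster")
    clusters: dict[str, Node] = {lab: Node(lab) for lab in labels}
    sizes: dict[str, int] = {lab: 1 for lab in labels}
    key: dict[str, str] = {lab: lab for lab in labels}  # cluster -> sort key (min leaf)
    dist: dict[frozenset, float] = {}
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            dist[frozenset((a, labels[j]))] = float(D[i, j])
    merges: list[tuple[str, str, float]] = []
    counter = 0
    while len(clusters) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted(key[c] for c in kv[0]))),
        )
        pair, h = best
        a, b = sorted(pair, key=lambda c: key[c])
        node = Node(
            label=f"node_{counter}",
            height=h,
            children=(clusters[a], clusters[b]),
        )
        counter += 1
        merges.append((key[a], key[b], h))
        new = node.label
        for other in list(clusters):
            if other in (a, b):
                continue
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((new, other))] = (
                sizes[a] * da + sizes[b] * db
            ) / (sizes[a] + sizes[b])
        dist.pop(frozenset((a, b)))
        clusters[new] = node
        sizes[new] = sizes.pop(a) + sizes.pop(b)
        key[new] = min(key.pop(a), key.pop(b))
        del clusters[a], clusters[b]
    return UPGMATree(root=next(iter(clusters.values())), merges=merges)


@dataclass
class CorrelationClustering:
    r: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    tree: UPGMATree | None = None
    class_labels: pd.Series | None = None

    def significant_pairs(self, alpha: float = 0.05) -> pd.DataFrame:
        cols = self.q.columns
        rows = []
        for i, a in enumerate(cols):
            for j in range(i + 1, len(cols)):
                b = cols[j]
                if self.q.iloc[i, j] <= alpha:
                    rows.append({"a": a, "b": b, "r": self.r.iloc[i, j], "q": self.q.iloc[i, j]})
        return pd.DataFrame(rows, columns=["a", "b", "r", "q"])


def correlate_fdr(
    adjusted: AdjustedMatrix | pd.DataFrame,
    alpha: float = 0.05,
    extra_columns: pd.DataFrame | None = None,
    class_labels: pd.Series | None = None,
    cluster: bool = True,
) -> CorrelationClustering:
    """Pearson r for all pairs with exact-t p-values and BH-FDR.

    ``extra_columns`` (e.g. clinical creatinine / BUN) are appended before
    correlating.  Zero-variance columns yield NaN correlations for their
    pairs.  The UPGMA tree uses distance 1 - r over columns with no NaN.
    """
    values = adjusted.values if isinstance(adjusted, AdjustedMatrix) else adjusted
    if extra_columns is not None:
        values = pd.concat([values, extra_columns.reindex(values.index)], axis=1)
    n = values.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for correlation inference")
    X = values.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R[sd == 0, :] = np.nan
    R[:, sd == 0] = np.nan
    np.fill_diagonal(R, 1.0)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        rr = np.clip(R, -1.0, 1.0)
        t = rr * np.sqrt(df / np.maximum(1.0 - rr**2, 1e-300))
    P = 2.0 * stats.t.sf(np.abs(t), df)
    P = np.where(np.isnan(R), np.nan, P)
    np.fill_diagonal(P, np.nan)
    iu = np.triu_indices(R.shape[0], k=1)
    q_flat = fdr_adjust(P[iu])
    Q = np.full_like(P, np.nan)
    Q[iu] = q_flat
    Q.T[iu] = q_flat
    cols = values.columns
    rdf = pd.DataFrame(R, index=cols, columns=cols)
    result = CorrelationClustering(
        r=rdf,
        p=pd.DataFrame(P, index=cols, columns=cols),
        q=pd.DataFrame(Q, index=cols, columns=cols),
        class_labels=class_labels,
    )
    if cluster:
        ok = ~rdf.isna().any(axis=0)
        if ok.sum() >= 2:
            result.tree = upgma(1.0 - rdf.loc[ok, ok])
    return result
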