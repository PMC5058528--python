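"""Ordination and distance-based tests for dominant-marker genotypes.

* Jaccard distances between 0/1 genotypes (shared band presences only);
* nonmetric multidimensional scaling (NMDS) minimizing Kruskal stress-1, best
  of several restarts (restart 1 starts from classical metric scaling, the
  rest from random configurations);
* a goodness-of-fit test of a categorical factor on the ordination scores
  (R-squared of group centroids, permutation p) -- the categorical analogue of
  vegan's envfit;
* distance-based permutational MANOVA with sequential terms and optional
  nesting (the McArdle-Anderson projection construction behind vegan's
  adonis), with pseudo-F significance from permutations, optionally within
  strata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from skbio import DistanceMatrix
from sklearn.manifold import MDS

from .containers import MarkerMatrix


def jaccard_matrix(matrix: MarkerMatrix) -> DistanceMatrix:
    """Pairwise Jaccard distances 1 - |intersection| / |union| of band sets."""
    primary = matrix.primary()
    X = primary.calls.to_numpy().astype(bool)
    empty = ~X.any(axis=1)
    if empty.any():
        bad = list(primary.calls.index[empty])
        raise ValueError(f"samples with no band presences (Jaccard undefined): {bad}")
    d = squareform(pdist(X, metric="jaccard"))
    return DistanceMatrix(d, ids=list(primary.calls.index))


@dataclass
class OrdinationResult:
    scores: pd.DataFrame      # samples x k, centered
    stress: float             # Kruskal stress-1, as a fraction
    n_restarts: int
    best_restart: int


def _pcoa_coords(d: np.ndarray, k: int) -> np.ndarray:
    """Classical metric scaling coordinates (top-k, negative eigenvalues clipped)."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def nmds(d: DistanceMatrix, k: int = 2, n_restarts: int = 20, max_iter: int = 300,
         seed: int = 0) -> OrdinationResult:
    """Nonmetric MDS of a distance matrix, best of ``n_restarts``.

    Stress is Kruskal stress-1 reported as a fraction in [0, 1].
    """
    ids = list(d.ids)
    arr = d.data
    if len(ids) < k + 2:
        raise ValueError("need at least k + 2 samples")
    best = None
    rng = np.random.default_rng(seed)
    n = len(ids)
    for restart in range(n_restarts):
        mds = MDS(n_components=k, metric_mds=False, metric="precomputed",
                  max_iter=max_iter, n_init=1, init="random",
                  normalized_stress=True,
                  random_state=int(rng.integers(2 ** 31)))
        init = _pcoa_coords(arr, k) if restart == 0 \
            else rng.normal(size=(n, k)) * arr.max()
        scores = mds.fit_transform(arr, init=init)
        if best is None or mds.stress_ < best[0]:
            best = (float(mds.stress_), scores, restart)
    stress, scores, best_restart = best
    scores = scores - scores.mean(axis=0, keepdims=True)
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=ids,
                            columns=[f"NMDS{i + 1}" for i in range(k)]),
        stress=stress, n_restarts=n_restarts, best_restart=best_restart)


def _centroid_r2(X: np.ndarray, labels: np.ndarray) -> float:
    grand = X.mean(axis=0)
    ss_total = float(((X - grand) ** 2).sum())
    ss_within = 0.0
    for g in np.unique(labels):
        block = X[labels == g]
        ss_within += float(((block - block.mean(axis=0)) ** 2).sum())
    if ss_total == 0:
        return 0.0
    return 1.0 - ss_within / ss_total


def fit_factor(ordination: OrdinationResult, factor, n_perm: int = 5000,
               seed: int = 0):
    """Goodness of fit of a categorical factor on ordination scores.

    R-squared is the between-centroid fraction of the score sum of squares;
    p is the fraction of label permutations reaching the observed R-squared.
    Invariant to rotation/reflection of the scores.
    """
    X = ordination.scores.to_numpy()
    labels = np.asarray(pd.Series(factor).reindex(ordination.scores.index))
    if pd.isna(labels).any():
        raise ValueError("factor undefined for some samples")
    if len(np.unique(labels)) < 2:
        raise ValueError("factor has a single level")
    observed = _centroid_r2(X, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _centroid_r2(X, rng.permutation(labels)) >= observed - 1e-12:
            hits += 1
    return float(observed), float((hits + 1) / (n_perm + 1))


# ---------------------------------------------------------------------------
# distance-based permutational MANOVA
# ---------------------------------------------------------------------------

@dataclass
class PartitionTest:
    terms: list
    table: pd.DataFrame       # df, SS, R2, pseudo_F, p per term (+ residual, total)
    n_perm: int


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (d ** 2) @ j


def _dummy(series: pd.Series) -> np.ndarray:
    return pd.get_dummies(series.astype(str), drop_first=False).to_numpy(float)


def _term_columns(term: str, meta: pd.DataFrame) -> np.ndarray:
    """Design columns for a term: a metadata column or interaction 'a:b'."""
    parts = term.split(":")
    for p in parts:
        if p not in meta.columns:
            raise ValueError(f"unknown factor {p!r} in term {term!r}")
    if len(parts) == 1:
        return _dummy(meta[parts[0]])
    combined = meta[parts[0]].astype(str)
    for p in parts[1:]:
        combined = combined + "|" + meta[p].astype(str)
    return _dummy(combined)


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def adonis(d: DistanceMatrix, metadata: pd.DataFrame, terms, n_perm: int = 5000,
           seed: int = 0, strata: str | None = None) -> PartitionTest:
    """Sequential distance-based MANOVA (McArdle-Anderson partitioning).

    ``terms`` are fitted in order; each is a metadata column or an interaction
    ``"a:b"`` (nesting "host within location" is the sequence
    ``["location", "location:host"]``).  Permutations shuffle observations
    freely, or within the levels of ``strata`` when given.  R-squared terms
    plus residual sum to 1 by construction.
    """
    ids = list(d.ids)
    meta = metadata.loc[ids]
    n = len(ids)
    g = _gower_center(d.data)
    total_ss = float(np.trace(g))

    designs = [np.ones((n, 1))]
    ranks = [1]
    for term in terms:
        X = np.hstack([designs[-1], _term_columns(term, meta)])
        rank = np.linalg.matrix_rank(X)
        if rank == ranks[-1]:
            raise ValueError(f"term {term!r} is confounded with earlier terms")
        designs.append(X)
        ranks.append(rank)
    hats = [_hat(X) for X in designs]
    df_terms = [ranks[i + 1] - ranks[i] for i in range(len(terms))]
    df_res = n - ranks[-1]
    if df_res <= 0:
        raise ValueError("saturated design; no residual degrees of freedom")

    def partition(gm):
        # tr(H G) = sum(H * G) since both are symmetric
        traces = [float((h * gm).sum()) for h in hats]
        ss = [traces[i + 1] - traces[i] for i in range(len(terms))]
        ss_res = float(np.trace(gm)) - traces[-1]
        fs = [(s / df) / (ss_res / df_res) for s, df in zip(ss, df_terms)]
        return ss, ss_res, fs

    ss, ss_res, f_obs = partition(g)

    rng = np.random.default_rng(seed)
    hits = np.zeros(len(terms))
    if n_perm:
        if strata is not None:
            strata_labels = meta[strata].to_numpy()
            groups = [np.flatnonzero(strata_labels == s)
                      for s in pd.unique(strata_labels)]
        for _ in range(n_perm):
            perm = np.arange(n)
            if strata is None:
                perm = rng.permutation(n)
            else:
                for rows in groups:
                    perm[rows] = rows[rng.permutation(len(rows))]
            gp = g[np.ix_(perm, perm)]
            _, _, fp = partition(gp)
            hits += np.asarray(fp) >= np.asarray(f_obs) - 1e-12
    pvals = (hits + 1) / (n_perm + 1) if n_perm else [np.nan] * len(terms)

    rows = []
    for term, df, s, f, p in zip(terms, df_terms, ss, f_obs, pvals):
        rows.append({"term": term, "df": df, "SS": s, "R2": s / total_ss,
                     "pseudo_F": f, "p": float(p)})
    rows.append({"term": "residual", "df": df_res, "SS": ss_res,
                 "R2": ss_res / total_ss, "pseudo_F": np.nan, "p": np.nan})
    rows.append({"term": "total", "df": n - 1, "SS": total_ss, "R2": 1.0,
                 "pseudo_F": np.nan, "p": np.nan})
    table = pd.DataFrame(rows).set_index("term")
    return PartitionTest(terms=list(terms), table=table, n_perm=n_perm)
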