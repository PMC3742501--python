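"""Call-type clustering and cluster-validity assessment.

Calls are partitioned in the standardized 8-feature space with k-means
(Lloyd's algorithm, best of many seeded restarts). Solutions for K = 1..Kmax
are summarised by two validity indices built on the within-cluster sum of
squares WSS_K:

    EtaK = 1 - WSS_K / WSS_1        (variance reduction vs. no clustering)
    PreK = 1 - WSS_K / WSS_{K-1}    (improvement over the previous K)

Both indices telescope: 1 - EtaK(K) equals the product of (1 - PreK(j)) for
j = 2..K. The repertoire is characterised at K = 2 (low- vs high-frequency
calls, LF/HF) and K = 5 (LFs, LFm, LFt, HFs, HFm), with representative
calls (nearest the centroid) and discriminant-function loadings describing
each cluster.

The k-means implementation is local so the restart policy, the empty-cluster
repair and every tie-break are deterministic and seed-controlled: initial
centroids are sampled without replacement from the data; an emptied cluster
is reseeded from the point farthest from its assigned centroid; each K also
tries a warm start that splits the best (K-1) solution at its worst-fit
point, which guarantees WSS never increases in K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .acoustics import FEATURE_NAMES


@dataclass
class ClusterSolution:
    """A k-means partition: assignments, centroids and total WSS."""

    K: int
    assignments: np.ndarray  # (n,) cluster ids 0..K-1
    centroids: np.ndarray  # (K, p)
    wss: float


@dataclass
class ClusterValidityCurve:
    """Per-K within-cluster sum of squares and the EtaK/PreK indices."""

    K: np.ndarray
    wss: np.ndarray
    etaK: np.ndarray
    preK: np.ndarray  # preK[0] (K=1) is NaN

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"K": self.K, "wss": self.wss, "etaK": self.etaK, "preK": self.preK})


# ---------------------------------------------------------------------------
# k-means


def _assign(X: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)  # argmin ties -> lowest cluster id
    return labels, d2[np.arange(X.shape[0]), labels]


def _lloyd(X: np.ndarray, centroids: np.ndarray, max_iter: int = 300) -> ClusterSolution:
    K = centroids.shape[0]
    labels = np.full(X.shape[0], -1)
    for _ in range(max_iter):
        new_labels, d2 = _assign(X, centroids)
        for k in range(K):  # repair empties from the farthest point
            if not np.any(new_labels == k):
                far = int(np.argmax(d2))
                centroids[k] = X[far]
                new_labels[far] = k
                d2[far] = 0.0
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for k in range(K):
            centroids[k] = X[labels == k].mean(axis=0)
    labels, d2 = _assign(X, centroids)
    return ClusterSolution(K=K, assignments=labels, centroids=centroids, wss=float(d2.sum()))


def kmeans_partition(
    X: np.ndarray,
    K: int,
    n_restarts: int = 50,
    seed: int = 0,
    warm_start: ClusterSolution | None = None,
) -> ClusterSolution:
    """Best-of-restarts k-means partition into K clusters.

    Initial centroids for each restart are K distinct data points sampled
    without replacement. If ``warm_start`` (a K-1 solution on the same
    data) is given, one extra candidate splits it at its worst-fit point.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds the number of points ({n})")
    if K > np.unique(X, axis=0).shape[0]:
        raise ValueError(f"K={K} exceeds the number of distinct points")
    rng = np.random.default_rng(seed)
    best: ClusterSolution | None = None
    for _ in range(n_restarts):
        init = X[rng.choice(n, size=K, replace=False)].copy()
        sol = _lloyd(X, init)
        if best is None or sol.wss < best.wss:
            best = sol
    if warm_start is not None and warm_start.K == K - 1:
        _, d2 = _assign(X, warm_start.centroids)
        init = np.vstack([warm_start.centroids, X[int(np.argmax(d2))]])
        sol = _lloyd(X, init.copy())
        if sol.wss < best.wss:
            best = sol
    return best


def total_sum_of_squares(X: np.ndarray) -> float:
    X = np.asarray(X, dtype=np.float64)
    return float(((X - X.mean(axis=0)) ** 2).sum())


def validity_curve(
    X: np.ndarray, Kmax: int = 15, n_restarts: int = 50, seed: int = 0
) -> tuple[ClusterValidityCurve, dict[int, ClusterSolution]]:
    """Cluster X for K = 1..Kmax and compute the EtaK/PreK validity curve.

    Returns the curve and the per-K solutions. WSS_1 is the total sum of
    squares about the grand mean; EtaK(1) = 0 and PreK(1) is undefined
    (NaN).
    """
    if Kmax < 2:
        raise ValueError("Kmax must be >= 2")
    X = np.asarray(X, dtype=np.float64)
    seeds = np.random.SeedSequence(seed).spawn(Kmax + 1)
    wss = np.empty(Kmax)
    wss[0] = total_sum_of_squares(X)
    solutions: dict[int, ClusterSolution] = {
        1: ClusterSolution(
            K=1,
            assignments=np.zeros(X.shape[0], dtype=int),
            centroids=X.mean(axis=0, keepdims=True),
            wss=wss[0],
        )
    }
    for K in range(2, Kmax + 1):
        sol = kmeans_partition(
            X,
            K,
            n_restarts=n_restarts,
            seed=int(seeds[K].generate_state(1)[0] % 2**31),
            warm_start=solutions[K - 1],
        )
        solutions[K] = sol
        wss[K - 1] = sol.wss
    etaK = 1.0 - wss / wss[0]
    preK = np.full(Kmax, np.nan)
    preK[1:] = 1.0 - wss[1:] / wss[:-1]
    return (
        ClusterValidityCurve(K=np.arange(1, Kmax + 1), wss=wss, etaK=etaK, preK=preK),
        solutions,
    )


# ---------------------------------------------------------------------------
# cluster characterisation


def representative_call(
    X: np.ndarray, solution: ClusterSolution, cluster_id: int, call_ids=None
) -> int | str:
    """The call with the shortest Euclidean distance to its cluster centre.

    Ties break to the lowest call index/id. Returns the call id if
    ``call_ids`` is given, else the row index.
    """
    members = np.flatnonzero(solution.assignments == cluster_id)
    if members.size == 0:
        raise ValueError(f"cluster {cluster_id} is empty")
    d2 = ((np.asarray(X)[members] - solution.centroids[cluster_id]) ** 2).sum(axis=1)
    winner = members[int(np.argmin(d2))]
    return call_ids[winner] if call_ids is not None else int(winner)


def name_call_types(
    solution: ClusterSolution, features_natural: pd.DataFrame
) -> dict[int, str]:
    """Map cluster ids to repertoire names using natural-unit profiles.

    K=2 splits by mean q50 into LF/HF. K=5 names the two highest-q50
    clusters HF (the more frequency-modulated one HFm, the other HFs) and,
    among the LF clusters, the lowest-entropy one LFt, the most modulated
    of the rest LFm and the remainder LFs. Other K get generic names.
    """
    K = solution.K
    if K not in (2, 5):
        warnings.warn(f"no canonical names for K={K}; using generic labels", stacklevel=2)
        return {k: f"C{k + 1}" for k in range(K)}
    stats = features_natural.groupby(solution.assignments).mean()
    q50 = stats["q50"]
    if K == 2:
        hf = q50.idxmax()
        return {k: ("HF" if k == hf else "LF") for k in range(2)}
    names: dict[int, str] = {}
    hf_ids = list(q50.sort_values(ascending=False).index[:2])
    modulation = (stats["q50end"] - stats["q50start"]).abs()
    hfm = max(hf_ids, key=lambda k: modulation[k])
    names[hfm] = "HFm"
    names[[k for k in hf_ids if k != hfm][0]] = "HFs"
    lf_ids = [k for k in range(5) if k not in hf_ids]
    lft = min(lf_ids, key=lambda k: stats["ent"][k])
    names[lft] = "LFt"
    rest = [k for k in lf_ids if k != lft]
    lfm = max(rest, key=lambda k: modulation[k])
    names[lfm] = "LFm"
    names[[k for k in rest if k != lfm][0]] = "LFs"
    return names


def nesting_crosstab(
    solution_a: ClusterSolution, solution_b: ClusterSolution
) -> pd.DataFrame:
    """Proportion of each cluster of ``solution_b`` falling in each cluster
    of ``solution_a`` (rows: b-clusters; rows sum to 1)."""
    if solution_a.assignments.shape != solution_b.assignments.shape:
        raise ValueError("solutions must partition the same call set")
    table = pd.crosstab(solution_b.assignments, solution_a.assignments)
    table = table.reindex(
        index=range(solution_b.K), columns=range(solution_a.K), fill_value=0
    )
    return table.div(table.sum(axis=1), axis=0)


def cluster_dfa_loadings(X: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Standardized discriminant-function loadings of each variable.

    Solves the generalized eigenproblem of the between- versus within-class
    scatter matrices; coefficients are scaled by the pooled within-class SD
    of each variable so their magnitudes are comparable. Columns are
    discriminant functions ordered by decreasing eigenvalue.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 cluster labels")
    grand = X.mean(axis=0)
    p = X.shape[1]
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for c in classes:
        Xc = X[labels == c]
        if Xc.shape[0] < 2:
            raise ValueError(f"cluster {c} has fewer than 2 members")
        diff = Xc - Xc.mean(axis=0)
        Sw += diff.T @ diff
        d = (Xc.mean(axis=0) - grand)[:, None]
        Sb += Xc.shape[0] * (d @ d.T)
    try:
        from scipy.linalg import eigh

        eigvals, eigvecs = eigh(Sb, Sw)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "pooled within-class scatter is singular; drop collinear variables "
            "or add a ridge"
        ) from exc
    order = np.argsort(eigvals)[::-1][: classes.size - 1]
    coefs = eigvecs[:, order]
    pooled_sd = np.sqrt(np.diag(Sw) / (X.shape[0] - classes.size))
    loadings = coefs * pooled_sd[:, None]
    columns = [f"DF{i + 1}" for i in range(loadings.shape[1])]
    index = FEATURE_NAMES if p == len(FEATURE_NAMES) else [f"x{i + 1}" for i in range(p)]
    return pd.DataFrame(loadings, index=index, columns=columns)


def label_agreement(true_labels, predicted) -> float:
    """Best agreement between two labelings after Hungarian matching of
    the label sets (fraction of calls on the matched diagonal)."""
    table = pd.crosstab(pd.Series(true_labels), pd.Series(predicted)).to_numpy()
    rows, cols = linear_sum_assignment(-table)
    return float(table[rows, cols].sum() / table.sum())
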