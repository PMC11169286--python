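"""Parcel-wise and network-level group comparisons of aligned gradients.

Each node's gradient score is regressed on diagnostic group plus nuisance
covariates (age, sex, APOE-e4); the resulting t-map is cleaned with a
cluster-extent filter on the parcel adjacency graph.  The global
"contraction" of a gradient — poles moving toward the center — is
summarized per subject as the standard deviation of that component's
scores across nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csgraph, csr_matrix

from .errors import InvalidParameterError

DEFAULT_COVARIATES = ("age", "sex", "apoe4")


@dataclass
class StatMap:
    """Parcel-wise test statistics with p-values and a significance mask."""

    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    contrast_label: str = ""
    covariates_used: tuple = ()
    estimate: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.p = np.asarray(self.p, float)
        self.significant = np.asarray(self.significant, bool)
        ok = np.isfinite(self.p)
        if ((self.p[ok] < 0) | (self.p[ok] > 1)).any():
            raise InvalidParameterError("p-values must lie in [0, 1]")


def _design_matrix(covariates: pd.DataFrame | None, index=None) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.empty((0 if index is None else len(index), 0)), []
    cov = covariates if index is None else covariates.loc[index]
    return cov.to_numpy(dtype=float), list(cov.columns)


def ols_tmap(X: np.ndarray, Y: np.ndarray, term: int, names=None):
    """Vectorized OLS of many outcomes on one shared design matrix.

    Returns (beta, t, p) for column ``term`` of ``X`` across all columns of
    ``Y``.  Raises on rank deficiency, naming the collinear columns.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        names = names or [f"x{j}" for j in range(k)]
        bad = _collinear_columns(X, names)
        raise InvalidParameterError(f"design matrix is rank deficient; collinear columns: {bad}")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * xtx_inv[term, term])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[term] / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta[term], t, p


def _collinear_columns(X, names):
    """Identify a minimal set of columns involved in the rank deficiency."""
    bad = []
    kept = []
    for j in range(X.shape[1]):
        trial = kept + [j]
        if np.linalg.matrix_rank(X[:, trial]) < len(trial):
            bad.append(names[j])
        else:
            kept.append(j)
    return bad


def node_contrast(
    scores,
    component_index: int,
    groups,
    group_a: str,
    group_b: str,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> StatMap:
    """Per-node OLS of gradient score on group (A vs B) plus covariates.

    ``scores`` is (S, N, K) or (S, N); ``groups`` is length S.  The t and
    two-sided p are for the group term (indicator of ``group_a``).
    """
    scores = np.asarray(scores, float)
    groups = np.asarray(groups)
    if scores.ndim == 3:
        scores = scores[:, :, component_index]
    sel = np.isin(groups, [group_a, group_b])
    if not (groups == group_a).any() or not (groups == group_b).any():
        raise InvalidParameterError("both groups must be non-empty")
    y = scores[sel]
    g = (groups[sel] == group_a).astype(float)
    cov, cov_names = _design_matrix(covariates)
    cov = cov[sel] if cov.size else np.empty((sel.sum(), 0))
    X = np.column_stack([np.ones(sel.sum()), g, cov])
    names = ["intercept", "group", *cov_names]
    est, t, p = ols_tmap(X, y, term=1, names=names)
    return StatMap(
        t=t,
        p=p,
        significant=p < alpha,
        contrast_label=f"{group_a} vs {group_b}",
        covariates_used=tuple(cov_names),
        estimate=est,
    )


def parcel_adjacency(centroids: np.ndarray, k: int = 6) -> np.ndarray:
    """Boolean adjacency from k-nearest centroids, symmetrized by union."""
    c = np.asarray(centroids, float)
    n = c.shape[0]
    d = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    adj = np.zeros((n, n), dtype=bool)
    nearest = np.argsort(d, axis=1, kind="stable")[:, :k]
    adj[np.arange(n)[:, None], nearest] = True
    return adj | adj.T


def cluster_fwe(
    statmap: StatMap,
    adjacency: np.ndarray,
    p_threshold: float = 0.01,
    min_cluster_size: int = 5,
) -> StatMap:
    """Extent-based family-wise cleanup: supra-threshold nodes are grouped
    into connected components on the parcel graph and components smaller
    than ``min_cluster_size`` parcels are unmasked."""
    adj = np.asarray(adjacency, bool)
    if not adj.any():
        raise InvalidParameterError("empty parcel adjacency")
    supra = statmap.p < p_threshold
    mask = np.zeros_like(supra)
    if supra.any():
        sub = adj[np.ix_(supra, supra)]
        n_comp, labels = csgraph.connected_components(csr_matrix(sub), directed=False)
        idx = np.flatnonzero(supra)
        for comp in range(n_comp):
            members = idx[labels == comp]
            if members.size >= min_cluster_size:
                mask[members] = True
    return StatMap(
        t=statmap.t,
        p=statmap.p,
        significant=mask,
        contrast_label=statmap.contrast_label,
        covariates_used=statmap.covariates_used,
        estimate=statmap.estimate,
        meta={**statmap.meta, "p_threshold": p_threshold, "min_cluster_size": min_cluster_size},
    )


def default_min_cluster_size(n_nodes: int, base: int = 5) -> int:
    """Extent threshold scaled to parcellation size (base parcels per ~100
    nodes)."""
    return max(1, int(round(base * n_nodes / 100.0)))


def network_summary(
    scores,
    component_index: int,
    network_labels,
    groups,
    group_a: str,
    group_b: str,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Group contrast of network-averaged gradient scores.

    Per network: each subject's mean score over the network's nodes is the
    outcome of an OLS on group + covariates.  Returns estimate, t, p, and
    the per-group SEM of the network means.
    """
    scores = np.asarray(scores, float)
    groups = np.asarray(groups)
    if scores.ndim == 3:
        scores = scores[:, :, component_index]
    labels = np.asarray(network_labels)
    sel = np.isin(groups, [group_a, group_b])
    g = (groups[sel] == group_a).astype(float)
    cov, cov_names = _design_matrix(covariates)
    cov = cov[sel] if cov.size else np.empty((int(sel.sum()), 0))
    X = np.column_stack([np.ones(int(sel.sum())), g, cov])
    rows = []
    for net in dict.fromkeys(labels.tolist()):
        nodes = labels == net
        if not nodes.any():
            raise InvalidParameterError(f"network {net!r} has no nodes")
        y = scores[sel][:, nodes].mean(axis=1)
        est, t, p = ols_tmap(X, y[:, None], term=1, names=["intercept", "group", *cov_names])
        rows.append(
            {
                "network": net,
                "estimate": float(est[0]),
                "t": float(t[0]),
                "p": float(p[0]),
                "sem_a": float(stats.sem(y[g == 1])),
                "sem_b": float(stats.sem(y[g == 0])),
            }
        )
    return pd.DataFrame(rows)


def contraction_metric(scores, component_index: int = 0):
    """Dispersion of a gradient component: SD of its scores across nodes.

    Lower values mean the gradient's poles have moved toward the center —
    the contraction signature.  Accepts one subject (N, K) -> scalar or a
    stack (S, N, K) -> per-subject vector.
    """
    scores = np.asarray(scores, float)
    if scores.ndim == 1:
        return float(scores.std())
    if scores.ndim == 2:
        return float(scores[:, component_index].std())
    return scores[:, :, component_index].std(axis=1)
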