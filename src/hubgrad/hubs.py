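"""Subject-specific gradient-space hub model of longitudinal tau accumulation.

For each participant, high-degree nodes of the thresholded, binarized
connectome are the *hubs*; for every region of interest the k hubs nearest
in low-dimensional (default 3D) gradient space are its *connected hubs*.
Baseline tau averaged within those hubs (separately for the functional and
structural connectome) then predicts the region's longitudinal tau
accumulation rate across participants:

    dtau_ROI ~ baseline tau_ROI + tau_FC_hubs + tau_SC_hubs + age + sex + APOE-e4

with a per-region OLS across participants and extent-based multiple
comparison cleanup on the t-maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contrasts import StatMap, cluster_fwe
from .embedding import threshold_rows
from .errors import InvalidParameterError

#: (n_hubs, k nearest) defaults per atlas scale: 50/10 at >= 1000 nodes,
#: 15/5 at ~100 nodes — proportionally similar hub fractions.
HUB_COUNTS = {"large": (50, 10), "small": (15, 5)}

SENSITIVITY_VARIANTS = ("nearest_any", "furthest_nonhub", "distance_predictors")


@dataclass
class HubSelection:
    """Hub node set and each ROI's ordered nearest-hub list for one
    subject and modality."""

    subject_id: str
    modality: str
    hub_nodes: np.ndarray
    per_roi_nearest: dict  # node -> ordered array of hub indices


def node_degree(connectome, sparsity: float = 0.20) -> np.ndarray:
    """Degree of the thresholded, binarized connectome.

    Row-wise thresholding is asymmetric, so the binary matrix is
    symmetrized by union before summing.
    """
    t = threshold_rows(connectome, sparsity)
    w = t.weights if hasattr(t, "weights") else t
    b = w != 0
    b = b | b.T
    np.fill_diagonal(b, False)
    return b.sum(axis=1).astype(int)


def select_hubs(degree_vector, n_hubs: int) -> np.ndarray:
    """Indices of the ``n_hubs`` highest-degree nodes; ties at the cutoff
    go to the lower node index."""
    deg = np.asarray(degree_vector)
    if n_hubs >= deg.size:
        raise InvalidParameterError(f"n_hubs={n_hubs} must be smaller than N={deg.size}")
    order = np.argsort(-deg, kind="stable")
    return np.sort(order[:n_hubs])


def nearest_hubs_in_gradient_space(gradients, hub_set, k: int, n_dims: int = 3) -> dict:
    """For each ROI, the k hubs with smallest Euclidean distance in the
    first ``n_dims`` gradient components, excluding the ROI itself.
    Ordered by distance; ties broken by node index."""
    scores = gradients.scores if hasattr(gradients, "scores") else np.asarray(gradients, float)
    coords = scores[:, :n_dims]
    hubs = np.asarray(sorted(hub_set), dtype=int)
    n = coords.shape[0]
    if hubs.size < k:
        raise InvalidParameterError(f"only {hubs.size} hubs available, need k={k}")
    d = np.sqrt(((coords[:, None, :] - coords[hubs][None, :, :]) ** 2).sum(-1))  # (N, H)
    per_roi = {}
    for roi in range(n):
        cand_mask = hubs != roi
        cand = hubs[cand_mask]
        if cand.size < k:
            raise InvalidParameterError(f"ROI {roi}: fewer than k={k} hubs after self-exclusion")
        dd = d[roi, cand_mask]
        order = np.lexsort((cand, dd))
        per_roi[roi] = cand[order[:k]]
    return per_roi


def select_neighbors_variant(gradients, hub_set, k: int, variant: str, n_dims: int = 3) -> dict:
    """Alternative neighbor selections for the sensitivity analyses:
    ``nearest_any`` (k nearest nodes regardless of hub status) and
    ``furthest_nonhub`` (k non-hubs at maximal gradient-space distance)."""
    scores = gradients.scores if hasattr(gradients, "scores") else np.asarray(gradients, float)
    coords = scores[:, :n_dims]
    n = coords.shape[0]
    hubs = set(int(h) for h in hub_set)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    per_roi = {}
    for roi in range(n):
        if variant == "nearest_any":
            cand = np.array([j for j in range(n) if j != roi])
            order = np.lexsort((cand, d[roi, cand]))
        elif variant == "furthest_nonhub":
            cand = np.array([j for j in range(n) if j != roi and j not in hubs])
            order = np.lexsort((cand, -d[roi, cand]))
        else:
            raise InvalidParameterError(f"unknown neighbor variant {variant!r}")
        if cand.size < k:
            raise InvalidParameterError(f"ROI {roi}: fewer than k={k} candidates")
        per_roi[roi] = cand[order[:k]]
    return per_roi


def build_hub_features(
    subject_ids, fc_selections, sc_selections, baseline_tau, delta_tau_maps
) -> pd.DataFrame:
    """Per subject x ROI: baseline tau averaged within the FC- and
    SC-selected hub lists, plus the ROI's own baseline tau and tau change.

    ``fc_selections``/``sc_selections`` map subject -> per-ROI nearest-hub
    dict (or HubSelection); ``baseline_tau``/``delta_tau_maps`` map subject
    -> N-vector.
    """
    rows = []
    for sid in subject_ids:
        for name, store in (("baseline tau", baseline_tau), ("delta tau", delta_tau_maps)):
            if sid not in store:
                raise InvalidParameterError(f"missing {name} map for subject {sid}")
        tau = np.asarray(
            getattr(baseline_tau[sid], "values", baseline_tau[sid]), float
        )
        dtau = np.asarray(getattr(delta_tau_maps[sid], "values", delta_tau_maps[sid]), float)
        fc = fc_selections[sid]
        sc = sc_selections[sid]
        fc_lists = fc.per_roi_nearest if isinstance(fc, HubSelection) else fc
        sc_lists = sc.per_roi_nearest if isinstance(sc, HubSelection) else sc
        for roi in range(tau.size):
            rows.append(
                {
                    "subject_id": sid,
                    "roi": roi,
                    "tau_fc_hubs": tau[fc_lists[roi]].mean(),
                    "tau_sc_hubs": tau[sc_lists[roi]].mean(),
                    "baseline_tau_roi": tau[roi],
                    "delta_tau_roi": dtau[roi],
                }
            )
    return pd.DataFrame(rows)


def build_distance_features(subject_ids, fc_selections, sc_selections, gradients, n_dims: int = 3):
    """Replace the hub-tau features with mean gradient-space distances to
    the selected hubs (the ``distance_predictors`` sensitivity variant).
    ``gradients`` maps subject -> {"FC": GradientSet, "SC": GradientSet}."""
    out = {}
    for sid in subject_ids:
        feats = np.empty((2, 0))
        per_mod = []
        for mod, sels in (("FC", fc_selections), ("SC", sc_selections)):
            coords = gradients[sid][mod].scores[:, :n_dims]
            lists = sels[sid]
            if isinstance(lists, HubSelection):
                lists = lists.per_roi_nearest
            vals = np.array(
                [
                    np.sqrt(((coords[lists[roi]] - coords[roi]) ** 2).sum(-1)).mean()
                    for roi in range(coords.shape[0])
                ]
            )
            per_mod.append(vals)
        out[sid] = {"FC": per_mod[0], "SC": per_mod[1]}
    return out


def _per_roi_ols(table, covariates, feature_cols):
    """Per-ROI OLS of delta_tau_roi on baseline tau + features + covariates
    across subjects.  Returns dict feature -> (t, p, beta) arrays over ROIs."""
    rois = np.sort(table["roi"].unique())
    n_roi = rois.size
    cov_names = list(covariates.columns) if covariates is not None else []
    res = {f: {"t": np.full(n_roi, np.nan), "p": np.ones(n_roi), "beta": np.full(n_roi, np.nan)}
           for f in feature_cols}
    failed = []
    for ridx, roi in enumerate(rois):
        sub = table[table["roi"] == roi]
        sids = sub["subject_id"].to_numpy()
        y = sub["delta_tau_roi"].to_numpy(float)
        cols = [np.ones(len(sub)), sub["baseline_tau_roi"].to_numpy(float)]
        cols += [sub[f].to_numpy(float) for f in feature_cols]
        if covariates is not None:
            cov = covariates.loc[sids].to_numpy(float)
            cols += [cov[:, j] for j in range(cov.shape[1])]
        X = np.column_stack(cols)
        n, kdim = X.shape
        if n <= kdim or np.linalg.matrix_rank(X) < kdim:
            failed.append(int(roi))
            continue
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ X.T @ y
        resid = y - X @ beta
        dof = n - kdim
        sigma2 = (resid**2).sum() / dof
        for fi, f in enumerate(feature_cols):
            j = 2 + fi
            se = np.sqrt(sigma2 * xtx_inv[j, j])
            t = beta[j] / se if se > 0 else 0.0
            res[f]["t"][ridx] = t
            res[f]["p"][ridx] = 2.0 * stats.t.sf(abs(t), dof)
            res[f]["beta"][ridx] = beta[j]
    return rois, res, failed, cov_names


def fit_accumulation_model(
    table: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    mode: str = "main",
    adjacency: np.ndarray | None = None,
    p_threshold: float = 1e-3,
    min_cluster_size: int | None = None,
    feature_cols: tuple = ("tau_fc_hubs", "tau_sc_hubs"),
):
    """Fit the hub accumulation model per ROI.

    ``mode="main"`` enters both hub features together; ``mode="single"``
    fits each alone.  Returns a (FC StatMap, SC StatMap) pair; ROIs with a
    collinear design are masked out and listed in ``meta["failed_rois"]``.
    """
    n_subj = table["subject_id"].nunique()
    if n_subj < 20:
        raise InvalidParameterError(f"need >= 20 subjects, got {n_subj}")
    if mode not in ("main", "single"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    maps = []
    for f in feature_cols:
        cols = feature_cols if mode == "main" else (f,)
        rois, res, failed, cov_names = _per_roi_ols(table, covariates, list(cols))
        r = res[f]
        sm = StatMap(
            t=r["t"],
            p=r["p"],
            significant=r["p"] < p_threshold,
            contrast_label=f"delta_tau ~ {f} ({mode})",
            covariates_used=tuple(cov_names),
            estimate=r["beta"],
            meta={"failed_rois": failed, "rois": rois.tolist()},
        )
        if adjacency is not None:
            mcs = min_cluster_size if min_cluster_size is not None else 5
            sm = cluster_fwe(sm, adjacency, p_threshold=p_threshold, min_cluster_size=mcs)
            sm.meta.setdefault("failed_rois", failed)
        maps.append(sm)
    return tuple(maps)


def loocv_relative_rmse(
    table: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    feature_cols: tuple = ("tau_fc_hubs", "tau_sc_hubs"),
    normalizer: str = "range",
):
    """Leave-one-subject-out prediction error of the accumulation model.

    Per ROI the exact LOO residuals of OLS (residual / (1 - leverage)) give
    the cross-validated RMSE, normalized by the ROI's observed delta-tau
    range (or mean, with ``normalizer="mean"``).  Returns (per-ROI Series,
    mean over ROIs).
    """
    n_subj = table["subject_id"].nunique()
    if n_subj < 5:
        raise InvalidParameterError("need >= 5 subjects for LOOCV")
    rois = np.sort(table["roi"].unique())
    rel = pd.Series(index=rois, dtype=float)
    for roi in rois:
        sub = table[table["roi"] == roi]
        sids = sub["subject_id"].to_numpy()
        y = sub["delta_tau_roi"].to_numpy(float)
        cols = [np.ones(len(sub)), sub["baseline_tau_roi"].to_numpy(float)]
        cols += [sub[f].to_numpy(float) for f in feature_cols]
        if covariates is not None:
            cols.append(covariates.loc[sids].to_numpy(float))
        X = np.column_stack(cols)
        H = X @ np.linalg.pinv(X)
        resid = y - H @ y
        h = np.clip(np.diag(H), 0.0, 1.0 - 1e-12)
        loo = resid / (1.0 - h)
        rmse = np.sqrt(np.mean(loo**2))
        if normalizer == "range":
            denom = y.max() - y.min()
        elif normalizer == "mean":
            denom = abs(y.mean())
        else:
            raise InvalidParameterError(f"unknown normalizer {normalizer!r}")
        rel[roi] = rmse / denom if denom > 0 else np.nan
    return rel, float(rel.mean())


def sensitivity_variant(table_builder, variant: str, covariates=None, **fit_kwargs):
    """Run one of the documented sensitivity analyses.

    ``table_builder(variant)`` must return the feature table for that
    variant (``nearest_any``, ``furthest_nonhub`` reuse the tau features;
    ``distance_predictors`` supplies ``fc_hub_dist``/``sc_hub_dist``).
    """
    if variant not in SENSITIVITY_VARIANTS:
        raise InvalidParameterError(f"unknown variant {variant!r}")
    table = table_builder(variant)
    features = (
        ("fc_hub_dist", "sc_hub_dist")
        if variant == "distance_predictors"
        else ("tau_fc_hubs", "tau_sc_hubs")
    )
    return fit_accumulation_model(
        table, covariates=covariates, feature_cols=features, **fit_kwargs
    )
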