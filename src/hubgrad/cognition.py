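"""Tau x gradient interaction models of cognition and gradient-binned
meta-ROI brain-behavior analysis.

Cross-sectionally, each node's tau uptake and gradient score enter an
interaction model of a cognitive composite; longitudinally, a linear mixed
model with a random subject intercept tests the three-way
time x tau x gradient interaction on cognitive change.  Separately, parcels
are grouped into equally sized bins along a template gradient and each
bin's mean tau is partially correlated with cognition (controlling
covariates), with the Fisher-z correlation trend over bin order testing
whether brain-behavior coupling changes progressively along the cortical
hierarchy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .contrasts import StatMap, ols_tmap
from .errors import InvalidParameterError

COGNITIVE_DOMAINS = (
    "MMSE",
    "delayed_memory",
    "immediate_memory",
    "language",
    "speed",
    "executive",
    "object_recognition",
    "cognitive_flexibility",
    "word_reading",
)

DEFAULT_COG_COVARIATES = ("age", "sex", "apoe4", "education")


@dataclass
class MetaRoiBinning:
    """Equal-size contiguous bins of parcels ordered along a gradient."""

    component_id: str
    n_bins: int
    bin_label: np.ndarray  # per node, 1..n_bins


# ---------------------------------------------------------------------------
# composites
# ---------------------------------------------------------------------------


def build_composites(
    raw_subscores: dict,
    control_mask=None,
    method: str = "z",
) -> pd.DataFrame:
    """Standardize raw neuropsychological subscores and average them into
    domain composites.

    ``raw_subscores`` maps domain -> DataFrame (subjects x subscores).
    ``method="z"`` standardizes against the control-group mean/SD
    (cohort-wide if no control mask); ``method="minmax"`` rescales each
    subscore to [0, 1] across the cohort.
    """
    out = {}
    for domain, df in raw_subscores.items():
        z = pd.DataFrame(index=df.index)
        for col in df.columns:
            x = df[col].to_numpy(float)
            ref = x if control_mask is None else x[np.asarray(control_mask, bool)]
            if method == "z":
                sd = ref.std(ddof=1)
                if sd == 0:
                    raise InvalidParameterError(f"subscore {col!r} has zero variance")
                z[col] = (x - ref.mean()) / sd
            elif method == "minmax":
                rng_ = x.max() - x.min()
                if rng_ == 0:
                    raise InvalidParameterError(f"subscore {col!r} has zero variance")
                z[col] = (x - x.min()) / rng_
            else:
                raise InvalidParameterError(f"unknown standardization {method!r}")
        out[domain] = z.mean(axis=1)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# interaction models
# ---------------------------------------------------------------------------


def interaction_map(
    tau_maps,
    gradient_scores,
    composite,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> StatMap:
    """Per-node OLS: composite ~ tau*G + tau + G + covariates; the reported
    t is for the interaction term.  ``tau_maps`` and ``gradient_scores``
    are (S, N); ``composite`` is (S,)."""
    tau = np.asarray(tau_maps, float)
    g = np.asarray(gradient_scores, float)
    y = np.asarray(composite, float)
    if tau.shape != g.shape or tau.shape[0] != y.size:
        raise InvalidParameterError("tau / gradient / composite shapes do not match")
    s, n = tau.shape
    cov = covariates.to_numpy(float) if covariates is not None else np.empty((s, 0))
    cov_names = tuple(covariates.columns) if covariates is not None else ()
    t_out = np.empty(n)
    p_out = np.empty(n)
    est = np.empty(n)
    for node in range(n):
        X = np.column_stack(
            [np.ones(s), tau[:, node] * g[:, node], tau[:, node], g[:, node], cov]
        )
        b, t, p = ols_tmap(
            X, y[:, None], term=1, names=["intercept", "tau_x_g", "tau", "g", *cov_names]
        )
        est[node], t_out[node], p_out[node] = b[0], t[0], p[0]
    return StatMap(
        t=t_out,
        p=p_out,
        significant=p_out < alpha,
        contrast_label="tau x gradient interaction",
        covariates_used=cov_names,
        estimate=est,
    )


def longitudinal_interaction(
    tau_maps,
    gradient_scores,
    composites_long: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    nodes=None,
    alpha: float = 0.05,
) -> StatMap:
    """Per-node linear mixed model of cognition over visits.

    ``composites_long`` has columns subject_id, time, value; only subjects
    with at least one follow-up score are included.  Fixed effects are the
    full factorial of time, tau, and gradient score (all mains, two-way and
    three-way interactions) plus covariates, with a random intercept per
    subject.  The reported statistic is the large-sample Wald z for the
    three-way time x tau x G term.
    """
    tau = np.asarray(tau_maps, float)
    g = np.asarray(gradient_scores, float)
    s, n = tau.shape
    counts = composites_long.groupby("subject_id")["time"].nunique()
    keep_subjects = counts[counts >= 2].index
    if keep_subjects.empty:
        raise InvalidParameterError("no subject has a follow-up cognitive score")
    long = composites_long[composites_long["subject_id"].isin(keep_subjects)].reset_index(
        drop=True
    )
    subj_index = {sid: i for i, sid in enumerate(composites_long["subject_id"].unique())}
    row_subj = np.array([subj_index[sid] for sid in long["subject_id"]])
    time = long["time"].to_numpy(float)
    y = long["value"].to_numpy(float)
    if covariates is not None:
        cov = covariates.to_numpy(float)[row_subj]
        cov_names = tuple(covariates.columns)
    else:
        cov = np.empty((len(long), 0))
        cov_names = ()
    node_iter = range(n) if nodes is None else nodes
    t_out = np.full(n, np.nan)
    p_out = np.ones(n)
    est = np.full(n, np.nan)
    groups_codes = long["subject_id"].to_numpy()
    for node in node_iter:
        tv = tau[row_subj, node]
        gv = g[row_subj, node]
        X = np.column_stack(
            [
                np.ones(len(long)),
                time,
                tv,
                gv,
                time * tv,
                time * gv,
                tv * gv,
                time * tv * gv,
                cov,
            ]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(y, X, groups=groups_codes)
            try:
                fit = model.fit(reml=True, method="lbfgs", maxiter=200, disp=False)
            except np.linalg.LinAlgError:
                # boundary (zero) random-effect variance can make the
                # l-bfgs step singular; the default optimizer handles it
                fit = model.fit(reml=True, disp=False)
        z = fit.fe_params[7] / fit.bse_fe[7]
        t_out[node] = z
        p_out[node] = 2.0 * stats.norm.sf(abs(z))
        est[node] = fit.fe_params[7]
    return StatMap(
        t=t_out,
        p=p_out,
        significant=p_out < alpha,
        contrast_label="time x tau x gradient (mixed model)",
        covariates_used=cov_names,
        estimate=est,
    )


# ---------------------------------------------------------------------------
# gradient bins and brain-behavior trends
# ---------------------------------------------------------------------------


def gradient_bins(template_scores, n_bins: int = 6, component_id: str = "G1") -> MetaRoiBinning:
    """Split nodes into ``n_bins`` contiguous, equally sized groups along a
    gradient axis.  Any remainder is distributed from the low end, so the
    first bins can be one node larger."""
    scores = np.asarray(
        template_scores.scores[:, 0] if hasattr(template_scores, "scores") else template_scores,
        float,
    )
    n = scores.size
    if n_bins < 2 or n_bins > n // 2:
        raise InvalidParameterError(f"n_bins must be in [2, N/2], got {n_bins} for N={n}")
    order = np.argsort(scores, kind="stable")
    base, rem = divmod(n, n_bins)
    sizes = [base + 1 if b < rem else base for b in range(n_bins)]
    labels = np.empty(n, dtype=int)
    start = 0
    for b, size in enumerate(sizes, start=1):
        labels[order[start : start + size]] = b
        start += size
    return MetaRoiBinning(component_id=component_id, n_bins=n_bins, bin_label=labels)


def partial_pearson(x, y, covariates=None):
    """Pearson correlation of x and y after residualizing both on an
    intercept plus covariates (residual-on-residual correlation), with the
    t-test p-value at the residual degrees of freedom."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nsub = x.size
    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[1] == 0):
        Z = np.ones((nsub, 1))
    else:
        Z = np.column_stack([np.ones(nsub), np.asarray(covariates, float)])
    H = Z @ np.linalg.pinv(Z)
    rx = x - H @ x
    ry = y - H @ y
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise InvalidParameterError("zero variance after residualization")
    r = float((rx * ry).sum() / denom)
    dof = nsub - Z.shape[1] - 1
    t = r * np.sqrt(dof / max(1e-300, 1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return r, float(p)


def _meta_roi_partial_r(labels, label_order, tau_maps, composite, covariates):
    tau = np.asarray(tau_maps, float)
    y = np.asarray(composite, float)
    cov = covariates.to_numpy(float) if covariates is not None else None
    rows = []
    for lab in label_order:
        nodes = np.asarray(labels) == lab
        bin_tau = tau[:, nodes].mean(axis=1)
        if bin_tau.std() == 0:
            raise InvalidParameterError(f"bin {lab!r}: zero variance in bin-averaged tau")
        r, p = partial_pearson(bin_tau, y, cov)
        rows.append({"region": lab, "r": r, "abs_r": abs(r), "p": p})
    return pd.DataFrame(rows)


def bin_brain_behavior(
    binning: MetaRoiBinning, tau_maps, composite, covariates: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Partial Pearson R between each gradient bin's mean tau and a
    cognitive composite, controlling covariates."""
    return _meta_roi_partial_r(
        binning.bin_label, list(range(1, binning.n_bins + 1)), tau_maps, composite, covariates
    )


def braak_meta_roi_comparison(
    braak_labels, tau_maps, composite, covariates: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Same partial-R machinery over the six Braak-stage meta-ROIs, for
    side-by-side comparison with the gradient bins."""
    labels = np.asarray(braak_labels)
    stages = [s for s in ("I", "II", "III", "IV", "V", "VI") if (labels == s).any()]
    if not stages:
        raise InvalidParameterError("no Braak stage labels present")
    return _meta_roi_partial_r(labels, stages, tau_maps, composite, covariates)


def topology_trend(per_bin_r, bin_order=None):
    """OLS of Fisher-z-transformed correlations on bin ordering; returns
    (slope, two-sided p for the slope)."""
    r = np.asarray(per_bin_r, float)
    if r.size < 3:
        raise InvalidParameterError("need >= 3 bins for a trend")
    x = np.asarray(bin_order, float) if bin_order is not None else np.arange(1.0, r.size + 1)
    z = np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7))
    res = stats.linregress(x, z)
    return float(res.slope), float(res.pvalue)


def fdr_adjust(pvalues, alpha: float = 0.05):
    """Benjamini-Hochberg adjusted p-values over a test family."""
    p = np.asarray(pvalues, float)
    rejected, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, rejected
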