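"""Connectome gradients: thresholding, similarity kernels, diffusion map
embedding, and Procrustes alignment.

A connectivity matrix (functional correlation or structural streamline
weights) is row-thresholded to its strongest connections, converted into a
node-by-node similarity ("affinity") matrix, and decomposed with diffusion
map embedding into a small number of spatial components — the *gradients*.
Nodes with similar brain-wide connectivity profiles land close together on a
gradient; nodes with distinct profiles land far apart.  Individual gradient
sets are made comparable by orthogonal Procrustes alignment to a template
derived from the group-averaged connectome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import csgraph, csr_matrix

from .errors import (
    DegenerateNodeError,
    DisconnectedGraphError,
    InvalidParameterError,
    ModalityError,
)

logger = logging.getLogger(__name__)

FC = "FC"
SC = "SC"

#: |r| is clamped below 1 by this margin before the Fisher transform so the
#: transform stays finite on perfectly correlated rows.
FISHER_CLAMP = 1e-7

#: eigenvalues within this distance of 1 are treated as the trivial
#: stationary component of the Markov operator and dropped.
TRIVIAL_EIGENVALUE_TOL = 1e-12


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ConnectivityMatrix:
    """A single subject's N x N weighted connectivity matrix.

    FC entries are correlation coefficients in [-1, 1]; SC entries are
    non-negative streamline weights.  ``thresholded`` marks the (generally
    asymmetric) result of row-wise sparsification.
    """

    weights: np.ndarray
    modality: str
    subject_id: str | None = None
    thresholded: bool = False
    sparsity: float | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InvalidParameterError("connectivity matrix must be square")
        if not np.isfinite(w).all():
            raise InvalidParameterError("connectivity matrix contains non-finite values")
        if self.modality not in (FC, SC):
            raise ModalityError(f"unknown modality {self.modality!r}")
        if not self.thresholded and not np.allclose(w, w.T, atol=1e-9):
            raise InvalidParameterError("raw connectivity matrix must be symmetric (1e-9)")
        if not self.thresholded:
            # raw-scale invariants; thresholded matrices may carry
            # Fisher-transformed values outside the raw range
            if self.modality == SC and (w < 0).any():
                raise InvalidParameterError("SC weights must be non-negative")
            if self.modality == FC and (np.abs(w) > 1 + 1e-12).any():
                raise InvalidParameterError("FC entries must lie in [-1, 1]")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class AffinityMatrix:
    """Node-by-node similarity between thresholded connectivity rows."""

    values: np.ndarray
    kernel: str  # "cosine" | "normalized_angle"


@dataclass
class GradientSet:
    """N x K embedding scores with spectral provenance.

    ``explained_info`` holds each retained eigenvalue's share of the summed
    top-K eigenvalues (the "explained information" of a component).
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    kernel: str
    alpha: float = 0.5
    diffusion_time: int = 0
    template_id: str = "unaligned"
    explained_info: np.ndarray = field(default=None)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.explained_info is None:
            total = self.eigenvalues.sum()
            self.explained_info = (
                self.eigenvalues / total if total > 0 else np.full_like(self.eigenvalues, np.nan)
            )
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise InvalidParameterError("eigenvalues must be non-increasing")
        if not np.isfinite(self.scores).all():
            raise InvalidParameterError("gradient scores must be finite")

    @property
    def n_nodes(self) -> int:
        return self.scores.shape[0]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class GradientTemplate:
    """Reference gradients from a group-averaged connectome, used as the
    Procrustes target for individual gradient sets."""

    scores: np.ndarray
    source: str  # "cohort" or "group:<label>"
    construction: str = "averaged-connectome"
    eigenvalues: np.ndarray | None = None

    @property
    def template_id(self) -> str:
        return self.source


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _as_array(matrix):
    return matrix.weights if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix, float)


def threshold_rows(matrix, sparsity: float = 0.20):
    """Keep the top ``ceil(sparsity * (N-1))`` off-diagonal entries per row.

    Values are retained as-is; everything else (including the diagonal) is
    set to zero.  Ties at the cutoff are broken in favour of the lower
    column index.  The result is generally asymmetric.
    """
    if not 0 < sparsity <= 1:
        raise InvalidParameterError(f"sparsity must be in (0, 1], got {sparsity}")
    w = _as_array(matrix)
    n = w.shape[0]
    keep = int(np.ceil(sparsity * (n - 1)))
    out = np.zeros_like(w)
    cols = np.arange(n)
    for i in range(n):
        off = cols != i
        v = w[i, off]
        c = cols[off]
        # stable sort on -v: among ties the lower column index comes first
        order = np.argsort(-v, kind="stable")
        sel = c[order[:keep]]
        out[i, sel] = w[i, sel]
    if isinstance(matrix, ConnectivityMatrix):
        return replace(matrix, weights=out, thresholded=True, sparsity=sparsity)
    return out


def fisher_transform(matrix):
    """Entrywise atanh of an FC matrix, diagonal forced to zero first and
    |r| clamped at 1 - 1e-7 so perfect correlations stay finite."""
    if isinstance(matrix, ConnectivityMatrix) and matrix.modality != FC:
        raise ModalityError("Fisher transform applies to FC matrices only")
    w = _as_array(matrix).copy()
    np.fill_diagonal(w, 0.0)
    w = np.clip(w, -1 + FISHER_CLAMP, 1 - FISHER_CLAMP)
    z = np.arctanh(w)
    if isinstance(matrix, ConnectivityMatrix):
        return replace(matrix, weights=z)
    return z


def build_affinity(matrix, kernel: str = "cosine") -> AffinityMatrix:
    """Cosine (or normalized-angle) similarity between rows of a thresholded
    connectivity matrix; diagonal set to 1."""
    if kernel not in ("cosine", "normalized_angle"):
        raise InvalidParameterError(f"unknown kernel {kernel!r}")
    w = _as_array(matrix)
    norms = np.linalg.norm(w, axis=1)
    dead = np.flatnonzero(norms == 0)
    if dead.size:
        raise DegenerateNodeError(dead, f"row(s) {dead.tolist()} have no retained connections")
    cos = (w @ w.T) / np.outer(norms, norms)
    cos = np.clip(cos, -1.0, 1.0)
    if kernel == "normalized_angle":
        a = 1.0 - np.arccos(cos) / np.pi
    else:
        a = cos
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return AffinityMatrix(values=a, kernel=kernel)


def _affinity_values(affinity):
    if isinstance(affinity, AffinityMatrix):
        return affinity.values, affinity.kernel
    return np.asarray(affinity, float), "cosine"


def diffusion_embedding(
    affinity,
    n_components: int = 10,
    alpha: float = 0.5,
    diffusion_time: int = 0,
) -> GradientSet:
    """Diffusion map embedding of a symmetric affinity matrix.

    The affinity is density-normalized with exponent ``alpha``
    (``L = A / (d^alpha d^alpha^T)``), row-normalized into a Markov
    transition matrix, and eigendecomposed.  The trivial stationary
    eigenvector (eigenvalue 1) is dropped and, at diffusion time 0, each
    remaining component is scaled by ``lambda / (1 - lambda)`` so that all
    time scales contribute.  Negative affinities are clipped to zero before
    normalization (negative transition weights are undefined).
    """
    a, kernel = _affinity_values(affinity)
    if not np.allclose(a, a.T, atol=1e-10):
        raise InvalidParameterError("affinity matrix must be symmetric")
    if (a < 0).any():
        logger.info(
            "clipping %d negative affinity entries to 0 before Markov normalization",
            int((a < 0).sum()),
        )
        a = np.clip(a, 0.0, None)
    n_comp_graph, labels = csgraph.connected_components(csr_matrix(a > 0), directed=False)
    if n_comp_graph > 1:
        raise DisconnectedGraphError(
            labels, f"affinity graph has {n_comp_graph} connected components"
        )

    d = a.sum(axis=1)
    L = a / np.outer(d**alpha, d**alpha)
    d2 = L.sum(axis=1)
    # symmetric conjugate of the Markov operator D2^-1 L: same eigenvalues,
    # eigenvectors related through D2^(1/2)
    sq = np.sqrt(d2)
    S = L / np.outer(sq, sq)
    S = (S + S.T) / 2.0
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = evecs / sq[:, None]

    keep = evals < 1.0 - TRIVIAL_EIGENVALUE_TOL
    evals, psi = evals[keep], psi[:, keep]
    k = min(n_components, evals.size)
    lam = evals[:k]
    scores = psi[:, :k] * (lam / (1.0 - lam))
    total = lam.sum()
    explained = lam / total if total > 0 else np.full(k, np.nan)
    return GradientSet(
        scores=scores,
        eigenvalues=lam,
        kernel=kernel,
        alpha=alpha,
        diffusion_time=diffusion_time,
        explained_info=explained,
    )


def pca_embedding(affinity, n_components: int = 10) -> GradientSet:
    """Principal components of the column-centered affinity matrix; used
    for the diffusion-embedding-vs-PCA comparison."""
    a, kernel = _affinity_values(affinity)
    if not np.allclose(a, a.T, atol=1e-10):
        raise InvalidParameterError("affinity matrix must be symmetric")
    x = a - a.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, s.size)
    var = s**2
    total = var[:k].sum()
    explained = var[:k] / total if total > 0 else np.full(k, np.nan)
    return GradientSet(
        scores=u[:, :k] * s[:k],
        eigenvalues=var[:k],
        kernel=kernel,
        alpha=np.nan,
        diffusion_time=0,
        explained_info=explained,
    )


def _fix_signs(scores: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the node with the largest |loading|
    of each component is made positive."""
    out = scores.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def embed_connectome(
    connectome: ConnectivityMatrix,
    sparsity: float = 0.20,
    kernel: str = "cosine",
    n_components: int = 10,
    method: str = "diffusion",
) -> GradientSet:
    """Full single-matrix chain: threshold -> (Fisher if FC) -> affinity ->
    embedding."""
    t = threshold_rows(connectome, sparsity)
    if connectome.modality == FC:
        t = fisher_transform(t)
    aff = build_affinity(t, kernel)
    if method == "diffusion":
        return diffusion_embedding(aff, n_components=n_components)
    if method == "pca":
        return pca_embedding(aff, n_components=n_components)
    raise InvalidParameterError(f"unknown embedding method {method!r}")


def build_template(
    connectomes,
    kernel: str = "cosine",
    sparsity: float = 0.20,
    n_components: int = 10,
    source: str = "cohort",
) -> GradientTemplate:
    """Template gradients from the elementwise mean of raw connectomes."""
    mats = list(connectomes)
    if len(mats) < 2:
        raise InvalidParameterError("need at least two connectomes for a template")
    modality = mats[0].modality
    n = mats[0].n_nodes
    for m in mats[1:]:
        if m.modality != modality:
            raise InvalidParameterError("mixed modalities in template construction")
        if m.n_nodes != n:
            raise InvalidParameterError("mismatched matrix sizes in template construction")
    mean = ConnectivityMatrix(
        weights=np.mean([m.weights for m in mats], axis=0),
        modality=modality,
        subject_id=f"template:{source}",
    )
    g = embed_connectome(mean, sparsity=sparsity, kernel=kernel, n_components=n_components)
    return GradientTemplate(
        scores=_fix_signs(g.scores), source=source, eigenvalues=g.eigenvalues
    )


def build_group_templates(connectomes, labels, **kwargs):
    """One template per group label, from each group's mean connectome."""
    labels = np.asarray(labels)
    out = {}
    for lab in dict.fromkeys(labels.tolist()):
        grp = [c for c, l in zip(connectomes, labels) if l == lab]
        out[lab] = build_template(grp, source=f"group:{lab}", **kwargs)
    return out


def procrustes_align(gradients: GradientSet, template) -> GradientSet:
    """Orthogonal Procrustes alignment (rotation + reflection, no scaling
    or translation) of a gradient set onto a template."""
    tmpl_scores = template.scores if hasattr(template, "scores") else np.asarray(template, float)
    src = gradients.scores
    if src.shape != tmpl_scores.shape:
        raise InvalidParameterError(
            f"shape mismatch: gradients {src.shape} vs template {tmpl_scores.shape}"
        )
    u, _, vt = np.linalg.svd(src.T @ tmpl_scores)
    rot = u @ vt
    aligned = src @ rot
    template_id = getattr(template, "template_id", "template")
    return replace(gradients, scores=aligned, template_id=template_id)
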