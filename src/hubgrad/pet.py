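"""PET covariance networks and their gradients.

Group-level covariance matrices are built by correlating every pair of
parcels' SUVR values across subjects (tau, longitudinal tau change, or
inflammation), then decomposed with the same threshold -> similarity ->
diffusion-embedding chain used for connectomes.  "Covariance" is
implemented as the across-subject Pearson correlation (scale-free, the
standard choice in the structural-covariance literature).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .embedding import GradientSet, build_affinity, diffusion_embedding, threshold_rows
from .errors import DegenerateNodeError, InvalidParameterError

TRACERS = ("tau", "inflammation", "abeta")


@dataclass
class SuvrMap:
    """One subject's parcel-wise standardized uptake value ratios."""

    subject_id: str
    tracer: str
    visit: str  # "baseline" | "followup"
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.isfinite(v).all() or (v <= 0).any():
            raise InvalidParameterError(
                f"SUVR values for {self.subject_id} must be positive and finite"
            )
        self.values = v


@dataclass
class DeltaTauMap:
    """Per-day change in tau SUVR between baseline and follow-up."""

    subject_id: str
    values: np.ndarray
    delta_days: int


@dataclass
class PetCovariance:
    """Across-subject node-by-node correlation of PET uptake."""

    values: np.ndarray
    tracer: str
    group_label: str
    sparsity_applied: float | None = None


def delta_tau(baseline: SuvrMap, followup: SuvrMap, delta_days: int) -> DeltaTauMap:
    """(follow-up - baseline SUVR) / time between scans in days."""
    if delta_days <= 0:
        raise InvalidParameterError(f"delta_days must be positive, got {delta_days}")
    if baseline.values.shape != followup.values.shape:
        raise InvalidParameterError("baseline and follow-up maps have different lengths")
    if baseline.subject_id != followup.subject_id:
        raise InvalidParameterError("baseline and follow-up maps are from different subjects")
    return DeltaTauMap(
        subject_id=baseline.subject_id,
        values=(followup.values - baseline.values) / float(delta_days),
        delta_days=int(delta_days),
    )


def pet_covariance_matrix(maps, group_label: str = "all") -> PetCovariance:
    """Pearson correlation between every pair of nodes' values across
    subjects.  ``maps`` may hold SuvrMap or DeltaTauMap objects (or plain
    vectors) of one tracer/visit."""
    maps = list(maps)
    if len(maps) < 3:
        raise InvalidParameterError("need at least 3 subjects for a covariance matrix")
    tracer = getattr(maps[0], "tracer", "delta_tau")
    data = np.vstack([np.asarray(getattr(m, "values", m), float) for m in maps])
    sd = data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise DegenerateNodeError(
            dead, f"node(s) {dead.tolist()} have zero across-subject variance"
        )
    c = np.corrcoef(data, rowvar=False)
    np.fill_diagonal(c, 1.0)
    return PetCovariance(values=c, tracer=tracer, group_label=group_label)


def pet_gradients(
    cov: PetCovariance,
    sparsity: float = 0.20,
    kernel: str = "cosine",
    n_components: int = 10,
) -> GradientSet:
    """Gradients of a PET covariance matrix.

    The default sparsity is 20% (matching the connectome threshold); 50% is
    the appropriate choice for small-sample covariances such as tau-change
    or inflammation, and the whole 20-50% range is supported.
    """
    t = threshold_rows(cov.values, sparsity)
    aff = build_affinity(t, kernel)
    g = diffusion_embedding(aff, n_components=n_components)
    return g


def biomarker_regroup(subject_ids, amyloid_status, tau_status):
    """Map per-subject amyloid/tau PET positivity into A-T-, A+T-, A+T+
    profiles.  The biologically implausible A-T+ profile is excluded with a
    warning and labeled None."""
    labels = {}
    for sid, a, t in zip(subject_ids, amyloid_status, tau_status):
        if a not in ("+", "-") or t not in ("+", "-"):
            raise InvalidParameterError(f"missing or invalid A/T status for subject {sid}")
        if a == "-" and t == "+":
            warnings.warn(f"subject {sid} is A-T+; excluded from biomarker regrouping")
            labels[sid] = None
        else:
            labels[sid] = f"A{a}T{t}"
    return labels
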