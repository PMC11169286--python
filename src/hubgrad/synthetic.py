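"""Synthetic cohort generator with planted, recoverable structure.

Every downstream stage of the pipeline is exercised on data from this
module: parcellations with community and Braak-like labels, symmetric
connectomes organized along smooth latent axes (with group-dependent
gradient contraction in the impaired group), spatially autocorrelated PET
maps whose longitudinal change is driven by tau within gradient-space
hubs, and cognitive composites with planted tau x gradient interactions.

The planted effects are expressed in interpretable units: hub effects as
regression coefficients on hub-averaged SUVR (scaled to a realistic
per-day accumulation rate), the cognition interaction as an effect in
standard-deviation units of the composite.  Group sizes default to
100/35/75 (controls / preclinical / impaired).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import embedding as emb
from . import hubs as hub_ops
from .errors import InvalidParameterError

GROUPS = ("CN_Aneg", "CN_Apos", "CI")

#: accumulation-rate scale: 1e-4 SUVR/day ~ 0.04 SUVR/year, the magnitude
#: of tau accumulation seen over a ~420-day follow-up interval
RATE_SCALE = 1e-4

#: baseline tau amplitude (SUVR above floor) per group
GROUP_TAU_AMPLITUDE = {"CN_Aneg": 0.15, "CN_Apos": 0.35, "CI": 0.7}

SUVR_FLOOR = 1.1

#: per-day noise SD on the accumulation rate; kept signal-dominant so the
#: planted hub effects are recoverable at the designed sample sizes
RATE_NOISE_SD = 1.2e-5

#: spatial field SD of subject-level SUVR noise
FIELD_SD = 0.2

#: self-accumulation coefficient (per day per SUVR) applied to every ROI
SELF_RATE = 0.3


@dataclass
class Parcellation:
    """Synthetic parcel geometry and labels.

    Centroids sit on a ~70 mm sphere split into mirrored hemispheres;
    communities are angular sectors; Braak-like stages I..VI occupy a
    contiguous posterior-inferior sector sequence.  ``latent_fc`` and
    ``latent_sc`` are the smooth planted organization axes (standardized).
    """

    centroids: np.ndarray
    network_label: np.ndarray
    braak_label: np.ndarray
    hemisphere: np.ndarray
    latent_fc: np.ndarray
    latent_sc: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.centroids.shape[0]

    @property
    def node_id(self) -> np.ndarray:
        return np.arange(self.n_nodes)

    def distances(self) -> np.ndarray:
        d = self.centroids[:, None, :] - self.centroids[None, :, :]
        return np.sqrt((d**2).sum(-1))


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    age: float
    sex: int  # 0 = F, 1 = M
    apoe4: int
    education: float
    visit_times: list = dc_field(default_factory=lambda: [0])
    cognition: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        vt = list(self.visit_times)
        if vt[0] != 0 or any(b <= a for a, b in zip(vt, vt[1:])):
            raise InvalidParameterError("visit_times must be strictly increasing from 0")
        for v in (self.age, self.education):
            if not np.isfinite(v):
                raise InvalidParameterError("covariates must be finite")


@dataclass
class CohortConfig:
    n_nodes: int = 100
    n_subjects_per_group: dict = dc_field(
        default_factory=lambda: {"CN_Aneg": 100, "CN_Apos": 35, "CI": 75}
    )
    latent_axis_strength: float = 1.0
    contraction_factor: float = 0.3
    hub_effect_fc: float = 0.5
    hub_effect_sc: float = 0.5
    interaction_effect: float = -0.5
    noise_sd: float = 0.1
    spatial_corr_length: float = 20.0
    seed: int = 0
    n_communities: int = 7
    n_hubs: int = 15
    k_nearest_hubs: int = 5
    n_visits: int = 3
    visit_interval_days: int = 365

    def __post_init__(self):
        if self.n_nodes < 20:
            raise InvalidParameterError("n_nodes must be >= 20")
        for name in (
            "latent_axis_strength",
            "contraction_factor",
            "hub_effect_fc",
            "hub_effect_sc",
            "noise_sd",
            "spatial_corr_length",
        ):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# parcellation
# ---------------------------------------------------------------------------

_FC_AXIS = np.array([0.0, 0.5, np.sqrt(1 - 0.25)])  # anterior-superior mix
_SC_AXIS = np.array([0.0, 1.0, 0.0])  # posterior-anterior


def _smooth_axis(centroids: np.ndarray, direction: np.ndarray, k: int = 10) -> np.ndarray:
    g = centroids @ direction
    d = centroids[:, None, :] - centroids[None, :, :]
    dist = np.sqrt((d**2).sum(-1))
    nearest = np.argsort(dist, axis=1, kind="stable")[:, :k]
    g = g[nearest].mean(axis=1)
    return (g - g.mean()) / g.std()


def make_parcellation(n_nodes: int, seed: int = 0) -> Parcellation:
    """Random spherical parcellation with mirrored hemispheres, angular
    communities, Braak-like stages, and two planted latent axes."""
    if n_nodes < 20:
        raise InvalidParameterError("n_nodes must be >= 20")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    n_right = n_nodes // 2
    n_left = n_nodes - n_right
    pts = rng.standard_normal((n_left, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts[:, 0] = np.abs(pts[:, 0])  # right hemisphere: x > 0
    right = 70.0 * pts[:n_right]
    left = 70.0 * pts * np.array([-1.0, 1.0, 1.0])
    centroids = np.vstack([right, left])
    hemisphere = np.array(["R"] * n_right + ["L"] * n_left)

    n_comm = 7
    theta = np.arctan2(centroids[:, 2], centroids[:, 1])  # sector in the (y, z) plane
    sector = np.clip(((theta + np.pi) / (2 * np.pi) * n_comm).astype(int), 0, n_comm - 1)
    network_label = np.array([f"net{s + 1}" for s in sector])

    # Braak-like contiguous posterior-inferior sequence over 60% of nodes
    post_inf = -centroids[:, 1] - centroids[:, 2]
    order = np.argsort(-post_inf, kind="stable")
    n_staged = int(round(0.6 * n_nodes))
    stage_names = ("I", "II", "III", "IV", "V", "VI")
    braak = np.array(["none"] * n_nodes, dtype=object)
    chunks = np.array_split(order[:n_staged], 6)
    for name, chunk in zip(stage_names, chunks):
        braak[chunk] = name

    return Parcellation(
        centroids=centroids,
        network_label=network_label,
        braak_label=braak.astype(str),
        hemisphere=hemisphere,
        latent_fc=_smooth_axis(centroids, _FC_AXIS),
        latent_sc=_smooth_axis(centroids, _SC_AXIS),
    )


# ---------------------------------------------------------------------------
# connectomes
# ---------------------------------------------------------------------------


def make_connectome(
    parcellation: Parcellation,
    modality: str,
    group: str,
    config: CohortConfig,
    seed,
    subject_id: str | None = None,
) -> emb.ConnectivityMatrix:
    """One subject's connectome.

    FC: similarity along the planted latent axis plus a same-community
    bonus and symmetric Gaussian noise, clipped to [-1, 1] with unit
    diagonal.  In the impaired group the latent coordinates are first
    shrunk toward their mean by ``contraction_factor`` (planting gradient
    contraction).  SC: non-negative weights decaying with centroid distance
    and along a posterior-anterior latent axis, zero diagonal.
    """
    if modality not in (emb.FC, emb.SC):
        raise InvalidParameterError(f"unknown modality {modality!r}")
    rng = np.random.default_rng(seed)
    n = parcellation.n_nodes
    noise = rng.standard_normal((n, n)) * config.noise_sd
    noise = (noise + noise.T) / np.sqrt(2.0)
    same_comm = parcellation.network_label[:, None] == parcellation.network_label[None, :]

    if modality == emb.FC:
        g = parcellation.latent_fc.copy()
        if group == "CI" and config.contraction_factor > 0:
            g = g.mean() + (g - g.mean()) * (1.0 - config.contraction_factor)
        sim = np.exp(-0.5 * (g[:, None] - g[None, :]) ** 2)
        w = 0.5 * config.latent_axis_strength * sim + 0.15 * same_comm + noise
        w = np.clip((w + w.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(w, 1.0)
    else:
        g = parcellation.latent_sc
        d = parcellation.distances()
        sim = np.exp(-0.5 * (g[:, None] - g[None, :]) ** 2)
        w = (
            0.4 * np.exp(-d / 40.0)
            + 0.3 * config.latent_axis_strength * sim
            + 0.1 * same_comm
            + noise
        )
        w = np.clip((w + w.T) / 2.0, 0.0, None)
        np.fill_diagonal(w, 0.0)
    return emb.ConnectivityMatrix(weights=w, modality=modality, subject_id=subject_id)


# ---------------------------------------------------------------------------
# subjects
# ---------------------------------------------------------------------------

_APOE_RATE = {"CN_Aneg": 0.26, "CN_Apos": 0.26, "CI": 0.57}


def make_subjects(config: CohortConfig, seed) -> list[SubjectRecord]:
    """Demographics mirroring a memory-clinic cohort: age ~ N(69, 9),
    ~60% female, education ~ N(15, 3.8), APOE-e4 enriched in the impaired
    group."""
    rng = np.random.default_rng(seed)
    visit_times = [config.visit_interval_days * v for v in range(config.n_visits)]
    subjects = []
    i = 0
    for group in GROUPS:
        for _ in range(config.n_subjects_per_group.get(group, 0)):
            subjects.append(
                SubjectRecord(
                    subject_id=f"sub-{i:04d}",
                    group=group,
                    age=float(np.clip(rng.normal(69.0, 9.0), 45, 95)),
                    sex=int(rng.random() < 0.4),
                    apoe4=int(rng.random() < _APOE_RATE[group]),
                    education=float(np.clip(rng.normal(15.0, 3.8), 6, 25)),
                    visit_times=visit_times,
                )
            )
            i += 1
    return subjects


def covariate_frame(subjects, education: bool = False) -> pd.DataFrame:
    cols = {
        "age": [s.age for s in subjects],
        "sex": [s.sex for s in subjects],
        "apoe4": [s.apoe4 for s in subjects],
    }
    if education:
        cols["education"] = [s.education for s in subjects]
    return pd.DataFrame(cols, index=[s.subject_id for s in subjects])


# ---------------------------------------------------------------------------
# PET maps
# ---------------------------------------------------------------------------


@dataclass
class SubjectGradients:
    """Aligned gradients and per-ROI nearest-hub lists for one subject."""

    fc: emb.GradientSet
    sc: emb.GradientSet
    fc_hub_rois: dict
    sc_hub_rois: dict


@dataclass
class PetCohort:
    baseline: dict  # subject_id -> N-vector SUVR
    followup: dict
    inflammation: dict
    delta_days: dict
    planted_fc_mask: np.ndarray  # fronto-lateral sector, FC hub effect
    planted_sc_mask: np.ndarray  # posterior sector, SC hub effect


def spatial_field_cholesky(distances: np.ndarray, corr_length: float) -> np.ndarray:
    """Cholesky factor of the exponential spatial covariance
    C_ij = exp(-d_ij / corr_length)."""
    c = np.exp(-distances / corr_length)
    return np.linalg.cholesky(c + 1e-8 * np.eye(distances.shape[0]))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def planted_region_masks(parcellation: Parcellation):
    """Planted effect regions: SC hub effect in the posterior third,
    FC hub effect in the fronto-lateral (anterior) third."""
    y = parcellation.centroids[:, 1]
    sc_mask = y < np.percentile(y, 30)
    fc_mask = y > np.percentile(y, 70)
    return fc_mask, sc_mask


def make_pet_cohort(
    parcellation: Parcellation,
    gradients: dict,
    subjects,
    config: CohortConfig,
    seed,
) -> PetCohort:
    """Baseline / follow-up tau and inflammation maps.

    Baseline tau is a monotone (sigmoid) function of the structural
    gradient plus a spatially correlated Gaussian field; the follow-up
    rate adds self-accumulation and, within the planted sectors,
    accumulation driven by mean baseline tau inside each ROI's FC or SC
    gradient-space hubs.  Inflammation follows the structural gradient
    ordering.
    """
    missing = [s.subject_id for s in subjects if s.subject_id not in gradients]
    if missing:
        raise InvalidParameterError(f"missing gradients for subjects: {missing[:5]}")
    rng = np.random.default_rng(seed)
    n = parcellation.n_nodes
    chol = spatial_field_cholesky(parcellation.distances(), config.spatial_corr_length)
    fc_mask, sc_mask = planted_region_masks(parcellation)

    ref = np.mean([gradients[s.subject_id].sc.scores[:, 0] for s in subjects], axis=0)
    ref = (ref - ref.mean()) / ref.std()

    baseline, followup, inflammation, delta_days = {}, {}, {}, {}
    for s in subjects:
        # per-subject severity spreads the gradient-shaped component across
        # subjects, so the across-subject covariance is loaded along the
        # gradient (not just the spatial noise field)
        amp = GROUP_TAU_AMPLITUDE[s.group] * (0.7 + 0.6 * rng.random())
        f = chol @ rng.standard_normal(n) * FIELD_SD
        tau0 = np.maximum(SUVR_FLOOR + amp * _sigmoid(1.5 * ref) + f, 0.6)
        sg = gradients[s.subject_id]
        tau_fc_hubs = np.array([tau0[sg.fc_hub_rois[i]].mean() for i in range(n)])
        tau_sc_hubs = np.array([tau0[sg.sc_hub_rois[i]].mean() for i in range(n)])
        rate = RATE_SCALE * (
            SELF_RATE * (tau0 - SUVR_FLOOR)
            + config.hub_effect_fc * fc_mask * (tau_fc_hubs - SUVR_FLOOR)
            + config.hub_effect_sc * sc_mask * (tau_sc_hubs - SUVR_FLOOR)
        )
        rate = rate + rng.standard_normal(n) * RATE_NOISE_SD
        dt = int(rng.integers(340, 501))
        baseline[s.subject_id] = tau0
        followup[s.subject_id] = np.maximum(tau0 + dt * rate, 0.5)
        delta_days[s.subject_id] = dt
        inf_field = chol @ rng.standard_normal(n) * FIELD_SD
        inflammation[s.subject_id] = np.maximum(
            1.0 + 0.4 * (0.7 + 0.6 * rng.random()) * _sigmoid(1.5 * ref) + inf_field, 0.5
        )
    return PetCohort(
        baseline=baseline,
        followup=followup,
        inflammation=inflammation,
        delta_days=delta_days,
        planted_fc_mask=fc_mask,
        planted_sc_mask=sc_mask,
    )


# ---------------------------------------------------------------------------
# cognition
# ---------------------------------------------------------------------------

COGNITION_DOMAINS = (
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


@dataclass
class CognitionData:
    cross_sectional: pd.DataFrame  # subjects x domains, baseline visit
    longitudinal: pd.DataFrame  # subject_id, time (days), domain, value
    planted_nodes: np.ndarray  # boolean mask of the planted ROI set
    interaction_driver: pd.Series  # standardized tau x G driver per subject


def make_cognition(
    subjects,
    tau_maps: dict,
    gradient_scores: dict,
    config: CohortConfig,
    seed,
) -> CognitionData:
    """Cognitive composites with a planted tau x gradient interaction.

    The interaction driver is the mean centered tau x centered gradient
    product over the planted ROI set (the transmodal quartile of the
    functional gradient), standardized across the cohort so
    ``interaction_effect`` is in SD units of the composite.  Longitudinal
    visits add a time slope modulated by the same driver.
    """
    rng = np.random.default_rng(seed)
    sids = [s.subject_id for s in subjects]
    tau = np.vstack([np.asarray(tau_maps[sid], float) for sid in sids])
    g = np.vstack([np.asarray(gradient_scores[sid], float) for sid in sids])
    mean_g = g.mean(axis=0)
    planted = mean_g > np.percentile(mean_g, 75)

    tau_c = tau - tau.mean(axis=0)
    g_c = g - g.mean(axis=0)
    driver = (tau_c[:, planted] * g_c[:, planted]).mean(axis=1)
    driver = (driver - driver.mean()) / driver.std()

    tau_bar = tau.mean(axis=1)
    tau_bar = (tau_bar - tau_bar.mean()) / tau_bar.std()
    g_bar = g.mean(axis=1)
    g_sd = g_bar.std()
    g_bar = (g_bar - g_bar.mean()) / g_sd if g_sd > 0 else np.zeros_like(g_bar)

    age = np.array([s.age for s in subjects])
    edu = np.array([s.education for s in subjects])
    base = (
        -0.5 * tau_bar
        + 0.2 * g_bar
        + config.interaction_effect * driver
        - 0.01 * (age - 69.0)
        + 0.01 * (edu - 15.0)
    )
    slope_per_year = -0.1 + 0.5 * config.interaction_effect * driver

    visit_times = subjects[0].visit_times
    cross_rows = {}
    long_rows = []
    # homoscedastic visit noise: the longitudinal mixed model assumes a
    # common residual variance across visits
    visit_noise_sd = 0.25
    for d in COGNITION_DOMAINS:
        for v, t_days in enumerate(visit_times):
            vals = (
                base
                + slope_per_year * (t_days / 365.0)
                + rng.standard_normal(len(subjects)) * visit_noise_sd
            )
            if v == 0:
                cross_rows[d] = vals
            for sid, val in zip(sids, vals):
                long_rows.append(
                    {"subject_id": sid, "time": t_days / 365.0, "domain": d, "value": val}
                )
    cross = pd.DataFrame(cross_rows, index=sids)
    long = pd.DataFrame(long_rows)
    for s in subjects:
        s.cognition = {
            d: dict(
                zip(
                    visit_times,
                    long[(long.subject_id == s.subject_id) & (long.domain == d)][
                        "value"
                    ].tolist(),
                )
            )
            for d in COGNITION_DOMAINS
        }
    return CognitionData(
        cross_sectional=cross,
        longitudinal=long,
        planted_nodes=planted,
        interaction_driver=pd.Series(driver, index=sids),
    )


# ---------------------------------------------------------------------------
# whole-cohort orchestration
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    config: CohortConfig
    parcellation: Parcellation
    subjects: list
    connectomes: dict  # sid -> {"FC": ..., "SC": ...}
    fc_template: emb.GradientTemplate
    sc_template: emb.GradientTemplate
    gradients: dict  # sid -> SubjectGradients
    pet: PetCohort | None = None
    cognition: CognitionData | None = None

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    def covariates(self, education: bool = False) -> pd.DataFrame:
        return covariate_frame(self.subjects, education=education)

    def gradient_stack(self, modality: str = "FC") -> np.ndarray:
        key = modality.lower()
        return np.stack([getattr(self.gradients[s.subject_id], key).scores for s in self.subjects])


def generate_cohort(
    config: CohortConfig,
    with_pet: bool = True,
    with_cognition: bool = True,
    sparsity: float = 0.20,
    kernel: str = "cosine",
) -> Cohort:
    """Generate the full synthetic study: parcellation, subjects,
    connectomes, aligned gradients, hub selections, PET maps, cognition."""
    root = np.random.SeedSequence(config.seed)
    ss_parc, ss_subj, ss_conn, ss_pet, ss_cog = root.spawn(5)
    parc = make_parcellation(config.n_nodes, seed=config.seed)
    subjects = make_subjects(config, ss_subj)
    conn_seeds = ss_conn.spawn(len(subjects))
    connectomes = {}
    for s, cs in zip(subjects, conn_seeds):
        fc_ss, sc_ss = cs.spawn(2)
        connectomes[s.subject_id] = {
            "FC": make_connectome(parc, emb.FC, s.group, config, fc_ss, s.subject_id),
            "SC": make_connectome(parc, emb.SC, s.group, config, sc_ss, s.subject_id),
        }
    fc_template = emb.build_template(
        [connectomes[s.subject_id]["FC"] for s in subjects], kernel=kernel, sparsity=sparsity
    )
    sc_template = emb.build_template(
        [connectomes[s.subject_id]["SC"] for s in subjects], kernel=kernel, sparsity=sparsity
    )
    gradients = {}
    for s in subjects:
        sid = s.subject_id
        fc_g = emb.procrustes_align(
            emb.embed_connectome(connectomes[sid]["FC"], sparsity=sparsity, kernel=kernel),
            fc_template,
        )
        sc_g = emb.procrustes_align(
            emb.embed_connectome(connectomes[sid]["SC"], sparsity=sparsity, kernel=kernel),
            sc_template,
        )
        sels = {}
        for mod, gset in (("FC", fc_g), ("SC", sc_g)):
            deg = hub_ops.node_degree(connectomes[sid][mod], sparsity=sparsity)
            hubs = hub_ops.select_hubs(deg, config.n_hubs)
            sels[mod] = hub_ops.nearest_hubs_in_gradient_space(
                gset, hubs, k=config.k_nearest_hubs
            )
        gradients[sid] = SubjectGradients(
            fc=fc_g, sc=sc_g, fc_hub_rois=sels["FC"], sc_hub_rois=sels["SC"]
        )
    cohort = Cohort(
        config=config,
        parcellation=parc,
        subjects=subjects,
        connectomes=connectomes,
        fc_template=fc_template,
        sc_template=sc_template,
        gradients=gradients,
    )
    if with_pet:
        cohort.pet = make_pet_cohort(parc, gradients, subjects, config, ss_pet)
    if with_cognition and with_pet:
        g1 = {sid: gradients[sid].fc.scores[:, 0] for sid in cohort.pet.baseline}
        cohort.cognition = make_cognition(
            subjects, cohort.pet.baseline, g1, config, ss_cog
        )
    return cohort
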