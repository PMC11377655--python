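"""Synthetic cohorts with a hippocampal hub-failure signal.

The generator emulates the statistical structure the analysis assumes,
not any particular scanner or tractography pipeline:

* **Connectomes.**  Expected streamline counts follow a multiplicative
  hub model, lambda_ij = base_scale * h_i * h_j * g_ij * u, where h is a
  per-region hubness profile (elevated for bilateral hippocampus,
  thalamus, precuneus and superior frontal cortex; editable preset), g
  is a lattice factor that strengthens within-hemisphere neighbours and
  homotopic pairs (the geometric backbone real connectomes have), and u
  is a subject-level lognormal factor mimicking residual global
  tractogram-size variation.  Counts are drawn once per upper-triangle
  cell from a negative binomial (overdispersed; Poisson in the
  dispersion -> infinity limit), so matrices are symmetric nonnegative
  integers with a zero diagonal by construction.

* **Lesion.**  Patients receive a multiplicative attenuation of every
  edge incident to the lesioned nodes (default: both hippocampi,
  delta = 0.15) and a mild gain on edges of a compensating hub (default:
  right precuneus), modelling hub failure with load redistribution.

* **Phenotypes.**  Hippocampal volumes are linearly coupled to the
  subject's own-hemisphere hippocampal node-strength AUC with
  coefficients solved from a pilot ensemble so the model-implied Pearson
  correlation hits the configured targets; a verbal-memory score is
  coupled to left hippocampal strength AUC with age and education
  confounds so the covariate-adjusted partial correlation hits its
  target.  All coefficients are recorded in the returned ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .io import Cohort, ConnectivityMatrix, ParcellationTable, SubjectRecord, default_parcellation
from .stats import curve_auc
from .thresholding import ThresholdRange, default_range, edge_count_for_density, edge_order

log = logging.getLogger(__name__)


def default_hubness(parcellation: ParcellationTable) -> np.ndarray:
    """The bundled hubness preset aligned to a parcellation's labels."""
    with resources.files("structconn.data").joinpath("hubness_default.csv").open() as f:
        table = pd.read_csv(f).set_index("label")["hubness"]
    try:
        return table.loc[parcellation.labels].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValueError(f"hubness preset missing labels for this parcellation: {exc}") from exc


@dataclass
class SyntheticConfig:
    """Generative parameters; defaults are the emulated study conditions."""

    n_patients: int = 61
    n_controls: int = 61
    base_scale: float = 30.0
    dispersion: float = 8.0  # negative-binomial size; inf = Poisson
    subject_sd: float = 0.15  # lognormal sd of the global subject factor
    lattice_amplitude: float = 20.0
    lattice_decay: float = 4.5
    homotopic_gain: float = 12.0
    lesion_nodes: tuple[str, ...] = ("Left-Hippocampus", "Right-Hippocampus")
    lesion_delta: float = 0.15
    gain_nodes: tuple[str, ...] = ("rh.precuneus",)
    gain_gamma: float = 0.05
    vol_coupling_left: float = 0.33
    vol_coupling_right: float = 0.53
    cog_partial_r: float = 0.30
    age_range: tuple[float, float] = (15.0, 50.0)
    edu_range: tuple[float, float] = (8.0, 18.0)
    icv_mean: float = 1.5e6  # mm^3
    icv_sd: float = 1.5e5
    n_pilot: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_scale <= 0 or self.dispersion <= 0:
            raise ValueError("rates must be positive")
        if not 0 <= self.lesion_delta < 1:
            raise ValueError("lesion_delta must lie in [0, 1)")
        if self.gain_gamma < 0:
            raise ValueError("gain_gamma must be nonnegative")
        for r in (self.vol_coupling_left, self.vol_coupling_right, self.cog_partial_r):
            if not -1 < r < 1:
                raise ValueError(f"coupling target {r} must lie in (-1, 1)")


#: phenotype scale constants (means / non-ICV standard deviations, mm^3 or score units)
_VOLUME_SCALES = {
    "left_hippocampus": (4000.0, 400.0, 0.002),  # mean, sd, ICV slope
    "right_hippocampus": (4100.0, 400.0, 0.002),
    "posterior_cingulate": (3500.0, 350.0, 0.0015),
    "cerebral_white_matter": (450000.0, 40000.0, 0.2),
}
_RAVLT_MEAN, _RAVLT_SD = 8.0, 3.0
_AGE_SLOPE, _EDU_SLOPE = -0.05, 0.2


@dataclass
class GroundTruth:
    """Everything needed to recompute expected values of the generator."""

    config: SyntheticConfig
    parcellation: ParcellationTable
    hubness: np.ndarray
    lattice: np.ndarray
    lambda_base: np.ndarray  # expected counts for u = 1, no lesion
    lesion_idx: np.ndarray
    gain_idx: np.ndarray
    subject_factors: dict[str, float]
    vol_coefficients: dict[str, dict[str, float]]
    cog_coefficients: dict[str, float]
    pilot_strength_stats: dict[str, tuple[float, float]]  # scope -> (mean, sd) of AUC

    def lesion_factor_matrix(self) -> np.ndarray:
        f = np.ones_like(self.lambda_base)
        for i in self.lesion_idx:
            f[i, :] *= 1 - self.config.lesion_delta
            f[:, i] *= 1 - self.config.lesion_delta
        for i in self.gain_idx:
            if i in set(self.lesion_idx.tolist()):
                continue
            mask = np.ones(len(f), dtype=bool)
            mask[self.lesion_idx] = False
            f[i, mask] *= 1 + self.config.gain_gamma
            f[mask, i] *= 1 + self.config.gain_gamma
            f[i, i] = 1.0
        return f

    def expected_matrix(self, group: str) -> np.ndarray:
        if group == "control":
            return self.lambda_base.copy()
        if group == "patient":
            return self.lambda_base * self.lesion_factor_matrix()
        raise ValueError(f"unknown group {group!r}")


def _lattice_matrix(parcellation: ParcellationTable, config: SyntheticConfig) -> np.ndarray:
    """Distance-decaying within-hemisphere ring boosts plus homotopic edges.

    g_ij = 1 + amplitude * exp(-(ring_distance-1)/decay) for pairs in the
    same hemisphere; homotopic pairs get a flat gain.  This geometric
    backbone gives thresholded networks the lattice-like clustering that
    keeps them small-world through the integration range.
    """
    n = parcellation.n
    hemi = parcellation.table["hemisphere"].to_numpy()
    g = np.ones((n, n))
    for h in ("left", "right"):
        idx = np.flatnonzero(hemi == h)
        m = len(idx)
        for a in range(m):
            for b in range(a + 1, m):
                ring = min(b - a, m - (b - a))
                boost = 1 + config.lattice_amplitude * np.exp(-(ring - 1) / config.lattice_decay)
                g[idx[a], idx[b]] = g[idx[b], idx[a]] = boost
    left = np.flatnonzero(hemi == "left")
    right = np.flatnonzero(hemi == "right")
    if len(left) == len(right):
        for a, b in zip(left, right):
            g[a, b] = g[b, a] = config.homotopic_gain
    np.fill_diagonal(g, 1.0)
    return g


def generate_base_connectome(
    lambda_base: np.ndarray,
    parcellation: ParcellationTable,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[ConnectivityMatrix, float]:
    """One subject's count matrix; returns (matrix, subject factor u).

    The upper triangle is drawn once and mirrored, giving exact symmetry
    and a zero diagonal.
    """
    n = lambda_base.shape[0]
    sd = config.subject_sd
    u = float(rng.lognormal(mean=-0.5 * sd**2, sigma=sd)) if sd > 0 else 1.0
    iu, ju = np.triu_indices(n, 1)
    lam = lambda_base[iu, ju] * u
    if np.isinf(config.dispersion):
        counts = rng.poisson(lam)
    else:
        theta = config.dispersion
        counts = rng.negative_binomial(theta, theta / (theta + lam))
    w = np.zeros((n, n))
    w[iu, ju] = counts
    w[ju, iu] = counts
    return ConnectivityMatrix(w, parcellation), u


def apply_hub_lesion(
    m: ConnectivityMatrix,
    lesion_idx: np.ndarray,
    delta: float,
    gain_idx: np.ndarray | None = None,
    gamma: float = 0.0,
) -> ConnectivityMatrix:
    """Attenuate all edges of lesioned nodes; boost edges of gain nodes.

    Edges between two lesioned nodes are attenuated twice ((1-delta)^2).
    A node in both sets is treated as lesioned (logged).
    """
    w = m.weights.copy()
    lesion_set = set(np.asarray(lesion_idx, dtype=int).tolist())
    for i in lesion_set:
        w[i, :] *= 1 - delta
        w[:, i] *= 1 - delta
    if gain_idx is not None and gamma != 0.0:
        lesion_mask = np.zeros(m.n, dtype=bool)
        lesion_mask[list(lesion_set)] = True
        for i in np.asarray(gain_idx, dtype=int):
            if i in lesion_set:
                log.warning("node %d in both lesion and gain sets; lesion takes precedence", i)
                continue
            keep = ~lesion_mask
            w[i, keep] *= 1 + gamma
            w[keep, i] *= 1 + gamma
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(w, m.parcellation)


def strength_auc(m: ConnectivityMatrix, nodes: np.ndarray, grid: ThresholdRange) -> np.ndarray:
    """Node-strength AUC over the density grid for the given nodes.

    Uses the same deterministic edge ordering as the thresholding
    module, so values agree exactly with thresholding each density and
    summing weights.
    """
    ii, jj = edge_order(m)
    wsorted = m.weights[ii, jj]
    n = m.n
    curves = np.empty((len(grid), len(nodes)))
    for di, density in enumerate(grid.densities):
        k = edge_count_for_density(n, density)
        s = np.bincount(ii[:k], weights=wsorted[:k], minlength=n)
        s += np.bincount(jj[:k], weights=wsorted[:k], minlength=n)
        curves[di] = s[np.asarray(nodes, dtype=int)]
    d = np.asarray(grid.densities)
    return np.array([curve_auc(d, curves[:, j]) for j in range(len(nodes))])


def _labels_to_idx(parcellation: ParcellationTable, labels: tuple[str, ...]) -> np.ndarray:
    return np.array([parcellation.index_of(lb) for lb in labels], dtype=int)


def generate_cohort(
    config: SyntheticConfig | None = None,
    parcellation: ParcellationTable | None = None,
    hubness: np.ndarray | None = None,
    grid: ThresholdRange | None = None,
) -> tuple[Cohort, GroundTruth]:
    """Draw a full cohort (controls + lesioned patients) with ground truth.

    Coupling coefficients for volumes and the memory score are solved
    from a pilot ensemble of ``config.n_pilot`` patient draws, so the
    model-implied correlations equal the configured targets.  The whole
    cohort is reproducible from ``config.seed``.
    """
    config = config or SyntheticConfig()
    parcellation = parcellation or default_parcellation()
    h = np.asarray(hubness if hubness is not None else default_hubness(parcellation), dtype=float)
    if np.any(h <= 0):
        raise ValueError("hubness values must be positive")
    grid = grid or default_range()

    lattice = _lattice_matrix(parcellation, config)
    lambda_base = config.base_scale * np.outer(h, h) * lattice
    np.fill_diagonal(lambda_base, 0.0)

    lesion_idx = _labels_to_idx(parcellation, config.lesion_nodes)
    gain_idx = _labels_to_idx(parcellation, config.gain_nodes)
    lh = parcellation.index_of("Left-Hippocampus")
    rh = parcellation.index_of("Right-Hippocampus")

    root = np.random.SeedSequence(config.seed)
    ss_pilot, ss_subjects, ss_pheno = root.spawn(3)

    # --- pilot ensemble: variance of the coupling variables under the patient model
    pilot_rng = np.random.default_rng(ss_pilot)
    pilot_aucs = np.empty((config.n_pilot, 2))
    for p in range(config.n_pilot):
        m, _ = generate_base_connectome(lambda_base, parcellation, config, pilot_rng)
        m = apply_hub_lesion(m, lesion_idx, config.lesion_delta, gain_idx, config.gain_gamma)
        pilot_aucs[p] = strength_auc(m, np.array([lh, rh]), grid)
    pilot_stats = {
        "left_hippocampus": (float(pilot_aucs[:, 0].mean()), float(pilot_aucs[:, 0].std(ddof=1))),
        "right_hippocampus": (float(pilot_aucs[:, 1].mean()), float(pilot_aucs[:, 1].std(ddof=1))),
    }
    for scope, (_, sd) in pilot_stats.items():
        if sd == 0:
            raise ValueError(
                f"pilot strength AUC for {scope} has zero variance; "
                "coupling targets unreachable (increase dispersion or subject_sd)"
            )

    # --- solve coupling coefficients (slope and residual sd per target r)
    vol_coef: dict[str, dict[str, float]] = {}
    for region, target_r, scope in (
        ("left_hippocampus", config.vol_coupling_left, "left_hippocampus"),
        ("right_hippocampus", config.vol_coupling_right, "right_hippocampus"),
    ):
        mean_v, sd_v, icv_slope = _VOLUME_SCALES[region]
        mean_x, sd_x = pilot_stats[scope]
        vol_coef[region] = {
            "intercept": mean_v,
            "slope": target_r * sd_v / sd_x,
            "x_center": mean_x,
            "icv_slope": icv_slope,
            "noise_sd": sd_v * float(np.sqrt(1 - target_r**2)),
        }
    for region in ("posterior_cingulate", "cerebral_white_matter"):
        mean_v, sd_v, icv_slope = _VOLUME_SCALES[region]
        vol_coef[region] = {
            "intercept": mean_v, "slope": 0.0, "x_center": 0.0,
            "icv_slope": icv_slope, "noise_sd": sd_v,
        }
    mean_xl, sd_xl = pilot_stats["left_hippocampus"]
    cog_coef = {
        "intercept": _RAVLT_MEAN,
        "slope": config.cog_partial_r * _RAVLT_SD / sd_xl,
        "x_center": mean_xl,
        "age_slope": _AGE_SLOPE,
        "edu_slope": _EDU_SLOPE,
        "noise_sd": _RAVLT_SD * float(np.sqrt(1 - config.cog_partial_r**2)),
    }

    # --- cohort draws
    n_total = config.n_patients + config.n_controls
    subj_seeds = ss_subjects.spawn(n_total)
    pheno_rng = np.random.default_rng(ss_pheno)
    ages = pheno_rng.uniform(*config.age_range, size=n_total)
    edus = pheno_rng.uniform(*config.edu_range, size=n_total)
    icvs = pheno_rng.normal(config.icv_mean, config.icv_sd, size=n_total)
    age_center = float(np.mean(config.age_range))
    edu_center = float(np.mean(config.edu_range))

    subjects: list[SubjectRecord] = []
    factors: dict[str, float] = {}
    for k in range(n_total):
        is_patient = k < config.n_patients
        group = "patient" if is_patient else "control"
        sid = f"{'pat' if is_patient else 'con'}{(k if is_patient else k - config.n_patients) + 1:03d}"
        rng = np.random.default_rng(subj_seeds[k])
        m, u = generate_base_connectome(lambda_base, parcellation, config, rng)
        if is_patient:
            m = apply_hub_lesion(m, lesion_idx, config.lesion_delta, gain_idx, config.gain_gamma)
        factors[sid] = u
        x_left, x_right = strength_auc(m, np.array([lh, rh]), grid)

        volumes = {}
        for region, coef in vol_coef.items():
            x = {"left_hippocampus": x_left, "right_hippocampus": x_right}.get(region, 0.0)
            volumes[region] = float(
                coef["intercept"]
                + coef["slope"] * (x - coef["x_center"])
                + coef["icv_slope"] * (icvs[k] - config.icv_mean)
                + rng.normal(0.0, coef["noise_sd"])
            )
        if is_patient:
            scores = {
                "mrs_acute": float(rng.integers(2, 6)),
                "onset_treatment_days": float(np.round(rng.lognormal(np.log(19.0), 0.9))),
                "ravlt_delayed": float(
                    cog_coef["intercept"]
                    + cog_coef["slope"] * (x_left - cog_coef["x_center"])
                    + cog_coef["age_slope"] * (ages[k] - age_center)
                    + cog_coef["edu_slope"] * (edus[k] - edu_center)
                    + rng.normal(0.0, cog_coef["noise_sd"])
                ),
                "rocf_delayed": float(rng.normal(15.0, 6.0)),
                "gonogo": float(rng.normal(550.0, 80.0)),
            }
        else:
            scores = {name: float("nan") for name in
                      ("mrs_acute", "onset_treatment_days", "ravlt_delayed", "rocf_delayed", "gonogo")}
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=group,
                matrix=m,
                age=float(ages[k]),
                education=float(edus[k]),
                icv=float(icvs[k]),
                regional_volumes=volumes,
                scores=scores,
            )
        )

    truth = GroundTruth(
        config=config,
        parcellation=parcellation,
        hubness=h,
        lattice=lattice,
        lambda_base=lambda_base,
        lesion_idx=lesion_idx,
        gain_idx=gain_idx,
        subject_factors=factors,
        vol_coefficients=vol_coef,
        cog_coefficients=cog_coef,
        pilot_strength_stats=pilot_stats,
    )
    return Cohort(subjects), truth
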