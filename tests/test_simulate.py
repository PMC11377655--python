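import numpy as np
import pytest

from structconn.io import load_cohort, load_parcellation, write_cohort
from structconn.metrics import node_strength
from structconn.simulate import (
    GroundTruth,
    SyntheticConfig,
    apply_hub_lesion,
    default_hubness,
    generate_base_connectome,
    generate_cohort,
    strength_auc,
    _lattice_matrix,
    _labels_to_idx,
)
from structconn.thresholding import apply_density_threshold, default_range

from conftest import matrix_from


@pytest.fixture(scope="module")
def base_model(parc84):
    cfg = SyntheticConfig(seed=0)
    h = default_hubness(parc84)
    lat = _lattice_matrix(parc84, cfg)
    lam = cfg.base_scale * np.outer(h, h) * lat
    np.fill_diagonal(lam, 0.0)
    return cfg, parc84, lam


class TestBaseConnectome:
    def test_symmetric_zero_diagonal_integer_counts(self, base_model):
        cfg, parc, lam = base_model
        rng = np.random.default_rng(0)
        m, u = generate_base_connectome(lam, parc, cfg, rng)
        assert np.array_equal(m.weights, m.weights.T)
        assert np.all(np.diag(m.weights) == 0)
        assert np.all(m.weights == np.round(m.weights))
        assert u > 0

    def test_expected_strength_matches_analytic_mean(self, base_model):
        cfg, parc, lam = base_model
        rng = np.random.default_rng(1)
        n_draws = 200
        strengths = np.zeros((n_draws, parc.n))
        us = np.zeros(n_draws)
        for d in range(n_draws):
            m, u = generate_base_connectome(lam, parc, cfg, rng)
            strengths[d] = node_strength(m)
            us[d] = u
        # conditional on the drawn subject factors, E[strength_i] = mean(u)*sum_j lam_ij
        expected = us.mean() * lam.sum(axis=1)
        observed = strengths.mean(axis=0)
        se = strengths.std(axis=0, ddof=1) / np.sqrt(n_draws)
        assert np.all(np.abs(observed - expected) < 5 * se + 1e-9)

    def test_poisson_limit_variance_over_mean_near_one(self, base_model):
        _, parc, lam = base_model
        cfg = SyntheticConfig(dispersion=np.inf, subject_sd=0.0, seed=0)
        rng = np.random.default_rng(2)
        draws = np.array([
            generate_base_connectome(lam, parc, cfg, rng)[0].weights[0, 1]
            for _ in range(3000)
        ])
        ratio = draws.var(ddof=1) / draws.mean()
        assert 0.9 < ratio < 1.1

    def test_negative_binomial_is_overdispersed(self, base_model):
        _, parc, lam = base_model
        cfg = SyntheticConfig(dispersion=4.0, subject_sd=0.0, seed=0)
        rng = np.random.default_rng(3)
        draws = np.array([
            generate_base_connectome(lam, parc, cfg, rng)[0].weights[0, 1]
            for _ in range(3000)
        ])
        mean = draws.mean()
        expected_ratio = 1 + mean / 4.0
        assert draws.var(ddof=1) / mean > 0.7 * expected_ratio


class TestHubLesion:
    def test_zero_delta_zero_gamma_identity(self):
        rng = np.random.default_rng(0)
        w = rng.integers(0, 50, size=(6, 6)).astype(float)
        w = np.triu(w, 1)
        w = w + w.T
        m = matrix_from(w)
        out = apply_hub_lesion(m, np.array([1]), 0.0, np.array([2]), 0.0)
        assert np.array_equal(out.weights, m.weights)

    def test_closed_form_scaling(self):
        w = np.full((4, 4), 10.0)
        np.fill_diagonal(w, 0.0)
        m = matrix_from(w)
        out = apply_hub_lesion(m, np.array([0, 1]), 0.15)
        assert out.weights[0, 2] == pytest.approx(10 * 0.85)
        assert out.weights[0, 1] == pytest.approx(10 * 0.85**2)
        assert out.weights[2, 3] == pytest.approx(10.0)
        # lesioned node strength vs non-lesioned neighbours scales by 0.85
        assert node_strength(out)[0] == pytest.approx(10 * 0.85**2 + 2 * 10 * 0.85)

    def test_gain_nodes_boosted_except_toward_lesion(self):
        w = np.full((4, 4), 10.0)
        np.fill_diagonal(w, 0.0)
        m = matrix_from(w)
        out = apply_hub_lesion(m, np.array([0]), 0.2, np.array([2]), 0.1)
        assert out.weights[2, 3] == pytest.approx(11.0)
        assert out.weights[0, 2] == pytest.approx(10 * 0.8)  # lesion wins on shared edge

    def test_gain_raises_precuneus_strength_on_average(self, base_model):
        cfg, parc, lam = base_model
        idx = _labels_to_idx(parc, ("rh.precuneus",))[0]
        lesion = _labels_to_idx(parc, cfg.lesion_nodes)
        rng = np.random.default_rng(4)
        pat, con = [], []
        for _ in range(40):
            m, _ = generate_base_connectome(lam, parc, cfg, rng)
            con.append(node_strength(m)[idx])
            pat.append(node_strength(
                apply_hub_lesion(m, lesion, cfg.lesion_delta, np.array([idx]), 0.05)
            )[idx])
        assert np.mean(pat) > np.mean(con)


class TestGenerateCohort:
    def test_cohort_counts_and_roundtrip(self, synth_cohort_small, tmp_path):
        cohort, truth = synth_cohort_small
        assert cohort.n_subjects == 24
        assert len(cohort.by_group("patient")) == 12
        manifest = write_cohort(cohort, tmp_path)
        parc = load_parcellation(tmp_path / "parcellation.csv")
        reloaded = load_cohort(manifest, parc)
        for a, b in zip(cohort.subjects, reloaded.subjects):
            assert np.array_equal(a.matrix.weights, b.matrix.weights)

    def test_determinism_byte_identical_files(self, tmp_path):
        cfg = SyntheticConfig(n_patients=3, n_controls=3, n_pilot=10, seed=9)
        for run in ("a", "b"):
            cohort, _ = generate_cohort(cfg)
            write_cohort(cohort, tmp_path / run)
        for f in sorted((tmp_path / "a").rglob("*.csv")):
            other = tmp_path / "b" / f.relative_to(tmp_path / "a")
            assert f.read_bytes() == other.read_bytes(), f.name

    def test_hippocampal_strength_reduced_in_patients(self, synth_cohort_small):
        cohort, truth = synth_cohort_small
        parc = cohort.parcellation
        grid = default_range()
        for label in ("Left-Hippocampus", "Right-Hippocampus"):
            idx = np.array([parc.index_of(label)])
            pat = np.mean([strength_auc(s.matrix, idx, grid)[0] for s in cohort.by_group("patient")])
            con = np.mean([strength_auc(s.matrix, idx, grid)[0] for s in cohort.by_group("control")])
            assert pat < con

    def test_expected_matrix_reflects_lesion(self, synth_cohort_small):
        cohort, truth = synth_cohort_small
        lam_p = truth.expected_matrix("patient")
        lam_c = truth.expected_matrix("control")
        lh = truth.parcellation.index_of("Left-Hippocampus")
        other = 0  # a non-lesioned, non-gain node
        assert lam_p[lh, other] == pytest.approx(lam_c[lh, other] * 0.85)

    def test_controls_have_missing_scores_patients_complete(self, synth_cohort_small):
        cohort, _ = synth_cohort_small
        for s in cohort.by_group("control"):
            assert np.isnan(s.scores["ravlt_delayed"])
        for s in cohort.by_group("patient"):
            assert np.isfinite(s.scores["ravlt_delayed"])

    def test_strength_auc_matches_explicit_thresholding(self, synth_cohort_small):
        from structconn.stats import curve_auc

        cohort, _ = synth_cohort_small
        subj = cohort.subjects[0]
        parc = cohort.parcellation
        idx = parc.index_of("Left-Hippocampus")
        grid = default_range()
        fast = strength_auc(subj.matrix, np.array([idx]), grid)[0]
        explicit = curve_auc(
            np.array(grid.densities),
            [node_strength(apply_density_threshold(subj.matrix, d))[idx] for d in grid.densities],
        )
        assert fast == pytest.approx(explicit, rel=1e-12)
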