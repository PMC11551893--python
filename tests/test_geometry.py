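"""Tests of prewhitening, crossnobis distances, MDS and the cross-phase statistic."""

import numpy as np
import pandas as pd
import pytest

from seqmvpa import (
    MDSEmbedding,
    PatternDataset,
    SimulationConfig,
    classical_mds,
    cross_phase_distance,
    cross_phase_statistic,
    crossnobis_rdm,
    estimate_noise_covariance,
    mds_from_dataset,
    normalize_cross_phase,
    simulate_cross_phase_baseline,
    simulate_subject_patterns,
    whiten,
)
from seqmvpa.geometry import test_against_baseline as group_vs_baseline
from seqmvpa.datasets import PREPARATION, PRODUCTION, complete_design_labels
from seqmvpa.geometry import CONDITION_ORDER, NoiseCovariance
from seqmvpa.stats import DegenerateTestError


def _dataset_from_rows(rows_by_run, phases=(PREPARATION,)):
    """Build a dataset from {run: (4, P) array} with canonical condition order."""
    labels = complete_design_labels(len(rows_by_run), phases=phases)
    patterns = np.vstack([rows_by_run[k] for k in sorted(rows_by_run)])
    return PatternDataset(patterns, labels)


class TestNoiseCovariance:
    def test_iid_residuals_give_identity(self, rng):
        # one condition, many runs, unit-variance white residuals
        n_runs, P = 400, 12
        labels = pd.DataFrame(
            {"order": 1, "timing": 1, "phase": PREPARATION,
             "run": np.arange(1, n_runs + 1)}
        )
        ds = PatternDataset(rng.normal(size=(n_runs, P)), labels)
        noise = estimate_noise_covariance(ds, shrinkage=0.0)
        assert np.allclose(noise.covariance, np.eye(P), atol=0.35)
        assert np.allclose(noise.whitener, np.eye(P), atol=0.35)

    def test_full_shrinkage_is_diagonal(self, default_subject):
        noise = estimate_noise_covariance(default_subject, shrinkage=1.0)
        off = noise.covariance - np.diag(np.diag(noise.covariance))
        assert np.allclose(off, 0.0)

    def test_whitener_is_inverse_principal_sqrt(self, default_subject):
        noise = estimate_noise_covariance(default_subject, shrinkage=0.3)
        P = noise.covariance.shape[0]
        ident = noise.whitener @ noise.covariance @ noise.whitener.T
        assert np.allclose(ident, np.eye(P), atol=1e-8)
        # principal square root is symmetric
        assert np.allclose(noise.whitener, noise.whitener.T, atol=1e-10)

    def test_whitening_oracle_on_correlated_noise(self, rng):
        # residuals with a known AR(1)-structured covariance: after whitening
        # with the estimated covariance, their sample covariance is identity
        P, n_runs = 10, 1000
        Sigma = 0.7 ** np.abs(np.subtract.outer(np.arange(P), np.arange(P)))
        L = np.linalg.cholesky(Sigma)
        labels = pd.DataFrame(
            {"order": 1, "timing": 1, "phase": PREPARATION,
             "run": np.arange(1, n_runs + 1)}
        )
        X = rng.normal(size=(n_runs, P)) @ L.T
        ds = PatternDataset(X, labels)
        noise = estimate_noise_covariance(ds, shrinkage=0.0)
        wds = whiten(ds, noise)
        resid = wds.patterns - wds.patterns.mean(axis=0)
        emp = resid.T @ resid / (n_runs - 1)
        assert np.linalg.norm(emp - np.eye(P), ord="fro") < 0.1


class TestCrossnobis:
    def test_closed_form_single_voxel_difference(self):
        # conditions differing by delta in one voxel, identity noise,
        # no run noise: d = delta^2 / P exactly
        P, K, delta = 8, 4, 3.0
        base = np.zeros((4, P))
        rows = {}
        for k in range(1, K + 1):
            block_prep = base.copy()
            block_prep[0, 0] += delta  # condition (1,1) shifted
            rows[k] = block_prep
        prep = {k: rows[k] for k in rows}
        prod = {k: np.zeros((4, P)) for k in rows}
        stacked = {k: np.vstack([prep[k], prod[k]]) for k in rows}
        labels = complete_design_labels(K)
        # labels order per run: phase-major — build matching patterns
        patterns = []
        for k in sorted(stacked):
            patterns.append(stacked[k])
        ds = PatternDataset(np.vstack(patterns), labels)
        identity = NoiseCovariance(np.eye(P), 0.0, np.eye(P))
        rdm = crossnobis_rdm(ds, noise=identity)
        d = rdm.value((1, 1, PREPARATION), (1, 2, PREPARATION))
        assert d == pytest.approx(delta**2 / P)
        # conditions with identical patterns are at distance zero
        assert rdm.value((2, 1, PREPARATION), (2, 2, PREPARATION)) == pytest.approx(0.0)

    def test_translation_invariance(self, default_subject):
        rdm1 = crossnobis_rdm(default_subject, shrinkage=0.4)
        shifted = PatternDataset(
            default_subject.patterns + 7.5, default_subject.labels.copy()
        )
        rdm2 = crossnobis_rdm(shifted, shrinkage=0.4)
        assert np.allclose(rdm1.distances, rdm2.distances, atol=1e-9)

    def test_rdm_symmetry_and_zero_diagonal(self, default_subject):
        rdm = crossnobis_rdm(default_subject, shrinkage=0.4)
        assert np.allclose(rdm.distances, rdm.distances.T)
        assert np.allclose(np.diag(rdm.distances), 0.0)

    def test_unbiased_for_identical_conditions(self):
        # light version; the full 500-simulation check lives in the
        # acceptance suite
        from seqmvpa.experiments import crossnobis_null

        summary = crossnobis_null(n_sims=100, n_voxels=24, seed=3)
        assert summary.mean_over_se < 3.0


class TestClassicalMDS:
    def test_square_configuration(self):
        pts = np.array(
            [[1.0, 1.0], [1.0, -1.0], [-1.0, -1.0], [-1.0, 1.0]]
        )
        emb = classical_mds(pts)
        w = emb.eigenvalues
        assert w[0] == pytest.approx(w[1])
        assert w[0] > 0
        assert np.allclose(w[2:], 0.0, atol=1e-9)
        d_in = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d_out = np.linalg.norm(
            emb.coordinates[:, None] - emb.coordinates[None], axis=-1
        )
        assert np.allclose(d_in, d_out, atol=1e-8)

    def test_exact_distance_recovery_full_rank(self, rng):
        pts = rng.normal(size=(8, 20))
        emb = classical_mds(pts)
        d_in = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d_out = np.linalg.norm(
            emb.coordinates[:, None] - emb.coordinates[None], axis=-1
        )
        assert np.allclose(d_in, d_out, atol=1e-8)
        assert np.all(np.diff(emb.eigenvalues) <= 1e-9)  # nonincreasing
        assert np.allclose(emb.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_identical_points_give_zero_coordinates(self):
        emb = classical_mds(np.ones((5, 7)) * 3.14)
        assert np.allclose(emb.coordinates, 0.0, atol=1e-9)

    def test_phase_offset_dominates_first_component(self):
        ds = simulate_subject_patterns(SimulationConfig(seed=42))
        emb = mds_from_dataset(ds, shrinkage=0.4)
        assert emb.variance_explained[0] == emb.variance_explained.max()
        pc1 = emb.coordinates[:, 0]
        prep_sign = np.sign(
            [pc1[emb.conditions.index((o, t, PREPARATION))]
             for o in (1, 2) for t in (1, 2)]
        )
        prod_sign = np.sign(
            [pc1[emb.conditions.index((o, t, PRODUCTION))]
             for o in (1, 2) for t in (1, 2)]
        )
        assert len(set(prep_sign)) == 1
        assert len(set(prod_sign)) == 1
        assert prep_sign[0] != prod_sign[0]


def _manual_embedding(prep_coords, prod_coords):
    coords = np.vstack([prep_coords, prod_coords])
    return MDSEmbedding(
        coordinates=coords,
        eigenvalues=np.zeros(coords.shape[1]),
        variance_explained=np.zeros(coords.shape[1]),
        conditions=list(CONDITION_ORDER),
    )


class TestCrossPhaseStatistic:
    def test_three_four_five_triangle(self):
        prep = np.tile([0.0, 3.0, 4.0], (4, 1))
        prep += np.arange(4)[:, None] * [0, 10, 0]  # spread sequences apart
        prod = np.tile([9.0, 0.0, 0.0], (4, 1))
        prod += np.arange(4)[:, None] * [0, 10, 0]
        emb = _manual_embedding(prep, prod)
        d = cross_phase_distance(emb)
        assert np.allclose(d, 5.0)

    def test_zero_cross_phase_distance_normalizes_to_zero(self):
        coords = np.arange(8.0)[:, None] % 4 * np.array([[0.0, 1.0, 2.0]])
        emb = _manual_embedding(coords[:4], coords[:4])
        res = normalize_cross_phase(emb)
        assert res.normalized_distance == 0.0
        assert len(res.per_sequence_distance) == 4

    def test_scale_invariance(self, default_subject):
        emb = mds_from_dataset(default_subject, shrinkage=0.4)
        res1 = normalize_cross_phase(emb)
        doubled = MDSEmbedding(
            emb.coordinates * 2, emb.eigenvalues, emb.variance_explained,
            emb.conditions,
        )
        res2 = normalize_cross_phase(doubled)
        assert res2.normalized_distance == pytest.approx(res1.normalized_distance)

    def test_statistic_scale_invariant_under_pattern_rescaling(self, default_subject):
        res1 = cross_phase_statistic(default_subject, shrinkage=0.4)
        rescaled = PatternDataset(
            default_subject.patterns * 3.0, default_subject.labels.copy()
        )
        res2 = cross_phase_statistic(rescaled, shrinkage=0.4)
        assert res2.normalized_distance == pytest.approx(
            res1.normalized_distance, rel=1e-8
        )

    def test_degenerate_normalization_raises(self):
        emb = _manual_embedding(np.zeros((4, 3)), np.zeros((4, 3)))
        with pytest.raises(ZeroDivisionError):
            normalize_cross_phase(emb)


class TestBaselines:
    def test_noswitch_baseline_positive_but_switch_larger(self):
        common = dict(
            n_voxels=60, n_runs=6, snr_prep=0.5, snr_prod=1.0, n_sims=25,
            shrinkage=0.4, seed=5,
        )
        no_switch = simulate_cross_phase_baseline(switch=False, **common)
        switch = simulate_cross_phase_baseline(switch=True, **common)
        assert no_switch.mean > 0.0  # noise-driven positive bias
        assert switch.mean > no_switch.mean

    def test_noiseless_limit_baseline_vanishes(self):
        # with the phase offset at zero the no-switch preparation and
        # production configurations coincide exactly once noise vanishes.
        # (a finite offset leaves a small deterministic leakage of the offset
        # direction into components 2-3, which the matched baseline absorbs)
        base = simulate_cross_phase_baseline(
            n_voxels=60, n_runs=6, snr_prep=1e6, snr_prod=1e6,
            switch=False, n_sims=5, var_r=0.0, phase_offset=0.0,
            shrinkage=0.4, seed=6,
        )
        assert base.mean < 0.01

    def test_group_test_closed_form(self):
        res = group_vs_baseline(np.array([1.0, 2.0, 3.0]), 0.0)
        assert res.t == pytest.approx(np.sqrt(12), abs=1e-9)  # 3.464
        assert res.cohens_d == pytest.approx(2.0)
        assert res.tails == "one"
        with pytest.raises(DegenerateTestError):
            group_vs_baseline(np.array([0.5, 0.5, 0.5]), 0.5)
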