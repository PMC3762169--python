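"""Fiber axis extraction: directional sampling, clustered vMF, Std baseline."""

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from fiberodf import (
    EmptySampleError,
    SphereGrid,
    add_rician,
    crossing_compartments,
    directional_sample,
    estimate_vmf,
    reconstruct_odf,
    shell_scheme,
    std_peaks,
    synth_signal,
)
from fiberodf.gqi import ODFProfile, build_basis, gfa
from fiberodf.simulate import DEFAULT_EIGENVALUES, TensorCompartment
from fiberodf.sphere import axial_angle_matrix


def profile_from(normalized):
    """Build an ODFProfile directly from a normalized vector (for unit tests)."""
    v = np.asarray(normalized, dtype=float)
    return ODFProfile(values=v, normalized=v, gfa=gfa(v) if v.any() else 0.0)


class TestDirectionalSample:
    def test_constant_profile_is_unresolvable(self, grid321):
        with pytest.raises(EmptySampleError):
            directional_sample(profile_from(np.zeros(321)), grid321, threshold=0.4)

    def test_one_hot_gives_vertex_and_antipode(self, grid321):
        v = np.zeros(321)
        v[17] = 1.0
        pts, w = directional_sample(profile_from(v), grid321, threshold=0.4)
        assert pts.shape == (2, 3)
        assert np.allclose(pts[0], -pts[1])
        assert np.allclose(w, 1.0)

    def test_two_tensor_sample_splits_into_four_lobes(self, grid321, basis_b3000):
        """Antipodal duplication of a 90-degree crossing yields 4 point groups."""
        comps = crossing_compartments(90.0)
        odf = reconstruct_odf(synth_signal(comps, basis_b3000.scheme), basis_b3000)
        pts, _ = directional_sample(odf, grid321, threshold=0.4)
        # plain (non-axial) adjacency on the duplicated full-sphere sample
        dots = np.clip(pts @ pts.T, -1, 1)
        adj = np.degrees(np.arccos(dots)) < 12.0
        n_comp, _ = connected_components(csr_matrix(adj), directed=False)
        assert n_comp == 4

    def test_threshold_validation(self, grid321):
        with pytest.raises(ValueError):
            directional_sample(profile_from(np.ones(321)), grid321, threshold=1.0)


class TestEstimateVMF:
    def test_single_fiber_recovery(self, grid321, basis_b3000):
        axis = np.array([np.cos(1.1), np.sin(1.1), 0.0])
        comp = TensorCompartment(DEFAULT_EIGENVALUES, axis, 1.0)
        odf = reconstruct_odf(synth_signal([comp], basis_b3000.scheme), basis_b3000)
        est = estimate_vmf(odf, grid321, seed=0)
        assert est.n_fibers == 1
        assert axial_angle_matrix(est.axes[0], axis)[0, 0] < 5.0
        assert est.weights[0] == pytest.approx(1.0, abs=1e-9)

    def test_two_fiber_90deg_recovery(self, grid321, basis_b3000):
        comps = crossing_compartments(90.0)
        truth = np.array([c.axis for c in comps])
        odf = reconstruct_odf(synth_signal(comps, basis_b3000.scheme), basis_b3000)
        est = estimate_vmf(odf, grid321, seed=0)
        assert est.n_fibers == 2
        errs = axial_angle_matrix(est.axes, truth).min(axis=1)
        assert np.all(errs < 5.0)
        assert np.all(np.diff(est.weights) <= 1e-12)  # sorted descending

    def test_three_fiber_60deg_noisy_recovery(self, grid321, basis_b3000):
        """Three fibers 60 degrees apart at b=3000 survive sigma=0.033 noise."""
        comps = crossing_compartments([0.0, 60.0, 120.0])
        odf = reconstruct_odf(
            add_rician(synth_signal(comps, basis_b3000.scheme), 0.033, seed=1), basis_b3000
        )
        est = estimate_vmf(odf, grid321, seed=1)
        assert est.n_fibers == 3

    def test_invariant_under_grid_sign_flip(self, grid321, basis_b3000):
        comps = crossing_compartments(75.0)
        odf = reconstruct_odf(synth_signal(comps, basis_b3000.scheme), basis_b3000)
        flipped = SphereGrid(vertices=-grid321.vertices, level=grid321.level, hemisphere_flag=True)
        a = estimate_vmf(odf, grid321, seed=4)
        b = estimate_vmf(odf, flipped, seed=4)
        assert a.n_fibers == b.n_fibers
        # arccos granularity near 0 limits resolution to ~1e-6 degrees
        assert np.all(axial_angle_matrix(a.axes, b.axes).min(axis=1) < 1e-5)

    def test_kappa_and_weights_reported_per_axis(self, grid321, basis_b3000):
        comps = crossing_compartments(90.0)
        odf = reconstruct_odf(synth_signal(comps, basis_b3000.scheme), basis_b3000)
        est = estimate_vmf(odf, grid321, seed=0)
        assert est.kappas.shape == (2,)
        assert np.all(est.kappas > 0)
        assert est.weights.sum() == pytest.approx(1.0, abs=1e-9)


class TestStdPeaks:
    def test_one_hot_profile_has_single_peak(self, grid321):
        v = np.zeros(321)
        v[100] = 1.0
        est = std_peaks(profile_from(v), grid321)
        assert est.n_fibers == 1
        assert np.allclose(est.axes[0], grid321.vertices[100])

    def test_constant_profile_has_no_peaks(self, grid321):
        est = std_peaks(profile_from(np.zeros(321)), grid321)
        assert est.n_fibers == 0

    def test_matches_exhaustive_local_maxima_search(self, grid321, basis_b3000):
        """Grid-mode peaks equal an independent exhaustive neighborhood scan."""
        comps = crossing_compartments(90.0)
        odf = reconstruct_odf(synth_signal(comps, basis_b3000.scheme), basis_b3000)
        est = std_peaks(odf, grid321, threshold=0.4, radius_deg=25.0, max_fibers=10)

        ang = axial_angle_matrix(grid321.vertices, grid321.vertices)
        oracle = [
            i
            for i in range(321)
            if odf.normalized[i] >= 0.4
            and all(odf.normalized[i] >= odf.normalized[j] for j in np.where(ang[i] <= 25.0)[0])
        ]
        # dedupe oracle peaks within the radius, keeping the larger
        oracle.sort(key=lambda i: -odf.normalized[i])
        kept = []
        for i in oracle:
            if all(ang[i, j] > 25.0 for j in kept):
                kept.append(i)
        assert sorted(map(tuple, est.axes.tolist())) == sorted(
            map(tuple, grid321.vertices[kept].tolist())
        )

    def test_randomized_mode_finds_the_main_lobes(self, grid321, basis_b3000):
        comps = crossing_compartments(90.0)
        odf = reconstruct_odf(synth_signal(comps, basis_b3000.scheme), basis_b3000)
        est = std_peaks(odf, grid321, n_samples=500, seed=9)
        assert est.n_fibers == 2

    def test_truncation_to_max_fibers(self, grid321, basis_b3000):
        comps = crossing_compartments(90.0)
        odf = reconstruct_odf(synth_signal(comps, basis_b3000.scheme), basis_b3000)
        est = std_peaks(odf, grid321, max_fibers=1)
        assert est.n_fibers == 1  # the global maximum = major fiber


def test_vmf_and_std_agree_on_well_separated_lobes(grid321, basis_b3000):
    comps = crossing_compartments(80.0)
    odf = reconstruct_odf(synth_signal(comps, basis_b3000.scheme), basis_b3000)
    v = estimate_vmf(odf, grid321, seed=0)
    s = std_peaks(odf, grid321)
    assert v.n_fibers == s.n_fibers == 2
    assert np.all(axial_angle_matrix(v.axes, s.axes).min(axis=1) < 10.0)
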