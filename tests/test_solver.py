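"""Quasistatic solver: analytic cases, conservation, linearity, symmetry."""

import numpy as np
import pytest

from tistim.phantom import (
    Phantom,
    Tissue,
    make_layered_sphere_phantom,
    make_orientation_field,
)
from tistim.solver import (
    build_conductivity_tensors,
    injected_current,
    normalize_to_current,
    region_current,
    solve_electrode_pair,
    surface_current,
)


def _box_phantom(shape, sigma_by_layer, spacing=5.0):
    """Rectangular slab phantom; ``sigma_by_layer`` maps x-index ranges to
    conductivities via a list of (n_layers, sigma)."""
    labels = np.zeros(shape, np.int16)
    table = {}
    x0 = 0
    for lid, (nx, sigma) in enumerate(sigma_by_layer, start=1):
        labels[x0 : x0 + nx] = lid
        table[lid] = Tissue(f"layer{lid}", sigma)
        x0 += nx
    return Phantom(
        labels=labels, spacing=(spacing,) * 3, tissue_table=table, origin=np.zeros(3)
    )


@pytest.fixture(scope="module")
def uniform_cube():
    """sigma = 0.3 S/m; 100 mm between full-face electrode layers;
    cross-section 0.01 m^2. Analytic: E = 10 V/m, I = sigma E A = 30 mA."""
    ph = _box_phantom((22, 20, 20), [(22, 0.3)])
    tens = build_conductivity_tensors(ph)
    anode = np.zeros(ph.shape, bool)
    anode[0] = True
    cathode = np.zeros(ph.shape, bool)
    cathode[-1] = True
    sol = solve_electrode_pair(ph, tens, anode, cathode, 1.0, tolerance=1e-10)
    return ph, tens, sol


class TestTensors:
    def test_axis_aligned_orientation_gives_diagonal_tensor(self):
        p = make_layered_sphere_phantom([40], [0.3], 4.0, names=["gray"])
        p = make_orientation_field(p, "uniform", vector=(1, 0, 0))
        tf = build_conductivity_tensors(p, 0.2, 0.1, anisotropic_labels=[1])
        T = tf.values[p.brain_mask()][0]
        assert np.allclose(T, np.diag([0.2, 0.1, 0.1]))

    def test_equal_long_trans_reduces_to_isotropic(self):
        p = make_layered_sphere_phantom([40], [0.3], 4.0, names=["gray"])
        p = make_orientation_field(p, "radial")
        tf = build_conductivity_tensors(p, 0.3, 0.3, anisotropic_labels=[1])
        assert np.allclose(tf.values[p.brain_mask()], 0.3 * np.eye(3))

    def test_oblique_orientation_eigenstructure(self):
        # eigendecomposition oracle: principal eigenvector parallel to n,
        # eigenvalues {sigma_long, sigma_trans, sigma_trans}
        p = make_layered_sphere_phantom([40], [0.3], 4.0, names=["gray"])
        n = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        p = make_orientation_field(p, "uniform", vector=n)
        tf = build_conductivity_tensors(p, 0.2, 0.1, anisotropic_labels=[1])
        tf.validate()
        w, v = np.linalg.eigh(tf.values[p.brain_mask()][0])
        assert np.allclose(np.sort(w), [0.1, 0.1, 0.2], atol=1e-12)
        assert abs(np.dot(v[:, -1], n)) == pytest.approx(1.0, abs=1e-12)

    def test_missing_orientation_rejected(self):
        p = make_layered_sphere_phantom([40], [0.3], 4.0, names=["gray"])
        with pytest.raises(ValueError):
            build_conductivity_tensors(p, 0.2, 0.1, anisotropic_labels=[1])


class TestAnalyticFields:
    def test_uniform_cube_field_within_1pct(self, uniform_cube):
        _, _, sol = uniform_cube
        E = np.linalg.norm(sol.E[1:-1], axis=-1)
        assert np.all(np.abs(E - 10.0) / 10.0 < 0.01)

    def test_uniform_cube_injected_current_sigma_E_A(self, uniform_cube):
        _, _, sol = uniform_cube
        assert sol.injected_current_mA == pytest.approx(30.0, rel=0.01)

    def test_surface_integral_agrees_with_reaction_current(self, uniform_cube):
        ph, tens, sol = uniform_cube
        region = np.zeros(ph.shape, bool)
        region[:4] = True  # box around the anode layer
        assert surface_current(sol, tens, region) == pytest.approx(
            sol.injected_current_mA, rel=0.01
        )

    def test_two_layer_slab_field_ratio_is_3(self):
        # equal-thickness layers, sigma 0.3 / 0.1: current-density continuity
        # forces E_low = 3 E_high
        ph = _box_phantom((22, 20, 20), [(11, 0.3), (11, 0.1)])
        tens = build_conductivity_tensors(ph)
        anode = np.zeros(ph.shape, bool)
        anode[0] = True
        cathode = np.zeros(ph.shape, bool)
        cathode[-1] = True
        sol = solve_electrode_pair(ph, tens, anode, cathode, 1.0, tolerance=1e-10)
        e_hi = np.linalg.norm(sol.E[2:9], axis=-1).mean()
        e_lo = np.linalg.norm(sol.E[13:20], axis=-1).mean()
        assert e_lo / e_hi == pytest.approx(3.0, rel=0.01)

    def test_slab_exact_across_resolutions(self):
        # grid convergence: the piecewise-linear solution is in the trial
        # space, so refining the grid keeps the field at the analytic value
        for spacing, nx in [(10.0, 11), (5.0, 22)]:
            ph = _box_phantom((nx, 10, 10), [(nx, 0.3)], spacing=spacing)
            tens = build_conductivity_tensors(ph)
            anode = np.zeros(ph.shape, bool)
            anode[0] = True
            cathode = np.zeros(ph.shape, bool)
            cathode[-1] = True
            sol = solve_electrode_pair(ph, tens, anode, cathode, 1.0, tolerance=1e-10)
            E = np.linalg.norm(sol.E[1:-1], axis=-1)
            expected = 1.0 / ((nx - 2) * spacing * 1e-3)
            assert np.allclose(E, expected, rtol=1e-6)


@pytest.fixture(scope="module")
def antipodal_sphere():
    ph = make_layered_sphere_phantom([60], [0.3], 3.0, names=["gray"])
    tens = build_conductivity_tensors(ph)
    centers = ph.voxel_centers()
    r = np.linalg.norm(centers, axis=-1)
    surface = (ph.labels > 0) & (r > 60 - 2 * 3.0)
    anode = surface & (centers[..., 1] > 54)
    cathode = surface & (centers[..., 1] < -54)
    sol = solve_electrode_pair(ph, tens, anode, cathode, 1.0, tolerance=1e-9)
    return ph, tens, anode, cathode, sol


class TestSphere:
    def test_potential_antisymmetric_about_equator(self, antipodal_sphere):
        ph, _, _, _, sol = antipodal_sphere
        phi = sol.phi
        flipped = -phi[:, ::-1, :]
        m = np.isfinite(phi) & np.isfinite(flipped)
        scale = np.nanmax(np.abs(phi))
        assert np.max(np.abs(phi[m] - flipped[m])) / scale < 1e-6

    def test_interior_closed_surface_conserves_current(self, antipodal_sphere):
        ph, tens, _, _, sol = antipodal_sphere
        inj = abs(sol.injected_current_mA)
        region = np.zeros(ph.shape, bool)
        c = ph.shape[0] // 2
        region[c - 5 : c + 5, c - 5 : c + 5, c - 5 : c + 5] = True
        assert abs(region_current(sol, region)) < 0.005 * inj
        assert abs(surface_current(sol, tens, region)) < 0.005 * inj

    def test_reciprocity_swapping_electrodes_negates_potential(self, antipodal_sphere):
        ph, tens, anode, cathode, sol = antipodal_sphere
        swapped = solve_electrode_pair(ph, tens, cathode, anode, 1.0, tolerance=1e-9)
        m = np.isfinite(sol.phi)
        scale = np.nanmax(np.abs(sol.phi))
        assert np.max(np.abs(sol.phi[m] + swapped.phi[m])) / scale < 1e-6
        assert swapped.injected_current_mA == pytest.approx(
            sol.injected_current_mA, rel=1e-6
        )

    def test_voltage_scaling_linearity(self, antipodal_sphere):
        ph, tens, anode, cathode, sol = antipodal_sphere
        sol2 = solve_electrode_pair(ph, tens, anode, cathode, 2.0, tolerance=1e-9)
        m = np.isfinite(sol.phi)
        scale = np.nanmax(np.abs(sol.phi))
        assert np.max(np.abs(sol2.phi[m] - 2 * sol.phi[m])) / scale < 1e-6


class TestNormalization:
    def test_normalize_scales_by_current_ratio(self, uniform_cube):
        _, _, sol = uniform_cube
        norm = normalize_to_current(sol, 1.0)
        factor = 1.0 / sol.injected_current_mA
        m = np.isfinite(sol.phi)
        assert np.allclose(norm.phi[m], sol.phi[m] * factor)
        assert np.allclose(norm.E[~np.isnan(norm.E)], sol.E[~np.isnan(sol.E)] * factor)
        assert norm.injected_current_mA == pytest.approx(1.0)

    def test_normalize_to_measured_current_is_identity(self, uniform_cube):
        _, _, sol = uniform_cube
        same = normalize_to_current(sol, sol.injected_current_mA)
        m = np.isfinite(sol.phi)
        assert np.allclose(same.phi[m], sol.phi[m])

    def test_doubling_target_doubles_fields(self, uniform_cube):
        _, _, sol = uniform_cube
        one = normalize_to_current(sol, 1.0)
        two = normalize_to_current(sol, 2.0)
        m = np.isfinite(one.phi)
        assert np.allclose(two.phi[m], 2 * one.phi[m])

    def test_cathode_current_balances_anode(self, uniform_cube):
        _, _, sol = uniform_cube
        assert injected_current(sol, electrode="cathode") == pytest.approx(
            sol.injected_current_mA, rel=1e-6
        )


class TestErrors:
    def test_disconnected_domain_rejected(self):
        labels = np.zeros((20, 10, 10), np.int16)
        labels[:8] = 1
        labels[12:] = 1  # gap between the two blocks
        ph = Phantom(
            labels=labels,
            spacing=(5.0,) * 3,
            tissue_table={1: Tissue("m", 0.3)},
            origin=np.zeros(3),
        )
        tens = build_conductivity_tensors(ph)
        anode = np.zeros(ph.shape, bool)
        anode[0] = True
        cathode = np.zeros(ph.shape, bool)
        cathode[-1] = True
        with pytest.raises(ValueError):
            solve_electrode_pair(ph, tens, anode, cathode)

    def test_empty_and_overlapping_patches_rejected(self, uniform_cube):
        ph, tens, _ = uniform_cube
        empty = np.zeros(ph.shape, bool)
        full = np.zeros(ph.shape, bool)
        full[0] = True
        with pytest.raises(ValueError):
            solve_electrode_pair(ph, tens, empty, full)
        with pytest.raises(ValueError):
            solve_electrode_pair(ph, tens, full, full)

    def test_surface_enclosing_both_electrodes_rejected(self, uniform_cube):
        ph, _, sol = uniform_cube
        region = np.ones(ph.shape, bool)
        with pytest.raises(ValueError):
            region_current(sol, region)
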