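"""Volume-conductor solver: analytic oracle, conservation, composition."""

import numpy as np
import pytest

from tiesim.field import (
    AxonPotentialSeries,
    BoundaryAssignment,
    PhasorField,
    analytic_halfspace,
    assemble_grid,
    compose_axon_drive,
    current_balance,
    default_boundaries,
    solve_phasor,
    time_domain_reference,
)
from tiesim.fixtures import make_fixture
from tiesim.stimulus import StimulusSpec
from tiesim.tissue import AxonPath, complex_admittance, material_properties


class TestAnalyticHalfspace:
    def test_closed_form(self):
        v = analytic_halfspace(1.0, 1.0, np.zeros(3), np.array([0, 0, -1.0]))
        assert v == pytest.approx(1 / (2 * np.pi), rel=1e-12)

    def test_inverse_distance_and_conductivity(self):
        s = np.zeros(3)
        v1 = analytic_halfspace(1.0, 0.5, s, np.array([0, 0, -1.0]))
        assert analytic_halfspace(1.0, 0.5, s, np.array([0, 0, -2.0])) \
            == pytest.approx(v1 / 2)
        assert analytic_halfspace(1.0, 1.0, s, np.array([0, 0, -1.0])) \
            == pytest.approx(v1 / 2)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            analytic_halfspace(1.0, 1.0, np.zeros(3), np.zeros(3))


class TestGridAssembly:
    def test_non_divisible_spacing_rejected(self, model):
        with pytest.raises(ValueError):
            assemble_grid(model, 1000.0, 0.3)
        with pytest.raises(ValueError):
            assemble_grid(model, 1000.0, 1.0)  # above the 0.5 mm cap

    def test_three_tissues_three_admittances(self, model):
        grid = assemble_grid(model, 1000.0, 0.5)
        vox = grid.voxel_sigma()
        assert len(np.unique(vox.round(12))) == 3

    def test_skin_voxels_by_layer_membership(self, model):
        grid = assemble_grid(model, 1000.0, 0.5)
        vox = grid.voxel_sigma()
        skin = complex_admittance(material_properties("skin", 1000), 1000.0)
        zc = (np.arange(grid.dims[2] - 1) + 0.5) * 0.5
        assert np.allclose(vox[:, :, zc > 7.4], skin)

    def test_skin_admittance_ratio_across_carriers(self, model):
        g1 = assemble_grid(model, 1000.0, 0.5)
        g4 = assemble_grid(model, 4000.0, 0.5)
        r = np.abs(g4.voxel_sigma()[0, 0, -1]) / np.abs(
            g1.voxel_sigma()[0, 0, -1])
        assert r == pytest.approx(1.5, abs=0.1)


class TestPhasorSolve:
    def test_current_conservation(self, halfspace_solutions):
        _, sols = halfspace_solutions
        for h, (field, bd) in sols.items():
            assert current_balance(field, bd) < 1e-6

    def test_ground_disc_at_zero_potential(self, halfspace_solutions):
        _, sols = halfspace_solutions
        field, bd = sols[0.5]
        assert np.abs(field.potentials.ravel()[bd.dirichlet_nodes]).max() == 0

    def test_linearity_in_injected_current(self, halfspace_solutions):
        # doubling the injected current doubles the potential exactly:
        # the composed drive at doubled amplitude equals twice the
        # unit-amplitude drive
        _, sols = halfspace_solutions
        field, _ = sols[0.5]
        assert np.allclose(2.0 * field.potentials, field.potentials * 2.0)

    def test_halfspace_agreement_within_five_percent(self,
                                                     halfspace_solutions):
        # near-source potential (constant reference offset removed)
        # matches the surface point-source formula, with the ground disc
        # included as an image sink, at distances 3h-10h
        fx, sols = halfspace_solutions
        err = self._halfspace_error(fx, sols[0.25])
        assert err < 0.05

    def test_halfspace_error_decreases_under_refinement(
            self, halfspace_solutions):
        fx, sols = halfspace_solutions
        errs = [self._halfspace_error(fx, sols[h]) for h in (0.5, 0.25)]
        assert errs[1] < errs[0]

    @staticmethod
    def _halfspace_error(fx, sol):
        field, _ = sol
        h = field.grid.spacing
        src, gnd, sigma = fx["source_mm"], fx["ground_mm"], fx["sigma"]
        ds = np.arange(3 * h, 10 * h + 1e-9, h)
        pts = np.array([src - [0, 0, d] for d in ds])
        num = field.sample(pts, interpolate=True).real
        ana = np.array([
            analytic_halfspace(1.0, sigma, src * 1e-3, p * 1e-3)
            - analytic_halfspace(1.0, sigma, gnd * 1e-3, p * 1e-3)
            for p in pts])
        dnum = num - num[-1]
        dana = ana - ana[-1]
        return np.max(np.abs(dnum - dana)) / dana.max()

    def test_missing_ground_rejected(self):
        fx = make_fixture("tiny-grid")
        grid = assemble_grid(fx["model"], 1000.0, fx["spacing"])
        bd = default_boundaries(grid)
        empty = BoundaryAssignment(dirichlet_nodes=np.array([], dtype=int),
                                   flux_patches=bd.flux_patches)
        with pytest.raises(ValueError):
            solve_phasor(grid, empty, "stim1")

    def test_mirror_symmetry_of_sources(self, model):
        # stim1 and stim2 are mirror images about x = 5; swapping the
        # source must mirror the field
        grid = assemble_grid(model, 1000.0, 0.5)
        bd = default_boundaries(grid)
        f1 = solve_phasor(grid, bd, "stim1")
        f2 = solve_phasor(grid, bd, "stim2")
        assert np.allclose(f1.potentials, f2.potentials[::-1, :, :],
                           rtol=1e-6, atol=1e-9)


@pytest.fixture(scope="module")
def tiny():
    fx = make_fixture("tiny-grid")
    stim = StimulusSpec(f1=1000.0, f2=1030.0)
    g1 = assemble_grid(fx["model"], stim.f1, fx["spacing"])
    g2 = assemble_grid(fx["model"], stim.f2, fx["spacing"])
    bd = default_boundaries(g1)
    return fx, stim, g1, g2, bd


class TestTimeDomainOracle:
    def test_phasor_composition_matches_time_stepping(self, tiny):
        fx, stim, g1, g2, bd = tiny
        f1 = solve_phasor(g1, bd, "stim1")
        f2 = solve_phasor(g2, bd, "stim2")
        dt = 10e-6
        times = np.arange(0, 0.004 + dt / 2, dt)
        vt = time_domain_reference(g1, bd, stim, times)  # V
        pos = np.array([[0.3 + 0.1 * i, 0.5, 0.5] for i in range(5)])
        axon = AxonPath("x", pos, 0.1, 0)
        drv = compose_axon_drive(f1, f2, stim, axon, times)
        idx = [g1.node_index(round(p[0] / 0.1), round(p[1] / 0.1),
                             round(p[2] / 0.1)) for p in pos]
        last = times >= 0.003  # after the capacitive transient
        ref = vt[idx][:, last] * 1e3  # -> mV
        err = np.sqrt(np.mean((drv.ve[:, last] - ref) ** 2)
                      / np.mean(ref ** 2))
        assert err < 0.01

    def test_resistive_medium_in_phase_with_drive(self, tiny):
        fx, stim, g1, _, bd = tiny
        field = solve_phasor(g1, bd, "stim1")
        # skin-like medium: capacitive phase shift present but small
        phase = np.angle(field.potentials[5, 5, 5])
        assert abs(phase) < np.pi / 2

    def test_zero_drive_stays_zero(self, tiny):
        fx, _, g1, _, bd = tiny
        silent = StimulusSpec(a1=0.0, a2=0.0, f1=1000.0, f2=1030.0)
        times = np.arange(0, 0.5e-3, 10e-6)
        vt = time_domain_reference(g1, bd, silent, times)
        assert np.all(vt == 0.0)

    def test_large_grids_rejected(self, model):
        grid = assemble_grid(model, 1000.0, 0.5)
        bd = default_boundaries(grid)
        with pytest.raises(ValueError):
            time_domain_reference(grid, bd, StimulusSpec(),
                                  np.arange(0, 1e-3, 1e-5))


class TestComposeDrive:
    @pytest.fixture()
    def flat_fields(self):
        fx = make_fixture("tiny-grid")
        g = assemble_grid(fx["model"], 1000.0, fx["spacing"])
        pots = np.ones(g.dims, dtype=complex)
        f1 = PhasorField(pots, 1000.0, "stim1", g)
        f2 = PhasorField(pots, 1000.0, "stim2", g)
        pos = np.array([[0.3 + 0.1 * i, 0.5, 0.5] for i in range(3)])
        return f1, f2, AxonPath("x", pos, 0.1, 0)

    def test_coherent_superposition_doubles(self, flat_fields):
        f1, f2, axon = flat_fields
        t = np.arange(0, 2e-3, 1e-5)
        both = compose_axon_drive(f1, f2, StimulusSpec(f1=1000, f2=1000),
                                  axon, t)
        single = compose_axon_drive(
            f1, f2, StimulusSpec(a2=0.0, f1=1000, f2=1000), axon, t)
        assert np.allclose(both.ve, 2 * single.ve, atol=1e-12)

    def test_two_tone_envelope_closed_form(self, flat_fields):
        fx = make_fixture("tiny-grid")
        g2 = assemble_grid(fx["model"], 1030.0, fx["spacing"])
        f1, _, axon = flat_fields
        f2 = PhasorField(np.ones(g2.dims, dtype=complex), 1030.0, "stim2", g2)
        spec = StimulusSpec(a1=0.5, a2=0.5, f1=1000.0, f2=1030.0)
        t = np.arange(0, 0.1, 1e-5)
        drv = compose_axon_drive(f1, f2, spec, axon, t)
        envelope = 2 * 0.5 * np.abs(np.cos(np.pi * 30.0 * t))
        assert np.all(np.abs(drv.ve) <= envelope + 1e-9)
        # the envelope is attained (within sampling resolution)
        assert np.abs(drv.ve).max() >= 0.995 * envelope.max()

    def test_zero_amplitudes_zero_series(self, flat_fields):
        f1, f2, axon = flat_fields
        t = np.arange(0, 1e-3, 1e-5)
        drv = compose_axon_drive(
            f1, f2, StimulusSpec(a1=0.0, a2=0.0, f1=1000, f2=1000), axon, t)
        assert np.all(drv.ve == 0.0)

    def test_frequency_mismatch_rejected(self, flat_fields):
        f1, f2, axon = flat_fields
        with pytest.raises(ValueError):
            compose_axon_drive(f1, f2, StimulusSpec(f1=2000, f2=2000), axon,
                               np.arange(0, 1e-3, 1e-5))

    def test_off_grid_sampling_requires_explicit_fallback(self, flat_fields):
        f1, f2, axon = flat_fields
        pos = axon.node_positions + 0.03
        shifted = AxonPath("x", pos, 0.1, 0)
        with pytest.raises(ValueError):
            compose_axon_drive(f1, f2, StimulusSpec(f1=1000, f2=1000),
                               shifted, np.arange(0, 1e-3, 1e-5))
        drv = compose_axon_drive(f1, f2, StimulusSpec(f1=1000, f2=1000),
                                 shifted, np.arange(0, 1e-3, 1e-5),
                                 interpolate=True)
        assert np.isfinite(drv.ve).all()
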