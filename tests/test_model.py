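"""Force field and Langevin integrator.

Pair forces are checked against numerical differentiation of the pair
potential; diffusion against the Einstein relation; non-crossing against
knot conservation; temperature against equipartition.
"""

import io

import numpy as np
import pytest

from loopex.model import (
    ChainSystem,
    ForceField,
    IntegratorParams,
    ModelError,
    WCA_CUTOFF,
    build_ring,
    compute_forces,
    read_xyz,
    step_langevin,
    write_xyz,
)
from loopex.topology import identify_knot
from loopex.configs import torus_knot_coords


def two_bead_system(r, phantom_first=False):
    s = ChainSystem()
    s.positions = np.array([[0.0, 0, 0], [r, 0, 0]])
    s.velocities = np.zeros((2, 3))
    s.ring_index = np.array([0, 1])
    s.phantom_flag = np.array([phantom_first, False])
    s.ctcf_flag = np.zeros(2, bool)
    return s


class TestBuildRing:
    @pytest.mark.parametrize("n", [3, 133, 4000])
    def test_bead_and_bond_counts(self, n):
        s = build_ring(n)
        assert s.n_beads == n
        assert len(s.bonds) == n  # closed cycle: one bond per bead
        assert not s.phantom_flag.any() and not s.ctcf_flag.any()
        s.validate()

    def test_too_small_ring_rejected(self):
        with pytest.raises(ModelError):
            build_ring(2)


class TestPairForces:
    def test_zero_at_cutoff(self):
        F = compute_forces(two_bead_system(WCA_CUTOFF), ForceField())
        assert np.allclose(F, 0.0)

    def test_repulsive_24_at_contact(self):
        F = compute_forces(two_bead_system(1.0), ForceField())
        assert F[0, 0] == pytest.approx(-24.0)  # pushed apart
        assert np.allclose(F[0], -F[1])  # equal and opposite

    def test_matches_numerical_gradient(self):
        def wca(r):
            if r >= WCA_CUTOFF:
                return 0.0
            return 4 * ((1 / r) ** 12 - (1 / r) ** 6) + 1

        h = 1e-6
        for r in (0.9, 1.0, 1.05, 1.11):
            expected = -(wca(r + h) - wca(r - h)) / (2 * h)
            F = compute_forces(two_bead_system(r), ForceField())
            assert F[1, 0] == pytest.approx(expected, rel=1e-5)

    def test_phantom_pair_ignored(self):
        F = compute_forces(two_bead_system(1.0, phantom_first=True), ForceField())
        assert np.allclose(F, 0.0)

    def test_clash_is_warning_not_crash(self, caplog):
        import logging

        s = two_bead_system(1e-8)
        with caplog.at_level(logging.WARNING, logger="loopex"):
            F = compute_forces(s, ForceField())
        assert np.all(np.isfinite(F))
        assert any("clash" in r.message for r in caplog.records)


class TestIntegrator:
    def test_zero_steps_is_noop(self):
        s = build_ring(20)
        p0 = s.positions.copy()
        step_langevin(s, ForceField(), IntegratorParams(seed=1), 0)
        assert np.array_equal(s.positions, p0)

    def test_negative_steps_rejected(self):
        with pytest.raises(ModelError):
            step_langevin(build_ring(20), ForceField(), IntegratorParams(), -1)

    def test_deterministic(self):
        runs = []
        for _ in range(2):
            s = build_ring(40)
            step_langevin(s, ForceField(), IntegratorParams(seed=7), 2000)
            runs.append(s.positions)
        assert np.array_equal(runs[0], runs[1])

    def test_einstein_relation(self):
        """Free-bead MSD = 6 D t with D = kBT / (m gamma), within 20%."""
        gamma, t_steps, dt = 5.0, 100_000, 0.01
        msds = []
        for seed in range(8):
            s = ChainSystem()
            # four independent phantom beads per seed (no interactions)
            s.positions = np.array([[100.0 * k, 0, 0] for k in range(4)])
            s.velocities = np.zeros((4, 3))
            s.ring_index = np.arange(4)
            s.phantom_flag = np.ones(4, bool)
            s.ctcf_flag = np.zeros(4, bool)
            p0 = s.positions.copy()
            step_langevin(s, ForceField(), IntegratorParams(seed=seed, gamma=gamma), t_steps)
            msds.extend(np.sum((s.positions - p0) ** 2, axis=1))
        expected = 6.0 * (1.0 / gamma) * t_steps * dt
        assert np.mean(msds) == pytest.approx(expected, rel=0.20)

    def test_temperature_equipartition(self):
        s = build_ring(133)
        step_langevin(s, ForceField(), IntegratorParams(seed=2), 120_000)
        assert s.meta["last_ke_per_dof"] == pytest.approx(0.5, rel=0.05)

    def test_confinement_holds(self):
        s = build_ring(60)
        s.sphere_radius = 6.0
        step_langevin(s, ForceField(), IntegratorParams(seed=3), 50_000)
        assert np.linalg.norm(s.positions, axis=1).max() < 6.5
        s.validate()

    def test_integration_blowup_reported(self):
        """Diverging coordinates raise a blow-up error instead of silently
        producing non-finite positions."""
        from loopex.model import IntegrationBlowup

        s = two_bead_system(5.0)
        s.add_bond(0, 1, 1, 1e12, 1.0)  # absurd stiffness: overflow by design
        with pytest.raises(IntegrationBlowup, match="step"):
            step_langevin(s, ForceField(), IntegratorParams(seed=0, v_cap=0.0), 3000)

    def test_knot_conserved_quick(self):
        """Self-avoiding dynamics cannot change the knot type (short check;
        the long 5-seed x 1e6-step version runs in the acceptance suite)."""
        s = ChainSystem()
        s.add_ring(torus_knot_coords(2, 3, 133).vertices)
        step_langevin(s, ForceField(), IntegratorParams(seed=11), 200_000)
        assert identify_knot(s.curve(0)).name == "3_1"


class TestXYZ:
    def test_roundtrip(self, tmp_path):
        s = build_ring(10)
        s2 = build_ring(7)
        s.add_ring(s2.positions + 20.0)
        path = tmp_path / "t.xyz"
        with open(path, "w") as fh:
            write_xyz(fh, s, comment="frame 0")
            s.positions += 1.0
            write_xyz(fh, s, comment="frame 1")
        frames = read_xyz(path)
        assert len(frames) == 2
        rings, pos = frames[1]
        assert pos.shape == (17, 3)
        assert list(np.unique(rings)) == [0, 1]
        assert np.allclose(pos, s.positions, atol=1e-5)
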