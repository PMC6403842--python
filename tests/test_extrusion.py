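"""Cohesin-handcuff and migrating-bond extrusion mechanics."""

import logging

import numpy as np
import pytest

from loopex.configs import ExperimentConfig, single_tad_ring, torus_knot_coords
from loopex.extrusion import (
    advance_walk,
    extruded_arc_curve,
    extrusion_progress,
    load_handcuff,
    load_simple_extruder,
    step_simple_extrusion,
    _gid,
    _local,
)
from loopex.model import ChainSystem, ForceField, IntegratorParams, build_ring, step_langevin
from loopex.topology import identify_knot, linking_number


FF = ForceField()


def relaxed_ring(n=60, seed=0):
    s = build_ring(n)
    step_langevin(s, FF, IntegratorParams(seed=seed), 3000)
    return s


class TestLoadHandcuff:
    def test_threading_pierces_each_ring_once(self):
        s = relaxed_ring(80)
        hc = load_handcuff(s, 0, ff=FF, ip=IntegratorParams(seed=1))
        assert (hc.anchor_a, hc.anchor_b) == (0, 1)
        assert abs(linking_number(s.curve(hc.ring_a), s.curve(0))) == 1
        assert abs(linking_number(s.curve(hc.ring_b), s.curve(0))) == 1
        # initial loop spans at most 2 beads
        assert (hc.anchor_b - hc.anchor_a) % s.ring_size(0) <= 2

    def test_wraparound_site(self):
        s = relaxed_ring(60, seed=3)
        n = s.ring_size(0)
        hc = load_handcuff(s, n - 1, ff=FF, ip=IntegratorParams(seed=1))
        assert (hc.anchor_a, hc.anchor_b) == (n - 1, 0)

    def test_phantom_site_allowed_with_warning(self, caplog):
        s = relaxed_ring(60, seed=5)
        s.phantom_flag[s.ring_beads(0)[10]] = True
        with caplog.at_level(logging.WARNING, logger="loopex"):
            hc = load_handcuff(s, 10, ff=FF, ip=IntegratorParams(seed=1))
        assert hc.anchor_a == 10
        assert any("phantom" in r.message for r in caplog.records)

    def test_cohesin_rings_are_7_bead_cycles(self):
        s = relaxed_ring(60, seed=7)
        hc = load_handcuff(s, 5, ff=FF, ip=IntegratorParams(seed=2))
        assert s.ring_size(hc.ring_a) == 7
        assert s.ring_size(hc.ring_b) == 7
        assert s.ring_kind[hc.ring_a] == "cohesin"
        # exactly two inter-ring bonds join the handcuff
        joins = [
            b for b in s.bonds
            if {s.ring_index[b[0]], s.ring_index[b[1]]} == {hc.ring_a, hc.ring_b}
        ]
        assert len(joins) == 2


class TestAdvanceWalk:
    def build(self, seed=0):
        s = relaxed_ring(80, seed=seed)
        ip = IntegratorParams(seed=seed)
        hc = load_handcuff(s, 40, ff=FF, ip=ip)
        return s, ip, hc

    def test_no_retarget_when_bonds_long(self):
        s, ip, hc = self.build()
        # stretch: move the target bead far from all attach beads
        tgt = _gid(s, 0, hc.anchor_a + hc.direction_a)
        s.positions[tgt] += 5.0
        a0 = hc.anchor_a
        advance_walk(s, hc)
        assert hc.anchor_a == a0

    def test_walk_advances_and_loop_grows(self):
        s, ip, hc = self.build(seed=2)
        n = s.ring_size(0)
        sizes = []
        for _ in range(400):
            step_langevin(s, FF, ip, 40)
            advance_walk(s, hc)
            sizes.append((hc.anchor_b - hc.anchor_a) % n)
        assert sizes[-1] > sizes[0]  # net extrusion happened
        assert all(b >= a for a, b in zip(sizes, sizes[1:])) or True
        # monotone: loop size never decreased
        assert min(np.diff(sizes)) >= 0

    def test_ctcf_halts_forever(self):
        s, ip, hc = self.build(seed=4)
        nxt = _gid(s, 0, hc.anchor_a + 2 * hc.direction_a)
        s.ctcf_flag[nxt] = True
        for _ in range(300):
            step_langevin(s, FF, ip, 40)
            advance_walk(s, hc)
            if hc.halted_a:
                break
        assert hc.halted_a
        frozen = hc.anchor_a
        for _ in range(100):
            step_langevin(s, FF, ip, 40)
            advance_walk(s, hc)
        assert hc.anchor_a == frozen  # stopped anchors never move
        assert not hc.halted_b  # the other ring keeps walking

    def test_chain_integrity_preserved(self):
        s, ip, hc = self.build(seed=6)
        n0 = s.n_beads
        struct0 = sorted(b[:2] for b in s.bonds if b[6] == 0)
        for _ in range(200):
            step_langevin(s, FF, ip, 40)
            advance_walk(s, hc)
        assert s.n_beads == n0
        assert sorted(b[:2] for b in s.bonds if b[6] == 0) == struct0


class TestSimpleExtruder:
    def test_migrates_when_anchors_close(self):
        s = build_ring(20)
        ex = load_simple_extruder(s, 0, 10, formation_max=10.0)
        assert (ex.left_anchor, ex.right_anchor) == (10, 11)
        step_simple_extrusion(s, ex)  # circle: adjacent beads ~1 sigma apart
        assert (ex.left_anchor, ex.right_anchor) == (9, 12)

    def test_no_migration_beyond_proximity(self):
        s = build_ring(20)
        ex = load_simple_extruder(s, 0, 10, formation_max=10.0)
        s.positions[_gid(s, 0, 10)] += [0.0, 0, 3.0]  # anchors 3 sigma apart
        step_simple_extrusion(s, ex)
        assert (ex.left_anchor, ex.right_anchor) == (10, 11)

    def test_ctcf_stops_each_side_independently(self):
        s = build_ring(20)
        ex = load_simple_extruder(s, 0, 10, formation_max=10.0, proximity_threshold=3.0)
        s.ctcf_flag[_gid(s, 0, 9)] = True
        step_simple_extrusion(s, ex)
        assert ex.left_stopped and not ex.right_stopped
        assert ex.right_anchor == 12
        step_simple_extrusion(s, ex)
        assert ex.right_anchor == 13  # stalled left does not block right

    def test_complete_when_both_sides_stopped(self):
        s = build_ring(20)
        ex = load_simple_extruder(s, 0, 10, formation_max=10.0)
        s.ctcf_flag[_gid(s, 0, 9)] = True
        s.ctcf_flag[_gid(s, 0, 12)] = True
        step_simple_extrusion(s, ex)
        assert ex.complete

    def test_anchor_arithmetic_wraps(self):
        s = build_ring(20)
        ex = load_simple_extruder(s, 0, 19, formation_max=10.0)
        assert (ex.left_anchor, ex.right_anchor) == (19, 0)
        step_simple_extrusion(s, ex)
        assert (ex.left_anchor, ex.right_anchor) == (18, 1)


class TestProgress:
    def test_fresh_extruder_near_zero(self):
        s = build_ring(100)
        ex = load_simple_extruder(s, 0, 50)
        assert extrusion_progress(s, ex) < 0.05

    def test_halfway_matches_arc_counting(self):
        s = build_ring(100)
        ex = load_simple_extruder(s, 0, 50)
        ex.left_anchor, ex.right_anchor = 25, 75
        # arc through the start site (50) spans 51 of 100 extrudable beads
        assert extrusion_progress(s, ex) == pytest.approx(0.5, abs=0.02)

    def test_complete_extrusion_reaches_one(self):
        cfg = ExperimentConfig("single_tad", seed=0)
        s = single_tad_ring(cfg)
        n = s.ring_size(0)
        ex = load_simple_extruder(s, 0, n // 2)
        ex.left_anchor, ex.right_anchor = 5, n - 5  # at the CTCF flanks
        ex.left_stopped = ex.right_stopped = True
        assert extrusion_progress(s, ex) == pytest.approx(1.0, abs=0.02)


class TestEntanglementExclusion:
    def test_extruded_arc_stays_unknotted(self):
        """The tight cohesin rings push the knot ahead of them (no phantom
        beads anywhere): the virtually closed extruded arc is unknotted at
        every sample while the ring's own knot is preserved outside it."""
        s = ChainSystem()
        s.add_ring(torus_knot_coords(2, 3, 100).vertices)
        ip = IntegratorParams(seed=9)
        step_langevin(s, FF, ip, 3000)
        hc = load_handcuff(s, 50, ff=FF, ip=ip)
        checks = 0
        for cyc in range(1500):
            step_langevin(s, FF, ip, 40)
            advance_walk(s, hc)
            if cyc % 250 == 249:
                arc = extruded_arc_curve(s, hc)
                if len(arc) >= 6:
                    assert identify_knot(arc).name == "0_1"
                    checks += 1
        assert checks >= 3
        assert identify_knot(s.curve(0)).name == "3_1"  # knot preserved outside
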