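"""Loop-extrusion mechanisms: cohesin handcuffs and migrating strong bonds.

Two mechanisms grow a chromatin loop until they stall at CTCF stop beads:

* :class:`CohesinHandcuff` - an explicit pair of small 7-bead rings threaded
  around the fibre and joined by two bonds.  Each ring advances by a walking
  scheme: three strong springs (K = 20 kBT/sigma^2, rest length 1 sigma)
  connect nonconsecutive ring beads to the chromatin bead one position ahead
  of the embraced bead; once the springs have shrunk to about their rest
  length they are re-formed one bead further along (formation length up to
  2 sigma).  The tight ring aperture admits a single fibre strand, so
  entanglements are pushed ahead of the advancing rings rather than passing
  into the extruded loop.

* :class:`SimpleExtruder` - the reduced mechanism for large systems: one
  strong spring bond (K = 100 kBT/sigma^2, rest length 1 sigma) between the
  two loop anchors; whenever the anchors sit close together the bond
  migrates outward by one bead on each non-stalled side, enlarging the loop.

Anchors never retreat, a stalled side never blocks the other, and neither
mechanism ever alters the chromatin bond topology or bead count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    BOND_HARMONIC,
    ChainSystem,
    ForceField,
    IntegratorParams,
    logger,
    step_langevin,
)
from .topology import ClosedCurve, linking_number

__all__ = [
    "CohesinHandcuff",
    "SimpleExtruder",
    "PlacementError",
    "load_handcuff",
    "advance_walk",
    "load_simple_extruder",
    "step_simple_extrusion",
    "extrusion_progress",
    "extruded_arc_curve",
]

COHESIN_RING_BEADS = 7
# circumradius of a regular 7-gon with unit side; the resulting aperture
# (~0.65 sigma) admits exactly one fibre strand
_RING_RADIUS = 0.5 / np.sin(np.pi / COHESIN_RING_BEADS)
WALK_ATTACH = (0, 2, 4)  # nonconsecutive beads of a 7-ring carrying walk bonds


class PlacementError(RuntimeError):
    pass


@dataclass
class CohesinHandcuff:
    """Two joined 7-bead cohesin rings embracing a chromatin ring.

    Anchors are local bead indices on the chromatin ring; ring A walks in
    ``direction_a`` (toward decreasing indices by default), ring B the other
    way, so the loop spanned between them through the start site only grows.
    """

    chromatin_ring: int
    ring_a: int  # system ring id of cohesin ring A
    ring_b: int
    anchor_a: int
    anchor_b: int
    direction_a: int = -1
    direction_b: int = 1
    halted_a: bool = False
    halted_b: bool = False
    replace_threshold: float = 1.1
    formation_max: float = 2.0
    walk_k: float = 20.0
    tag_a: int = 0
    tag_b: int = 0
    start_site: int = 0
    stalls: int = 0

    @property
    def complete(self) -> bool:
        return self.halted_a and self.halted_b


@dataclass
class SimpleExtruder:
    """A migrating strong-bond extruder acting on one chromatin ring."""

    ring_id: int
    left_anchor: int  # local indices; the loop is the arc left -> right
    right_anchor: int  # through the start site
    left_stopped: bool = False
    right_stopped: bool = False
    spring_k: float = 100.0
    proximity_threshold: float = 1.2
    formation_max: float = 2.5
    stop_at_phantom: bool = True
    tag: int = 0
    start_site: int = 0
    stalls: int = 0

    @property
    def complete(self) -> bool:
        return self.left_stopped and self.right_stopped


def _local(system: ChainSystem, rid: int, idx: int) -> int:
    return int(idx) % system.ring_size(rid)


def _gid(system: ChainSystem, rid: int, idx: int) -> int:
    lo, _ = system._ring_range[rid]
    return lo + _local(system, rid, idx)


def _next_tag(system: ChainSystem) -> int:
    tag = system.meta.get("next_extruder_tag", 100)
    system.meta["next_extruder_tag"] = tag + 1
    return tag


# ---------------------------------------------------------------------------
# cohesin handcuff
# ---------------------------------------------------------------------------


def _set_walk_bonds(system, hc, cohesin_rid, tag, target_local):
    system.remove_bonds(tag)
    beads = system.ring_beads(cohesin_rid)
    tgt = _gid(system, hc.chromatin_ring, target_local)
    for m in WALK_ATTACH:
        system.add_bond(int(beads[m]), tgt, BOND_HARMONIC, hc.walk_k, 1.0, tag=tag)


def _walk_lengths(system, hc, cohesin_rid, target_local):
    beads = system.ring_beads(cohesin_rid)
    tgt = system.positions[_gid(system, hc.chromatin_ring, target_local)]
    return np.array(
        [np.linalg.norm(system.positions[beads[m]] - tgt) for m in WALK_ATTACH]
    )


def _cohesin_ring_coords(centre, tangent, phase):
    t = tangent / np.linalg.norm(tangent)
    a = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(t, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(t, e1)
    phis = 2 * np.pi * np.arange(COHESIN_RING_BEADS) / COHESIN_RING_BEADS + phase
    return centre + _RING_RADIUS * (
        np.cos(phis)[:, None] * e1 + np.sin(phis)[:, None] * e2
    )


def load_handcuff(
    system: ChainSystem,
    site: int,
    ring: int | None = None,
    ff: ForceField | None = None,
    ip: IntegratorParams | None = None,
    relax_steps: int = 600,
    max_attempts: int = 6,
) -> CohesinHandcuff:
    """Thread a cohesin handcuff around the fibre at beads ``site``/``site+1``.

    Each 7-bead ring is built in the plane normal to the local fibre tangent,
    centred on the embraced bead, so the fibre pierces it exactly once; a
    short force-capped relaxation removes construction overlaps, after which
    the threading is verified geometrically (|Lk| = 1 between each cohesin
    ring and the chromatin ring).  Loading on a phantom bead is allowed (the
    flags are independent) but logged.
    """
    ff = ff or ForceField()
    ip = ip or IntegratorParams()
    if ring is None:
        ring = system.chromatin_rings()[0]
    n = system.ring_size(ring)
    site = _local(system, ring, site)
    site_b = _local(system, ring, site + 1)
    if system.phantom_flag[_gid(system, ring, site)]:
        logger.warning("loading handcuff on a phantom bead (site %d)", site)

    chrom_curve_before = system.curve(ring)
    for attempt in range(max_attempts):
        phase = 2 * np.pi * attempt / max_attempts
        trial = system.copy()
        pos = trial.positions

        def tangent_at(local):
            p_prev = pos[_gid(trial, ring, local - 1)]
            p_next = pos[_gid(trial, ring, local + 1)]
            return p_next - p_prev

        coords_a = _cohesin_ring_coords(
            pos[_gid(trial, ring, site)], tangent_at(site), phase
        )
        coords_b = _cohesin_ring_coords(
            pos[_gid(trial, ring, site_b)], tangent_at(site_b), phase
        )
        rid_a = trial.add_ring(coords_a, kind="cohesin")
        rid_b = trial.add_ring(coords_b, kind="cohesin")
        beads_a = trial.ring_beads(rid_a)
        beads_b = trial.ring_beads(rid_b)
        # join the rings: two bonds between two neighbouring beads of each ring
        pair = min(
            range(COHESIN_RING_BEADS),
            key=lambda m: np.linalg.norm(
                trial.positions[beads_a[m]] - trial.positions[beads_b[m]]
            ),
        )
        pair2 = (pair + 1) % COHESIN_RING_BEADS
        trial.add_bond(int(beads_a[pair]), int(beads_b[pair]), BOND_HARMONIC, 30.0, 1.0)
        trial.add_bond(int(beads_a[pair2]), int(beads_b[pair2]), BOND_HARMONIC, 30.0, 1.0)

        hc = CohesinHandcuff(
            chromatin_ring=ring,
            ring_a=rid_a,
            ring_b=rid_b,
            anchor_a=site,
            anchor_b=site_b,
            tag_a=_next_tag(trial),
            tag_b=_next_tag(trial),
            start_site=site,
        )
        _set_walk_bonds(trial, hc, rid_a, hc.tag_a, site + hc.direction_a)
        _set_walk_bonds(trial, hc, rid_b, hc.tag_b, site_b + hc.direction_b)

        # capped push-off, then free relaxation
        soft = IntegratorParams(
            dt=ip.dt, gamma=ip.gamma, temperature=ip.temperature,
            seed=ip.seed + attempt, force_cap=50.0,
        )
        step_langevin(trial, ff, soft, relax_steps)
        step_langevin(trial, ff, ip, relax_steps)

        lk_a = abs(linking_number(trial.curve(rid_a), trial.curve(ring)))
        lk_b = abs(linking_number(trial.curve(rid_b), trial.curve(ring)))
        min_sep = _min_separation(trial)
        if lk_a == 1 and lk_b == 1 and min_sep > 0.6:
            # commit the trial state back into the caller's system
            system.__dict__.update(trial.__dict__)
            return hc
        logger.warning(
            "handcuff placement attempt %d failed (Lk_a=%d Lk_b=%d min_sep=%.2f)",
            attempt, lk_a, lk_b, min_sep,
        )
    raise PlacementError(f"could not thread handcuff at site {site}")


def _min_separation(system: ChainSystem) -> float:
    from scipy.spatial import cKDTree

    active = ~system.phantom_flag
    pos = system.positions[active]
    if len(pos) < 2:
        return np.inf
    d, _ = cKDTree(pos).query(pos, k=2)
    return float(d[:, 1].min())


def advance_walk(system: ChainSystem, hc: CohesinHandcuff) -> CohesinHandcuff:
    """One walking cycle for each cohesin ring of the handcuff.

    A ring advances when all three of its walk bonds have shrunk to the
    replace threshold: the bonds are re-formed one chromatin bead further
    along its direction and the anchor moves by one.  A ring whose next bead
    carries the CTCF flag halts permanently; a new target further than the
    formation length away postpones the cycle (stall).  Rings advance
    independently, so one side stopping never blocks the other.
    """
    n = system.ring_size(hc.chromatin_ring)
    for which in ("a", "b"):
        halted = getattr(hc, f"halted_{which}")
        if halted:
            continue
        anchor = getattr(hc, f"anchor_{which}")
        direction = getattr(hc, f"direction_{which}")
        rid = hc.ring_a if which == "a" else hc.ring_b
        tag = hc.tag_a if which == "a" else hc.tag_b
        target = _local(system, hc.chromatin_ring, anchor + direction)
        lengths = _walk_lengths(system, hc, rid, target)
        if np.any(lengths > hc.replace_threshold):
            continue
        new_anchor = target
        new_target = _local(system, hc.chromatin_ring, anchor + 2 * direction)
        if system.ctcf_flag[_gid(system, hc.chromatin_ring, new_target)]:
            setattr(hc, f"halted_{which}", True)
            setattr(hc, f"anchor_{which}", new_anchor)
            continue
        other_anchor = hc.anchor_b if which == "a" else hc.anchor_a
        if new_target == other_anchor:
            hc.halted_a = hc.halted_b = True
            setattr(hc, f"anchor_{which}", new_anchor)
            continue
        new_lengths = _walk_lengths(system, hc, rid, new_target)
        if np.any(new_lengths > hc.formation_max):
            hc.stalls += 1
            logger.debug("walk stall on ring %s (formation length exceeded)", which)
            continue
        _set_walk_bonds(system, hc, rid, tag, new_target)
        setattr(hc, f"anchor_{which}", new_anchor)
    return hc


# ---------------------------------------------------------------------------
# simplified migrating-bond extruder
# ---------------------------------------------------------------------------


def load_simple_extruder(
    system: ChainSystem, ring: int, site: int, **kwargs
) -> SimpleExtruder:
    """Create the smallest possible loop: a strong bond between adjacent beads."""
    site = _local(system, ring, site)
    ex = SimpleExtruder(
        ring_id=ring,
        left_anchor=site,
        right_anchor=_local(system, ring, site + 1),
        tag=_next_tag(system),
        start_site=site,
        **kwargs,
    )
    system.add_bond(
        _gid(system, ring, ex.left_anchor),
        _gid(system, ring, ex.right_anchor),
        BOND_HARMONIC,
        ex.spring_k,
        1.0,
        tag=ex.tag,
    )
    return ex


def step_simple_extrusion(system: ChainSystem, ex: SimpleExtruder) -> SimpleExtruder:
    """Migrate the loop bond outward by one bead per non-stalled side.

    Migration happens only once the current anchor pair has been pulled
    within the proximity threshold.  An anchor about to enter a CTCF bead
    (or, by default, a phantom segment) stops permanently; anchors meeting
    each other complete the extrusion.
    """
    if ex.complete:
        return ex
    rid = ex.ring_id
    d = np.linalg.norm(
        system.positions[_gid(system, rid, ex.left_anchor)]
        - system.positions[_gid(system, rid, ex.right_anchor)]
    )
    if d > ex.proximity_threshold:
        return ex

    def blocked(local):
        g = _gid(system, rid, local)
        return system.ctcf_flag[g] or (ex.stop_at_phantom and system.phantom_flag[g])

    new_left, new_right = ex.left_anchor, ex.right_anchor
    if not ex.left_stopped:
        cand = _local(system, rid, ex.left_anchor - 1)
        if blocked(cand):
            ex.left_stopped = True
        elif cand == ex.right_anchor or cand == _local(system, rid, ex.right_anchor + 1):
            ex.left_stopped = ex.right_stopped = True
        else:
            new_left = cand
    if not ex.right_stopped:
        cand = _local(system, rid, ex.right_anchor + 1)
        if blocked(cand):
            ex.right_stopped = True
        elif cand == new_left:
            ex.left_stopped = ex.right_stopped = True
            new_left = ex.left_anchor  # undo: anchors must never cross
        else:
            new_right = cand
    if (new_left, new_right) == (ex.left_anchor, ex.right_anchor):
        return ex
    d_new = np.linalg.norm(
        system.positions[_gid(system, rid, new_left)]
        - system.positions[_gid(system, rid, new_right)]
    )
    if d_new > ex.formation_max:
        ex.stalls += 1
        return ex
    system.remove_bonds(ex.tag)
    system.add_bond(
        _gid(system, rid, new_left),
        _gid(system, rid, new_right),
        BOND_HARMONIC,
        ex.spring_k,
        1.0,
        tag=ex.tag,
    )
    ex.left_anchor, ex.right_anchor = new_left, new_right
    return ex


# ---------------------------------------------------------------------------
# progress and arc geometry
# ---------------------------------------------------------------------------


def _anchors(ex_or_hc):
    if isinstance(ex_or_hc, CohesinHandcuff):
        return ex_or_hc.chromatin_ring, ex_or_hc.anchor_a, ex_or_hc.anchor_b
    return ex_or_hc.ring_id, ex_or_hc.left_anchor, ex_or_hc.right_anchor


def _extruded_count(system, ex_or_hc) -> int:
    """Beads in the closed arc [a .. b] containing the start site."""
    rid, a, b = _anchors(ex_or_hc)
    n = system.ring_size(rid)
    start = ex_or_hc.start_site
    count_fwd = (b - a) % n + 1  # arc walking a -> b by +1
    in_fwd = (start - a) % n <= (b - a) % n
    return count_fwd if in_fwd else n - count_fwd + 2


def extrusion_progress(system: ChainSystem, ex_or_hc) -> float:
    """Fraction of the extrudable contour already inside the loop.

    Extruded-arc bead count over (ring length - border-region length), where
    the border region is the contiguous stretch of CTCF/phantom beads the
    extruder cannot enter.  Monotone non-decreasing over a run.
    """
    rid, _, _ = _anchors(ex_or_hc)
    beads = system.ring_beads(rid)
    border = int(np.sum(system.ctcf_flag[beads] | system.phantom_flag[beads]))
    n = system.ring_size(rid)
    denom = max(1, n - border)
    return min(1.0, _extruded_count(system, ex_or_hc) / denom)


def extruded_arc_curve(system: ChainSystem, ex_or_hc) -> ClosedCurve:
    """The extruded arc as a virtually closed curve (chord between anchors).

    The anchors sit within a couple of bead diameters of each other, so the
    closing chord is short and the arc's knot state is well defined.
    """
    rid, a, b = _anchors(ex_or_hc)
    n = system.ring_size(rid)
    start = ex_or_hc.start_site
    in_fwd = (start - a) % n <= (b - a) % n
    if in_fwd:
        idx = [(a + k) % n for k in range((b - a) % n + 1)]
    else:
        idx = [(b + k) % n for k in range((a - b) % n + 1)]
    pts = system.positions[[_gid(system, rid, i) for i in idx]]
    return ClosedCurve(pts)
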