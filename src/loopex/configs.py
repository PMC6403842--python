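"""Synthetic starting configurations for the three extrusion experiments.

Builds the study systems entirely from parameters - no external data:

* ``single_tad``: one knotted ring (133 beads by default, bond length just
  under 1 sigma) representing a loop-forming TAD, with a border region of
  CTCF stop beads flanking a short phantom (Top2B) segment, and the
  extrusion start site diametrically opposite the border along the contour;
* ``three_tad``: a 400-bead circle laid out as one large trefoil and
  partitioned into three TADs separated by short border regions, a
  delocalised knot spanning all three domains;
* ``melt_demix``: eight rings confined in a sphere at 30% volume fraction,
  topologically equilibrated by switching excluded volume off (every bead
  phantom) so the thermally fluctuating chains pass freely through
  themselves and each other, then re-hardened through a force-capped
  push-off.  The equilibrated melt is knotted and catenated; the report
  carries each ring's knot type and the pairwise linking matrix.

Calibration: one bead = 10 nm = 400 bp, so a 4000-bead ring is a 1.6 Mb
chromatin portion; the desk-scale default of 300 beads per ring keeps the
same volume fraction and border layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import chi2_contingency

from .model import ChainSystem, ForceField, IntegratorParams, logger, step_langevin
from .topology import ClosedCurve, identify_knot, linking_matrix

__all__ = [
    "ExperimentConfig",
    "ConfigError",
    "torus_knot_coords",
    "connected_sum",
    "single_tad_ring",
    "three_tad_circle",
    "sphere_radius_for_fraction",
    "equilibrated_melt",
]

PHANTOM_SEGMENT = 5  # beads with excluded volume off at each TAD border
CTCF_FLANK = 2  # stop beads on each side of the phantom segment


class ConfigError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    """Parameters of one reproduced experiment."""

    experiment: str = "single_tad"
    n_beads_per_ring: int = 0  # 0: experiment default
    n_rings: int = 1
    knot_spec: tuple = (2, 3)
    volume_fraction: float = 0.30
    seed: int = 0
    phantom_len: int = PHANTOM_SEGMENT
    ctcf_len: int = CTCF_FLANK
    sequential: bool = False  # three_tad: extrude TADs one after another
    # dynamics budgets (steps); 0 (equil: -1) picks the experiment default,
    # equil_steps = 0 skips topological equilibration entirely
    md_budget: int = 0
    equil_steps: int = -1
    sample_every: int = 20_000
    advance_every: int = 40

    def __post_init__(self):
        if self.experiment not in ("single_tad", "three_tad", "melt_demix"):
            raise ConfigError(f"unknown experiment {self.experiment!r}")
        if not (0.0 < self.volume_fraction <= 0.49):
            raise ConfigError("volume_fraction must lie in (0, 0.49]")
        if self.n_beads_per_ring == 0:
            self.n_beads_per_ring = {
                "single_tad": 133,
                "three_tad": 400,
                "melt_demix": 300,
            }[self.experiment]
        if self.experiment == "melt_demix" and self.n_rings == 1:
            self.n_rings = 8
        if self.md_budget == 0:
            self.md_budget = {
                "single_tad": 400_000,
                "three_tad": 600_000,
                "melt_demix": 400_000,
            }[self.experiment]
        if self.equil_steps < 0:
            # 1600 tau of phantom dynamics; the stationarity check in
            # equilibrated_melt extends this in windows if the knot spectrum
            # is still drifting
            self.equil_steps = 160_000


# ---------------------------------------------------------------------------
# parametric knotted curves
# ---------------------------------------------------------------------------


def torus_knot_coords(
    p: int,
    q: int,
    n_beads: int,
    major_R: float = 2.0,
    minor_r: float = 1.0,
    spacing: float = 0.97,
) -> ClosedCurve:
    """A (p, q) torus-knot polygon, uniformly resampled to ``n_beads`` beads.

    The curve winds p times around the torus axis and q times around the
    tube; gcd(p, q) = 1 gives a knot ((1, q) is the unknot), gcd > 1 would
    give a multi-component link and is rejected.  The polygon is rescaled so
    the bond length equals ``spacing`` (just under 1 sigma, the rest length
    of a FENE/WCA bond).
    """
    if math.gcd(p, q) != 1:
        raise ConfigError(f"gcd({p},{q}) != 1: a (p,q) torus curve with common "
                          "factor is a link, not a knot")
    if n_beads < 3 * max(p, q):
        raise ConfigError("too few beads to realise this torus knot")
    fine = 40 * n_beads
    t = np.linspace(0, 2 * np.pi, fine, endpoint=False)
    x = (major_R + minor_r * np.cos(q * t)) * np.cos(p * t)
    y = (major_R + minor_r * np.cos(q * t)) * np.sin(p * t)
    z = minor_r * np.sin(q * t)
    pts = np.stack([x, y, z], axis=1)
    seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])[:-1]
    total = s[-1] + seg[-1]
    want = np.linspace(0, total, n_beads, endpoint=False)
    idx = np.clip(np.searchsorted(s, want), 0, fine - 1)
    poly = pts[idx]
    poly *= spacing * n_beads / total
    return ClosedCurve(poly)


def connected_sum(a: ClosedCurve, b: ClosedCurve, gap: float = 0.5) -> ClosedCurve:
    """Connected sum of two closed curves (used to build composite knots).

    The curves are placed side by side along x with their parameter origins
    facing each other, opened between last and first vertex, and joined by
    two short bridges.
    """
    va = np.array(a.vertices)
    vb = np.array(b.vertices)
    va = va - va.mean(axis=0)
    vb = vb - vb.mean(axis=0)
    vb[:, 0] *= -1  # rotate pi about z so the origins face each other
    vb[:, 1] *= -1
    va[:, 0] -= va[:, 0].max() + gap
    vb[:, 0] += -vb[:, 0].min() + gap
    return ClosedCurve(np.vstack([va, vb[::-1]]))


# ---------------------------------------------------------------------------
# TAD constructs
# ---------------------------------------------------------------------------


def _apply_border(system: ChainSystem, rid: int, centre: int, phantom_len: int, ctcf_len: int):
    beads = system.ring_beads(rid)
    n = len(beads)
    half = phantom_len // 2
    for k in range(-half, phantom_len - half):
        system.phantom_flag[beads[(centre + k) % n]] = True
    for k in range(1, ctcf_len + 1):
        system.ctcf_flag[beads[(centre - half - k) % n]] = True
        system.ctcf_flag[beads[(centre + (phantom_len - half - 1) + k) % n]] = True


def single_tad_ring(cfg: ExperimentConfig) -> ChainSystem:
    """One knotted TAD ring with a Top2B/CTCF border opposite the start site."""
    if cfg.experiment != "single_tad":
        raise ConfigError("config is not a single_tad experiment")
    curve = torus_knot_coords(*cfg.knot_spec, n_beads=cfg.n_beads_per_ring)
    system = ChainSystem()
    rid = system.add_ring(curve.vertices)
    _apply_border(system, rid, 0, cfg.phantom_len, cfg.ctcf_len)
    n = cfg.n_beads_per_ring
    system.meta["extruder_sites"] = {rid: n // 2}
    system.meta["border_centres"] = {rid: [0]}
    return system


def three_tad_circle(cfg: ExperimentConfig) -> ChainSystem:
    """A three-TAD circle forming one large, delocalised trefoil knot.

    The 400-bead ring is laid out as a global (2,3) torus curve; three
    equally spaced border regions (CTCF-flanked phantom segments) partition
    it into three TADs, each with an extrusion start site at its middle.
    """
    if cfg.experiment != "three_tad":
        raise ConfigError("config is not a three_tad experiment")
    curve = torus_knot_coords(*cfg.knot_spec, n_beads=cfg.n_beads_per_ring)
    system = ChainSystem()
    rid = system.add_ring(curve.vertices)
    n = cfg.n_beads_per_ring
    centres = [0, n // 3, (2 * n) // 3]
    for c in centres:
        _apply_border(system, rid, c, cfg.phantom_len, cfg.ctcf_len)
    sites = [(c + n // 6) % n for c in centres]
    system.meta["extruder_sites"] = {rid: sites}
    system.meta["border_centres"] = {rid: centres}
    return system


# ---------------------------------------------------------------------------
# confined melt
# ---------------------------------------------------------------------------


def sphere_radius_for_fraction(n_total_beads: int, phi: float) -> float:
    """Confining-sphere radius giving bead volume fraction ``phi``.

    n (pi/6) sigma^3 / ((4/3) pi R^3) = phi  =>  R = (n / (8 phi))^(1/3).
    """
    if not (0.0 < phi <= 0.49):
        raise ConfigError("volume fraction must lie in (0, 0.49]")
    return (n_total_beads / (8.0 * phi)) ** (1.0 / 3.0)


def _knot_spectrum(system: ChainSystem, seed: int) -> list:
    return [
        identify_knot(system.curve(rid), seed=seed).determinant
        for rid in system.chromatin_rings()
    ]


def knot_spectrum_stationary(window_a: list, window_b: list) -> bool:
    """Chi-square comparison of knot-determinant spectra from two windows."""
    cats = sorted(set(window_a) | set(window_b))
    if len(cats) < 2:
        return True
    table = np.array(
        [[window_a.count(c) + 1 for c in cats], [window_b.count(c) + 1 for c in cats]]
    )
    _, p, _, _ = chi2_contingency(table)
    return bool(p > 0.05)


def equilibrated_melt(
    cfg: ExperimentConfig,
    ff: ForceField | None = None,
    ip: IntegratorParams | None = None,
    check_stationarity: bool = True,
):
    """A topologically equilibrated confined ring melt, with topology report.

    Phase 1 marks every bead phantom (no excluded volume anywhere) and runs
    Langevin dynamics in the confining sphere until the knot spectrum is
    stationary across successive windows, letting rings knot and catenate
    freely.  Phase 2 restores excluded volume through a force-capped
    push-off, freezing the equilibrium topology.  Returns ``(system,
    report)`` where the report lists per-ring knot types and the pairwise
    linking matrix.
    """
    if cfg.experiment != "melt_demix":
        raise ConfigError("config is not a melt_demix experiment")
    ff = ff or ForceField()
    ip = ip or IntegratorParams(seed=cfg.seed)
    n = cfg.n_beads_per_ring
    radius = sphere_radius_for_fraction(cfg.n_rings * n, cfg.volume_fraction)
    system = ChainSystem()
    system.sphere_radius = radius
    rng = np.random.default_rng(cfg.seed % (2**31 - 1))
    # stacked coaxial circles: trivially unknotted and unlinked at start.
    # When an unstretched circle fits the sphere it is used as is (the
    # push-off then has nothing to do and the construction topology is
    # preserved exactly); at production density the circles are radially
    # compressed and their bonds relax during phase 1.
    r_unit = 0.97 * n / (2 * np.pi)
    r0 = min(r_unit, 0.5 * radius)
    z_max = 0.95 * np.sqrt(max(radius**2 - r0**2, 0.01)) - 0.5
    zs = np.linspace(-min(0.65 * radius, z_max), min(0.65 * radius, z_max), cfg.n_rings)
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    for k in range(cfg.n_rings):
        pos = np.stack(
            [r0 * np.cos(th), r0 * np.sin(th), np.full(n, zs[k])], axis=1
        )
        pos += 0.01 * rng.standard_normal(pos.shape)
        rid = system.add_ring(pos)
        _apply_border(system, rid, 0, cfg.phantom_len, cfg.ctcf_len)
    sites = {rid: system.ring_size(rid) // 2 for rid in system.chromatin_rings()}
    system.meta["extruder_sites"] = sites
    system.meta["border_centres"] = {rid: [0] for rid in system.chromatin_rings()}

    border_phantom = system.phantom_flag.copy()
    if cfg.equil_steps > 0:
        # phase 1: fully phantom chains in the sphere
        system.phantom_flag[:] = True
        window = max(cfg.equil_steps // 3, 1)
        step_langevin(system, ff, ip, cfg.equil_steps)
        if check_stationarity:
            prev = _knot_spectrum(system, seed=cfg.seed)
            for _ in range(4):
                step_langevin(system, ff, ip, window)
                cur = _knot_spectrum(system, seed=cfg.seed)
                if knot_spectrum_stationary(prev, cur):
                    break
                prev = cur
            else:
                logger.warning("knot spectrum still drifting after extra windows")
    # phase 2: restore excluded volume with a capped push-off
    system.phantom_flag = border_phantom
    soft = IntegratorParams(
        dt=ip.dt, gamma=ip.gamma, temperature=ip.temperature,
        seed=ip.seed, force_cap=50.0,
    )
    step_langevin(system, ff, soft, 15_000)
    step_langevin(system, ff, ip, 5_000)
    sep = _melt_min_separation(system)
    if sep < 0.5:
        raise ConfigError(f"push-off failed to remove clashes (min sep {sep:.2f})")
    report = melt_topology_report(system, seed=cfg.seed)
    return system, report


def _melt_min_separation(system: ChainSystem) -> float:
    active = ~system.phantom_flag
    pos = system.positions[active]
    d, idx = cKDTree(pos).query(pos, k=2)
    return float(d[:, 1].min())


def melt_topology_report(system: ChainSystem, seed: int = 0) -> dict:
    """Knot name per ring plus the pairwise Gauss linking matrix."""
    rids = system.chromatin_rings()
    knots = {rid: identify_knot(system.curve(rid), seed=seed) for rid in rids}
    lm = linking_matrix([system.curve(rid) for rid in rids])
    linked_pairs = int(np.sum(np.abs(np.triu(lm, 1)) > 0))
    return {
        "knots": {rid: kt.name for rid, kt in knots.items()},
        "knot_types": knots,
        "linking_matrix": lm,
        "linked_pairs": linked_pairs,
        "nontrivial_rings": sum(
            1
            for i, rid in enumerate(rids)
            if knots[rid].name != "0_1" or np.any(np.abs(lm[i]) > 0)
        ),
    }
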