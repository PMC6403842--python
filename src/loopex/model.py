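"""Bead-spring ring-polymer model with Langevin dynamics.

Chromatin fibres are modelled as closed chains of beads in reduced units:
the bead diameter sigma is the unit of length (10 nm, 400 bp of chromatin
per bead), kBT the unit of energy, and tau = sigma*sqrt(m/kBT) the unit of
time with bead mass m = 1.  The force field is the conventional
non-crossing combination:

* FENE bonds (k = 30 kBT/sigma^2, max extension 1.5 sigma) along each ring,
  with the purely repulsive 12-6 (WCA) term between the bonded pair;
* WCA excluded volume (epsilon = 1 kBT, cutoff 2^(1/6) sigma) between
  non-bonded bead pairs, skipped whenever either bead carries the phantom
  flag (a chain section mimicking Top2B: other segments may pass through);
* optional harmonic-cosine bending stiffness (default 0: fully flexible);
* a harmonic inward wall beyond the confining sphere radius.

Integration is BAOAB-split velocity Langevin dynamics.  With excluded
volume on and the recommended timestep, chain segments cannot pass through
each other, so ring topology is conserved - the premise the extrusion
experiments rest on.  Pair forces can be magnitude-capped for the soft
push-off used when switching excluded volume back on; near-coincident
beads are reported as clashes (capped force), never a crash.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .topology import ClosedCurve

logger = logging.getLogger("loopex")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.WARNING)

__all__ = [
    "ChainSystem",
    "ForceField",
    "IntegratorParams",
    "ModelError",
    "IntegrationBlowup",
    "build_ring",
    "compute_forces",
    "step_langevin",
    "write_xyz",
    "read_xyz",
]

WCA_CUTOFF = 2.0 ** (1.0 / 6.0)

BOND_FENE = 0
BOND_HARMONIC = 1

TAG_STRUCT = 0
TAG_WALK_A = 1
TAG_WALK_B = 2
TAG_EXTRUDER = 3
TAG_HANDCUFF = 4

_EXMAX = 10


class ModelError(ValueError):
    pass


class IntegrationBlowup(RuntimeError):
    pass


@dataclass
class ForceField:
    """Pair, wall and bending parameters (bond parameters live on the bonds)."""

    bond_style: str = "fene"
    bond_k: float = 30.0
    bond_rmax: float = 1.5
    ev_epsilon: float = 1.0
    ev_cutoff: float = WCA_CUTOFF
    bend_kappa: float = 0.0
    wall_stiffness: float = 100.0

    def __post_init__(self):
        if self.ev_cutoff <= 0:
            raise ModelError("ev_cutoff must be positive")
        if self.bond_style not in ("fene", "harmonic"):
            raise ModelError("bond_style must be 'fene' or 'harmonic'")


@dataclass
class IntegratorParams:
    dt: float = 0.01
    gamma: float = 1.0
    temperature: float = 1.0
    seed: int = 0
    force_cap: float = 0.0  # <= 0: no cap
    nl_every: int = 20
    skin: float = 0.7
    # speed limiter: tames the jolt when an extrusion spring is re-formed at
    # its 2-sigma formation length; far above thermal speeds (~1.7 sigma/tau)
    # so equilibrium dynamics are untouched
    v_cap: float = 6.0

    def __post_init__(self):
        if self.dt <= 0 or self.gamma <= 0:
            raise ModelError("dt and gamma must be positive")


class ChainSystem:
    """Mutable simulation state: beads, rings, bonds, flags, confinement.

    Beads of a ring occupy a contiguous index range and the ring is closed
    (last bead bonds to the first).  Rings are either chromatin fibres or
    the small cohesin rings of a handcuff.
    """

    def __init__(self, bp_per_bead: int = 400, nm_per_bead: float = 10.0):
        self.positions = np.zeros((0, 3))
        self.velocities = np.zeros((0, 3))
        self.ring_index = np.zeros(0, dtype=np.int64)
        self.phantom_flag = np.zeros(0, dtype=bool)
        self.ctcf_flag = np.zeros(0, dtype=bool)
        self.sphere_radius: float | None = None
        self.bp_per_bead = bp_per_bead
        self.nm_per_bead = nm_per_bead
        self.bonds: list = []  # (i, j, kind, k, r0, rmax, tag)
        self.ring_kind: dict = {}
        self._ring_range: dict = {}
        self.meta: dict = {}
        self._noise_chunk = 0
        self._arrays_cache = None

    # -- construction -----------------------------------------------------

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def ring_ids(self):
        return sorted(self._ring_range)

    def ring_beads(self, rid: int) -> np.ndarray:
        lo, hi = self._ring_range[rid]
        return np.arange(lo, hi)

    def ring_size(self, rid: int) -> int:
        lo, hi = self._ring_range[rid]
        return hi - lo

    def add_ring(
        self,
        positions: np.ndarray,
        kind: str = "chromatin",
        bond_k: float = 30.0,
        bond_rmax: float = 1.5,
    ) -> int:
        positions = np.asarray(positions, dtype=float)
        if positions.ndim != 2 or positions.shape[1] != 3 or len(positions) < 3:
            raise ModelError("a ring needs at least 3 beads (invalid topology)")
        lo = self.n_beads
        n = len(positions)
        rid = (max(self._ring_range) + 1) if self._ring_range else 0
        self.positions = np.vstack([self.positions, positions])
        self.velocities = np.vstack([self.velocities, np.zeros((n, 3))])
        self.ring_index = np.concatenate(
            [self.ring_index, np.full(n, rid, dtype=np.int64)]
        )
        self.phantom_flag = np.concatenate([self.phantom_flag, np.zeros(n, bool)])
        self.ctcf_flag = np.concatenate([self.ctcf_flag, np.zeros(n, bool)])
        self._ring_range[rid] = (lo, lo + n)
        self.ring_kind[rid] = kind
        for a in range(n):
            b = (a + 1) % n
            self.add_bond(lo + a, lo + b, BOND_FENE, bond_k, 0.0, bond_rmax)
        return rid

    def add_bond(self, i, j, kind, k, r0, rmax=0.0, tag=TAG_STRUCT):
        if i == j:
            raise ModelError("self-bond")
        self.bonds.append((int(i), int(j), int(kind), float(k), float(r0), float(rmax), int(tag)))
        self._arrays_cache = None

    def remove_bonds(self, tag: int):
        self.bonds = [b for b in self.bonds if b[6] != tag]
        self._arrays_cache = None

    def bonds_with_tag(self, tag: int):
        return [b for b in self.bonds if b[6] == tag]

    # -- derived views ----------------------------------------------------

    def curve(self, rid: int) -> ClosedCurve:
        return ClosedCurve(self.positions[self.ring_beads(rid)])

    def chromatin_rings(self):
        return [r for r in self.ring_ids if self.ring_kind[r] == "chromatin"]

    def copy(self) -> "ChainSystem":
        other = ChainSystem(self.bp_per_bead, self.nm_per_bead)
        other.positions = self.positions.copy()
        other.velocities = self.velocities.copy()
        other.ring_index = self.ring_index.copy()
        other.phantom_flag = self.phantom_flag.copy()
        other.ctcf_flag = self.ctcf_flag.copy()
        other.sphere_radius = self.sphere_radius
        other.bonds = list(self.bonds)
        other.ring_kind = dict(self.ring_kind)
        other._ring_range = dict(self._ring_range)
        other.meta = dict(self.meta)
        other._noise_chunk = self._noise_chunk
        return other

    def _compiled(self):
        if self._arrays_cache is None:
            nb = len(self.bonds)
            bi = np.zeros(nb, np.int64)
            bj = np.zeros(nb, np.int64)
            bk = np.zeros(nb, np.int64)
            bkk = np.zeros(nb)
            br0 = np.zeros(nb)
            brm = np.zeros(nb)
            for idx, (i, j, kind, k, r0, rmax, _tag) in enumerate(self.bonds):
                bi[idx], bj[idx], bk[idx] = i, j, kind
                bkk[idx], br0[idx], brm[idx] = k, r0, rmax
            excl = np.full((self.n_beads, _EXMAX), -1, np.int64)
            fill = np.zeros(self.n_beads, np.int64)
            for i, j in zip(bi, bj):
                for a, b in ((i, j), (j, i)):
                    if fill[a] >= _EXMAX:
                        raise ModelError(f"too many bonds on bead {a}")
                    excl[a, fill[a]] = b
                    fill[a] += 1
            self._arrays_cache = (bi, bj, bk, bkk, br0, brm, excl)
        return self._arrays_cache

    def validate(self):
        if not np.all(np.isfinite(self.positions)):
            raise ModelError("non-finite positions")
        if self.sphere_radius is not None:
            r = np.linalg.norm(self.positions, axis=1)
            if np.any(r > self.sphere_radius + 0.5):
                raise ModelError("bead outside confining sphere + 0.5 sigma")
        # every ring's structural bonds form a single closed cycle by
        # construction (add_ring); verify the count matches
        struct = self.bonds_with_tag(TAG_STRUCT) + self.bonds_with_tag(TAG_HANDCUFF)
        per_ring: dict = {}
        for i, j, *_ in struct:
            if self.ring_index[i] == self.ring_index[j]:
                per_ring[self.ring_index[i]] = per_ring.get(self.ring_index[i], 0) + 1
        for rid in self.ring_ids:
            if per_ring.get(rid, 0) < self.ring_size(rid):
                raise ModelError(f"ring {rid} is not a closed cycle")


def build_ring(n_beads: int, spacing: float = 1.0) -> ChainSystem:
    """A single planar circular ring of ``n_beads`` beads, bond length ``spacing``."""
    if n_beads < 3:
        raise ModelError("a ring needs at least 3 beads (invalid topology)")
    radius = n_beads * spacing / (2.0 * np.pi)
    th = np.linspace(0, 2 * np.pi, n_beads, endpoint=False)
    pos = np.stack([radius * np.cos(th), radius * np.sin(th), np.zeros(n_beads)], axis=1)
    system = ChainSystem()
    system.add_ring(pos)
    return system


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _build_pairs(pos, phantom, rcut2_skin, pairs, max_pairs):
    """Cell-list neighbour pairs within sqrt(rcut2_skin); returns count or -1.

    Pairs involving a phantom bead are omitted here already: they can never
    interact, and in the fully phantom equilibration phase this empties the
    list entirely.
    """
    n = pos.shape[0]
    lo0 = pos[0, 0]
    lo1 = pos[0, 1]
    lo2 = pos[0, 2]
    hi0, hi1, hi2 = lo0, lo1, lo2
    for i in range(n):
        if pos[i, 0] < lo0:
            lo0 = pos[i, 0]
        if pos[i, 1] < lo1:
            lo1 = pos[i, 1]
        if pos[i, 2] < lo2:
            lo2 = pos[i, 2]
        if pos[i, 0] > hi0:
            hi0 = pos[i, 0]
        if pos[i, 1] > hi1:
            hi1 = pos[i, 1]
        if pos[i, 2] > hi2:
            hi2 = pos[i, 2]
    cell = np.sqrt(rcut2_skin)
    nx = max(1, min(48, int((hi0 - lo0) / cell) + 1))
    ny = max(1, min(48, int((hi1 - lo1) / cell) + 1))
    nz = max(1, min(48, int((hi2 - lo2) / cell) + 1))
    sx = (hi0 - lo0) / nx + 1e-12
    sy = (hi1 - lo1) / ny + 1e-12
    sz = (hi2 - lo2) / nz + 1e-12
    ncell = nx * ny * nz
    cidx = np.empty(n, np.int64)
    counts = np.zeros(ncell + 1, np.int64)
    for i in range(n):
        cx = int((pos[i, 0] - lo0) / sx)
        cy = int((pos[i, 1] - lo1) / sy)
        cz = int((pos[i, 2] - lo2) / sz)
        if cx >= nx:
            cx = nx - 1
        if cy >= ny:
            cy = ny - 1
        if cz >= nz:
            cz = nz - 1
        c = (cx * ny + cy) * nz + cz
        cidx[i] = c
        counts[c + 1] += 1
    for c in range(ncell):
        counts[c + 1] += counts[c]
    order = np.empty(n, np.int64)
    fill = counts[:-1].copy()
    for i in range(n):
        order[fill[cidx[i]]] = i
        fill[cidx[i]] += 1
    # true cell size may exceed `cell` when the box is wider than 48 cells
    span_x = min(nx - 1, max(1, int(cell / sx) + 1)) if nx > 1 else 0
    span_y = min(ny - 1, max(1, int(cell / sy) + 1)) if ny > 1 else 0
    span_z = min(nz - 1, max(1, int(cell / sz) + 1)) if nz > 1 else 0
    npairs = 0
    for i in range(n):
        if phantom[i]:
            continue
        c = cidx[i]
        cz0 = c % nz
        cy0 = (c // nz) % ny
        cx0 = c // (ny * nz)
        for dx in range(-span_x, span_x + 1):
            cx = cx0 + dx
            if cx < 0 or cx >= nx:
                continue
            for dy in range(-span_y, span_y + 1):
                cy = cy0 + dy
                if cy < 0 or cy >= ny:
                    continue
                for dz in range(-span_z, span_z + 1):
                    cz = cz0 + dz
                    if cz < 0 or cz >= nz:
                        continue
                    cc = (cx * ny + cy) * nz + cz
                    for kk in range(counts[cc], counts[cc + 1]):
                        j = order[kk]
                        if j <= i:
                            continue
                        if phantom[i] or phantom[j]:
                            continue
                        d0 = pos[i, 0] - pos[j, 0]
                        d1 = pos[i, 1] - pos[j, 1]
                        d2 = pos[i, 2] - pos[j, 2]
                        r2 = d0 * d0 + d1 * d1 + d2 * d2
                        if r2 < rcut2_skin:
                            if npairs >= max_pairs:
                                return -1
                            pairs[npairs, 0] = i
                            pairs[npairs, 1] = j
                            npairs += 1
    return npairs


@njit(cache=True)
def _forces(
    pos,
    forces,
    pairs,
    npairs,
    excl,
    phantom,
    bi,
    bj,
    bk,
    bkk,
    br0,
    brm,
    tri,
    eps,
    cut2,
    kappa,
    wall_r,
    wall_k,
    fcap,
):
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    clashes = 0
    pe = 0.0
    # non-bonded WCA
    for p in range(npairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        if phantom[i] or phantom[j]:
            continue
        d0 = pos[i, 0] - pos[j, 0]
        d1 = pos[i, 1] - pos[j, 1]
        d2 = pos[i, 2] - pos[j, 2]
        r2 = d0 * d0 + d1 * d1 + d2 * d2
        if r2 >= cut2:
            continue
        skip = False
        for e in range(excl.shape[1]):
            if excl[i, e] == j:
                skip = True
                break
            if excl[i, e] < 0:
                break
        if skip:
            continue
        if r2 < 1e-12:
            clashes += 1
            cap = fcap if fcap > 0 else 50.0
            forces[i, 0] += cap
            forces[j, 0] -= cap
            continue
        inv2 = 1.0 / r2
        inv6 = inv2 * inv2 * inv2
        fmag = 24.0 * eps * inv6 * (2.0 * inv6 - 1.0) * inv2  # F/r
        pe += 4.0 * eps * inv6 * (inv6 - 1.0) + eps
        fr = fmag * np.sqrt(r2)
        if fcap > 0 and fr > fcap:
            fmag = fcap / np.sqrt(r2)
        forces[i, 0] += fmag * d0
        forces[i, 1] += fmag * d1
        forces[i, 2] += fmag * d2
        forces[j, 0] -= fmag * d0
        forces[j, 1] -= fmag * d1
        forces[j, 2] -= fmag * d2
    # bonds
    nb = bi.shape[0]
    for b in range(nb):
        i = bi[b]
        j = bj[b]
        d0 = pos[i, 0] - pos[j, 0]
        d1 = pos[i, 1] - pos[j, 1]
        d2 = pos[i, 2] - pos[j, 2]
        r2 = d0 * d0 + d1 * d1 + d2 * d2
        r = np.sqrt(r2)
        if bk[b] == 0:  # FENE + bonded WCA
            rmax = brm[b]
            rr = r
            if rr > 0.99 * rmax:
                rr = 0.99 * rmax  # clamp overstretched bond force
            x = rr / rmax
            fmag = -bkk[b] / (1.0 - x * x)  # F/r, attractive
            pe += -0.5 * bkk[b] * rmax * rmax * np.log(1.0 - x * x)
            if r2 < cut2 and r2 > 1e-12:
                inv2 = 1.0 / r2
                inv6 = inv2 * inv2 * inv2
                fmag += 24.0 * eps * inv6 * (2.0 * inv6 - 1.0) * inv2
                pe += 4.0 * eps * inv6 * (inv6 - 1.0) + eps
        else:  # harmonic
            if r < 1e-9:
                continue
            fmag = -bkk[b] * (r - br0[b]) / r
            pe += 0.5 * bkk[b] * (r - br0[b]) ** 2
        fr = abs(fmag) * r
        if fcap > 0 and fr > fcap:
            fmag = fmag / fr * fcap
        forces[i, 0] += fmag * d0
        forces[i, 1] += fmag * d1
        forces[i, 2] += fmag * d2
        forces[j, 0] -= fmag * d0
        forces[j, 1] -= fmag * d1
        forces[j, 2] -= fmag * d2
    # bending (harmonic cosine) on consecutive ring triplets
    if kappa > 0.0:
        for a in range(tri.shape[0]):
            i = tri[a, 0]
            j = tri[a, 1]
            k = tri[a, 2]
            r1x = pos[i, 0] - pos[j, 0]
            r1y = pos[i, 1] - pos[j, 1]
            r1z = pos[i, 2] - pos[j, 2]
            r2x = pos[k, 0] - pos[j, 0]
            r2y = pos[k, 1] - pos[j, 1]
            r2z = pos[k, 2] - pos[j, 2]
            l1 = np.sqrt(r1x * r1x + r1y * r1y + r1z * r1z)
            l2 = np.sqrt(r2x * r2x + r2y * r2y + r2z * r2z)
            if l1 < 1e-9 or l2 < 1e-9:
                continue
            c = (r1x * r2x + r1y * r2y + r1z * r2z) / (l1 * l2)
            if c > 1.0:
                c = 1.0
            if c < -1.0:
                c = -1.0
            pe += kappa * (1.0 + c)
            # dU/dcos = kappa ; F = -kappa * dcos/dr
            fi_x = -kappa * (r2x / (l1 * l2) - c * r1x / (l1 * l1))
            fi_y = -kappa * (r2y / (l1 * l2) - c * r1y / (l1 * l1))
            fi_z = -kappa * (r2z / (l1 * l2) - c * r1z / (l1 * l1))
            fk_x = -kappa * (r1x / (l1 * l2) - c * r2x / (l2 * l2))
            fk_y = -kappa * (r1y / (l1 * l2) - c * r2y / (l2 * l2))
            fk_z = -kappa * (r1z / (l1 * l2) - c * r2z / (l2 * l2))
            forces[i, 0] += fi_x
            forces[i, 1] += fi_y
            forces[i, 2] += fi_z
            forces[k, 0] += fk_x
            forces[k, 1] += fk_y
            forces[k, 2] += fk_z
            forces[j, 0] -= fi_x + fk_x
            forces[j, 1] -= fi_y + fk_y
            forces[j, 2] -= fi_z + fk_z
    # spherical wall
    if wall_r > 0.0:
        for i in range(n):
            rr = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
            if rr > wall_r:
                f = -wall_k * (rr - wall_r) / rr
                pe += 0.5 * wall_k * (rr - wall_r) ** 2
                forces[i, 0] += f * pos[i, 0]
                forces[i, 1] += f * pos[i, 1]
                forces[i, 2] += f * pos[i, 2]
    return clashes, pe


@njit(cache=True)
def _run_block(
    pos,
    vel,
    ref,
    pairs,
    state,
    excl,
    phantom,
    bi,
    bj,
    bk,
    bkk,
    br0,
    brm,
    tri,
    eps,
    cut2,
    rlist2,
    kappa,
    wall_r,
    wall_k,
    fcap,
    noise,
    c1,
    c2,
    dt,
    nl_every,
    trigger2,
    vcap2,
    step0,
    ke_from,
):
    """One block of BAOAB steps (block size = noise.shape[0]).

    Thermal noise is precomputed per block (vectorised generation is an
    order of magnitude faster than drawing normals in the loop).  Returns
    (status, clashes, ke_sum, ke_n, pe): status -1 = ok, -2 = pair-list
    overflow (caller grows the buffer and retries the block), >= 0 = global
    step index at which coordinates became non-finite.
    """
    n = pos.shape[0]
    bs = noise.shape[0]
    forces = np.zeros((n, 3))
    clashes, pe = _forces(
        pos, forces, pairs, state[0], excl, phantom,
        bi, bj, bk, bkk, br0, brm, tri,
        eps, cut2, kappa, wall_r, wall_k, fcap,
    )
    total_clashes = clashes
    ke_sum = 0.0
    ke_n = 0
    for step in range(bs):
        for i in range(n):
            vel[i, 0] += 0.5 * dt * forces[i, 0]
            vel[i, 1] += 0.5 * dt * forces[i, 1]
            vel[i, 2] += 0.5 * dt * forces[i, 2]
            v2 = vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            if v2 > vcap2:
                f = np.sqrt(vcap2 / v2)
                vel[i, 0] *= f
                vel[i, 1] *= f
                vel[i, 2] *= f
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            pos[i, 2] += 0.5 * dt * vel[i, 2]
        for i in range(n):
            vel[i, 0] = c1 * vel[i, 0] + c2 * noise[step, i, 0]
            vel[i, 1] = c1 * vel[i, 1] + c2 * noise[step, i, 1]
            vel[i, 2] = c1 * vel[i, 2] + c2 * noise[step, i, 2]
            v2 = vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            if v2 > vcap2:
                f = np.sqrt(vcap2 / v2)
                vel[i, 0] *= f
                vel[i, 1] *= f
                vel[i, 2] *= f
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            pos[i, 2] += 0.5 * dt * vel[i, 2]
        # rebuild the pair list once any bead has drifted half the skin
        maxdisp2 = 0.0
        for i in range(n):
            d2 = (
                (pos[i, 0] - ref[i, 0]) ** 2
                + (pos[i, 1] - ref[i, 1]) ** 2
                + (pos[i, 2] - ref[i, 2]) ** 2
            )
            if d2 > maxdisp2:
                maxdisp2 = d2
        if maxdisp2 > trigger2 or (step0 + step + 1) % nl_every == 0:
            for i in range(n):
                # NaN-safe divergence check: also catches runaway-but-finite
                # coordinates (no simulated system approaches 1e8 sigma)
                if not (
                    abs(pos[i, 0]) < 1e8
                    and abs(pos[i, 1]) < 1e8
                    and abs(pos[i, 2]) < 1e8
                ):
                    return step0 + step, total_clashes, ke_sum, ke_n, pe
            if maxdisp2 > trigger2:
                np_ = _build_pairs(pos, phantom, rlist2, pairs, pairs.shape[0])
                if np_ < 0:
                    return -2, total_clashes, ke_sum, ke_n, pe
                state[0] = np_
                for i in range(n):
                    ref[i, 0] = pos[i, 0]
                    ref[i, 1] = pos[i, 1]
                    ref[i, 2] = pos[i, 2]
        clashes, pe = _forces(
            pos, forces, pairs, state[0], excl, phantom,
            bi, bj, bk, bkk, br0, brm, tri,
            eps, cut2, kappa, wall_r, wall_k, fcap,
        )
        total_clashes += clashes
        for i in range(n):
            vel[i, 0] += 0.5 * dt * forces[i, 0]
            vel[i, 1] += 0.5 * dt * forces[i, 1]
            vel[i, 2] += 0.5 * dt * forces[i, 2]
        if step0 + step >= ke_from:
            for i in range(n):
                ke_sum += 0.5 * (
                    vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
                )
            ke_n += 3 * n
    return -1, total_clashes, ke_sum, ke_n, pe


def _bend_triplets(system: ChainSystem) -> np.ndarray:
    tri = []
    for rid in system.ring_ids:
        beads = system.ring_beads(rid)
        n = len(beads)
        for a in range(n):
            tri.append((beads[(a - 1) % n], beads[a], beads[(a + 1) % n]))
    return np.array(tri, dtype=np.int64).reshape(-1, 3)


def compute_forces(system: ChainSystem, ff: ForceField) -> np.ndarray:
    """Per-bead forces: negative gradient of bond + pair + bend + wall energy."""
    bi, bj, bk, bkk, br0, brm, excl = system._compiled()
    n = system.n_beads
    pos = np.ascontiguousarray(system.positions)
    forces = np.zeros((n, 3))
    max_pairs = 80 * n + 1024
    pairs = np.zeros((max_pairs, 2), np.int64)
    npairs = _build_pairs(pos, system.phantom_flag, ff.ev_cutoff**2 * 1.0001, pairs, max_pairs)
    while npairs < 0:
        max_pairs *= 2
        pairs = np.zeros((max_pairs, 2), np.int64)
        npairs = _build_pairs(pos, system.phantom_flag, ff.ev_cutoff**2 * 1.0001, pairs, max_pairs)
    tri = _bend_triplets(system) if ff.bend_kappa > 0 else np.zeros((0, 3), np.int64)
    wall_r = system.sphere_radius if system.sphere_radius is not None else -1.0
    clashes, _pe = _forces(
        pos, forces, pairs, npairs, excl, system.phantom_flag,
        bi, bj, bk, bkk, br0, brm, tri,
        ff.ev_epsilon, ff.ev_cutoff**2, ff.bend_kappa,
        wall_r, ff.wall_stiffness, 0.0,
    )
    if clashes:
        logger.warning("%d bead clash(es) at separation < 1e-6 sigma", clashes)
    return forces


def step_langevin(
    system: ChainSystem,
    ff: ForceField,
    ip: IntegratorParams,
    n_steps: int,
) -> ChainSystem:
    """Advance the system by ``n_steps`` BAOAB Langevin steps (in place).

    The thermal-noise stream is derived from ``ip.seed`` and a per-system
    chunk counter, so repeating an identical run reproduces the trajectory
    bit for bit.  Raises :class:`IntegrationBlowup` naming the step if any
    coordinate becomes non-finite.
    """
    if n_steps < 0:
        raise ModelError("n_steps must be >= 0")
    if n_steps == 0:
        return system
    bi, bj, bk, bkk, br0, brm, excl = system._compiled()
    tri = _bend_triplets(system) if ff.bend_kappa > 0 else np.zeros((0, 3), np.int64)
    wall_r = system.sphere_radius if system.sphere_radius is not None else -1.0
    seed = (ip.seed * 2654435761 + system._noise_chunk * 40503 + 7) % (2**31 - 1)
    system._noise_chunk += 1
    rng = np.random.default_rng(seed)
    pos = np.ascontiguousarray(system.positions)
    vel = np.ascontiguousarray(system.velocities)
    n = system.n_beads
    phantom = system.phantom_flag
    cut2 = ff.ev_cutoff**2
    rlist2 = (ff.ev_cutoff + ip.skin) ** 2
    max_pairs = 90 * max(1, int(np.sum(~phantom))) + 1024
    pairs = np.zeros((max_pairs, 2), np.int64)
    npairs = _build_pairs(pos, phantom, rlist2, pairs, max_pairs)
    while npairs < 0:
        max_pairs *= 2
        pairs = np.zeros((max_pairs, 2), np.int64)
        npairs = _build_pairs(pos, phantom, rlist2, pairs, max_pairs)
    state = np.array([npairs], np.int64)
    ref = pos.copy()
    c1 = float(np.exp(-ip.gamma * ip.dt))
    c2 = float(np.sqrt((1.0 - c1 * c1) * ip.temperature))
    vcap2 = ip.v_cap**2 if ip.v_cap > 0 else 1e300
    trigger2 = (0.5 * ip.skin) ** 2
    block = max(1, min(n_steps, 2_000_000 // (3 * n)))
    ke_from = n_steps // 2
    ke_sum_t = 0.0
    ke_n_t = 0
    clashes_t = 0
    pe = 0.0
    step0 = 0
    while step0 < n_steps:
        bs = min(block, n_steps - step0)
        noise = rng.standard_normal((bs, n, 3))
        snap = (pos.copy(), vel.copy(), ref.copy(), state.copy())
        while True:
            status, clashes, ke_sum, ke_n, pe = _run_block(
                pos, vel, ref, pairs, state, excl, phantom,
                bi, bj, bk, bkk, br0, brm, tri,
                ff.ev_epsilon, cut2, rlist2, ff.bend_kappa,
                wall_r, ff.wall_stiffness, ip.force_cap,
                noise, c1, c2, ip.dt, ip.nl_every, trigger2, vcap2,
                step0, ke_from,
            )
            if status == -2:  # pair buffer overflow: restore and retry larger
                pos[:], vel[:], ref[:], state[:] = snap
                max_pairs *= 2
                grown = np.zeros((max_pairs, 2), np.int64)
                grown[: len(pairs)] = pairs
                pairs = grown
                state[0] = _build_pairs(pos, phantom, rlist2, pairs, max_pairs)
                continue
            break
        if status >= 0:
            system.positions = pos
            system.velocities = vel
            raise IntegrationBlowup(
                f"non-finite or runaway coordinates at step {status}"
            )
        ke_sum_t += ke_sum
        ke_n_t += ke_n
        clashes_t += clashes
        step0 += bs
    system.positions = pos
    system.velocities = vel
    if clashes_t:
        logger.warning("%d clash events during chunk", clashes_t)
    if ke_n_t:
        system.meta["last_ke_per_dof"] = ke_sum_t / ke_n_t
    system.meta["last_pe"] = pe
    logger.debug(
        "chunk done: %d steps, pe=%.1f, ke/dof=%.3f",
        n_steps, pe, system.meta.get("last_ke_per_dof", float("nan")),
    )
    return system


# ---------------------------------------------------------------------------
# trajectory I/O (XYZ; ring id encoded in the atom-name column)
# ---------------------------------------------------------------------------


def write_xyz(fh, system: ChainSystem, comment: str = ""):
    """Append one XYZ frame; atom names are R<ring_id>."""
    close = False
    if isinstance(fh, (str, bytes)):
        fh = open(fh, "a")
        close = True
    try:
        fh.write(f"{system.n_beads}\n{comment}\n")
        for i in range(system.n_beads):
            x, y, z = system.positions[i]
            fh.write(f"R{system.ring_index[i]} {x:.6f} {y:.6f} {z:.6f}\n")
    finally:
        if close:
            fh.close()


def read_xyz(path):
    """Read all frames: list of (ring_index array, positions array)."""
    frames = []
    with open(path) as fh:
        while True:
            line = fh.readline()
            if not line.strip():
                break
            n = int(line)
            fh.readline()
            rings = np.zeros(n, np.int64)
            pos = np.zeros((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                rings[i] = int(parts[0].lstrip("R"))
                pos[i] = [float(v) for v in parts[1:4]]
            frames.append((rings, pos))
    return frames
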