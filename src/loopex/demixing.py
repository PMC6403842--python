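"""Voronoi tessellation of the confined melt and inter-chain interfacial area.

The confining sphere is partitioned into one convex polyhedron per bead
(the region of space closer to that bead than to any other).  The total
area of the facets separating beads of *different* rings measures how much
the rings intermingle; as loop extrusion segregates the rings into
territories this interfacial area falls.  The facets separating one ring's
beads from all others form that ring's Voronoi envelope, so summing
envelope areas over rings counts every inter-chain facet exactly twice.

The spherical wall is realised by ghost points: every bead near the wall is
reflected radially across the sphere surface, and a quasi-uniform set of
tangent-plane reflections closes the remaining gaps, so each boundary cell
is clipped by planes tangent to the sphere.  The union of all cells is then
a polyhedron circumscribing the sphere whose volume exceeds the sphere's by
about 3/K for K tangent points - the volume-conservation check uses this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi, cKDTree

__all__ = [
    "Tessellation",
    "InterfaceMetric",
    "TessellationError",
    "tessellate",
    "interchain_area",
    "demixing_series",
    "export_envelope_obj",
]


class TessellationError(ValueError):
    pass


@dataclass
class Tessellation:
    """Per-bead Voronoi cells clipped to the confining sphere.

    ``facet_beads[k] = (i, j)`` are the beads sharing facet k (j = -1 for a
    wall facet), ``facet_areas[k]`` its area; ``cell_volumes`` and
    ``cell_vertices``/``cell_facets`` describe the polyhedra.
    """

    positions: np.ndarray
    ring_index: np.ndarray
    sphere_radius: float
    facet_beads: np.ndarray
    facet_areas: np.ndarray
    cell_volumes: np.ndarray
    cell_facets: list
    cell_vertices: list
    facet_vertices: list  # ordered polygon vertices per facet

    @property
    def container_volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.sphere_radius**3

    def volume_error(self) -> float:
        """Relative deviation of the summed cell volumes from the sphere."""
        return abs(self.cell_volumes.sum() - self.container_volume) / self.container_volume


@dataclass
class InterfaceMetric:
    """Inter-chain interfacial area of one frame (units: sigma^2)."""

    total_interchain_area: float
    per_chain_envelope_area: dict
    frame_index: int = 0


def _fibonacci_sphere(k: int) -> np.ndarray:
    i = np.arange(k) + 0.5
    phi = np.arccos(1 - 2 * i / k)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def _polygon_area_normal(verts: np.ndarray):
    """(area, unit normal) of a planar convex polygon, vertices unordered."""
    c = verts.mean(axis=0)
    d = verts - c
    # plane normal from the widest vertex triple (robust to near-collinear)
    n = np.cross(d[1] - d[0], d[-1] - d[0])
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        best = 0.0
        for k in range(2, len(d)):
            cand = np.cross(d[1] - d[0], d[k] - d[0])
            cn = np.linalg.norm(cand)
            if cn > best:
                best, n, nn = cn, cand, cn
        if nn < 1e-12:
            return 0.0, np.array([0.0, 0.0, 1.0])
    n = n / nn
    e1 = d[1] - d[0]
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    x, y = d @ e1, d @ e2
    order = np.argsort(np.arctan2(y, x))
    x, y = x[order], y[order]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return area, n


def tessellate(
    positions: np.ndarray,
    ring_index: np.ndarray,
    sphere_radius: float,
    n_wall_points: int = 2000,
    mirror_shell: float = 3.0,
    wall_dirs: np.ndarray | None = None,
) -> Tessellation:
    """Voronoi cells of all beads, clipped to the spherical container.

    All beads must lie strictly inside the sphere; coincident beads are a
    tessellation error naming the pair.  Boundary clipping uses radial
    mirror beads (for beads within ``mirror_shell`` of the wall) plus
    ``n_wall_points`` tangent-plane reflections of the locally nearest bead.
    """
    pos = np.asarray(positions, dtype=float)
    ring_index = np.asarray(ring_index)
    n = len(pos)
    if n < 1:
        raise TessellationError("no beads")
    r = np.linalg.norm(pos, axis=1)
    if np.any(r >= sphere_radius):
        raise TessellationError("beads must lie strictly inside the sphere")
    if n > 1:
        clash = cKDTree(pos).query_pairs(1e-9)
        if clash:
            i, j = sorted(min(clash))
            raise TessellationError(f"coincident beads {i} and {j}")
    ghosts = []
    near = r > sphere_radius - mirror_shell
    if np.any(near):
        rn = r[near]
        ghosts.append(pos[near] * ((2 * sphere_radius - rn) / rn)[:, None])
    if wall_dirs is None:
        dirs = _fibonacci_sphere(n_wall_points)
    else:
        dirs = np.asarray(wall_dirs, float)
        dirs = dirs / np.linalg.norm(dirs, axis=1)[:, None]
    tang = sphere_radius * dirs
    _, nearest = cKDTree(pos).query(tang, k=1)
    p = pos[nearest]
    ghosts.append(p + 2 * (sphere_radius - np.sum(p * dirs, axis=1))[:, None] * dirs)
    allpts = np.vstack([pos] + ghosts)
    vor = Voronoi(allpts)

    volumes = np.zeros(n)
    facet_beads = []
    facet_areas = []
    facet_vertices = []
    cell_facets = [[] for _ in range(n)]
    vert_ids = [set() for _ in range(n)]
    groups: dict = {}  # polygon size -> list of (pi, pj, vertex ids)
    for (pi, pj), ridge in zip(vor.ridge_points, vor.ridge_vertices):
        if pi >= n and pj >= n:
            continue
        if -1 in ridge:
            raise TessellationError(
                "unbounded cell at the container boundary; increase n_wall_points"
            )
        groups.setdefault(len(ridge), []).append((pi, pj, ridge))
    for m, items in groups.items():
        ridx = np.array([it[2] for it in items])
        pij = np.array([(it[0], it[1]) for it in items])
        V = vor.vertices[ridx]  # (g, m, 3)
        c = V.mean(axis=1)
        d = V - c[:, None, :]
        normal = np.cross(d[:, 1] - d[:, 0], d[:, 2] - d[:, 0])
        nn = np.linalg.norm(normal, axis=1)
        bad = nn < 1e-12
        for g in np.flatnonzero(bad):  # rare near-collinear triples
            a, normal[g] = _polygon_area_normal(V[g])
            nn[g] = 1.0
        normal /= np.maximum(nn, 1e-300)[:, None]
        e1 = d[:, 1] - d[:, 0]
        e1 /= np.maximum(np.linalg.norm(e1, axis=1), 1e-300)[:, None]
        e2 = np.cross(normal, e1)
        x = np.einsum("gmk,gk->gm", d, e1)
        y = np.einsum("gmk,gk->gm", d, e2)
        order = np.argsort(np.arctan2(y, x), axis=1)
        x = np.take_along_axis(x, order, axis=1)
        y = np.take_along_axis(y, order, axis=1)
        area = 0.5 * np.abs(
            np.einsum("gm,gm->g", x, np.roll(y, -1, axis=1))
            - np.einsum("gm,gm->g", y, np.roll(x, -1, axis=1))
        )
        keep = area > 1e-12
        for g in np.flatnonzero(keep):
            pi, pj, ridge = items[g]
            k = len(facet_areas)
            facet_beads.append((pi if pi < n else -1, pj if pj < n else -1))
            facet_areas.append(area[g])
            facet_vertices.append(V[g][order[g]])
            for bead in (pi, pj):
                if bead >= n:
                    continue
                h = abs(np.dot(c[g] - pos[bead], normal[g]))
                volumes[bead] += area[g] * h / 3.0
                cell_facets[bead].append(k)
                vert_ids[bead].update(ridge)
    # store as (i, j) with j = -1 marking wall facets
    fb2 = np.empty((len(facet_beads), 2), dtype=np.int64)
    for k, (a, b) in enumerate(facet_beads):
        if a < 0 or b < 0:
            fb2[k] = (max(a, b), -1)
        else:
            fb2[k] = (min(a, b), max(a, b))
    cell_vertices = [vor.vertices[sorted(s)] for s in vert_ids]
    return Tessellation(
        positions=pos,
        ring_index=ring_index,
        sphere_radius=sphere_radius,
        facet_beads=fb2,
        facet_areas=np.array(facet_areas),
        cell_volumes=volumes,
        cell_facets=cell_facets,
        cell_vertices=cell_vertices,
        facet_vertices=facet_vertices,
    )


def interchain_area(t: Tessellation, ring_index=None) -> InterfaceMetric:
    """Total facet area between beads of different rings (each facet once).

    Wall facets are excluded.  Per-chain envelope areas are accumulated in
    the same pass; their sum is exactly twice the total.
    """
    rings = t.ring_index if ring_index is None else np.asarray(ring_index)
    total = 0.0
    env: dict = {int(rid): 0.0 for rid in np.unique(rings)}
    for (i, j), area in zip(t.facet_beads, t.facet_areas):
        if j < 0:
            continue
        ri, rj = int(rings[i]), int(rings[j])
        if ri != rj:
            total += area
            env[ri] += area
            env[rj] += area
    return InterfaceMetric(total_interchain_area=total, per_chain_envelope_area=env)


def export_envelope_obj(t: Tessellation, path, ring: int | None = None):
    """Write Voronoi-envelope facets as a Wavefront OBJ mesh.

    With ``ring`` given, only that ring's envelope (its facets against all
    other rings); otherwise every inter-chain facet.  Off the hot path -
    visualisation only.
    """
    lines = []
    nv = 0
    for (i, j), verts in zip(t.facet_beads, t.facet_vertices):
        if j < 0:
            continue
        ri, rj = int(t.ring_index[i]), int(t.ring_index[j])
        if ri == rj:
            continue
        if ring is not None and ring not in (ri, rj):
            continue
        for v in verts:
            lines.append(f"v {v[0]:.5f} {v[1]:.5f} {v[2]:.5f}")
        lines.append("f " + " ".join(str(nv + k + 1) for k in range(len(verts))))
        nv += len(verts)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def demixing_series(trajectory, ring_index, sphere_radius, **kwargs) -> list:
    """Inter-chain interfacial area for every frame of a trajectory."""
    out = []
    for f, pos in enumerate(trajectory):
        m = interchain_area(tessellate(pos, ring_index, sphere_radius, **kwargs))
        m.frame_index = f
        out.append(m)
    if not out:
        raise TessellationError("empty trajectory")
    return out
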