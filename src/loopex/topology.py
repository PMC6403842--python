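"""Knot and catenation analysis of closed bead rings.

A closed ring of beads is treated as a closed 3D polygon.  Its knot type is
obtained by the standard pipeline used for polymer trajectories:

1. geometric simplification that removes vertices only when the removal
   triangle is not pierced by any other chain segment, so the knot type is
   preserved (KMT-style reduction);
2. projection along a generic direction onto a plane, recording every
   transversal crossing with its over/under assignment and sign;
3. combinatorial reduction of the crossing diagram (Reidemeister I/II);
4. evaluation of the Alexander polynomial from the crossing matrix and
   lookup of (polynomial, determinant) in a bundled prime-knot table, with
   composite knots recognised by exact polynomial factorisation.

Knots are named in Alexander-Briggs notation ("3_1", "4_1", composite
"3_1#3_1").  Diagrams that remain above 12 crossings after reduction are
reported as "unclassified", with the invariants still recorded.  The
Alexander polynomial does not distinguish mirror images, so chirality is
never reported.

Catenation between two rings is measured by the Gauss linking number,
evaluated exactly for polygonal curves as a sum of signed solid angles over
segment pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from numba import njit

__all__ = [
    "ClosedCurve",
    "KnotDiagram",
    "KnotType",
    "TopologyError",
    "simplify_curve",
    "project_to_diagram",
    "reduce_diagram",
    "alexander_polynomial",
    "identify_knot",
    "linking_number",
    "catenation_partners",
    "KNOT_TABLE",
]


class TopologyError(ValueError):
    """Raised for malformed curves or irreducibly degenerate projections."""


# ---------------------------------------------------------------------------
# Closed polygonal curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClosedCurve:
    """An ordered closed polygon in 3D; the last vertex bonds back to the first."""

    vertices: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 3:
            raise TopologyError("a closed curve needs >= 3 vertices of dimension 3")
        if not np.all(np.isfinite(v)):
            raise TopologyError("curve vertices must be finite")
        d = np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1)
        if np.any(d < 1e-12):
            raise TopologyError("consecutive vertices coincide")
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


# ---------------------------------------------------------------------------
# KMT-style simplification
# ---------------------------------------------------------------------------


@njit(cache=True)
def _removal_blocked(verts, ip, i, inx, scale_tol):
    """Is the triangle (ip, i, inx) pierced by any non-incident segment?

    A segment blocks the removal of vertex i when it crosses the triangle
    plane transversally with the intersection point inside the triangle.
    Grazing contacts (an endpoint lying in the plane) never count; coplanar
    segments cannot pierce.  Degenerate (collinear) triangles block nothing.
    """
    n = verts.shape[0]
    p0 = verts[ip]
    p1 = verts[i]
    p2 = verts[inx]
    e1 = p1 - p0
    e2 = p2 - p0
    nx = e1[1] * e2[2] - e1[2] * e2[1]
    ny = e1[2] * e2[0] - e1[0] * e2[2]
    nz = e1[0] * e2[1] - e1[1] * e2[0]
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    if nn < scale_tol * scale_tol:
        return False  # collinear triangle: chord replaces edges exactly
    nx /= nn
    ny /= nn
    nz /= nn
    tol = scale_tol
    for j in range(n):
        if j == ip or j == i:
            continue  # the two edges being removed
        j2 = (j + 1) % n
        a = verts[j]
        b = verts[j2]
        da = (a[0] - p0[0]) * nx + (a[1] - p0[1]) * ny + (a[2] - p0[2]) * nz
        db = (b[0] - p0[0]) * nx + (b[1] - p0[1]) * ny + (b[2] - p0[2]) * nz
        if da > tol and db > tol:
            continue
        if da < -tol and db < -tol:
            continue
        if abs(da) <= tol and abs(db) <= tol:
            continue  # coplanar segment: cannot pierce a simple curve
        if abs(da) <= tol or abs(db) <= tol:
            continue  # grazing endpoint contact
        t = da / (da - db)
        qx = a[0] + t * (b[0] - a[0])
        qy = a[1] + t * (b[1] - a[1])
        qz = a[2] + t * (b[2] - a[2])
        # barycentric test (conservative: near-boundary counts as inside)
        v0x, v0y, v0z = e1[0], e1[1], e1[2]
        v1x, v1y, v1z = e2[0], e2[1], e2[2]
        v2x, v2y, v2z = qx - p0[0], qy - p0[1], qz - p0[2]
        d00 = v0x * v0x + v0y * v0y + v0z * v0z
        d01 = v0x * v1x + v0y * v1y + v0z * v1z
        d11 = v1x * v1x + v1y * v1y + v1z * v1z
        d20 = v2x * v0x + v2y * v0y + v2z * v0z
        d21 = v2x * v1x + v2y * v1y + v2z * v1z
        denom = d00 * d11 - d01 * d01
        if abs(denom) < 1e-30:
            continue
        u = (d11 * d20 - d01 * d21) / denom
        w = (d00 * d21 - d01 * d20) / denom
        eps = 1e-9
        if u >= -eps and w >= -eps and u + w <= 1.0 + eps:
            return True
    return False


def simplify_curve(curve: ClosedCurve, rng=None, max_passes: int = 200) -> ClosedCurve:
    """Reduce the vertex count of ``curve`` without changing its knot type.

    Vertices are visited in a randomised order; vertex i is dropped when the
    triangle spanned by its neighbours is not pierced by any other segment,
    which guarantees the chord deformation sweeps no other part of the chain.
    Iterates until a full pass removes nothing.  Worst case returns the input.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    verts = np.array(curve.vertices, dtype=float)
    scale = float(np.max(np.abs(verts)) + 1.0)
    tol = 1e-9 * scale
    for _ in range(max_passes):
        n = len(verts)
        if n == 3:
            break
        removed_any = False
        order = rng.permutation(n)
        alive = np.ones(n, dtype=bool)
        for i in order:
            n_alive = int(alive.sum())
            if n_alive <= 3:
                break
            if not alive[i]:
                continue
            idx = np.flatnonzero(alive)
            pos = int(np.searchsorted(idx, i))
            cur = verts[idx]
            ip = (pos - 1) % n_alive
            inx = (pos + 1) % n_alive
            if not _removal_blocked(cur, ip, pos, inx, tol):
                alive[i] = False
                removed_any = True
        verts = verts[alive]
        if not removed_any:
            break
    return ClosedCurve(verts)


# ---------------------------------------------------------------------------
# Planar crossing diagrams
# ---------------------------------------------------------------------------


@dataclass
class KnotDiagram:
    """A knot diagram as an oriented Gauss code.

    ``entries`` lists, in order along the curve, tuples
    ``(crossing_id, is_over)``; each crossing id appears exactly twice, once
    over and once under.  ``signs`` maps crossing id to its sign (+1 for a
    right-handed crossing).
    """

    entries: list
    signs: dict
    direction: np.ndarray | None = None

    @property
    def n_crossings(self) -> int:
        return len(self.entries) // 2

    @property
    def gauss_code(self) -> list:
        return [
            (cid, "o" if over else "u", self.signs[cid]) for cid, over in self.entries
        ]

    def validate(self):
        seen = {}
        for cid, over in self.entries:
            seen.setdefault(cid, []).append(over)
        for cid, overs in seen.items():
            if sorted(overs) != [False, True]:
                raise TopologyError(f"crossing {cid} is not visited once over, once under")


class _Degenerate(Exception):
    pass


def _project_once(verts: np.ndarray, direction: np.ndarray) -> KnotDiagram:
    u = direction / np.linalg.norm(direction)
    # orthonormal basis for the projection plane
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    xy = verts @ np.stack([e1, e2], axis=1)
    z = verts @ u
    n = len(verts)
    scale = float(np.max(np.abs(xy)) + 1.0)
    eps = 1e-9
    crossings = []  # (i, s, j, t, over_is_i, sign)
    for i in range(n):
        p = xy[i]
        r = xy[(i + 1) % n] - p
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):
                continue
            q = xy[j]
            s = xy[(j + 1) % n] - q
            denom = r[0] * s[1] - r[1] * s[0]
            lr = math.hypot(r[0], r[1])
            ls = math.hypot(s[0], s[1])
            if abs(denom) < 1e-12 * lr * ls:
                # parallel segments: degenerate only if they overlap
                d = q - p
                if abs(d[0] * r[1] - d[1] * r[0]) < eps * scale * lr:
                    raise _Degenerate
                continue
            d = q - p
            t1 = (d[0] * s[1] - d[1] * s[0]) / denom
            t2 = (d[0] * r[1] - d[1] * r[0]) / denom
            if -eps < t1 < eps or 1 - eps < t1 < 1 + eps:
                if -2 * eps < t2 < 1 + 2 * eps:
                    raise _Degenerate
                continue
            if -eps < t2 < eps or 1 - eps < t2 < 1 + eps:
                if -2 * eps < t1 < 1 + 2 * eps:
                    raise _Degenerate
                continue
            if 0 < t1 < 1 and 0 < t2 < 1:
                zi = z[i] + t1 * (z[(i + 1) % n] - z[i])
                zj = z[j] + t2 * (z[(j + 1) % n] - z[j])
                if abs(zi - zj) < 1e-9 * scale:
                    raise _Degenerate
                over_is_i = zi > zj
                if over_is_i:
                    sign = 1 if (r[0] * s[1] - r[1] * s[0]) > 0 else -1
                else:
                    sign = 1 if (s[0] * r[1] - s[1] * r[0]) > 0 else -1
                crossings.append((i, t1, j, t2, over_is_i, sign))
    events = []  # (segment, param, crossing_id, is_over)
    signs = {}
    for cid, (i, t1, j, t2, over_is_i, sign) in enumerate(crossings):
        events.append((i, t1, cid, over_is_i))
        events.append((j, t2, cid, not over_is_i))
        signs[cid] = sign
    events.sort(key=lambda e: (e[0], e[1]))
    entries = [(cid, over) for _, _, cid, over in events]
    return KnotDiagram(entries=entries, signs=signs, direction=u)


def project_to_diagram(
    curve: ClosedCurve, direction, rng=None, max_perturb: int = 100
) -> KnotDiagram:
    """Project ``curve`` along ``direction`` into a crossing diagram.

    Over/under assignment follows depth along the projection direction; signs
    follow the right-handed convention.  Non-generic directions (tangencies,
    near-coincident crossings) are perturbed until a generic one is found.
    """
    rng = np.random.default_rng(12345) if rng is None else rng
    d = np.asarray(direction, dtype=float)
    if np.linalg.norm(d) < 1e-12:
        raise TopologyError("projection direction must be a nonzero vector")
    for _ in range(max_perturb):
        try:
            return _project_once(curve.vertices, d)
        except _Degenerate:
            d = d / np.linalg.norm(d) + 0.02 * rng.standard_normal(3)
    raise TopologyError("no generic projection found after perturbations")


def reduce_diagram(diagram: KnotDiagram) -> KnotDiagram:
    """Apply Reidemeister I and II reductions until the Gauss code is stable."""
    entries = list(diagram.entries)
    signs = dict(diagram.signs)

    def drop(cids):
        nonlocal entries
        entries = [e for e in entries if e[0] not in cids]
        for c in cids:
            signs.pop(c, None)

    changed = True
    while changed and entries:
        changed = False
        m = len(entries)
        # R1: the two visits of a crossing are adjacent along the curve
        for p in range(m):
            a = entries[p]
            b = entries[(p + 1) % m]
            if a[0] == b[0]:
                drop({a[0]})
                changed = True
                break
        if changed:
            continue
        # R2: a bigon — two crossings adjacent along both strands, one strand
        # passing over both and the other under both
        adj = {}
        for p in range(m):
            a = entries[p]
            b = entries[(p + 1) % m]
            if a[0] == b[0]:
                continue
            key = frozenset((a[0], b[0]))
            adj.setdefault(key, []).append((a[1], b[1]))
        for key, visits in adj.items():
            if len(visits) < 2:
                continue
            flags = [set(v) for v in visits]
            if {True} in flags and {False} in flags:
                drop(set(key))
                changed = True
                break
    return KnotDiagram(entries=entries, signs=signs, direction=diagram.direction)


# ---------------------------------------------------------------------------
# Alexander polynomial
# ---------------------------------------------------------------------------


def _int_det_bareiss(m: list) -> int:
    """Exact determinant of a square integer matrix (fraction-free Bareiss)."""
    a = [row[:] for row in m]
    n = len(a)
    if n == 0:
        return 1
    sign = 1
    prev = 1
    for k in range(n - 1):
        if a[k][k] == 0:
            for r in range(k + 1, n):
                if a[r][k] != 0:
                    a[k], a[r] = a[r], a[k]
                    sign = -sign
                    break
            else:
                return 0
        for i in range(k + 1, n):
            for j in range(k + 1, n):
                a[i][j] = (a[i][j] * a[k][k] - a[i][k] * a[k][j]) // prev
        prev = a[k][k]
    return sign * a[n - 1][n - 1]


def _normalize_alexander(coeffs: list) -> tuple:
    c = list(coeffs)
    while c and c[0] == 0:
        c.pop(0)
    while c and c[-1] == 0:
        c.pop()
    if not c:
        return (0,)
    if c[-1] < 0:
        c = [-x for x in c]
    return tuple(c)


def _crossing_matrix_rows(diagram: KnotDiagram) -> list:
    """Wirtinger crossing matrix over Z[t]; entry (c0, c1) means c0 + c1*t."""
    diagram.validate()
    entries = diagram.entries
    under_pos = [p for p, (cid, over) in enumerate(entries) if not over]
    n_arcs = len(under_pos)

    def arc_of(pos: int) -> int:
        # arc k starts just after the k-th under event (cyclically)
        import bisect

        k = bisect.bisect_left(under_pos, pos)
        return (k - 1) % n_arcs

    over_of = {}
    for p, (cid, over) in enumerate(entries):
        if over:
            over_of[cid] = arc_of(p)
    rows = []
    for k, p in enumerate(under_pos):
        cid, _ = entries[p]
        a_in = (k - 1) % n_arcs
        a_out = k
        c = over_of[cid]
        row = [[0, 0] for _ in range(n_arcs)]
        if diagram.signs[cid] > 0:
            row[a_in][1] += 1  # t * a
            row[c][0] += 1  # (1 - t) * c
            row[c][1] -= 1
            row[a_out][0] -= 1  # -b
        else:
            row[a_in][0] += 1  # a
            row[c][0] -= 1  # (t - 1) * c
            row[c][1] += 1
            row[a_out][1] -= 1  # -t * b
        rows.append(row)
    return rows


def alexander_polynomial(diagram: KnotDiagram) -> tuple:
    """Alexander polynomial of a knot diagram, as integer coefficients.

    Built from the Wirtinger-presentation crossing matrix: at a positive
    crossing with over-arc c, incoming under-arc a and outgoing under-arc b
    the relation is  t*a + (1-t)*c - b = 0 ; at a negative crossing,
    a + (t-1)*c - t*b = 0.  Any (n-1)x(n-1) minor's determinant equals the
    polynomial up to a unit; the result is normalised to lowest degree 0 and
    positive leading coefficient.  The determinant of the knot is the
    absolute value at t = -1.
    """
    diagram = reduce_diagram(diagram)
    n = diagram.n_crossings
    if n == 0:
        return (1,)
    rows = _crossing_matrix_rows(diagram)
    # minor: delete last row and column
    size = n - 1
    if size == 0:
        return (1,)
    # determinant of a polynomial matrix by exact evaluation + interpolation
    deg_bound = size + 1
    points = list(range(2, 2 + deg_bound))
    values = []
    for t in points:
        mat = [[rows[i][j][0] + rows[i][j][1] * t for j in range(size)] for i in range(size)]
        values.append(_int_det_bareiss(mat))
    # Lagrange interpolation with exact rationals
    coeffs = [Fraction(0)] * deg_bound
    for xi, yi in zip(points, values):
        basis = [Fraction(1)]
        denom = Fraction(1)
        for xj in points:
            if xj == xi:
                continue
            new = [Fraction(0)] * (len(basis) + 1)
            for d, c in enumerate(basis):
                new[d] -= c * xj
                new[d + 1] += c
            basis = new
            denom *= xi - xj
        for d, c in enumerate(basis):
            coeffs[d] += yi * c / denom
    out = []
    for c in coeffs:
        assert c.denominator == 1
        out.append(int(c))
    return _normalize_alexander(out)


def knot_determinant(coeffs) -> int:
    return abs(sum(c * (-1) ** k for k, c in enumerate(coeffs)))


def diagram_determinant(diagram: KnotDiagram) -> int:
    """|Alexander polynomial at t = -1| straight from the crossing matrix.

    One integer determinant instead of a full polynomial interpolation, so
    it stays fast for the large diagrams of dense equilibrated rings.
    """
    diagram = reduce_diagram(diagram)
    n = diagram.n_crossings
    if n == 0:
        return 1
    rows = _crossing_matrix_rows(diagram)
    size = n - 1
    if size == 0:
        return 1
    mat = [[rows[i][j][0] - rows[i][j][1] for j in range(size)] for i in range(size)]
    return abs(_int_det_bareiss(mat))


# ---------------------------------------------------------------------------
# Prime-knot invariant table (Alexander-Briggs names, <= 8 crossings, plus
# the small torus knots that occur as clean generator outputs)
# ---------------------------------------------------------------------------

# name -> (min_crossings, alexander coefficients, determinant)
KNOT_TABLE = {
    "3_1": (3, (1, -1, 1), 3),
    "4_1": (4, (1, -3, 1), 5),
    "5_1": (5, (1, -1, 1, -1, 1), 5),
    "5_2": (5, (2, -3, 2), 7),
    "6_1": (6, (2, -5, 2), 9),
    "6_2": (6, (1, -3, 3, -3, 1), 11),
    "6_3": (6, (1, -3, 5, -3, 1), 13),
    "7_1": (7, (1, -1, 1, -1, 1, -1, 1), 7),
    "7_2": (7, (3, -5, 3), 11),
    "7_3": (7, (2, -3, 3, -3, 2), 13),
    "7_4": (7, (4, -7, 4), 15),
    "7_5": (7, (2, -4, 5, -4, 2), 17),
    "7_6": (7, (1, -5, 7, -5, 1), 19),
    "7_7": (7, (1, -5, 9, -5, 1), 21),
    "8_1": (8, (3, -7, 3), 13),
    "8_2": (8, (1, -3, 3, -3, 3, -3, 1), 17),
    "8_3": (8, (4, -9, 4), 17),
    "8_4": (8, (2, -5, 5, -5, 2), 19),
    "8_5": (8, (1, -3, 4, -5, 4, -3, 1), 21),
    "8_6": (8, (2, -6, 7, -6, 2), 23),
    "8_7": (8, (1, -3, 5, -5, 5, -3, 1), 23),
    "8_8": (8, (2, -6, 9, -6, 2), 25),
    "8_9": (8, (1, -3, 5, -7, 5, -3, 1), 25),
    "8_10": (8, (1, -3, 6, -7, 6, -3, 1), 27),
    "8_11": (8, (2, -7, 9, -7, 2), 27),
    "8_12": (8, (1, -7, 13, -7, 1), 29),
    "8_13": (8, (2, -7, 11, -7, 2), 29),
    "8_14": (8, (2, -8, 11, -8, 2), 31),
    "8_15": (8, (3, -8, 11, -8, 3), 33),
    "8_16": (8, (1, -4, 8, -9, 8, -4, 1), 35),
    "8_17": (8, (1, -4, 8, -11, 8, -4, 1), 37),
    "8_18": (8, (1, -5, 10, -13, 10, -5, 1), 45),
    "8_19": (8, (1, -1, 0, 1, 0, -1, 1), 3),  # torus knot T(3,4)
    "8_20": (8, (1, -2, 3, -2, 1), 9),
    "8_21": (8, (1, -4, 5, -4, 1), 15),
    "9_1": (9, (1, -1, 1, -1, 1, -1, 1, -1, 1), 9),  # torus knot T(2,9)
    "10_124": (10, (1, -1, 0, 1, -1, 1, 0, -1, 1), 1),  # torus knot T(3,5)
}

_TABLE_BY_POLY: dict = {}
for _name, (_cr, _poly, _det) in KNOT_TABLE.items():
    _TABLE_BY_POLY.setdefault(_poly, []).append(_name)
for _poly, _names in _TABLE_BY_POLY.items():
    _names.sort(key=lambda s: (int(s.split("_")[0]), int(s.split("_")[1])))


def _poly_mul(a, b):
    out = [0] * (len(a) + len(b) - 1)
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            out[i + j] += x * y
    return tuple(out)


def _poly_divide_exact(num, den):
    """Exact division of integer polynomials; None if not divisible."""
    num = list(num)
    den = list(den)
    if len(den) > len(num):
        return None
    q = [0] * (len(num) - len(den) + 1)
    r = num[:]
    for k in range(len(q) - 1, -1, -1):
        lead = r[k + len(den) - 1]
        if lead % den[-1] != 0:
            return None
        q[k] = lead // den[-1]
        for j, d in enumerate(den):
            r[k + j] -= q[k] * d
    if any(r):
        return None
    return tuple(q)


def _composite_decompose(poly: tuple, max_parts: int = 3):
    """Greedy factorisation of an Alexander polynomial into table entries.

    Heuristic: the Alexander polynomial of a connected sum is the product of
    the components' polynomials, but a factorisation does not certify a
    connected sum, so callers flag composite names accordingly.
    """
    table_polys = sorted(
        {(p, names[0]) for p, names in _TABLE_BY_POLY.items()},
        key=lambda it: (KNOT_TABLE[it[1]][0], it[1]),
    )

    def search(rem, parts):
        if rem == (1,):
            return parts if len(parts) >= 2 else None
        if len(parts) >= max_parts:
            return None
        for p, name in table_polys:
            q = _poly_divide_exact(rem, p)
            if q is None:
                q = _poly_divide_exact(rem, tuple(reversed(p)))
            if q is not None:
                got = search(_normalize_alexander(q), parts + [name])
                if got is not None:
                    return got
        return None

    return search(poly, [])


# ---------------------------------------------------------------------------
# Knot identification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KnotType:
    """A named knot type with the invariants that produced the name."""

    name: str
    crossing_estimate: int
    determinant: int
    alexander_coeffs: tuple
    candidates: tuple = ()
    is_composite: bool = False
    ambiguous: bool = False

    def __str__(self) -> str:
        return self.name


def _candidate_directions(verts: np.ndarray, k: int, rng) -> list:
    """Projection directions: the curve's principal axes, then random units.

    Principal axes of the vertex covariance are included because symmetric
    knots (torus knots in particular) project near-minimally along their
    symmetry axis; random directions cover the general case.
    """
    centred = verts - verts.mean(axis=0)
    cov = centred.T @ centred
    _, vecs = np.linalg.eigh(cov)
    dirs = [vecs[:, i] for i in range(3)]
    while len(dirs) < k:
        v = rng.standard_normal(3)
        nv = np.linalg.norm(v)
        if nv > 1e-6:
            dirs.append(v / nv)
    return dirs[:k]


def minimal_diagram(
    curve: ClosedCurve, n_directions: int = 10, seed: int = 0, presimplified: bool = False
) -> KnotDiagram:
    """Fully simplified diagram: KMT reduction, then the Reidemeister-reduced
    projection of minimal crossing number over seeded generic directions."""
    rng = np.random.default_rng(seed)
    simple = curve if presimplified else simplify_curve(curve, rng=rng)
    best = None
    for d in _candidate_directions(simple.vertices, n_directions, rng):
        dia = reduce_diagram(project_to_diagram(simple, d, rng=rng))
        if best is None or dia.n_crossings < best.n_crossings:
            best = dia
        if best.n_crossings == 0:
            break
    return best


def identify_knot(
    curve: ClosedCurve, n_directions: int = 10, seed: int = 0
) -> KnotType:
    """Name the knot type of a closed curve.

    The fully simplified minimal diagram supplies the crossing estimate (an
    upper bound on the minimal crossing number) and the Alexander polynomial;
    names come from the bundled prime table, composite names from polynomial
    factorisation.  Diagrams still above 12 crossings are "unclassified", as
    are trivial-polynomial diagrams that did not reach 0 crossings.
    """
    dia = minimal_diagram(curve, n_directions=n_directions, seed=seed)
    ce = dia.n_crossings
    if ce == 0:
        return KnotType("0_1", 0, 1, (1,))
    if ce > 16:
        # too complex to classify anyway; the full polynomial interpolation
        # is expensive here, so record the determinant invariant only
        return KnotType("unclassified", ce, diagram_determinant(dia), ())
    poly = alexander_polynomial(dia)
    det = knot_determinant(poly)
    if ce > 12:
        return KnotType("unclassified", ce, det, poly)
    if poly == (1,):
        # trivial invariants but a residual diagram: cannot certify the unknot
        return KnotType("unclassified", ce, det, poly, candidates=("0_1",), ambiguous=True)
    # hypotheses consistent with the crossing estimate (an upper bound on the
    # minimal crossing number, so entries needing more crossings are excluded)
    primes = _TABLE_BY_POLY.get(poly) or _TABLE_BY_POLY.get(tuple(reversed(poly))) or []
    hyps = [(KNOT_TABLE[nm][0], nm, False) for nm in primes if KNOT_TABLE[nm][0] <= ce]
    parts = _composite_decompose(poly)
    if parts:
        parts.sort(key=lambda s: (KNOT_TABLE[s][0], int(s.split("_")[1])))
        total_cr = sum(KNOT_TABLE[p][0] for p in parts)
        if total_cr <= ce:
            hyps.append((total_cr, "#".join(parts), True))
    if not hyps:
        return KnotType("unclassified", ce, det, poly)
    hyps.sort(key=lambda h: h[0])
    _, name, comp = hyps[0]
    if len(hyps) == 1:
        return KnotType(name, ce, det, poly, is_composite=comp)
    return KnotType(
        name,
        ce,
        det,
        poly,
        candidates=tuple(h[1] for h in hyps),
        is_composite=comp,
        ambiguous=True,
    )


# ---------------------------------------------------------------------------
# Gauss linking number and catenation
# ---------------------------------------------------------------------------


@njit(cache=True)
def _gauss_linking_sum(a, b):
    """Sum of signed solid angles over segment pairs, in units of 4*pi.

    Uses the exact two-segment Gauss-integral formula (solid angle of the
    quadrilateral spanned by the four endpoints).
    """
    na = a.shape[0]
    nb = b.shape[0]
    total = 0.0
    for i in range(na):
        p1 = a[i]
        p2 = a[(i + 1) % na]
        for j in range(nb):
            p3 = b[j]
            p4 = b[(j + 1) % nb]
            r13 = p3 - p1
            r14 = p4 - p1
            r23 = p3 - p2
            r24 = p4 - p2
            n1x = r13[1] * r14[2] - r13[2] * r14[1]
            n1y = r13[2] * r14[0] - r13[0] * r14[2]
            n1z = r13[0] * r14[1] - r13[1] * r14[0]
            n2x = r14[1] * r24[2] - r14[2] * r24[1]
            n2y = r14[2] * r24[0] - r14[0] * r24[2]
            n2z = r14[0] * r24[1] - r14[1] * r24[0]
            n3x = r24[1] * r23[2] - r24[2] * r23[1]
            n3y = r24[2] * r23[0] - r24[0] * r23[2]
            n3z = r24[0] * r23[1] - r24[1] * r23[0]
            n4x = r23[1] * r13[2] - r23[2] * r13[1]
            n4y = r23[2] * r13[0] - r23[0] * r13[2]
            n4z = r23[0] * r13[1] - r23[1] * r13[0]
            l1 = math.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
            l2 = math.sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
            l3 = math.sqrt(n3x * n3x + n3y * n3y + n3z * n3z)
            l4 = math.sqrt(n4x * n4x + n4y * n4y + n4z * n4z)
            if l1 < 1e-14 or l2 < 1e-14 or l3 < 1e-14 or l4 < 1e-14:
                continue
            d12 = (n1x * n2x + n1y * n2y + n1z * n2z) / (l1 * l2)
            d23 = (n2x * n3x + n2y * n3y + n2z * n3z) / (l2 * l3)
            d34 = (n3x * n4x + n3y * n4y + n3z * n4z) / (l3 * l4)
            d41 = (n4x * n1x + n4y * n1y + n4z * n1z) / (l4 * l1)
            d12 = min(1.0, max(-1.0, d12))
            d23 = min(1.0, max(-1.0, d23))
            d34 = min(1.0, max(-1.0, d34))
            d41 = min(1.0, max(-1.0, d41))
            omega = math.asin(d12) + math.asin(d23) + math.asin(d34) + math.asin(d41)
            r34x = p4[0] - p3[0]
            r34y = p4[1] - p3[1]
            r34z = p4[2] - p3[2]
            r12x = p2[0] - p1[0]
            r12y = p2[1] - p1[1]
            r12z = p2[2] - p1[2]
            cx = r34x * r12z - r34z * r12y  # placeholder, recomputed below
            # cross(r34, r12)
            cx = r34y * r12z - r34z * r12y
            cy = r34z * r12x - r34x * r12z
            cz = r34x * r12y - r34y * r12x
            s = cx * r13[0] + cy * r13[1] + cz * r13[2]
            if s > 0:
                total += omega
            elif s < 0:
                total -= omega
    return total / (4.0 * math.pi)


def linking_number(a: ClosedCurve, b: ClosedCurve) -> int:
    """Gauss linking number of two disjoint closed curves (exact integer)."""
    va = np.ascontiguousarray(a.vertices)
    vb = np.ascontiguousarray(b.vertices)
    # reject shared/intersecting points
    from scipy.spatial import cKDTree

    if cKDTree(va).query(vb, k=1)[0].min() < 1e-9:
        raise TopologyError("curves share points; linking number undefined")
    raw = _gauss_linking_sum(va, vb)
    lk = int(round(raw))
    if abs(raw - lk) > 0.05:
        raise TopologyError(
            f"Gauss sum {raw:.4f} is far from an integer; curves may intersect"
        )
    return lk


def catenation_partners(curves: list) -> list:
    """Number of other rings each ring is catenated with (|Lk| > 0)."""
    n = len(curves)
    counts = [0] * n
    for i in range(n):
        for j in range(i + 1, n):
            if linking_number(curves[i], curves[j]) != 0:
                counts[i] += 1
                counts[j] += 1
    return counts


def linking_matrix(curves: list) -> np.ndarray:
    n = len(curves)
    m = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            lk = linking_number(curves[i], curves[j])
            m[i, j] = lk
            m[j, i] = lk
    return m
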