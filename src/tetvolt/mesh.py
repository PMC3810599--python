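"""Tetrahedral mesh core: representation, I/O, measures and fixture generators.

The mesh is the geometric substrate for the vertex-centered finite-volume
potential solver: potentials live on vertices, membrane capacitance and
channels live on boundary triangles.  All quantities are strict SI
(coordinates in metres, volumes in m^3, areas in m^2).

Two fixture generators are provided so that no external mesher is needed:
a structured prism-stack cylinder (polygonal approximation of a circular
cross-section) and a symmetric binary tree obeying the 3/2 branching power
law, built from cylinder segments joined by conforming junction plugs.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = [
    "MeshError",
    "MeshParseError",
    "TetMesh",
    "MembraneSurface",
    "CompartmentProps",
    "tet_volume",
    "triangle_areas",
    "read_mesh",
    "write_tetgen",
    "write_msh2",
    "CylinderFixture",
    "BranchedFixture",
    "generate_cylinder_mesh",
    "generate_branched_mesh",
    "surface_correction_factor",
]

# faces of a positively oriented tet (v0,v1,v2,v3), wound outward
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


class MeshError(ValueError):
    """Invalid mesh content (degenerate or non-conforming)."""


class MeshParseError(ValueError):
    """Malformed mesh file; message names the file and line."""


def tet_volume(p, a, b, c) -> float:
    """Volume of the tetrahedron (p, a, b, c): ``|det[a-p, b-p, c-p]| / 6``.

    Zero is a legal return (degenerate input); the caller validates.
    """
    p = np.asarray(p, dtype=float)
    m = np.stack([np.asarray(a, float) - p,
                  np.asarray(b, float) - p,
                  np.asarray(c, float) - p])
    return abs(float(np.linalg.det(m))) / 6.0


def triangle_areas(vertices: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Areas of triangles given as index triples into ``vertices``."""
    v = vertices[tris]
    n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    return 0.5 * np.linalg.norm(n, axis=1)


@dataclass(eq=False)
class TetMesh:
    """Tetrahedral mesh with canonical (positive) tet orientation.

    ``boundary_tris`` are the triangles belonging to exactly one tet, wound
    so their normals point out of the mesh.
    """

    vertices: np.ndarray  # (n, 3) float64, metres
    tets: np.ndarray      # (m, 4) int64

    @classmethod
    def from_arrays(cls, vertices, tets, validate: bool = True) -> "TetMesh":
        vertices = np.ascontiguousarray(vertices, dtype=np.float64)
        tets = np.ascontiguousarray(tets, dtype=np.int64)
        if vertices.ndim != 2 or vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if tets.ndim != 2 or tets.shape[1] != 4:
            raise MeshError("tets must be an (m, 4) array")
        if tets.size and (tets.min() < 0 or tets.max() >= len(vertices)):
            raise MeshError("tet vertex index out of range")
        # canonical orientation: swap last two vertices where det < 0
        v = vertices[tets]
        det = np.linalg.det(v[:, 1:] - v[:, :1])
        neg = det < 0
        tets = tets.copy()
        tets[neg] = tets[neg][:, [0, 1, 3, 2]]
        mesh = cls(vertices=vertices, tets=tets)
        if validate:
            mesh.validate()
        return mesh

    # ---- derived geometry -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    @cached_property
    def tet_volumes(self) -> np.ndarray:
        v = self.vertices[self.tets]
        return np.linalg.det(v[:, 1:] - v[:, :1]) / 6.0

    @cached_property
    def _faces(self):
        """All oriented faces, their owner tet, and multiplicity data."""
        faces = self.tets[:, _TET_FACES]            # (m, 4, 3) outward wound
        faces = faces.reshape(-1, 3)
        owner = np.repeat(np.arange(self.n_tets), 4)
        key = np.sort(faces, axis=1)
        order = np.lexsort(key.T[::-1])
        key_sorted = key[order]
        new_group = np.any(np.diff(key_sorted, axis=0) != 0, axis=1)
        group_id = np.concatenate([[0], np.cumsum(new_group)])
        counts = np.bincount(group_id)
        return faces, owner, order, group_id, counts

    @cached_property
    def boundary_tris(self) -> np.ndarray:
        """Outward-wound triangles that belong to exactly one tet."""
        faces, _, order, group_id, counts = self._faces
        single = counts[group_id] == 1
        return faces[order[single]]

    @cached_property
    def boundary_tri_tets(self) -> np.ndarray:
        """For each boundary triangle, the index of its (inner) tet."""
        _, owner, order, group_id, counts = self._faces
        single = counts[group_id] == 1
        return owner[order[single]]

    @cached_property
    def boundary_tri_areas(self) -> np.ndarray:
        return triangle_areas(self.vertices, self.boundary_tris)

    @cached_property
    def edges(self) -> np.ndarray:
        """Unique mesh edges as (n_edges, 2) with u < v."""
        pairs = self.tets[:, [[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]]]
        pairs = np.sort(pairs.reshape(-1, 2), axis=1)
        return np.unique(pairs, axis=0)

    @property
    def volume(self) -> float:
        return float(self.tet_volumes.sum())

    def volume_by_divergence(self) -> float:
        """Mesh volume as a surface integral over the oriented boundary.

        Independent geometric oracle for the sum of tet volumes: by the
        divergence theorem ``V = (1/6) sum_T v0 . (v1 x v2)`` over outward
        boundary triangles.
        """
        v = self.vertices[self.boundary_tris]
        return float(np.einsum("ij,ij->", v[:, 0],
                               np.cross(v[:, 1], v[:, 2])) / 6.0)

    def validate(self) -> None:
        vols = self.tet_volumes
        scale = float(np.abs(self.vertices).max() or 1.0) ** 3
        bad = np.nonzero(vols <= 1e-14 * scale)[0]
        if bad.size:
            raise MeshError(
                f"degenerate (zero-volume) tetrahedra: ids {bad[:10].tolist()}"
                + ("..." if bad.size > 10 else ""))
        _, _, _, group_id, counts = self._faces
        if counts.size and counts.max() > 2:
            raise MeshError("non-conforming mesh: a triangle is shared by "
                            f"{int(counts.max())} tets")
        vsum = self.volume
        vdiv = self.volume_by_divergence()
        if not math.isclose(vsum, vdiv, rel_tol=1e-10):
            raise MeshError(
                f"tet volume sum {vsum!r} disagrees with divergence-theorem "
                f"volume {vdiv!r}; mesh is tangled or inverted")

    def relabel(self, perm: np.ndarray) -> "TetMesh":
        """Return a mesh with vertex i renamed to perm[i]."""
        perm = np.asarray(perm)
        new_vertices = np.empty_like(self.vertices)
        new_vertices[perm] = self.vertices
        return TetMesh.from_arrays(new_vertices, perm[self.tets],
                                   validate=False)


@dataclass(eq=False)
class CompartmentProps:
    """Bulk electrical properties of one intracellular compartment."""

    sigma: float               # cytoplasmic conductivity, S/m
    leak_g: float = 0.0        # membrane leak conductance per area, S/m^2
    leak_e: float = 0.0        # leak reversal potential, V

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("conductivity sigma must be > 0")


@dataclass(eq=False)
class MembraneSurface:
    """A set of mesh boundary triangles carrying capacitance and channels.

    ``tri_indices`` index into ``mesh.boundary_tris``.  Every triangle has a
    defined inner tetrahedron; the outer side is the earthed bath unless an
    outer tet mapping is supplied (internal membranes are out of scope).
    """

    mesh: TetMesh
    tri_indices: np.ndarray
    c_spec: float = 0.01       # specific capacitance, F/m^2 (1 uF/cm^2)
    outer: str = "bath"

    def __post_init__(self):
        self.tri_indices = np.unique(np.asarray(self.tri_indices,
                                                dtype=np.int64))
        nb = len(self.mesh.boundary_tris)
        if self.tri_indices.size == 0:
            raise MeshError("membrane must contain at least one triangle")
        if self.tri_indices.min() < 0 or self.tri_indices.max() >= nb:
            raise MeshError("membrane triangle index out of range")

    @cached_property
    def tris(self) -> np.ndarray:
        return self.mesh.boundary_tris[self.tri_indices]

    @cached_property
    def inner_tets(self) -> np.ndarray:
        return self.mesh.boundary_tri_tets[self.tri_indices]

    @cached_property
    def tri_areas(self) -> np.ndarray:
        return self.mesh.boundary_tri_areas[self.tri_indices]

    @property
    def area(self) -> float:
        return float(self.tri_areas.sum())

    @cached_property
    def vertex_ids(self) -> np.ndarray:
        return np.unique(self.tris)

    def is_edge_connected(self) -> bool:
        """True when the triangles form a single edge-connected surface."""
        tris = self.tris
        k = len(tris)
        if k == 1:
            return True
        e = np.sort(tris[:, [[0, 1], [1, 2], [0, 2]]].reshape(-1, 2), axis=1)
        tri_of = np.repeat(np.arange(k), 3)
        order = np.lexsort(e.T[::-1])
        e, tri_of = e[order], tri_of[order]
        same = np.all(np.diff(e, axis=0) == 0, axis=1)
        parent = np.arange(k)

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in np.nonzero(same)[0]:
            a, b = find(tri_of[i]), find(tri_of[i + 1])
            parent[a] = b
        return len({find(i) for i in range(k)}) == 1

    def is_closed(self) -> bool:
        """True when every membrane-triangle edge is shared by two tris."""
        e = np.sort(self.tris[:, [[0, 1], [1, 2], [0, 2]]].reshape(-1, 2),
                    axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def restricted(self, tri_indices) -> "MembraneSurface":
        """Sub-membrane over a subset of this membrane's triangles."""
        sub = np.intersect1d(np.asarray(tri_indices, np.int64),
                             self.tri_indices)
        return MembraneSurface(self.mesh, sub, c_spec=self.c_spec,
                               outer=self.outer)


def surface_correction_factor(membrane, ideal_area: float) -> float:
    """Scale factor ``f = ideal_area / mesh_area``.

    Multiplying the specific capacitance and the leak conductance-per-area
    by ``f`` makes the total membrane capacitance and leak conductance equal
    those of the ideal (smooth) geometry, compensating the polygonal
    surface-area error of a tetrahedral mesh.
    """
    if ideal_area <= 0:
        raise ValueError("ideal_area must be > 0")
    mesh_area = membrane.area if isinstance(membrane, MembraneSurface) \
        else float(membrane)
    if mesh_area <= 0:
        raise ValueError("membrane has zero area")
    return ideal_area / mesh_area


# ---------------------------------------------------------------------------
# file I/O: TetGen .node/.ele and Gmsh MSH v2 ASCII
# ---------------------------------------------------------------------------

def _data_lines(path):
    """Yield (lineno, fields) for non-blank, non-comment lines."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.split("#", 1)[0].strip()
            if s:
                yield lineno, s.split()


def _parse_error(path, lineno, msg):
    raise MeshParseError(f"{path}:{lineno}: {msg}")


def _read_tetgen(prefix: str, index_base=None) -> TetMesh:
    node_path, ele_path = prefix + ".node", prefix + ".ele"
    for p in (node_path, ele_path):
        if not os.path.exists(p):
            raise MeshParseError(f"missing TetGen file: {p}")

    lines = _data_lines(node_path)
    try:
        lineno, hdr = next(lines)
    except StopIteration:
        raise MeshParseError(f"{node_path}: empty file")
    try:
        n_pts, dim = int(hdr[0]), int(hdr[1])
    except (IndexError, ValueError):
        _parse_error(node_path, lineno, "bad node header")
    if dim != 3:
        _parse_error(node_path, lineno, f"expected dimension 3, got {dim}")
    ids = np.empty(n_pts, dtype=np.int64)
    coords = np.empty((n_pts, 3))
    for i in range(n_pts):
        try:
            lineno, f = next(lines)
            ids[i] = int(f[0])
            coords[i] = [float(f[1]), float(f[2]), float(f[3])]
        except StopIteration:
            raise MeshParseError(f"{node_path}: truncated after {i} points")
        except (IndexError, ValueError):
            _parse_error(node_path, lineno, "bad node line")

    lines = _data_lines(ele_path)
    try:
        lineno, hdr = next(lines)
        n_tets, npt = int(hdr[0]), int(hdr[1])
    except StopIteration:
        raise MeshParseError(f"{ele_path}: empty file")
    except (IndexError, ValueError):
        _parse_error(ele_path, lineno, "bad element header")
    if npt != 4:
        _parse_error(ele_path, lineno, "only 4-node tetrahedra supported")
    tets = np.empty((n_tets, 4), dtype=np.int64)
    for i in range(n_tets):
        try:
            lineno, f = next(lines)
            tets[i] = [int(x) for x in f[1:5]]
        except StopIteration:
            raise MeshParseError(f"{ele_path}: truncated after {i} elements")
        except (IndexError, ValueError):
            _parse_error(ele_path, lineno, "bad element line")

    if index_base is None:  # sniff the dialect from the node numbering
        index_base = int(ids.min()) if n_pts else 0
        if index_base not in (0, 1):
            raise MeshParseError(
                f"{node_path}: node indices start at {index_base}; pass "
                "index_base explicitly")
    remap = {int(i): k for k, i in enumerate(ids)}
    if len(remap) != n_pts:
        raise MeshParseError(f"{node_path}: duplicate node ids")
    try:
        tets = np.array([[remap[int(v)] for v in t] for t in tets],
                        dtype=np.int64).reshape(n_tets, 4)
    except KeyError as exc:
        raise MeshParseError(
            f"{ele_path}: element references unknown node {exc.args[0]}")
    return TetMesh.from_arrays(coords, tets)


def write_tetgen(mesh: TetMesh, prefix: str, index_base: int = 1) -> None:
    b = index_base
    with open(prefix + ".node", "w") as fh:
        fh.write(f"{mesh.n_vertices} 3 0 0\n")
        for i, (x, y, z) in enumerate(mesh.vertices):
            fh.write(f"{i + b} {x:.17g} {y:.17g} {z:.17g}\n")
    with open(prefix + ".ele", "w") as fh:
        fh.write(f"{mesh.n_tets} 4 0\n")
        for i, t in enumerate(mesh.tets):
            fh.write(f"{i + b} {t[0] + b} {t[1] + b} {t[2] + b} {t[3] + b}\n")


def _read_msh2(path: str) -> TetMesh:
    coords, tets = None, []
    node_ids = None
    with open(path) as fh:
        raw = fh.readlines()
    i = 0
    n = len(raw)

    def expect(idx, token):
        if idx >= n or raw[idx].strip() != token:
            _parse_error(path, idx + 1, f"expected {token}")

    while i < n:
        tok = raw[i].strip()
        if tok == "$MeshFormat":
            parts = raw[i + 1].split()
            if not parts or not parts[0].startswith("2"):
                _parse_error(path, i + 2, "only MSH format 2.x ASCII "
                                          "is supported")
            expect(i + 2, "$EndMeshFormat")
            i += 3
        elif tok == "$Nodes":
            try:
                cnt = int(raw[i + 1])
            except (IndexError, ValueError):
                _parse_error(path, i + 2, "bad node count")
            node_ids = np.empty(cnt, dtype=np.int64)
            coords = np.empty((cnt, 3))
            for k in range(cnt):
                f = raw[i + 2 + k].split()
                try:
                    node_ids[k] = int(f[0])
                    coords[k] = [float(f[1]), float(f[2]), float(f[3])]
                except (IndexError, ValueError):
                    _parse_error(path, i + 3 + k, "bad node line")
            expect(i + 2 + cnt, "$EndNodes")
            i += 3 + cnt
        elif tok == "$Elements":
            try:
                cnt = int(raw[i + 1])
            except (IndexError, ValueError):
                _parse_error(path, i + 2, "bad element count")
            for k in range(cnt):
                f = raw[i + 2 + k].split()
                try:
                    etype, ntags = int(f[1]), int(f[2])
                    if etype == 4:  # 4-node tetrahedron
                        tets.append([int(v) for v in f[3 + ntags:7 + ntags]])
                except (IndexError, ValueError):
                    _parse_error(path, i + 3 + k, "bad element line")
            expect(i + 2 + cnt, "$EndElements")
            i += 3 + cnt
        else:
            i += 1
    if coords is None:
        raise MeshParseError(f"{path}: no $Nodes section")
    if not tets:
        raise MeshParseError(f"{path}: no tetrahedral elements")
    remap = {int(v): k for k, v in enumerate(node_ids)}
    tets = np.array([[remap[v] for v in t] for t in tets], dtype=np.int64)
    return TetMesh.from_arrays(coords, tets)


def write_msh2(mesh: TetMesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write(f"$Nodes\n{mesh.n_vertices}\n")
        for i, (x, y, z) in enumerate(mesh.vertices):
            fh.write(f"{i + 1} {x:.17g} {y:.17g} {z:.17g}\n")
        fh.write("$EndNodes\n")
        fh.write(f"$Elements\n{mesh.n_tets}\n")
        for i, t in enumerate(mesh.tets):
            fh.write(f"{i + 1} 4 2 0 0 "
                     f"{t[0] + 1} {t[1] + 1} {t[2] + 1} {t[3] + 1}\n")
        fh.write("$EndElements\n")


def read_mesh(path, format: str | None = None, index_base=None) -> TetMesh:
    """Read a tetrahedral mesh from TetGen (.node/.ele) or Gmsh MSH v2.

    ``path`` may be a .node, .ele or .msh file, or a TetGen file prefix.
    Indices are normalized to 0-based internally regardless of dialect;
    for TetGen the base is sniffed from the node numbering unless
    ``index_base`` is given.
    """
    path = str(path)
    if format is None:
        if path.endswith(".msh"):
            format = "msh2"
        elif path.endswith((".node", ".ele")) or os.path.exists(path + ".node"):
            format = "tetgen"
        else:
            raise MeshParseError(f"cannot infer mesh format of {path}")
    if format == "msh2":
        return _read_msh2(path)
    if format == "tetgen":
        prefix = path
        for suffix in (".node", ".ele"):
            if prefix.endswith(suffix):
                prefix = prefix[: -len(suffix)]
        return _read_tetgen(prefix, index_base=index_base)
    raise ValueError(f"unknown mesh format {format!r}")


# ---------------------------------------------------------------------------
# structured fixtures
# ---------------------------------------------------------------------------

def _split_prism(bottom, top):
    """Split a (convex) triangular prism into tetrahedra.

    Quad-face diagonals follow the global min-vertex rule so that the split
    is conforming across prisms sharing a quad; the prism is then coned from
    its smallest vertex onto the remaining boundary triangles.
    """
    a, b = tuple(bottom), tuple(top)
    v = min(a + b)
    tris = [a, b]
    for i in range(3):
        q = (a[i], a[(i + 1) % 3], b[(i + 1) % 3], b[i])
        if min(q) in (q[0], q[2]):
            tris += [(q[0], q[1], q[2]), (q[0], q[2], q[3])]
        else:
            tris += [(q[1], q[2], q[3]), (q[1], q[3], q[0])]
    return [(v,) + t for t in tris if v not in t]


@dataclass(eq=False)
class CylinderFixture:
    """Structured cylinder mesh plus its (closed) membrane surface."""

    mesh: TetMesh
    membrane: MembraneSurface          # full closed boundary
    lateral_tris: np.ndarray           # indices into mesh.boundary_tris
    cap0_tris: np.ndarray
    cap1_tris: np.ndarray
    end0_vertices: np.ndarray          # all vertices in the z=0 plane
    end1_vertices: np.ndarray
    length: float
    diameter: float
    polygon_order: int
    n_slices: int
    surface_area_error: float          # lateral area vs pi*d*L, relative

    @property
    def lateral_membrane(self) -> MembraneSurface:
        return self.membrane.restricted(self.lateral_tris)

    @property
    def ideal_lateral_area(self) -> float:
        return math.pi * self.diameter * self.length


def _cylinder_layout(length, diameter, target_ntets):
    # choose the polygon order so rim edge length ~ axial slice thickness
    k = int(round(math.sqrt(math.pi * diameter * target_ntets /
                            (3.0 * length))))
    k = min(max(k, 3), 96)
    s = max(1, int(round(target_ntets / (3.0 * k))))
    return k, s


def generate_cylinder_mesh(length: float, diameter: float,
                           target_ntets: int = 3000,
                           match_volume: bool = True,
                           polygon_order: int | None = None,
                           c_spec: float = 0.01) -> CylinderFixture:
    """Structured prism-stack mesh of a cylinder along +z.

    The cross-section is a regular polygon (fan-triangulated about a centre
    vertex); each prism layer is split into tetrahedra with a consistent
    diagonal pattern.  With ``match_volume`` the polygon is scaled so the
    mesh volume equals the ideal cylinder volume exactly; the residual
    surface-area error (polygon-vs-circle perimeter deficit) is reported.
    """
    if length <= 0 or diameter <= 0:
        raise ValueError("length and diameter must be > 0")
    if target_ntets < 24:
        raise ValueError("target_ntets too small to form a prism stack "
                         "(need at least 24)")
    if polygon_order is None:
        k, s = _cylinder_layout(length, diameter, target_ntets)
    else:
        k = polygon_order
        if k < 3:
            raise ValueError("polygon_order must be >= 3")
        s = max(1, int(round(target_ntets / (3.0 * k))))

    r = diameter / 2.0
    if match_volume:
        # polygon area (k/2) R^2 sin(2 pi/k) == pi r^2
        R = r * math.sqrt(2.0 * math.pi / (k * math.sin(2.0 * math.pi / k)))
    else:
        R = r
    phi = 2.0 * math.pi * np.arange(k) / k
    ring = np.column_stack([R * np.cos(phi), R * np.sin(phi)])
    z = np.linspace(0.0, length, s + 1)

    nv_slice = k + 1
    verts = np.empty(((s + 1) * nv_slice, 3))
    for j in range(s + 1):
        base = j * nv_slice
        verts[base] = (0.0, 0.0, z[j])
        verts[base + 1: base + 1 + k, :2] = ring
        verts[base + 1: base + 1 + k, 2] = z[j]

    tets = []
    for j in range(s):
        lo, hi = j * nv_slice, (j + 1) * nv_slice
        for i in range(k):
            i2 = (i + 1) % k
            bottom = (lo, lo + 1 + i, lo + 1 + i2)
            top = (hi, hi + 1 + i, hi + 1 + i2)
            tets.extend(_split_prism(bottom, top))
    mesh = TetMesh.from_arrays(verts, np.array(tets, dtype=np.int64))

    centroids_z = mesh.vertices[mesh.boundary_tris][:, :, 2].mean(axis=1)
    nb = len(mesh.boundary_tris)
    cap0 = np.nonzero(np.isclose(centroids_z, 0.0, atol=1e-12 * length))[0]
    cap1 = np.nonzero(np.isclose(centroids_z, length,
                                 rtol=0, atol=1e-12 * length))[0]
    lateral = np.setdiff1d(np.arange(nb), np.concatenate([cap0, cap1]))
    membrane = MembraneSurface(mesh, np.arange(nb), c_spec=c_spec)

    lateral_area = float(mesh.boundary_tri_areas[lateral].sum())
    ideal = math.pi * diameter * length
    err = (lateral_area - ideal) / ideal

    zv = mesh.vertices[:, 2]
    return CylinderFixture(
        mesh=mesh, membrane=membrane, lateral_tris=lateral,
        cap0_tris=cap0, cap1_tris=cap1,
        end0_vertices=np.nonzero(zv == 0.0)[0],
        end1_vertices=np.nonzero(zv == length)[0],
        length=length, diameter=diameter, polygon_order=k, n_slices=s,
        surface_area_error=err)


# ---- branched tree --------------------------------------------------------

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))
# Candidate irrational multipliers for rolling the cap split line from one
# junction to the next.  The roll spreads branch planes in 3D; because it is
# quantized to the parent polygon order, no single multiplier clears every
# (levels, resolution) combination, so the builder tries these in turn and
# keeps the first layout that passes the self-intersection check.
_ROLL_MULTS = (0.7548776662466927, 0.5697, 0.6180339887498949,
               0.3819660112501051, 0.23, 0.909)
_ROLL_MULT = _ROLL_MULTS[0]


@dataclass(eq=False)
class _Branch:
    level: int
    start: np.ndarray          # tube start point (disc centre)
    axis: np.ndarray           # unit axis
    e1: np.ndarray             # cross-section basis
    e2: np.ndarray
    tube_length: float
    full_length: float         # nominal cable length of this level
    diameter: float
    R: float                   # polygon circumradius
    k: int                     # polygon order (even)
    s: int                     # slices
    slice_ids: list = field(default_factory=list)  # per-slice vertex ids


@dataclass(eq=False)
class BranchedFixture:
    """Symmetric 3/2-power-law binary tree mesh plus membrane."""

    mesh: TetMesh
    membrane: MembraneSurface
    lateral_tris: np.ndarray
    root_cap_tris: np.ndarray
    leaf_cap_tris: np.ndarray
    root_end_vertices: np.ndarray
    leaf_end_vertices: np.ndarray
    levels: int
    level_lengths: np.ndarray      # per level, m
    level_diameters: np.ndarray    # per level, m
    path_length: float             # root to tip along the cable, m
    ideal_area: float              # sum over branches of pi d l, m^2
    ideal_volume: float
    surface_area_error: float


def _rotate(v, axis, angle):
    axis = axis / np.linalg.norm(axis)
    c, s = math.cos(angle), math.sin(angle)
    return (v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c))


def _stitch_loops(loop_a, loop_b, pos, origin, axis, e1, e2):
    """Triangulate the band between two vertex loops by azimuth merging.

    Both loops must wind the same way around ``axis``; a vertex lying on the
    axis (the parent cap centre) is assigned the azimuth of the gap it
    spans.  Returns a list of triangles (vertex id triples).
    """
    def azimuths(loop):
        p = pos[np.asarray(loop)] - origin
        x, y = p @ e1, p @ e2
        radial = np.hypot(x, y)
        ang = np.arctan2(y, x)
        on_axis = radial < 1e-9 * (radial.max() + 1e-300)
        if on_axis.any():
            if on_axis.sum() > 1:
                raise MeshError("stitch loop has several on-axis vertices")
            others = ang[~on_axis]
            mid = math.atan2(np.sin(others).mean(), np.cos(others).mean())
            ang[on_axis] = mid + math.pi
        return np.mod(ang, 2 * math.pi)

    def monotone_cycle(loop, ang):
        i0 = int(np.argmin(ang))
        loop = list(loop[i0:]) + list(loop[:i0])
        ang = np.concatenate([ang[i0:], ang[:i0]])
        diffs = np.diff(ang)
        if np.all(diffs > 0):
            return loop, ang
        if np.all(diffs < 0):
            return loop[::-1], None
        raise MeshError("stitch loop azimuths are not monotone")

    la, aa = monotone_cycle(list(loop_a), azimuths(loop_a))
    if aa is None:
        la, aa = monotone_cycle(la, azimuths(la))
    lb, ab = monotone_cycle(list(loop_b), azimuths(loop_b))
    if ab is None:
        lb, ab = monotone_cycle(lb, azimuths(lb))

    na, nb = len(la), len(lb)
    tris = []
    i = j = 0
    # merge walk: advance the loop whose upcoming vertex has smaller azimuth
    while i < na or j < nb:
        next_a = aa[(i + 1) % na] + (2 * math.pi if i + 1 >= na else 0)
        next_b = ab[(j + 1) % nb] + (2 * math.pi if j + 1 >= nb else 0)
        if i < na and (j >= nb or next_a <= next_b):
            tris.append((la[i % na], la[(i + 1) % na], lb[j % nb]))
            i += 1
        else:
            tris.append((lb[(j + 1) % nb], lb[j % nb], la[i % na]))
            j += 1
    return tris


def _branched_layout(levels, target_ntets, lengths, diameters):
    """Pick per-level polygon orders and slice counts near a tet budget."""
    best = None
    for k_root in range(8, 41, 2):
        ks, ss, total = [], [], 0
        for lev in range(levels):
            k = max(6, int(round(k_root * 2.0 ** (-lev / 3.0) / 2.0)) * 2)
            edge = math.pi * diameters[lev] / k
            s = max(2, int(round(lengths[lev] / (2.5 * edge))))
            ks.append(k)
            ss.append(s)
            total += 2 ** lev * (3 * k * s + 2 * k + 10)
        score = abs(total - target_ntets)
        if best is None or score < best[0]:
            best = (score, ks, ss)
    return best[1], best[2]


def generate_branched_mesh(levels: int, root_length: float = 32e-6,
                           root_diameter: float = 16e-6,
                           target_ntets: int = 60000,
                           c_spec: float = 0.01,
                           branch_angle: float = math.radians(30.0),
                           match_volume: bool = True) -> BranchedFixture:
    """Symmetric binary tree obeying the 3/2 power law.

    At each branch point the daughter diameter is ``d * 2**(-2/3)`` (so the
    summed ``d**(3/2)`` is conserved) and the daughter length is
    ``l * 2**(-1/3)``; an 8-level tree from a 32 um x 16 um root spans
    ~130 um of cable from root to tip.  Branches are prism-stack tubes
    joined by conforming star-shaped junction plugs; each daughter attaches
    to half of its parent's end-cap fan.  With ``match_volume`` a global
    radial scale is solved so the mesh volume equals the ideal
    union-of-cylinders volume.
    """
    last_err = None
    for angle_scale in (1.0, 1.15, 0.85, 1.3):
        for roll_mult in _ROLL_MULTS:
            try:
                return _generate_branched_once(
                    levels, root_length, root_diameter, target_ntets, c_spec,
                    branch_angle * angle_scale, match_volume, roll_mult)
            except MeshError as err:
                if "self-intersection" not in str(err):
                    raise
                last_err = err
    raise last_err


def _generate_branched_once(levels, root_length, root_diameter, target_ntets,
                            c_spec, branch_angle, match_volume,
                            roll_mult) -> BranchedFixture:
    if not 1 <= levels <= 8:
        raise ValueError("levels must be in [1, 8]")
    lengths = root_length * 2.0 ** (-np.arange(levels) / 3.0)
    diameters = root_diameter * 2.0 ** (-2.0 * np.arange(levels) / 3.0)

    if levels == 1:
        cyl = generate_cylinder_mesh(root_length, root_diameter,
                                     target_ntets, match_volume=match_volume,
                                     c_spec=c_spec)
        return BranchedFixture(
            mesh=cyl.mesh, membrane=cyl.membrane,
            lateral_tris=cyl.lateral_tris, root_cap_tris=cyl.cap0_tris,
            leaf_cap_tris=cyl.cap1_tris,
            root_end_vertices=cyl.end0_vertices,
            leaf_end_vertices=cyl.end1_vertices,
            levels=1, level_lengths=lengths, level_diameters=diameters,
            path_length=float(lengths.sum()),
            ideal_area=math.pi * root_diameter * root_length,
            ideal_volume=math.pi * root_diameter ** 2 / 4 * root_length,
            surface_area_error=cyl.surface_area_error)

    ks, ss = _branched_layout(levels, target_ntets, lengths, diameters)

    anchors: list = []      # per-vertex: point on the local axis
    radials: list = []      # per-vertex: radial offset (scaled by f)
    tets: list = []

    def add_vertex(anchor, radial):
        anchors.append(np.asarray(anchor, float))
        radials.append(np.asarray(radial, float))
        return len(anchors) - 1

    def add_slice(branch, centre):
        ring_r = branch.R
        ids = [add_vertex(centre, (0.0, 0.0, 0.0))]
        for i in range(branch.k):
            ang = 2 * math.pi * i / branch.k
            radial = ring_r * (math.cos(ang) * branch.e1 +
                               math.sin(ang) * branch.e2)
            ids.append(add_vertex(centre, radial))
        branch.slice_ids.append(ids)
        return ids

    def extrude(branch):
        dz = branch.tube_length / branch.s
        for j in range(1, branch.s + 1):
            add_slice(branch, branch.start + branch.axis * (j * dz))
        for j in range(branch.s):
            lo, hi = branch.slice_ids[j], branch.slice_ids[j + 1]
            for i in range(branch.k):
                i2 = (i + 1) % branch.k
                tets.extend(_split_prism((lo[0], lo[1 + i], lo[1 + i2]),
                                         (hi[0], hi[1 + i], hi[1 + i2])))

    def frame(axis, hint):
        e1 = hint - np.dot(hint, axis) * axis
        n = np.linalg.norm(e1)
        if n < 1e-12:
            e1 = np.array([0.0, 1.0, 0.0]) - axis[1] * axis
            n = np.linalg.norm(e1)
        e1 /= n
        return e1, np.cross(axis, e1)

    pos_of = lambda ids: np.array([anchors[i] + radials[i] for i in ids])

    root_axis = np.array([1.0, 0.0, 0.0])
    e1, e2 = frame(root_axis, np.array([0.0, 0.0, 1.0]))
    branches = [_Branch(level=1, start=np.zeros(3), axis=root_axis,
                        e1=e1, e2=e2, tube_length=float(lengths[0]),
                        full_length=float(lengths[0]),
                        diameter=float(diameters[0]),
                        R=_polygon_R(diameters[0], ks[0]), k=ks[0], s=ss[0])]
    add_slice(branches[0], branches[0].start)
    extrude(branches[0])

    frontier = [branches[0]]
    azim_counter = 0
    for lev in range(2, levels + 1):
        new_frontier = []
        d_child = float(diameters[lev - 1])
        l_child = float(lengths[lev - 1])
        k_child, s_child = ks[lev - 1], ss[lev - 1]
        R_child = _polygon_R(d_child, k_child)
        for parent in frontier:
            azim_counter += 1
            cap = parent.slice_ids[-1]
            centre_id, rim = cap[0], cap[1:]
            kp = parent.k
            O = anchors[centre_id].copy()
            delta = 2.0 * parent.R          # plug axial extent
            # split the parent cap fan into two halves; the split line is
            # rotated per branch by a golden-ratio sequence so that branch
            # planes decorrelate and cousins spread out in 3D
            roll = int((azim_counter * roll_mult) % 1.0 * kp)
            rim = rim[roll:] + rim[:roll]
            halves = [rim[: kp // 2 + 1], rim[kp // 2:] + rim[:1]]
            for side, half_rim in enumerate(halves):
                half_pos = pos_of(half_rim)
                m = half_pos.mean(axis=0) - O
                m -= np.dot(m, parent.axis) * parent.axis
                m /= np.linalg.norm(m)
                u = (math.cos(branch_angle) * parent.axis +
                     math.sin(branch_angle) * m)
                u /= np.linalg.norm(u)
                ce1, ce2 = frame(u, m)
                child = _Branch(level=lev, start=O + delta * u, axis=u,
                                e1=ce1, e2=ce2,
                                tube_length=l_child - delta,
                                full_length=l_child, diameter=d_child,
                                R=R_child, k=k_child, s=s_child)
                if child.tube_length <= 0:
                    raise MeshError(
                        f"junction plug does not fit inside the level-{lev} "
                        "branch length; geometry too coarse")
                disc = add_slice(child, child.start)
                extrude(child)
                # junction plug: cone an apex over the half cap, the child
                # disc, and the stitched lateral band between their rims
                half_tris = [(centre_id, half_rim[i], half_rim[i + 1])
                             for i in range(kp // 2)]
                disc_tris = [(disc[0], disc[1 + i],
                              disc[1 + (i + 1) % k_child])
                             for i in range(k_child)]
                loop_a = [centre_id] + list(half_rim)
                loop_b = disc[1:]
                pos = np.array([anchors[t] + radials[t]
                                for t in range(len(anchors))])
                band = _stitch_loops(loop_a, loop_b, pos,
                                     (O + child.start) / 2.0, u, ce1, ce2)
                apex_pos = 0.5 * (half_pos.mean(axis=0) + child.start)
                apex = add_vertex(apex_pos, (0.0, 0.0, 0.0))
                for tri in half_tris + disc_tris + band:
                    tets.append((apex,) + tuple(tri))
                new_frontier.append(child)
                branches.append(child)
        frontier = new_frontier

    anchors_arr = np.array(anchors)
    radials_arr = np.array(radials)
    tets_arr = np.array(tets, dtype=np.int64)

    _check_branch_intersections(branches)

    ideal_volume = float(np.sum(
        2.0 ** np.arange(levels) * math.pi * diameters ** 2 / 4 * lengths))
    ideal_area = float(np.sum(
        2.0 ** np.arange(levels) * math.pi * diameters * lengths))

    def build(f):
        return TetMesh.from_arrays(anchors_arr + f * radials_arr, tets_arr,
                                   validate=False)

    f = 1.0
    if match_volume:
        from scipy.optimize import brentq
        g = lambda fac: build(fac).volume - ideal_volume
        f = brentq(g, 0.7, 1.3, xtol=1e-14, rtol=1e-13)
    mesh = TetMesh.from_arrays(anchors_arr + f * radials_arr, tets_arr)

    # classify boundary triangles: root cap, leaf caps, lateral membrane
    root_cap_vids = set(branches[0].slice_ids[0])
    leaf_vids = set()
    leaf_end = []
    for br in branches:
        if br.level == levels:
            leaf_vids.update(br.slice_ids[-1])
            leaf_end.extend(br.slice_ids[-1])
    btris = mesh.boundary_tris
    nb = len(btris)
    in_root = np.array([all(v in root_cap_vids for v in t) for t in btris])
    in_leaf = np.array([all(v in leaf_vids for v in t) for t in btris])
    root_cap = np.nonzero(in_root)[0]
    leaf_cap = np.nonzero(in_leaf)[0]
    lateral = np.nonzero(~(in_root | in_leaf))[0]
    membrane = MembraneSurface(mesh, np.arange(nb), c_spec=c_spec)

    lateral_area = float(mesh.boundary_tri_areas[lateral].sum())
    err = (lateral_area - ideal_area) / ideal_area
    return BranchedFixture(
        mesh=mesh, membrane=membrane, lateral_tris=lateral,
        root_cap_tris=root_cap, leaf_cap_tris=leaf_cap,
        root_end_vertices=np.array(sorted(root_cap_vids), dtype=np.int64),
        leaf_end_vertices=np.unique(np.array(leaf_end, dtype=np.int64)),
        levels=levels, level_lengths=lengths, level_diameters=diameters,
        path_length=float(lengths.sum()), ideal_area=ideal_area,
        ideal_volume=ideal_volume, surface_area_error=err)


def _polygon_R(diameter, k):
    """Circumradius giving a regular k-gon the area of the circle."""
    return (diameter / 2.0) * math.sqrt(
        2.0 * math.pi / (k * math.sin(2.0 * math.pi / k)))


def _segment_distance(p0, p1, q0, q1):
    """Minimum distance between two 3D segments."""
    u, v, w = p1 - p0, q1 - q0, p0 - q0
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    den = a * c - b * b
    s = np.clip((b * e - c * d) / den if den > 1e-30 else 0.0, 0.0, 1.0)
    t = (b * s + e) / c if c > 1e-30 else 0.0
    t = np.clip(t, 0.0, 1.0)
    s = np.clip((b * t - d) / a if a > 1e-30 else 0.0, 0.0, 1.0)
    return float(np.linalg.norm(p0 + s * u - (q0 + t * v)))


def _check_branch_intersections(branches):
    segs = []
    for idx, br in enumerate(branches):
        segs.append((idx, br, br.start, br.start + br.axis * br.tube_length))
    parent_of = {}
    # reconstruct parent links by adjacency in build order (2 children each)
    for i, br in enumerate(branches):
        if i == 0:
            continue
        parent_of[i] = (i - 1) // 2
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            if parent_of.get(j) == i or parent_of.get(i) == j:
                continue
            if parent_of.get(i) is not None and \
                    parent_of.get(i) == parent_of.get(j):
                pass  # siblings are checked too
            _, bi, p0, p1 = segs[i]
            _, bj, q0, q1 = segs[j]
            dist = _segment_distance(p0, p1, q0, q1)
            if dist < 0.98 * (bi.R + bj.R):
                raise MeshError(
                    f"geometric self-intersection between a level-{bi.level} "
                    f"and a level-{bj.level} branch; increase branch_angle")
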