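"""Unit-sphere direction sets for ODF sampling and directional clustering.

ODF profiles are evaluated on near-uniform direction sets obtained by
recursive midpoint subdivision of the icosahedron.  Because diffusion is
antipodally symmetric, profiles are usually evaluated on a hemisphere: the
full-sphere tessellations (12, 42, 162, 642, ... vertices) reduce to 6, 21,
81, 321, ... directions, matching the sampling densities N = 81 and N = 321
commonly used in fiber mapping.

Subdivision is performed with an exact midpoint cache so that antipodal
vertex pairs match bit-for-bit and the vertex ordering is reproducible
across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SphereGrid",
    "subdivide_icosahedron",
    "hemisphere",
    "hemisphere_grid",
    "axial_angle",
    "axial_angle_matrix",
    "vertex_area_weights",
    "save_directions",
    "load_directions",
]

#: target hemisphere sizes -> subdivision depth of the full-sphere mesh
HEMISPHERE_SIZES = {6: 0, 21: 1, 81: 2, 321: 3, 1281: 4}


@dataclass(frozen=True)
class SphereGrid:
    """A set of unit direction vectors on the sphere (or hemisphere).

    Attributes
    ----------
    vertices : (N, 3) ndarray
        Unit direction cosines, ordered by (z, y, x) descending.
    level : int
        Icosahedron subdivision depth the grid was built from.
    hemisphere_flag : bool
        True when exactly one direction per antipodal pair is retained.
    faces : (F, 3) int ndarray or None
        Triangle faces (full-sphere grids only); indices into ``vertices``.
    """

    vertices: np.ndarray
    level: int
    hemisphere_flag: bool
    faces: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        object.__setattr__(self, "vertices", v)
        norms = np.linalg.norm(v, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("SphereGrid vertices must be unit norm (1e-12)")

    @property
    def n(self) -> int:
        return len(self.vertices)

    def __len__(self) -> int:
        return len(self.vertices)


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    """Regular icosahedron vertices (unit norm) and faces."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts[0])
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=int,
    )
    return verts, faces


def _subdivide_once(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One midpoint subdivision step; midpoints deduplicated by edge index.

    Midpoints are computed as (a + b) normalized, which preserves exact
    antipodal symmetry: negation commutes bit-exactly with both the sum and
    the normalization.
    """
    verts = list(map(tuple, verts))
    cache: dict[tuple[int, int], int] = {}

    def midpoint(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        if key in cache:
            return cache[key]
        a = np.array(verts[i])
        b = np.array(verts[j])
        m = a + b
        m /= np.linalg.norm(m)
        verts.append(tuple(m))
        cache[key] = len(verts) - 1
        return cache[key]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
    return np.array(verts, dtype=float), np.array(new_faces, dtype=int)


def _order(verts: np.ndarray, faces: np.ndarray | None) -> tuple[np.ndarray, np.ndarray | None]:
    """Sort vertices by (z, y, x) descending; remap faces accordingly."""
    order = np.lexsort((-verts[:, 0], -verts[:, 1], -verts[:, 2]))
    if faces is None:
        return verts[order], None
    inverse = np.empty(len(verts), dtype=int)
    inverse[order] = np.arange(len(verts))
    return verts[order], inverse[faces]


def subdivide_icosahedron(level: int) -> SphereGrid:
    """Full-sphere tessellation with 10 * 4**level + 2 vertices.

    Parameters
    ----------
    level : int
        Subdivision depth (>= 0); level 0 is the bare icosahedron.
    """
    if not isinstance(level, (int, np.integer)) or level < 0:
        raise ValueError(f"subdivision level must be a non-negative integer, got {level!r}")
    verts, faces = _icosahedron()
    for _ in range(level):
        verts, faces = _subdivide_once(verts, faces)
    verts, faces = _order(verts, faces)
    return SphereGrid(vertices=verts, level=int(level), hemisphere_flag=False, faces=faces)


def hemisphere(grid: SphereGrid, atol: float = 1e-9) -> SphereGrid:
    """Keep exactly one direction from each antipodal pair.

    Retention rule: keep u when u_z > 0; on the equator ring (u_z = 0) keep
    u with u_y > 0, and if u_y = 0 too, keep u with u_x > 0.  The rule is
    applied with tolerance ``atol`` so the grids are reproducible.
    """
    v = grid.vertices
    # verify exact antipodal pairing
    key = {tuple(np.round(x, 9)): i for i, x in enumerate(v)}
    unpaired = [i for i, x in enumerate(v) if tuple(np.round(-x, 9)) not in key]
    if unpaired:
        raise ValueError(f"grid is not antipodally paired; unpaired vertex indices: {unpaired}")

    z, y, x = v[:, 2], v[:, 1], v[:, 0]
    keep = (z > atol) | ((np.abs(z) <= atol) & (y > atol)) | (
        (np.abs(z) <= atol) & (np.abs(y) <= atol) & (x > atol)
    )
    kept = v[keep]
    if 2 * len(kept) != len(v):
        raise ValueError("hemisphere reduction did not halve the vertex count")
    kept, _ = _order(kept, None)
    return SphereGrid(vertices=kept, level=grid.level, hemisphere_flag=True)


def hemisphere_grid(n: int) -> SphereGrid:
    """Hemisphere direction set with exactly ``n`` directions (n in 6, 21, 81, 321, 1281)."""
    try:
        level = HEMISPHERE_SIZES[n]
    except KeyError:
        raise ValueError(
            f"no icosahedral hemisphere grid has {n} directions; choose from {sorted(HEMISPHERE_SIZES)}"
        ) from None
    return hemisphere(subdivide_icosahedron(level))


def _check_unit(u: np.ndarray, name: str) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if abs(np.linalg.norm(u) - 1.0) > 1e-6:
        raise ValueError(f"{name} must be a unit vector (norm within 1e-6), got norm {np.linalg.norm(u)}")
    return u


def axial_angle(u, v) -> float:
    """Angle in degrees between the axes spanned by u and v, in [0, 90].

    Axes are sign-invariant: u and -u describe the same fiber axis, so the
    angle is arccos(|u . v|).
    """
    u = _check_unit(u, "u")
    v = _check_unit(v, "v")
    return float(np.degrees(np.arccos(np.clip(abs(float(u @ v)), 0.0, 1.0))))


def axial_angle_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise axial angles (degrees) between rows of a (n,3) and b (m,3)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    return np.degrees(np.arccos(np.clip(np.abs(a @ b.T), 0.0, 1.0)))


def vertex_area_weights(grid: SphereGrid) -> np.ndarray:
    """Spherical quadrature weights: each vertex gets a third of the solid
    angle of its incident spherical triangles, so the weights sum to 4*pi
    exactly (up to rounding).

    Triangle solid angles use Van Oosterom & Strackee's formula."""
    if grid.faces is None:
        raise ValueError("area weights need a full-sphere grid with faces")
    v, f = grid.vertices, grid.faces
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    num = np.abs(np.einsum("ij,ij->i", a, np.cross(b, c)))
    den = 1.0 + np.einsum("ij,ij->i", a, b) + np.einsum("ij,ij->i", b, c) + np.einsum("ij,ij->i", a, c)
    area = 2.0 * np.arctan2(num, den)
    w = np.zeros(len(v))
    for k in range(3):
        np.add.at(w, f[:, k], area / 3.0)
    return w


def save_directions(path, grid: SphereGrid) -> None:
    """Write one 'x y z' row per direction (plain text, b-table direction dialect)."""
    np.savetxt(path, grid.vertices, fmt="%.17g")


def load_directions(path, level: int = -1, hemisphere_flag: bool = True) -> SphereGrid:
    """Read a 3-column direction list; vectors are renormalized."""
    v = np.atleast_2d(np.loadtxt(path))
    if v.shape[1] != 3:
        raise ValueError(f"direction list must have 3 columns, got {v.shape[1]}")
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    return SphereGrid(vertices=v, level=level, hemisphere_flag=hemisphere_flag)
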