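"""Triangle surface meshes in world coordinates.

A :class:`SurfaceMesh` holds vertex positions in millimetres (RAS world
space) and triangle faces.  White (gray/white interface) and pial
(gray/CSF interface) surfaces of one subject share vertex count and
vertex correspondence: vertex *i* on the white surface corresponds to
vertex *i* on the pial surface, and the straight segment between them
spans the cortical ribbon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse


class MeshValidationError(ValueError):
    """Raised when a mesh violates its structural invariants."""


@dataclass
class SurfaceMesh:
    vertices: np.ndarray          # (n, 3) float64, world mm
    faces: np.ndarray             # (m, 3) int
    hemisphere: str = "single"    # left | right | single
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be an (m, 3) array of vertex triples")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= self.n_vertices):
            raise MeshValidationError(
                f"face index out of range: max index {self.faces.max()} "
                f"for {self.n_vertices} vertices"
            )
        if self.hemisphere not in ("left", "right", "single"):
            raise MeshValidationError(f"unknown hemisphere tag {self.hemisphere!r}")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    # -- derived structure ------------------------------------------------

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) sorted-index array."""
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        return np.unique(e, axis=0)

    def edge_face_counts(self) -> np.ndarray:
        """How many faces share each unique edge (2 everywhere on a closed manifold)."""
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return counts

    def is_closed_manifold(self) -> bool:
        counts = self.edge_face_counts()
        return bool(counts.size) and bool(np.all(counts == 2))

    def adjacency(self) -> sparse.csr_matrix:
        """Sparse vertex adjacency (symmetric 0/1, no self loops)."""
        if "adjacency" not in self._cache:
            e = self.edges()
            n = self.n_vertices
            data = np.ones(2 * len(e))
            rows = np.concatenate([e[:, 0], e[:, 1]])
            cols = np.concatenate([e[:, 1], e[:, 0]])
            self._cache["adjacency"] = sparse.csr_matrix(
                (data, (rows, cols)), shape=(n, n)
            )
        return self._cache["adjacency"]

    def vertex_normals(self) -> np.ndarray:
        """Outward unit vertex normals, angle-weighted over incident faces.

        Each incident face contributes its unit normal weighted by the
        interior angle at the vertex; the accumulated vector is normalised.
        Deterministic and independent of face ordering.
        """
        if "normals" in self._cache:
            return self._cache["normals"]
        v = self.vertices
        f = self.faces
        p0, p1, p2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
        fn = np.cross(p1 - p0, p2 - p0)
        norm = np.linalg.norm(fn, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        fn = fn / norm

        def corner_angle(a, b, c):
            u, w = b - a, c - a
            cosang = np.einsum("ij,ij->i", u, w) / (
                np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1)
            )
            return np.arccos(np.clip(cosang, -1.0, 1.0))

        angles = np.stack(
            [
                corner_angle(p0, p1, p2),
                corner_angle(p1, p2, p0),
                corner_angle(p2, p0, p1),
            ],
            axis=1,
        )
        acc = np.zeros_like(v)
        for k in range(3):
            np.add.at(acc, f[:, k], fn * angles[:, k, None])
        n = np.linalg.norm(acc, axis=1, keepdims=True)
        n[n == 0] = 1.0
        normals = acc / n
        self._cache["normals"] = normals
        return normals

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.vertices).tobytes())
        h.update(np.ascontiguousarray(self.faces).tobytes())
        return h.hexdigest()


def check_vertex_correspondence(white: SurfaceMesh, pial: SurfaceMesh) -> None:
    """White/pial pairs must have equal vertex counts (1:1 correspondence)."""
    if white.n_vertices != pial.n_vertices:
        raise MeshValidationError(
            f"white ({white.n_vertices} vertices) and pial ({pial.n_vertices}) "
            "surfaces do not correspond"
        )


def cortical_thickness(white: SurfaceMesh, pial: SurfaceMesh) -> np.ndarray:
    """Per-vertex thickness (mm): Euclidean white-to-pial vertex distance."""
    check_vertex_correspondence(white, pial)
    return np.linalg.norm(pial.vertices - white.vertices, axis=1)
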