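"""Readers and writers for every on-disk object the pipeline touches.

Canonical mesh interchange is OFF/PLY (via trimesh); FreeSurfer binary
surfaces are supported read-only (via nibabel).  Volumes are NIfTI-1
(nibabel).  Cohort tables are UTF-8 CSV with a header row.  Per-vertex
maps are written both as ``vertex_index,value`` CSV and as a ``.npy``
matrix with a JSON sidecar.  All coordinates are world-space mm, RAS;
voxel indices are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .mesh import MeshValidationError, SurfaceMesh

VALID_LABELS = ("AD", "CN", "MCI-C", "MCI-NC")


class FormatError(ValueError):
    """Unreadable or structurally invalid on-disk object."""


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------

def read_surface(path: str | Path, hemisphere: str = "single") -> SurfaceMesh:
    """Read a PLY, OFF, or FreeSurfer binary surface as a :class:`SurfaceMesh`.

    Coordinates are interpreted as world millimetres.  Structural
    invariants (face indices in range) are enforced; a non-manifold mesh
    is accepted with a warning since only phantom meshes are guaranteed
    closed.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"surface file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".ply", ".off"):
        try:
            m = trimesh.load(path, file_type=suffix[1:], process=False)
        except Exception as exc:  # trimesh raises a mixture of types
            raise FormatError(f"cannot parse {path} as {suffix[1:].upper()}: {exc}") from exc
        if not isinstance(m, trimesh.Trimesh) or m.faces is None or len(m.faces) == 0:
            raise FormatError(f"{path}: no triangle faces found")
        vertices = np.asarray(m.vertices, dtype=np.float64)
        faces = np.asarray(m.faces, dtype=np.int64)
    else:
        # FreeSurfer binary surface (e.g. lh.white) — read-only convenience
        try:
            vertices, faces = nib.freesurfer.read_geometry(str(path))
        except Exception as exc:
            raise FormatError(f"cannot parse {path} as a FreeSurfer surface: {exc}") from exc
        vertices = np.asarray(vertices, dtype=np.float64)
        faces = np.asarray(faces, dtype=np.int64)
    try:
        mesh = SurfaceMesh(vertices, faces, hemisphere=hemisphere)
    except MeshValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if not mesh.is_closed_manifold():
        import warnings

        warnings.warn(f"{path}: mesh is not a closed manifold", stacklevel=2)
    return mesh


def write_surface(mesh: SurfaceMesh, path: str | Path) -> Path:
    """Write a mesh as PLY or OFF (chosen by extension)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in (".ply", ".off"):
        raise FormatError(f"unsupported surface format {suffix!r} (use .ply or .off)")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    path.parent.mkdir(parents=True, exist_ok=True)
    tm.export(path, file_type=suffix[1:])
    return path


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

@dataclass
class VolumeImage:
    """3-D scalar grid plus a voxel-to-world affine (mm)."""

    data: np.ndarray      # (i, j, k) scalar grid
    affine: np.ndarray    # 4x4 voxel -> world (mm)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise FormatError("volume data must be 3-D")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("affine is singular (not invertible)")
        if not np.all(np.isfinite(self.affine)):
            raise FormatError("affine contains non-finite values")

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm, derived from the affine columns."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_to_voxel(self, world: np.ndarray) -> np.ndarray:
        """Map world-mm coordinates (n, 3) to continuous 0-based voxel indices."""
        inv = np.linalg.inv(self.affine)
        w = np.asarray(world, dtype=np.float64)
        return w @ inv[:3, :3].T + inv[:3, 3]


def read_volume(path: str | Path) -> VolumeImage:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as NIfTI: {exc}") from exc
    if img.affine is None:
        raise FormatError(f"{path}: missing affine")
    return VolumeImage(np.asanyarray(img.dataobj), img.affine)


def write_volume(vol: VolumeImage, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    if "subject_id" not in table.columns or "label" not in table.columns:
        raise FormatError("cohort table needs 'subject_id' and 'label' columns")
    if table["subject_id"].duplicated().any():
        dup = table.loc[table["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise FormatError(f"duplicate subject_id {dup!r}")
    bad = set(table["label"]) - set(VALID_LABELS)
    if bad:
        raise FormatError(f"unknown diagnosis labels {sorted(bad)}; expected {VALID_LABELS}")
    return table


def read_cohort(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"cohort file not found: {path}")
    table = pd.read_csv(path, dtype={"subject_id": str})
    return validate_cohort(table)


def write_cohort(table: pd.DataFrame, path: str | Path) -> Path:
    validate_cohort(table)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# per-vertex maps and matrices
# ---------------------------------------------------------------------------

def write_vertex_map_csv(values: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"vertex_index": np.arange(len(values)), "value": values})
    df.to_csv(path, index=False)
    return path


def read_vertex_map_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    if not {"vertex_index", "value"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns vertex_index,value")
    out = np.full(int(df["vertex_index"].max()) + 1, np.nan)
    out[df["vertex_index"].to_numpy()] = df["value"].to_numpy()
    return out


def write_matrix(matrix: np.ndarray, path: str | Path, meta: dict | None = None) -> Path:
    """Binary matrix container (.npy) with a JSON sidecar describing it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path, np.asarray(matrix))
    sidecar = dict(meta or {})
    sidecar.setdefault("shape", list(np.asarray(matrix).shape))
    sidecar.setdefault("dtype", str(np.asarray(matrix).dtype))
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )
    return path


def read_matrix(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"matrix file not found: {path}")
    matrix = np.load(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return matrix, meta
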