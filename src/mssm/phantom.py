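"""Synthetic cortical phantoms with analytic ground truth.

The phantom is a sphere-based cortical ribbon: the white surface (the
gray/white interface) is an icosphere, and the pial surface (gray/CSF
interface) lies one local cortical thickness outward along the vertex
normal.  The accompanying T1-like volume is piecewise constant by
tissue (WM > GM > CSF), optionally multiplied by a smooth bias field
and degraded with additive Gaussian noise.  Disease-like effects —
cortical thinning and loss of GM/WM contrast — are confined to
configurable "signature" vertex masks, with per-subject Gaussian
jitter.  Everything is reproducible from a single integer seed.

Sulcal folding is deliberately absent: the point of the phantom is an
exact analytic ground truth for every downstream stage, and no tested
property depends on folded geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import cKDTree

from .io_formats import VolumeImage
from .mesh import SurfaceMesh


class PhantomError(ValueError):
    pass


@dataclass
class PhantomConfig:
    """Geometry, intensity and degradation parameters of one phantom brain.

    Intensity means follow T1 ordering (WM > GM > CSF); defaults are
    typical MP-RAGE-like arbitrary units.  ``bias_amplitude`` is the peak
    fractional deviation of the smooth multiplicative bias field (0.1 =
    +/-10%); ``bias_wavelength_mm`` its spatial scale, kept large relative
    to the cortical ribbon so the field is locally near-constant, the
    regime in which ratio features normalise it away.
    """

    subdivisions: int = 4                 # icosphere level; 4 -> 2562 vertices
    base_radius_mm: float = 40.0          # white-surface radius
    thickness_mm: float = 2.5             # cortical thickness (scalar or per-vertex)
    wm_mean: float = 110.0
    gm_mean: float = 75.0
    csf_mean: float = 20.0
    noise_sd: float = 4.0
    bias_amplitude: float = 0.1
    bias_wavelength_mm: float = 150.0
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.2)
    margin_mm: float = 4.0
    # healthy between-subject variation: a small global thickness offset
    # plus independent per-vertex variability (local cortical variation);
    # without the local term the synthetic thickness maps would be
    # perfectly correlated across vertices within subject
    thickness_subject_sd: float = 0.05    # global thickness offset per subject (mm)
    thickness_vertex_sd: float = 0.2      # per-vertex thickness variation (mm)
    gm_subject_sd: float = 1.0            # global GM-mean offset per subject

    def validate(self) -> "PhantomConfig":
        if not (self.wm_mean > self.gm_mean > self.csf_mean):
            raise PhantomError("intensity ordering must be WM > GM > CSF")
        if np.any(np.asarray(self.thickness_mm) <= 0):
            raise PhantomError("thickness must be positive everywhere")
        if self.noise_sd < 0:
            raise PhantomError("noise_sd must be >= 0")
        if self.bias_amplitude < 0 or self.bias_amplitude >= 1:
            raise PhantomError("bias_amplitude must be in [0, 1)")
        return self


@dataclass
class EffectSpec:
    """Group-level effect confined to signature vertex masks.

    ``thickness_delta_mm`` thins the cortex inside ``thickness_mask``;
    ``contrast_delta`` moves the GM intensity inside ``contrast_mask``
    toward the WM intensity by that fraction of the GM-WM gap, i.e. it
    reduces the gray/white contrast.  ``*_subject_sd`` are the between-
    subject standard deviations of the two deltas.
    """

    thickness_mask: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    thickness_delta_mm: float = 0.0
    contrast_mask: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    contrast_delta: float = 0.0
    thickness_subject_sd: float = 0.0
    contrast_subject_sd: float = 0.0

    def validate(self, n_vertices: int) -> "EffectSpec":
        for name, mask in (("thickness_mask", self.thickness_mask),
                           ("contrast_mask", self.contrast_mask)):
            mask = np.asarray(mask, dtype=int)
            if mask.size and (mask.min() < 0 or mask.max() >= n_vertices):
                raise PhantomError(f"{name} contains out-of-range vertex indices")
        if self.thickness_delta_mm < 0 or self.contrast_delta < 0:
            raise PhantomError("effect deltas must be >= 0")
        return self

    def scaled(self, factor: float) -> "EffectSpec":
        """Same masks, deltas scaled by ``factor`` (e.g. an intermediate cohort)."""
        return replace(
            self,
            thickness_delta_mm=self.thickness_delta_mm * factor,
            contrast_delta=self.contrast_delta * factor,
            thickness_subject_sd=self.thickness_subject_sd * factor,
            contrast_subject_sd=self.contrast_subject_sd * factor,
        )


@dataclass
class PhantomSubject:
    white: SurfaceMesh
    pial: SurfaceMesh
    volume: VolumeImage
    truth: dict


@dataclass
class SyntheticCohort:
    subjects: list[PhantomSubject]
    table: pd.DataFrame
    effect: EffectSpec | None
    config: PhantomConfig


def white_icosphere(config: PhantomConfig) -> SurfaceMesh:
    ico = trimesh.creation.icosphere(
        subdivisions=config.subdivisions, radius=config.base_radius_mm
    )
    return SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


def cap_mask(mesh: SurfaceMesh, direction: np.ndarray, n_vertices: int) -> np.ndarray:
    """Indices of the ``n_vertices`` mesh vertices closest in angle to ``direction``.

    A deterministic spherical-cap "signature region" used to place effects.
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    unit = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    order = np.argsort(-(unit @ d), kind="stable")
    return np.sort(order[:n_vertices])


def _bias_field(points: np.ndarray, amplitude: float, wavelength: float,
                rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field: 1 + amplitude * (3 cosine modes, unit peak)."""
    f = np.zeros(points.shape[0])
    for _ in range(3):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        f += np.cos(2.0 * np.pi * (points @ u) / wavelength + phase)
    peak = np.max(np.abs(f))
    if peak > 0:
        f /= peak
    return 1.0 + amplitude * f


def make_phantom_subject(
    config: PhantomConfig,
    effect: EffectSpec | None = None,
    rng_seed: int | np.random.Generator = 0,
    affected: bool = True,
) -> PhantomSubject:
    """Build one subject: white mesh, pial mesh, and T1-like volume.

    Voxels are labelled by the innermost region containing their centre
    (inside white -> WM, between white and pial -> GM, outside pial ->
    CSF), assigned their tissue mean (with the contrast effect applied
    to masked GM), then bias-multiplied and noise-added.
    """
    config.validate()
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))

    white = white_icosphere(config)
    n = white.n_vertices
    thickness = np.broadcast_to(
        np.asarray(config.thickness_mm, dtype=float), (n,)
    ).copy()

    # subject-level healthy variation (drawn unconditionally: keeps the
    # stream aligned between affected and control subjects)
    thickness += rng.normal(0.0, config.thickness_subject_sd)
    if config.thickness_vertex_sd > 0:
        thickness += rng.normal(0.0, config.thickness_vertex_sd, size=n)
    gm_mean = config.gm_mean + rng.normal(0.0, config.gm_subject_sd)

    t_delta = c_delta = 0.0
    if effect is not None:
        effect.validate(n)
        t_delta = max(0.0, rng.normal(effect.thickness_delta_mm,
                                      effect.thickness_subject_sd))
        c_delta = float(np.clip(rng.normal(effect.contrast_delta,
                                           effect.contrast_subject_sd), 0.0, 1.0))
        if affected and effect.thickness_mask.size:
            thickness[np.asarray(effect.thickness_mask, dtype=int)] -= t_delta
    if not affected:
        t_delta = c_delta = 0.0
    if np.any(thickness <= 0):
        raise PhantomError(
            "thickness delta >= thickness somewhere: degenerate cortical ribbon"
        )

    normals = white.vertex_normals()
    pial = SurfaceMesh(white.vertices + thickness[:, None] * normals, white.faces)

    # ---- volume -----------------------------------------------------------
    voxel = np.asarray(config.voxel_size_mm, dtype=float)
    extent = config.base_radius_mm + float(np.max(thickness)) + config.margin_mm
    shape = np.ceil(2.0 * extent / voxel).astype(int)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(voxel)
    affine[:3, 3] = -(shape - 1) / 2.0 * voxel

    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    centers = idx * voxel + affine[:3, 3]
    r = np.linalg.norm(centers, axis=1)

    data = np.full(int(np.prod(shape)), config.csf_mean, dtype=np.float64)
    data[r < config.base_radius_mm] = config.wm_mean

    # candidate GM shell: resolve the local pial radius via the nearest
    # white vertex in direction (direction-based correspondence)
    max_pial = config.base_radius_mm + float(np.max(thickness))
    shell = (r >= config.base_radius_mm) & (r < max_pial)
    if np.any(shell):
        unit_vertices = white.vertices / np.linalg.norm(
            white.vertices, axis=1, keepdims=True
        )
        tree = cKDTree(unit_vertices)
        dirs = centers[shell] / r[shell, None]
        _, nearest = tree.query(dirs, k=1)
        pial_r = config.base_radius_mm + thickness[nearest]
        gm_here = r[shell] < pial_r
        gm_value = np.full(gm_here.sum(), gm_mean)
        if affected and c_delta > 0 and effect is not None and effect.contrast_mask.size:
            in_mask = np.zeros(n, dtype=bool)
            in_mask[np.asarray(effect.contrast_mask, dtype=int)] = True
            affected_vox = in_mask[nearest[gm_here]]
            gm_value[affected_vox] = gm_mean + c_delta * (config.wm_mean - gm_mean)
        shell_idx = np.flatnonzero(shell)
        data[shell_idx[gm_here]] = gm_value

    if config.bias_amplitude > 0:
        data *= _bias_field(centers, config.bias_amplitude,
                            config.bias_wavelength_mm, rng)
    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, size=data.shape)

    volume = VolumeImage(data.reshape(shape).astype(np.float32), affine)
    truth = {
        "affected": bool(affected),
        "thickness_delta_mm": float(t_delta if affected else 0.0),
        "contrast_delta": float(c_delta if affected else 0.0),
        "gm_mean": float(gm_mean),
        "mean_thickness_mm": float(np.mean(thickness)),
    }
    return PhantomSubject(white, pial, volume, truth)


def make_cohort(
    config: PhantomConfig,
    effect: EffectSpec | None,
    n_affected: int,
    n_control: int,
    seed: int,
    affected_label: str = "AD",
    control_label: str = "CN",
) -> SyntheticCohort:
    """Generate a two-group cohort; affected subjects carry the effect.

    Subject seeds are spawned deterministically from ``seed``, so the
    cohort (meshes, volumes, table) is bit-reproducible.
    """
    if n_affected < 2 or n_control < 2:
        raise PhantomError("need at least 2 subjects per group")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_affected + n_control)
    subjects: list[PhantomSubject] = []
    rows = []
    for i in range(n_affected + n_control):
        affected = i < n_affected
        subj = make_phantom_subject(
            config, effect, np.random.default_rng(children[i]), affected=affected
        )
        sid = f"{'A' if affected else 'C'}{i:03d}"
        subjects.append(subj)
        rows.append(
            {
                "subject_id": sid,
                "label": affected_label if affected else control_label,
                **{f"true_{k}": v for k, v in subj.truth.items() if k != "affected"},
            }
        )
    table = pd.DataFrame(rows)
    return SyntheticCohort(subjects, table, effect, config)


def cognitive_scores(
    cohort: SyntheticCohort,
    contrast_coef: float = 20.0,
    thickness_coef: float = 5.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """FAQ-like impairment score generated from each subject's true effect.

    Higher = worse, driven by the realised contrast and thinning deltas
    plus Gaussian noise; controls score near zero.  Used to test the
    extra-region correlation analysis with a known generating model.
    """
    rng = np.random.default_rng(seed)
    scores = np.array(
        [
            contrast_coef * s.truth["contrast_delta"]
            + thickness_coef * s.truth["thickness_delta_mm"]
            for s in cohort.subjects
        ]
    )
    return scores + rng.normal(0.0, noise_sd, size=len(scores))
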