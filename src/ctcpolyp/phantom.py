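"""Synthetic CT-colonography phantom with voxel-level ground truth.

The phantom emulates the imaging situations the downstream stages must
handle: an air-distended, tube-like colon following a gently curved path,
haustral folds, small polyps of known height/width on the wall, a
gravitationally layered pool of tagged fluid with a partial-volume
transition layer at the air/fluid interface, a pseudo-enhancement halo
bleeding into nearby tissue, and additive Gaussian noise.  Ground truth
(material label map, lumen/boundary masks, per-polyp masks and true sizes)
is derived from the geometry alone, so it is independent of the noise.

Conventions: voxel axes are ``(slice, row, col)``; "gravity" is the +row
direction of each axial slice (supine patient); the fluid surface is a
horizontal plane.  All sizes are millimetres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from . import cleansing
from .cleansing import (
    AIR,
    CONTRAST,
    FAT,
    INTERFACE,
    SOFT_TISSUE,
    _TOLERANCES,
    build_lookup,
)
from .volume_io import CtVolume

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PolypSpec:
    """One polyp: position along/around the colon, true size, shape.

    ``z_frac`` is the fractional position along the slice axis, ``angle_deg``
    the position around the lumen circumference (90 deg = gravitational
    bottom).  ``height_mm`` is the protrusion depth into the lumen,
    ``width_mm`` the base diameter.  Shape is ``sessile`` (taller than
    broad), ``flat`` (broader than tall) or ``pedunculated``.
    """

    z_frac: float
    angle_deg: float
    height_mm: float
    width_mm: float
    shape: str = "sessile"


@dataclass(frozen=True)
class FoldSpec:
    """One haustral fold: a thin fin-like ridge protruding into the lumen.

    In an axial slice the fold appears as a radial fin ``height_mm`` tall
    and ``thickness_mm`` wide (arc direction), running ``length_mm`` along
    the colon; its medial axis points into the lumen, which is what the
    skeleton-based measurement relies on.
    """

    z_frac: float
    angle_deg: float = 90.0
    height_mm: float = 7.0
    thickness_mm: float = 3.0
    length_mm: float = 8.0


@dataclass(frozen=True)
class TaggingSpec:
    """Tagged residual fluid: pool size and HU.

    ``fill_fraction`` is the fraction of lumen voxels submerged (by row
    quantile).  The pool mean sits well above the +130 HU contrast
    threshold, as orally tagged fluid does clinically (several hundred HU);
    ``partially_tagged`` dilutes random patches of the pool to half HU to
    emulate inhomogeneous tagging.
    """

    fill_fraction: float = 0.3
    hu_mean: float = 500.0
    hu_sd: float = 15.0
    partially_tagged: bool = False


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple[int, int, int] = (40, 128, 128)  # (slices, rows, cols)
    spacing: tuple[float, float, float] = (0.7, 0.7, 1.25)  # (row, col, slice) mm
    kvp: float = 120.0
    radius_mm: float = 12.0
    wall_thickness_mm: float = 5.0
    path_amplitude_mm: float = 6.0
    # fold centres sit at diagonal clock positions: a wall-hugging crescent
    # centred on a scan-axis extreme is shadowed in both scan directions,
    # an inherent limit of scan-line stitching (see the methods note)
    folds: tuple[FoldSpec, ...] = (
        FoldSpec(z_frac=0.18, angle_deg=225.0),
        FoldSpec(z_frac=0.55, angle_deg=315.0),
        FoldSpec(z_frac=0.85, angle_deg=135.0),
    )
    # polyp positions also avoid the exact scan-axis extremes (0/90/180/270
    # degrees), where a cap's base lies beyond the contour's extreme scan
    # line and cannot be reached by stitching
    polyps: tuple[PolypSpec, ...] = (
        PolypSpec(z_frac=0.3, angle_deg=145.0, height_mm=4.0, width_mm=2.5),
        PolypSpec(z_frac=0.5, angle_deg=250.0, height_mm=4.0, width_mm=5.0, shape="flat"),
        PolypSpec(z_frac=0.72, angle_deg=35.0, height_mm=5.0, width_mm=6.0, shape="flat"),
    )
    tagging: TaggingSpec = TaggingSpec()
    noise_sd_hu: float = 1.0
    material_jitter_frac: float = 0.25  # per-material texture sd, as fraction of HU tolerance
    halo_amplitude_hu: float = 60.0
    halo_decay_mm: float = 1.5
    interface_thickness_vox: int = 2
    decoy_diameter_mm: float = 12.0  # small-bowel-like air pocket; 0 disables
    fluid_plane_row_mm: float | None = None  # explicit fluid surface override
    seed: int = 0


@dataclass(frozen=True)
class PolypTruth:
    polyp_id: int
    mask: np.ndarray
    height_mm: float
    width_mm: float
    shape: str
    center_mm: tuple[float, float, float]  # (slice, row, col) physical position
    slice_index: int


@dataclass
class PhantomTruth:
    """Ground truth emitted with every phantom volume."""

    label_map: np.ndarray  # material codes incl. INTERFACE
    lumen_mask: np.ndarray  # air + fluid + interface inside the colon
    boundary_mask: np.ndarray  # ~1-voxel ring just outside the lumen radius
    colon_region: np.ndarray  # lumen + structures + boundary ring (the VOI)
    tagged_mask: np.ndarray
    interface_mask: np.ndarray
    polyps: list[PolypTruth]
    fold_mask: np.ndarray
    fluid_plane_row_mm: float | None
    config: PhantomConfig


def _centerline(cfg: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-slice lumen centre (row_mm, col_mm): a gentle sigmoid-like S-path."""
    ns, nr, nc = cfg.shape
    z = np.arange(ns) / max(ns - 1, 1)
    r0 = (nr - 1) / 2.0 * cfg.spacing[0]
    c0 = (nc - 1) / 2.0 * cfg.spacing[1]
    a = cfg.path_amplitude_mm
    return (
        r0 + a * np.sin(2 * np.pi * z * 0.8),
        c0 + a * np.cos(2 * np.pi * z * 0.6 + 1.0),
    )


def generate_phantom(cfg: PhantomConfig) -> tuple[CtVolume, PhantomTruth]:
    """Generate a synthetic CTC volume and its ground truth.

    Deterministic for a fixed config (seed included): the same config
    yields a bit-identical volume and truth.
    """
    ns, nr, nc = cfg.shape
    row_sp, col_sp, slice_sp = cfg.spacing
    max_h = max((p.height_mm for p in cfg.polyps), default=0.0)
    if max_h >= cfg.radius_mm:
        raise ValueError(
            f"polyp height {max_h} mm does not fit inside lumen radius "
            f"{cfg.radius_mm} mm"
        )

    rows_mm = np.arange(nr)[None, :, None] * row_sp
    cols_mm = np.arange(nc)[None, None, :] * col_sp
    cr, cc = _centerline(cfg)
    dr = rows_mm - cr[:, None, None]
    dc = cols_mm - cc[:, None, None]
    rho = np.hypot(dr, dc)  # in-plane distance (mm) to the centreline
    theta = np.degrees(np.arctan2(dr, dc)) % 360.0  # 90 deg = +row = bottom
    z_mm = np.broadcast_to(
        (np.arange(ns) * slice_sp)[:, None, None], cfg.shape
    )

    lumen_geom = rho <= cfg.radius_mm
    wall = (rho > cfg.radius_mm) & (rho <= cfg.radius_mm + cfg.wall_thickness_mm)

    labels = np.full(cfg.shape, FAT, dtype=np.uint8)
    labels[wall] = SOFT_TISSUE
    labels[lumen_geom] = AIR

    # haustral folds: thin fin-like ridges protruding into the lumen
    fold_mask = np.zeros(cfg.shape, dtype=bool)
    z_extent = (ns - 1) * slice_sp
    for fold in cfg.folds:
        z0 = fold.z_frac * z_extent
        ddeg = np.abs((theta - fold.angle_deg + 180.0) % 360.0 - 180.0)
        arc_mm = rho * np.radians(ddeg)  # lateral offset from the fin plane
        ridge = (
            (np.abs(z_mm - z0) <= fold.length_mm / 2.0)
            & (rho >= cfg.radius_mm - fold.height_mm)
            & lumen_geom
            & (arc_mm <= fold.thickness_mm / 2.0)
        )
        fold_mask |= ridge
    labels[fold_mask] = SOFT_TISSUE

    # polyps: ellipsoidal caps protruding from the wall into the lumen
    polyps: list[PolypTruth] = []
    for pid, p in enumerate(cfg.polyps):
        z0 = p.z_frac * z_extent
        a = np.radians(p.angle_deg)
        u = np.array([np.sin(a), np.cos(a)])  # radial (row, col) direction
        t = np.array([np.cos(a), -np.sin(a)])  # wall tangent, in-plane
        slice_idx = int(round(z0 / slice_sp))
        base_r = cr[slice_idx] + cfg.radius_mm * u[0]
        base_c = cc[slice_idx] + cfg.radius_mm * u[1]
        lat = (rows_mm - base_r) * t[0] + (cols_mm - base_c) * t[1]
        depth = cfg.radius_mm - rho  # protrusion depth into the lumen
        half_w = p.width_mm / 2.0
        outward = dr * u[0] + dc * u[1]  # gate to the polyp's half-plane
        cap = (
            (depth >= 0)
            & (outward > 0)
            & lumen_geom
            & (
                (lat / half_w) ** 2
                + ((z_mm - z0) / half_w) ** 2
                + (depth / p.height_mm) ** 2
                <= 1.0
            )
        )
        cap &= ~fold_mask
        if not cap.any():
            raise ValueError(f"polyp {pid} produced an empty mask (too small?)")
        labels[cap] = SOFT_TISSUE
        polyps.append(
            PolypTruth(
                polyp_id=pid,
                mask=cap,
                height_mm=p.height_mm,
                width_mm=p.width_mm,
                shape=p.shape,
                center_mm=(z0, float(base_r), float(base_c)),
                slice_index=slice_idx,
            )
        )

    # decoy: a small-bowel-like air pocket in the body, to exercise the
    # distension-diameter blob filter
    if cfg.decoy_diameter_mm > 0:
        dec_r = cfg.radius_mm + cfg.wall_thickness_mm + cfg.decoy_diameter_mm
        pos_r = cr[ns // 2] - dec_r
        pos_c = cc[ns // 2] - dec_r
        dd = np.sqrt(
            (rows_mm - pos_r) ** 2
            + (cols_mm - pos_c) ** 2
            + (z_mm - z_mm[ns // 2, 0, 0]) ** 2
        )
        decoy = (dd <= cfg.decoy_diameter_mm / 2.0) & (labels == FAT)
        labels[decoy] = AIR

    # tagged fluid: fills the gravitationally lowest fraction of the lumen
    air_lumen = (labels == AIR) & lumen_geom
    plane_mm = cfg.fluid_plane_row_mm
    if plane_mm is None and cfg.tagging.fill_fraction > 0:
        lum_rows = rows_mm[0, :, 0][np.nonzero(air_lumen)[1]]
        plane_mm = float(np.quantile(lum_rows, 1.0 - cfg.tagging.fill_fraction))
    tagged = np.zeros(cfg.shape, dtype=bool)
    if plane_mm is not None:
        tagged = air_lumen & (np.broadcast_to(rows_mm, cfg.shape) >= plane_mm)
        labels[tagged] = CONTRAST

    # partial-volume transition layer on the air side of every air/fluid face
    interface = np.zeros(cfg.shape, dtype=bool)
    mix = np.zeros(cfg.shape, dtype=float)
    if tagged.any():
        structure = ndimage.generate_binary_structure(3, 1)
        ring = tagged
        t_vox = cfg.interface_thickness_vox
        for i in range(1, t_vox + 1):
            ring = ndimage.binary_dilation(ring, structure=structure)
            band = ring & (labels == AIR) & ~interface
            interface |= band
            mix[band] = 1.0 - i / (t_vox + 1.0)
        labels[interface] = INTERFACE

    # --- HU synthesis -------------------------------------------------------
    # independent full-volume noise fields keyed to the seed: voxel HU does
    # not depend on mask extents, so raising the fluid level (submersion)
    # leaves every tissue voxel's value bit-identical
    ss = np.random.SeedSequence(cfg.seed)
    r_jitter, r_tag, r_partial, r_noise = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    jitter_field = r_jitter.standard_normal(cfg.shape)
    tag_field = r_tag.standard_normal(cfg.shape)
    lut = build_lookup(cfg.kvp)
    hu = np.zeros(cfg.shape, dtype=float)
    for material in (AIR, FAT, SOFT_TISSUE):
        m = labels == material
        center = lut.centers[material]
        hu[m] = center + (_TOLERANCES[material] * cfg.material_jitter_frac) * jitter_field[m]
    hu[tagged] = cfg.tagging.hu_mean + cfg.tagging.hu_sd * tag_field[tagged]
    if cfg.tagging.partially_tagged and tagged.any():
        dilute = tagged & (r_partial.random(cfg.shape) < 0.3)
        hu[dilute] *= 0.5
    air_center = lut.centers[AIR]
    hu[interface] = air_center + mix[interface] * (cfg.tagging.hu_mean - air_center)

    # pseudo-enhancement halo: exponential HU elevation into nearby tissue.
    # Polyp voxels are kept halo-free so their HU (and hence the size
    # ground truth) is invariant under submersion.
    if tagged.any() and cfg.halo_amplitude_hu > 0:
        dist = ndimage.distance_transform_edt(
            ~tagged, sampling=(slice_sp, row_sp, col_sp)
        )
        tissueish = (labels == SOFT_TISSUE) | (labels == FAT)
        for p in polyps:
            tissueish &= ~p.mask
        near = tissueish & (dist <= 6.0 * cfg.halo_decay_mm)
        hu[near] += cfg.halo_amplitude_hu * np.exp(-dist[near] / cfg.halo_decay_mm)

    if cfg.noise_sd_hu > 0:
        hu += cfg.noise_sd_hu * r_noise.standard_normal(cfg.shape)

    vol = CtVolume(hu, cfg.spacing, kvp=cfg.kvp, meta={"phantom_seed": cfg.seed})

    inplane_px = max(row_sp, col_sp)
    boundary = (rho > cfg.radius_mm) & (rho <= cfg.radius_mm + inplane_px)
    # lumen disc (incl. all structures) plus the mucosal surface pixels:
    # pixels whose centre lies within half a pitch of the interface
    colon_region = rho <= cfg.radius_mm + inplane_px / 2.0
    lumen_mask = lumen_geom & (
        (labels == AIR) | (labels == CONTRAST) | (labels == INTERFACE)
    )
    truth = PhantomTruth(
        label_map=labels,
        lumen_mask=lumen_mask,
        boundary_mask=boundary,
        colon_region=colon_region,
        tagged_mask=tagged,
        interface_mask=interface,
        polyps=polyps,
        fold_mask=fold_mask,
        fluid_plane_row_mm=plane_mm,
        config=cfg,
    )
    return vol, truth


def submerge_polyp(
    truth: PhantomTruth, polyp_id: int, fraction: float
) -> tuple[CtVolume, PhantomTruth]:
    """Raise the tagged fluid so ``fraction`` of a polyp's height is submerged.

    The phantom is regenerated with the same seed and an explicit fluid
    plane, so polyp HU statistics are unchanged; only the pool rises.
    ``fraction=0`` reproduces the original phantom; ``fraction=1`` places
    the surface one voxel above the polyp so no polyp voxel touches air.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    ids = [p.polyp_id for p in truth.polyps]
    if polyp_id not in ids:
        raise KeyError(f"unknown polyp id {polyp_id}; have {ids}")
    cfg = truth.config
    if fraction == 0.0:
        return generate_phantom(cfg)
    polyp = truth.polyps[ids.index(polyp_id)]
    rows = np.nonzero(polyp.mask)[1] * cfg.spacing[0]
    rmin, rmax = float(rows.min()), float(rows.max())
    if fraction >= 1.0:
        plane = rmin - 1.5 * cfg.spacing[0]
    else:
        plane = rmax - fraction * (rmax - rmin)
    current = truth.fluid_plane_row_mm
    if current is not None:
        plane = min(plane, current)  # only ever raise the fluid
    return generate_phantom(replace(cfg, fluid_plane_row_mm=plane))


def random_polyp_config(
    seed: int,
    width_mm: float | None = None,
    shape: tuple[int, int, int] = (16, 96, 96),
) -> PhantomConfig:
    """A small single-polyp phantom for measurement recovery studies.

    Widths are drawn uniformly from 2-12 mm unless given; heights scale
    with width (aspect 0.8-1.2) so the protrusion axis points into the
    lumen, as for the sessile/fold-borne lesions the measurement targets.
    """
    rng = np.random.default_rng(seed)
    w = float(width_mm) if width_mm is not None else float(rng.uniform(2.0, 12.0))
    h = float(w * rng.uniform(0.8, 1.2))
    angle = float(rng.uniform(135.0, 405.0) % 360.0)  # keep clear of the pool
    return PhantomConfig(
        shape=shape,
        radius_mm=16.0,
        polyps=(PolypSpec(z_frac=0.5, angle_deg=angle, height_mm=h, width_mm=w),),
        folds=(),
        tagging=TaggingSpec(fill_fraction=0.0),
        decoy_diameter_mm=0.0,
        seed=seed,
    )
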