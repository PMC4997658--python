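"""Voxel taphonomy: erosion of dentary phantoms and artifact grooves.

A juvenile monotreme dentary that has already lost Meckel's cartilage can
retain only a faint lingual seam over the mandibular canal, where the bone
wall is thin and poorly mineralised.  Diagenetic surface attrition — here
modelled as morphological erosion of the binary bone volume, or as raising
the segmentation threshold of the greyscale volume — thins that wall from
both sides until the canal opens into a deep channel that closely resembles
a true Meckel's groove, while the rest of the bone surface keeps its
anatomical detail.  This module builds parametric greyscale phantoms with
exactly that architecture, applies erosion/thresholding, and measures the
artifact groove depth against a buccal control region.

Geometry convention: axis 0 is z (mesio-distal, along the jaw), axis 1 is
y (dorso-ventral), axis 2 is x (lingual-buccal; the lingual surface faces
low x).  Intensities are normalised to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelVolume",
    "GrooveProfile",
    "make_phantom",
    "erode",
    "threshold_surface",
    "groove_metric",
    "ErosionError",
]


class ErosionError(ValueError):
    pass


@dataclass
class VoxelVolume:
    """A 3D grid of intensities (greyscale in [0,1]) or a binary mask."""

    data: np.ndarray
    voxel_size_um: float = 30.0
    #: (y, x) position of the seam locus in cross-section, set by the phantom
    seam_locus: "tuple[int, int] | None" = None
    #: x coordinate of the cross-section centre (lingual/buccal divider)
    centre_x: "int | None" = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ErosionError("volume must be 3-dimensional")
        if self.data.dtype != bool and np.any(self.data < 0):
            raise ErosionError("intensities must be non-negative")

    @property
    def is_binary(self) -> bool:
        return self.data.dtype == bool

    def meta(self) -> dict:
        return dict(
            voxel_size_um=self.voxel_size_um,
            seam_locus=self.seam_locus,
            centre_x=self.centre_x,
        )

    def write_tiff(self, path) -> None:
        import tifffile

        arr = self.data.astype(np.uint8) * 255 if self.is_binary else (
            (self.data * 65535).astype(np.uint16)
        )
        tifffile.imwrite(str(path), arr)


@dataclass
class GrooveProfile:
    """Per-slice groove depth at the seam locus, plus control roughness."""

    depths: np.ndarray           # voxels, one entry per informative z slice
    control_rms: float           # buccal-side RMS surface deviation, voxels
    slices: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def mean_depth(self) -> float:
        return float(self.depths.mean()) if len(self.depths) else 0.0

    @property
    def max_depth(self) -> float:
        return float(self.depths.max()) if len(self.depths) else 0.0


# --------------------------------------------------------------- phantom


def make_phantom(
    length: int = 60,
    radius: int = 24,
    seam_depth: int = 2,
    seam_intensity_deficit: float = 0.2,
    shell_density_contrast: float = 0.3,
    noise_sd: float = 0.02,
    seed: int = 0,
    canal_radius: int = 4,
    canal_wall: int = 5,
) -> VoxelVolume:
    """Build a dentary-like greyscale phantom with a faint lingual seam.

    The phantom is an elongated half-cylinder (flat dorsal face) with a
    denser outer shell, an internal mandibular-canal tube running the full
    length near the lingual surface, and a shallow seam notch of
    ``seam_depth`` voxels on the lingual surface directly over the canal.
    The bone wall between seam floor and canal is ``canal_wall`` voxels
    thick and carries the seam's intensity deficit — the poorly
    mineralised infill whose attrition fabricates an artifact groove.
    """
    if seam_depth < 0:
        raise ErosionError("seam_depth must be non-negative")
    if seam_depth >= radius:
        raise ErosionError("seam deeper than the phantom radius")
    pad = 4
    ny = radius + 2 * pad
    nx = 2 * radius + 2 * pad
    if length * ny * nx < 40 ** 3 / 8:  # generous lower bound on size
        pass
    rng = np.random.default_rng(seed)
    cy = ny - pad          # circle centre sits at the flat dorsal face
    cx = nx // 2
    y, x = np.mgrid[0:ny, 0:nx]
    r2 = (x - cx) ** 2 + (y - cy) ** 2
    inside = (r2 <= radius ** 2) & (y <= cy)

    base = np.full((ny, nx), 0.0)
    base[inside] = 0.6
    shell = inside & (r2 >= (radius - 2) ** 2)
    base[shell] = 0.6 + shell_density_contrast

    # mandibular canal: tube near the lingual surface at the seam height
    y_seam = cy - radius // 2
    x_surf = cx - int(np.sqrt(max(radius ** 2 - (y_seam - cy) ** 2, 0)))
    canal_cx = x_surf + canal_wall + canal_radius
    canal = (x - canal_cx) ** 2 + (y - y_seam) ** 2 <= canal_radius ** 2
    base[canal] = 0.05

    # seam notch: remove seam_depth voxels of surface over the canal and
    # weaken the wall material beneath it
    for dy in (-1, 0, 1):
        yy = y_seam + dy
        row = np.flatnonzero(base[yy] > 0.1)
        if len(row) == 0:
            continue
        xs = row.min()
        depth = seam_depth if dy == 0 else max(seam_depth - 1, 0)
        base[yy, xs:xs + depth] = 0.0
        wall = np.s_[yy, xs + depth:canal_cx - canal_radius + 1]
        base[wall] = np.maximum(base[wall] - seam_intensity_deficit, 0.1)

    vol = np.repeat(base[None, :, :], length, axis=0)
    if noise_sd > 0:
        vol = vol + rng.normal(0.0, noise_sd, vol.shape)
    vol = np.clip(vol, 0.0, 1.0)
    return VoxelVolume(
        data=vol, seam_locus=(y_seam, x_surf), centre_x=cx
    )


# ------------------------------------------------------------ operations


def erode(volume: VoxelVolume, n_layers: int, connectivity: int = 6) -> VoxelVolume:
    """Morphological erosion removing ``n_layers`` of surface voxels.

    6-connectivity (face neighbours) by default; 26-connectivity available.
    Anti-extensive: the output is a subset of the input.
    """
    if not volume.is_binary:
        raise ErosionError("erode expects a binary volume (threshold first)")
    if n_layers < 0:
        raise ErosionError("n_layers must be non-negative")
    if connectivity not in (6, 26):
        raise ErosionError("connectivity must be 6 or 26")
    if n_layers == 0:
        return VoxelVolume(volume.data.copy(), **volume.meta())
    structure = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    out = ndimage.binary_erosion(
        volume.data, structure=structure, iterations=n_layers
    )
    if not out.any():
        warnings.warn("erosion removed the entire volume", stacklevel=2)
    return VoxelVolume(out, **volume.meta())


def threshold_surface(volume: VoxelVolume, level: float) -> VoxelVolume:
    """Binary mask of voxels with intensity >= level.

    Raising the level on a shell-contrast phantom strips the less dense
    material (seam infill, trabecular core) before the dense shell.
    """
    if volume.is_binary:
        raise ErosionError("volume is already binary")
    lo, hi = float(volume.data.min()), float(volume.data.max())
    if not lo <= level <= hi:
        raise ErosionError(f"level {level} outside intensity range [{lo}, {hi}]")
    mask = volume.data >= level
    if not mask.any():
        warnings.warn("threshold excludes every voxel", stacklevel=2)
    return VoxelVolume(mask, **volume.meta())


def _contour(slice2d: np.ndarray, side: str) -> "tuple[np.ndarray, np.ndarray]":
    """(ys, xs) of the lingual (min-x) or buccal (max-x) contour."""
    ys, xs = [], []
    for yy in range(slice2d.shape[0]):
        nz = np.flatnonzero(slice2d[yy])
        if len(nz):
            ys.append(yy)
            xs.append(nz[0] if side == "lingual" else nz[-1])
    return np.array(ys, float), np.array(xs, float)


def _convex_envelope(ys: np.ndarray, xs: np.ndarray, lower: bool) -> np.ndarray:
    """Convex envelope of x(y): lower minorant or upper majorant.

    The lower envelope is the lingual silhouette of the convex hull of the
    cross-section (the surface a seamless convex bone would show); the
    deviation of the actual contour from it is the groove/defect depth.
    """
    sign = 1.0 if lower else -1.0
    pts = list(zip(ys, sign * xs))
    hull: list[tuple[float, float]] = []
    for p in pts:
        while len(hull) >= 2:
            (y1, x1), (y2, x2) = hull[-2], hull[-1]
            # keep only convex (right) turns for a lower hull
            if (y2 - y1) * (p[1] - x1) - (p[0] - y1) * (x2 - x1) <= 0:
                hull.pop()
            else:
                break
        hull.append(p)
    hy = np.array([h[0] for h in hull])
    hx = np.array([h[1] for h in hull])
    return sign * np.interp(ys, hy, hx)


def groove_metric(
    volume: VoxelVolume,
    seam_locus: "tuple[int, int] | None" = None,
) -> GrooveProfile:
    """Measure groove depth at the seam and buccal control roughness.

    Depth per z slice = deviation of the lingual contour from its local
    convex hull, read at the seam row.  Control roughness = RMS deviation
    of the buccal contour from *its* convex hull, pooled over slices —
    uniform attrition of a convex surface leaves it near zero, anatomical
    damage inflates it.
    """
    if not volume.is_binary:
        raise ErosionError("groove_metric expects a binary volume")
    locus = seam_locus or volume.seam_locus
    if locus is None:
        raise ErosionError("seam locus unknown (not a phantom?)")
    y0 = locus[0]
    depths = []
    slices = []
    control_sq: list[float] = []
    for z in range(volume.data.shape[0]):
        sl = volume.data[z]
        if not sl.any():
            continue
        ys, xs = _contour(sl, "lingual")
        if y0 in ys and len(ys) >= 3:
            env = _convex_envelope(ys, xs, lower=True)
            dev = xs - env
            # voxelisation of a smooth convex contour leaves a sub-voxel
            # hull deviation everywhere; subtract that baseline
            baseline = float(np.median(dev))
            depths.append(max(float(dev[np.flatnonzero(ys == y0)[0]]) - baseline, 0.0))
            slices.append(z)
        bys, bxs = _contour(sl, "buccal")
        if len(bys) >= 3:
            benv = _convex_envelope(bys, bxs, lower=False)
            control_sq.extend(((benv - bxs) ** 2).tolist())
    if not depths:
        raise ErosionError("no slice intersects the phantom at the seam row")
    rms = float(np.sqrt(np.mean(control_sq))) if control_sq else 0.0
    return GrooveProfile(
        depths=np.array(depths), control_rms=rms, slices=np.array(slices, int)
    )
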