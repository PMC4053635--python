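"""Digital head-CT phantoms for the synthetic cohort.

Real baseline scans in this setting are acquired in two blocks — upper
cerebrum and brain base — and carry the radiological features that matter
for haemorrhage risk: focal ischemic hypoattenuation in the MCA territory,
a hyperdense MCA dot, periventricular white-matter change, and a diffuse
background texture standing in for small-vessel disease / atrophy burden.
The phantom renders each :class:`~sichml.cohort.LatentTruth` as a simple
ellipsoidal brain (parenchyma ~33 HU) with ventricles and a > 200 HU skull
shell, splits it into two overlapping sections, applies a small random
rigid jitter per section (imperfect spatial normalisation), and adds
Gaussian noise.  Everything is HU-valued and deterministic given the seed.

This is artifact plumbing, not an anatomical simulation: its job is to give
downstream stages images whose risk-relevant signal is controllable (the
``amplitude`` knob scales every truth-driven feature, so amplitude 0 yields
images that are pure anatomy plus noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from sichml.cohort import LatentTruth, Side
from sichml.preprocess import CTSection, SectionKind, _rigid_resample


@dataclass(frozen=True)
class GridSpec:
    """Common-grid geometry for the two-section acquisition.

    The lower (brain-base) section covers slices ``[0, lower_stop)``, the
    upper section ``[upper_start, nz)``; the two must overlap.
    """

    shape: tuple[int, int, int] = (64, 64, 40)
    spacing: tuple[float, float, float] = (3.0, 3.0, 4.0)   # mm
    upper_start: int = 12
    lower_stop: int = 16

    def __post_init__(self) -> None:
        if not self.upper_start < self.lower_stop <= self.shape[2]:
            raise ValueError("sections must overlap within the grid")

    @property
    def overlap_slices(self) -> int:
        return self.lower_stop - self.upper_start


@dataclass(frozen=True)
class SignalParams:
    """HU deltas of the truth-driven image features.

    ``amplitude`` scales them all; at 0 the rendered image is independent of
    the latent truth.
    """

    parenchyma_hu: float = 33.0
    ventricle_hu: float = 8.0
    skull_hu: float = 700.0
    lesion_delta: float = 8.0       # wedge hypoattenuation
    dot_delta: float = 32.0         # hyperdense vessel, above parenchyma
    fazekas_delta: float = 2.5      # per Fazekas grade, periventricular
    burden_texture_hu: float = 3.0  # texture SD per unit background burden
    amplitude: float = 1.0


def _normalized_radius(grid: GridSpec) -> np.ndarray:
    nx, ny, nz = grid.shape
    x, y, z = np.indices(grid.shape, dtype=float)
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    a, b, c = 0.42 * nx, 0.46 * ny, 0.44 * nz
    return np.sqrt(((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2)


def _ventricle_radius(grid: GridSpec) -> np.ndarray:
    """Min normalized distance to either lateral-ventricle ellipsoid."""
    nx, ny, nz = grid.shape
    x, y, z = np.indices(grid.shape, dtype=float)
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    a = 0.42 * nx
    out = np.full(grid.shape, np.inf)
    for sign in (-1.0, 1.0):
        vx, vy, vz = cx + sign * 0.18 * a, cy, cz + 0.05 * nz
        sa, sb, sc = 0.10 * nx, 0.22 * ny, 0.20 * nz
        r = np.sqrt(((x - vx) / sa) ** 2 + ((y - vy) / sb) ** 2 + ((z - vz) / sc) ** 2)
        out = np.minimum(out, r)
    return out


def brain_mask(grid: GridSpec) -> np.ndarray:
    """Inclusive brain mask without ventricles, with a safety margin inside
    the skull so small rigid jitter never drags bone into the mask."""
    return (_normalized_radius(grid) <= 0.90) & (_ventricle_radius(grid) > 1.0)


def wedge_mask(grid: GridSpec, side: Side, fraction: float) -> np.ndarray:
    """Ischemic wedge of relative angular size ``fraction`` of the MCA
    territory (taken as the lateral half-plane fan of one hemisphere)."""
    if fraction <= 0:
        return np.zeros(grid.shape, dtype=bool)
    nx, ny, nz = grid.shape
    x, y, z = np.indices(grid.shape, dtype=float)
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    lateral = 1.0 if side == Side.RIGHT else -1.0
    dx, dy = (x - cx) * lateral, y - cy
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.arccos(np.clip(dx / np.maximum(np.sqrt(dx**2 + dy**2), 1e-9), -1, 1))
    r = _normalized_radius(grid)
    half_angle = 0.5 * np.pi * min(fraction, 1.0)
    return ((phi <= half_angle) & (r >= 0.15) & (r <= 0.92)
            & (np.abs(z - cz) <= 0.55 * 0.44 * nz)
            & (_ventricle_radius(grid) > 1.0))


def hyperdense_locus_mask(grid: GridSpec, side: Side, dilate: int = 0) -> np.ndarray:
    """Spherical locus of the hyperdense MCA dot (optionally dilated, e.g. to
    tolerate rigid jitter when measuring)."""
    nx, ny, nz = grid.shape
    x, y, z = np.indices(grid.shape, dtype=float)
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    lateral = 1.0 if side == Side.RIGHT else -1.0
    dot = (cx + lateral * 0.55 * 0.42 * nx, cy - 0.05 * ny, cz)
    dist = np.sqrt((x - dot[0]) ** 2 + (y - dot[1]) ** 2 + (z - dot[2]) ** 2)
    mask = dist <= 1.6
    if dilate:
        mask = ndimage.binary_dilation(mask, iterations=dilate)
    return mask


def render_volume(truth: LatentTruth, grid: GridSpec,
                  signal: SignalParams, rng: np.random.Generator) -> np.ndarray:
    """Whole-head volume in canonical (template) space, before sectioning."""
    r = _normalized_radius(grid)
    vr = _ventricle_radius(grid)
    amp = signal.amplitude

    vol = np.zeros(grid.shape)
    brain = r <= 1.0
    skull = (r > 1.0) & (r <= 1.14)
    parenchyma = brain & (vr > 1.0)

    tissue = np.full(grid.shape, signal.parenchyma_hu)

    if truth.fazekas > 0 and amp > 0:
        cap = (vr > 1.0) & (vr <= 1.0 + 0.18 * truth.fazekas) & brain
        tissue[cap] -= signal.fazekas_delta * truth.fazekas * amp

    if truth.background_burden > 0 and amp > 0:
        field = ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma=2.0)
        sd = field.std()
        if sd > 0:
            field = np.clip(field / sd, -2.5, 2.5)
        tissue += field * signal.burden_texture_hu * truth.background_burden * amp

    if truth.ischemia_present and amp > 0:
        wedge = wedge_mask(grid, truth.lesion_side, truth.ischemia_fraction_mca)
        tissue[wedge] -= signal.lesion_delta * amp

    np.clip(tissue, 5.0, 150.0, out=tissue)

    if truth.hyperdense_mca and amp > 0:
        dot = hyperdense_locus_mask(grid, truth.lesion_side)
        tissue[dot] = signal.parenchyma_hu + signal.dot_delta * amp

    vol[parenchyma] = tissue[parenchyma]
    vol[brain & (vr <= 1.0)] = signal.ventricle_hu
    vol[skull] = signal.skull_hu
    return vol


def render_ct(truth: LatentTruth, grid: GridSpec | None = None,
              noise_sd: float = 2.0, seed: int = 0,
              signal: SignalParams | None = None,
              jitter: bool = True) -> tuple[CTSection, CTSection]:
    """Render a subject's two-section CT acquisition.

    Each section gets an independent small rigid jitter (in-plane translation
    SD 0.5 voxel truncated at 1.5, through-plane SD 0.25 truncated at 0.75,
    rotation SD 1 degree truncated at 2) emulating imperfect normalisation,
    then independent additive Gaussian noise.  Deterministic given ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    grid = grid or GridSpec()
    signal = signal or SignalParams()
    rng = np.random.default_rng(seed)
    vol = render_volume(truth, grid, signal, rng)

    sections = []
    for kind in (SectionKind.UPPER, SectionKind.LOWER):
        if jitter:
            shift = np.clip(rng.normal(0.0, [0.5, 0.5, 0.25]), -1.5, 1.5)
            shift[2] = np.clip(shift[2], -0.75, 0.75)
            theta = float(np.clip(rng.normal(0.0, np.deg2rad(1.0)),
                                  -np.deg2rad(2.0), np.deg2rad(2.0)))
            moved = _rigid_resample(vol, shift, theta)
        else:
            rng.normal(0.0, [0.5, 0.5, 0.25])   # keep the stream aligned
            rng.normal(0.0, np.deg2rad(1.0))
            moved = vol
        if kind == SectionKind.UPPER:
            z0, z1 = grid.upper_start, grid.shape[2]
        else:
            z0, z1 = 0, grid.lower_stop
        voxels = moved[:, :, z0:z1].copy()
        if noise_sd > 0:
            voxels += rng.normal(0.0, noise_sd, voxels.shape)
        sections.append(CTSection(voxels=voxels, spacing=grid.spacing,
                                  origin_offset=z0, section_kind=kind))
    return sections[0], sections[1]


def render_template_sections(grid: GridSpec,
                             signal: SignalParams | None = None
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free, feature-free template renderings of the two sections,
    used as registration targets by :func:`sichml.preprocess.normalize_section`."""
    signal = signal or SignalParams()
    blank = LatentTruth(ischemia_present=False, ischemia_fraction_mca=0.0,
                        hyperdense_mca=False, fazekas=0, background_burden=0.0,
                        lesion_side=Side.LEFT, sich_probability=0.0)
    vol = render_volume(blank, grid, signal, np.random.default_rng(0))
    return (vol[:, :, grid.upper_start:].copy(),
            vol[:, :, :grid.lower_stop].copy())
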