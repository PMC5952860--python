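"""Synthetic metacarpal-head phantom with known ground truth.

The phantom emulates the geometry the detection pipeline consumes: a
spherical cortical shell (bone ~1000 gray, marrow ~0) enclosing a rectangular
rod lattice of trabecular bone, with cylindrical interruption channels
drilled radially through the cortex and ellipsoidal (spherical) voids of
requested volume carved beneath them. Gaussian blur then additive Gaussian
noise model the imaging chain; a two-level gray model is used deliberately —
the algorithm consumes binary morphology downstream, so geometric fidelity is
what matters, not CT physics.

Whenever space allows, an extra *decoy* void (large enough to pass the
diameter threshold but unconnected to any interruption) is placed at the
joint centre, so the connectivity filter of the void-extension stage is
exercised both positively and negatively.

Default dimensions follow the clinical acquisition: 82 μm voxels, a
~4 mm-radius head (about half a metacarpal-head width), 0.8 mm cortex, and a
trabecular lattice whose 3D pore diameter (what Tb.Sp measures) is ~0.63 mm —
below the 0.738 mm void threshold, so normal marrow spacing never qualifies
as a void. Rods are drawn ~3 voxels wide, the apparent trabecular thickness
of binary HR-pQCT images at this resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import BinaryMask, ImageVolume

__all__ = [
    "InterruptionSpec",
    "PhantomSpec",
    "PhantomTruth",
    "make_joint_phantom",
    "rescan_variant",
    "make_scan_pair",
]

BONE_GRAY = 1000.0


@dataclass
class InterruptionSpec:
    """One drilled cortical interruption.

    ``position`` is a direction vector (z, y, x) from the joint centre; the
    channel is drilled radially along it. ``void_volume_mm3`` = 0 drills a
    channel with no sub-cortical void.
    """

    diameter_mm: float
    void_volume_mm3: float = 0.0
    position: tuple[float, float, float] = (0.0, 0.0, 1.0)


@dataclass
class PhantomSpec:
    """Full description of a synthetic joint; the seed determines everything."""

    shape_voxels: tuple[int, int, int] = (110, 110, 110)
    voxel_size_mm: float = 0.082
    outer_radius_mm: float = 4.0
    cortex_thickness_mm: float = 0.8
    #: drawn rod width; ~3 voxels, the apparent (binary) trabecular thickness
    #: at this resolution — thinner rods do not survive the imaging blur
    trabecular_rod_mm: float = 0.25
    #: target 3D pore diameter of the lattice (what Tb.Sp measures); the
    #: axis-aligned rod gap is spacing / sqrt(2) so the largest sphere fitting
    #: the pore diagonal has this diameter
    trabecular_spacing_mm: float = 0.63
    #: depth of the cortical detection peel the phantom is built for; carved
    #: voids reach up to this depth below the periosteal surface, as a real
    #: erosion cavity replaces the cortex it destroyed
    cortical_peel_mm: float = 0.328
    interruptions: list[InterruptionSpec] = field(default_factory=list)
    noise_sigma: float = 50.0
    #: imaging point-spread, sigma of the Gaussian; ~0.13 mm FWHM
    blur_sigma_mm: float = 0.055
    seed: int = 0
    add_decoy_void: bool = True

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be > 0")
        half_extent = min(self.shape_voxels) * self.voxel_size_mm / 2.0
        if self.outer_radius_mm >= half_extent:
            raise ValueError("outer radius does not fit in the volume")
        if self.cortex_thickness_mm >= self.outer_radius_mm:
            raise ValueError("cortex thicker than the object radius")
        for it in self.interruptions:
            if it.diameter_mm >= 2 * self.outer_radius_mm:
                raise ValueError("interruption diameter exceeds object extent")


@dataclass
class TruthComponent:
    """Ground truth of one interruption + void pair.

    ``channel_volume_mm3`` counts drilled channel voxels in the cortical
    shell outside the void; ``peel_channel_volume_mm3`` restricts that to the
    detection peel (the top ``cortical_peel_mm`` of the shell), which is the
    part the interruption-detection stage can report. The carved void volume
    is exact by construction: carved voxel count times the voxel volume.
    """

    diameter_mm: float
    channel_volume_mm3: float
    peel_channel_volume_mm3: float
    void_volume_mm3: float
    centre_vox: tuple[float, float, float]


@dataclass
class PhantomTruth:
    """Everything the generator knows about the volume it built."""

    n_interruptions: int
    components: list[TruthComponent]
    bone: BinaryMask
    cortex: BinaryMask
    void: BinaryMask  # union of carved sub-cortical voids (no decoy)
    decoy: BinaryMask
    clean: np.ndarray  # blurred, noise-free gray volume
    voxel_size_mm: float

    @property
    def total_void_volume_mm3(self) -> float:
        return float(sum(c.void_volume_mm3 for c in self.components))


def _radial_grids(shape: tuple[int, int, int], v: float):
    """Physical coordinate grids (mm) centred on the volume centre."""
    centre = [(s - 1) / 2.0 for s in shape]
    axes = [(np.arange(s) - c) * v for s, c in zip(shape, centre)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _rod_lattice(coords, pitch: float, rod: float) -> np.ndarray:
    """Union of square rods along all three axes on a cubic grid."""
    z, y, x = coords
    half = rod / 2.0

    def stripe(c):
        return np.abs(((c + half) % pitch) - half) <= half

    sz, sy, sx = stripe(z), stripe(y), stripe(x)
    rods_z = sy & sx
    rods_y = sz & sx
    rods_x = sz & sy
    return rods_z | rods_y | rods_x


def make_joint_phantom(spec: PhantomSpec) -> tuple[ImageVolume, PhantomTruth]:
    """Build the phantom volume and its ground truth. Deterministic per seed."""
    v = spec.voxel_size_mm
    z, y, x = _radial_grids(spec.shape_voxels, v)
    r = np.sqrt(z**2 + y**2 + x**2)
    R = spec.outer_radius_mm
    R_in = R - spec.cortex_thickness_mm

    shell = (r <= R) & (r >= R_in)
    interior = r < R_in
    pitch = spec.trabecular_rod_mm + spec.trabecular_spacing_mm / np.sqrt(2.0)
    lattice = _rod_lattice((z, y, x), pitch, spec.trabecular_rod_mm) & interior
    bone = shell | lattice

    components: list[TruthComponent] = []
    void_union = np.zeros(spec.shape_voxels, dtype=bool)
    carve_union = np.zeros(spec.shape_voxels, dtype=bool)
    centre_vox = [(s - 1) / 2.0 for s in spec.shape_voxels]

    for it in spec.interruptions:
        u = np.asarray(it.position, dtype=float)
        norm = np.linalg.norm(u)
        if norm == 0:
            raise ValueError("interruption position must be a nonzero direction")
        u = u / norm
        axial = z * u[0] + y * u[1] + x * u[2]
        perp2 = np.maximum(r**2 - axial**2, 0.0)

        if it.void_volume_mm3 > 0:
            rv = (3.0 * it.void_volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
            if rv >= R_in:
                raise ValueError("void larger than the trabecular interior")
            # void top touches the bottom of the detection peel: an erosion
            # cavity replaces the cortical bone it destroyed
            a_c = R - spec.cortical_peel_mm - rv
            if a_c - rv <= -R_in:
                raise ValueError("void larger than the trabecular interior")
        else:
            rv = 0.0
            a_c = R_in - 0.5

        channel = (
            (perp2 <= (it.diameter_mm / 2.0) ** 2)
            & (axial >= a_c)
            & (axial <= R + 2 * v)
        )
        carved = channel.copy()
        void_sphere = np.zeros(spec.shape_voxels, dtype=bool)
        if rv > 0:
            cz, cy, cx = a_c * u
            void_sphere = (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= rv**2
            carved |= void_sphere

        if (carve_union & carved).any():
            raise ValueError("overlapping interruptions in the phantom spec")
        carve_union |= carved
        void_union |= void_sphere

        centre = tuple(c + off / v for c, off in zip(centre_vox, a_c * u))
        ch_shell = channel & shell & ~void_sphere
        ch_peel = ch_shell & (r >= R - spec.cortical_peel_mm)
        components.append(
            TruthComponent(
                diameter_mm=it.diameter_mm,
                channel_volume_mm3=float(ch_shell.sum()) * v**3,
                peel_channel_volume_mm3=float(ch_peel.sum()) * v**3,
                void_volume_mm3=float(void_sphere.sum()) * v**3,
                centre_vox=centre,
            )
        )
        bone &= ~carved

    # decoy: unconnected control void at the joint centre, only when it stays
    # clear of every carved structure
    decoy = np.zeros(spec.shape_voxels, dtype=bool)
    if spec.add_decoy_void and spec.interruptions:
        decoy_r = 0.5
        margin = 0.3
        clear = all(
            (c.centre_vox is not None)
            and (
                (np.linalg.norm(np.array(c.centre_vox) - np.array(centre_vox)) * v)
                > decoy_r
                + (3.0 * c.void_volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
                + margin
                if c.void_volume_mm3 > 0
                else True
            )
            for c in components
        )
        if clear and decoy_r + margin < R_in:
            decoy = r <= decoy_r
            if not (decoy & carve_union).any():
                bone &= ~decoy
            else:
                decoy[:] = False

    gray = bone.astype(float) * BONE_GRAY
    if spec.blur_sigma_mm > 0:
        gray = ndimage.gaussian_filter(gray, sigma=spec.blur_sigma_mm / v)
    clean = gray.copy()
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        gray = gray + rng.normal(0.0, spec.noise_sigma, size=gray.shape)

    cortex_truth = shell & bone
    truth = PhantomTruth(
        n_interruptions=len(spec.interruptions),
        components=components,
        bone=BinaryMask(bone, v, "bone"),
        cortex=BinaryMask(cortex_truth, v, "cortical_mask"),
        void=BinaryMask(void_union, v, "void"),
        decoy=BinaryMask(decoy, v, "void"),
        clean=clean,
        voxel_size_mm=v,
    )
    return ImageVolume(gray, v), truth


def _int_shift(data: np.ndarray, shift: tuple[int, int, int]) -> np.ndarray:
    """Integer-voxel rigid shift with zero fill."""
    out = np.zeros_like(data)
    src = []
    dst = []
    for s, n in zip(shift, data.shape):
        if abs(s) >= n:
            return out
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = data[tuple(src)]
    return out


def rescan_variant(
    vol: ImageVolume,
    truth: PhantomTruth | None,
    seed: int,
    max_shift_voxels: int = 3,
    noise_sigma: float = 50.0,
    shift: tuple[int, int, int] | None = None,
) -> tuple[ImageVolume, tuple[int, int, int]]:
    """Repositioned "re-scan": small rigid integer shift plus a fresh noise draw.

    The shift is drawn uniformly in ``[-max_shift, max_shift]`` per axis
    unless given explicitly. Pass the *clean* volume (``truth.clean``) to
    model two independent scans of the same joint. Zero shift and zero noise
    return an identical volume.
    """
    rng = np.random.default_rng(seed)
    if shift is None:
        shift = tuple(int(s) for s in rng.integers(-max_shift_voxels, max_shift_voxels + 1, 3))
    if any(abs(s) > max_shift_voxels for s in shift):
        raise ValueError(f"shift {shift} exceeds max_shift_voxels={max_shift_voxels}")
    data = _int_shift(np.asarray(vol.data, dtype=float), shift)
    if noise_sigma > 0:
        data = data + rng.normal(0.0, noise_sigma, size=data.shape)
    return ImageVolume(data, vol.voxel_size_mm), shift


def make_scan_pair(
    spec: PhantomSpec, max_shift_voxels: int = 3
) -> tuple[ImageVolume, ImageVolume, PhantomTruth]:
    """Scan/re-scan pair of one phantom with independent noise realizations.

    Scan 1 is the phantom as generated; scan 2 is the clean volume rigidly
    shifted and given a fresh noise draw — emulating repositioning between
    acquisitions.
    """
    vol1, truth = make_joint_phantom(spec)
    clean = ImageVolume(truth.clean, spec.voxel_size_mm)
    vol2, _ = rescan_variant(
        clean,
        truth,
        seed=spec.seed + 1,
        max_shift_voxels=max_shift_voxels,
        noise_sigma=spec.noise_sigma,
    )
    return vol1, vol2, truth
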