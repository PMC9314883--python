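"""Seeded synthetic phantoms, MR-like images, DREAM acquisitions and E-fields.

Every generator here is a pure function of its spec/seed so that the whole
segmentation + dosimetry pipeline is testable without any downloaded data.
The phantom is a minimal head anatomy — nested ellipsoidal shells (fat,
muscle, skull, CSF, gray matter, white matter) on a neck column, with two
eye spheres and paranasal-sinus-like air cavities inside the bone — chosen
to reproduce every tissue adjacency the SAR averaging has to handle, not to
be anatomically realistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import (
    DEFAULT_ORIENTATION,
    FieldSet,
    ImageVolume,
    LabelVolume,
    TissueLabel,
    check_same_geometry,
)

__all__ = [
    "PhantomSpec",
    "PhantomError",
    "DEFAULT_T1W_MEANS",
    "make_phantom",
    "enforce_skin_layer",
    "simulate_t1w",
    "make_synthetic_b1",
    "simulate_dream",
    "make_efields",
    "ball",
]

log = logging.getLogger(__name__)


class PhantomError(ValueError):
    """Raised when a phantom spec cannot be realized (e.g. grid too small)."""


#: Typical T1-weighted tissue intensities (arbitrary units, unit bias).
#: White matter is brightest among brain tissues, CSF dark, fat bright.
DEFAULT_T1W_MEANS: dict[int, float] = {
    int(TissueLabel.BACKGROUND): 0.0,
    int(TissueLabel.INTERNAL_AIR): 0.03,
    int(TissueLabel.BONE): 0.20,
    int(TissueLabel.MUSCLE): 0.50,
    int(TissueLabel.FAT): 0.95,
    int(TissueLabel.WHITE_MATTER): 0.78,
    int(TissueLabel.GRAY_MATTER): 0.55,
    int(TissueLabel.CSF): 0.12,
    int(TissueLabel.EYE): 0.32,
}


@dataclass
class PhantomSpec:
    """Parameters of the synthetic head phantom.

    ``shell_fractions`` are the outer radii of the concentric head shells as
    fractions of the head semi-axes, ordered from the surface inwards.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    seed: int = 0
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    shell_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "fat": 1.0,
            "muscle": 0.88,
            "bone": 0.76,
            "csf": 0.66,
            "gray_matter": 0.57,
            "white_matter": 0.46,
        }
    )
    cavity_count: int = 2
    noise_sd: float = 0.05
    neck_dropoff_strength: float = 0.75
    jitter: float = 0.03

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if any(s <= 0 for s in self.shape):
            raise PhantomError("phantom shape must be positive")
        if self.noise_sd < 0:
            raise PhantomError("noise_sd must be non-negative")


def ball(radius: int) -> np.ndarray:
    """Boolean Euclidean ball structuring element of the given voxel radius."""
    r = int(radius)
    ax = np.arange(-r, r + 1)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return x * x + y * y + z * z <= r * r


def _ellipsoid_r2(shape, center, semi):
    idx = [np.arange(n, dtype=np.float64) for n in shape]
    x, y, z = np.meshgrid(*idx, indexing="ij", sparse=True)
    return (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    )


def make_phantom(spec: PhantomSpec) -> LabelVolume:
    """Generate a labeled head phantom.

    Deterministic for a fixed seed.  All nine label codes are present in the
    output; internal-air cavities are surrounded by at least 2 voxels of
    bone (a >=2 mm wall at 1 mm voxels), mirroring how paranasal sinuses sit
    inside the cranial bone.

    Raises
    ------
    PhantomError
        If the grid is too small to contain the nested shells.
    """
    nx, ny, nz = spec.shape
    if min(spec.shape) < 32:
        raise PhantomError(
            f"shape {spec.shape} too small to contain the nested tissue shells"
        )
    rng = np.random.default_rng(spec.seed)

    # head ellipsoid sits in the superior part of the grid (axis 2 = I->S)
    jit = lambda: 1.0 + spec.jitter * rng.uniform(-1.0, 1.0)  # noqa: E731
    center = np.array([nx / 2 * jit(), ny / 2 * jit(), 0.62 * nz * jit()])
    semi = np.array([0.40 * nx * jit(), 0.44 * ny * jit(), 0.36 * nz * jit()])

    r2 = _ellipsoid_r2(spec.shape, center, semi)
    grid = np.zeros(spec.shape, dtype=np.int16)
    sf = spec.shell_fractions
    shells = [
        (sf["fat"], TissueLabel.FAT),
        (sf["muscle"], TissueLabel.MUSCLE),
        (sf["bone"], TissueLabel.BONE),
        (sf["csf"], TissueLabel.CSF),
        (sf["gray_matter"], TissueLabel.GRAY_MATTER),
        (sf["white_matter"], TissueLabel.WHITE_MATTER),
    ]
    for frac, code in shells:
        grid[r2 <= frac * frac] = code

    # neck column from the inferior edge up to the head centre
    idx = [np.arange(n, dtype=np.float64) for n in spec.shape]
    x, y, z = np.meshgrid(*idx, indexing="ij", sparse=True)
    neck_r = 0.55 * semi[0]
    rad2 = ((x - center[0]) / neck_r) ** 2 + ((y - (center[1] - 0.08 * ny)) / neck_r) ** 2
    neck = (rad2 <= 1.0) & (z < center[2]) & (grid == 0)
    grid[neck & (rad2 > 0.81)] = TissueLabel.FAT
    grid[neck & (rad2 <= 0.81)] = TissueLabel.MUSCLE
    grid[neck & (rad2 <= 0.09)] = TissueLabel.BONE  # spine-like core

    # two eye spheres, anterior at mid-head level, embedded in the body
    eye_r = max(3.0, 0.18 * semi[0])
    body = grid != 0
    for sx in (-1.0, 1.0):
        ec = center + np.array([sx * 0.38 * semi[0], 0.80 * semi[1], 0.12 * semi[2]])
        sph = ((x - ec[0]) ** 2 + (y - ec[1]) ** 2 + (z - ec[2]) ** 2) <= eye_r**2
        grid[sph & body] = TissueLabel.EYE

    # paranasal-sinus-like air cavities inside the bone shell, anterior-inferior
    cav_r = max(2.5, 0.14 * semi[0])
    wall = 2  # voxels of bone enforced around each cavity
    cavity_mask = np.zeros(spec.shape, dtype=bool)
    for c in range(max(1, int(spec.cavity_count))):
        ang = rng.uniform(-0.5, 0.5)
        cc = center + np.array(
            [
                np.sin(ang) * 0.30 * semi[0],
                np.cos(ang) * 0.75 * semi[1] * 0.92,
                -0.35 * semi[2] + rng.uniform(-0.05, 0.05) * semi[2],
            ]
        )
        sph = ((x - cc[0]) ** 2 + (y - cc[1]) ** 2 + (z - cc[2]) ** 2) <= cav_r**2
        cavity_mask |= sph
    shell = ndimage.binary_dilation(cavity_mask, structure=ball(wall)) & ~cavity_mask
    grid[shell] = TissueLabel.BONE
    grid[cavity_mask] = TissueLabel.INTERNAL_AIR

    present = set(np.unique(grid).tolist())
    missing = [n for c, n in enumerate(  # pragma: no branch
        ("background", "internal_air", "bone", "muscle", "fat",
         "white_matter", "gray_matter", "csf", "eye")) if c not in present]
    if missing:
        raise PhantomError(
            f"shape {spec.shape} too small: tissue classes {missing} not realizable"
        )
    return LabelVolume(grid, spec.voxel_size, DEFAULT_ORIENTATION)


def enforce_skin_layer(labels: LabelVolume, thickness_mm: float = 1.0) -> LabelVolume:
    """Relabel fat within ``thickness_mm`` of the background as muscle.

    This emulates enforcing a skin layer on the body surface: subcutaneous
    fat at the outer boundary of the body is replaced by (skin-like) muscle.
    Idempotent; all non-fat voxels are left unchanged.
    """
    if thickness_mm < min(labels.voxel_size):
        raise ValueError("skin thickness must be at least one voxel")
    out = labels.copy()
    body = labels.body_mask()
    # distance (mm) from each body voxel to the nearest background voxel
    dist = ndimage.distance_transform_edt(body, sampling=labels.voxel_size)
    surface_fat = (labels.grid == TissueLabel.FAT) & (dist <= thickness_mm + 1e-9)
    out.grid[surface_fat] = TissueLabel.MUSCLE
    return out


def simulate_t1w(
    labels: LabelVolume,
    bias: ImageVolume,
    noise_sd: float,
    seed: int,
    means: dict[int, float] | None = None,
    noise_model: str = "gaussian",
    noise_profile: np.ndarray | None = None,
) -> ImageVolume:
    """Piecewise-constant T1w-like image times a multiplicative bias, plus noise.

    ``noise_sd`` is the noise standard deviation in the same (order-one)
    intensity units as the tissue means.  ``noise_model`` is ``"gaussian"``
    (default) or ``"rician"``; MR magnitude noise is Rician but Gaussian is
    an adequate high-SNR approximation.  ``noise_profile`` optionally
    modulates the noise SD spatially: at 7T the thermal noise is dominated
    by the body and scales with the receive sensitivity, so passing the
    (mean-normalized) receive profile here reproduces body-noise-dominated
    array data; the default is spatially uniform noise.
    """
    check_same_geometry(labels, bias, "labels/bias")
    if np.any(bias.grid <= 0):
        raise ValueError("bias field must be strictly positive")
    means = DEFAULT_T1W_MEANS if means is None else means
    lut = np.zeros(9, dtype=np.float64)
    for code, mu in means.items():
        lut[int(code)] = mu
    signal = lut[labels.grid] * bias.grid
    sd = noise_sd
    if noise_profile is not None:
        prof = np.asarray(noise_profile, dtype=np.float64)
        if prof.shape != labels.shape:
            raise ValueError("noise_profile geometry mismatch")
        sd = noise_sd * prof / prof.mean()
    rng = np.random.default_rng(seed)
    if noise_sd == 0:
        img = signal
    elif noise_model == "gaussian":
        img = signal + sd * rng.standard_normal(signal.shape)
    elif noise_model == "rician":
        n1 = sd * rng.standard_normal(signal.shape)
        n2 = sd * rng.standard_normal(signal.shape)
        img = np.sqrt((signal + n1) ** 2 + n2**2)
    else:
        raise ValueError(f"unknown noise model {noise_model!r}")
    return ImageVolume(img, labels.voxel_size, labels.orientation)


def make_synthetic_b1(
    labels: LabelVolume,
    neck_dropoff_strength: float = 0.75,
    b1_amplitude: float = 0.6,
    receive_amplitude: float = 1.0,
    seed: int = 0,
) -> tuple[ImageVolume, ImageVolume]:
    """Smooth synthetic transmit/receive profiles over the phantom grid.

    Returns ``(b1plus, m0b1minus)``.  The transmit map shows the typical 7T
    centre brightening, and a logistic attenuation towards the inferior
    (neck) end of the grid whose depth is set by ``neck_dropoff_strength``
    in [0, 1] — this is the physical source of the severe intensity
    drop-off towards the neck in 7T head data.  The receive-weighted
    proton-density map carries a strong peripheral brightening
    (``receive_amplitude``) as produced by a sum-of-squares combination of
    a close-fitting receive array.
    """
    nx, ny, nz = labels.shape
    rng = np.random.default_rng(seed)
    idx = [np.arange(n, dtype=np.float64) for n in labels.shape]
    x, y, z = np.meshgrid(*idx, indexing="ij", sparse=True)
    # centre-brightening bump, slightly off-centre as in a real CP drive,
    # so the bias varies appreciably even across the brain
    cx = nx / 2 + 0.08 * nx * rng.uniform(-1, 1)
    cy = ny / 2 + 0.08 * ny * rng.uniform(-1, 1)
    cz = 0.62 * nz
    rho2 = ((x - cx) / (0.50 * nx)) ** 2 + ((y - cy) / (0.50 * ny)) ** 2 + (
        (z - cz) / (0.50 * nz)
    ) ** 2
    b1 = 1.0 + b1_amplitude * (np.exp(-rho2 / 0.45) - 0.35)
    s = float(np.clip(neck_dropoff_strength, 0.0, 1.0))
    # the transmit field decays over several centimetres towards the neck
    z0, w = 0.30 * nz, 0.10 * nz
    neck = (1.0 - s) + s / (1.0 + np.exp(-(z - z0) / w))
    b1 = b1 * neck
    b1 = np.maximum(b1, 1e-3)
    # receive profile: array-like peripheral brightening plus a mild
    # random low-order ripple and an inferior-superior gradient
    phase = rng.uniform(0, 2 * np.pi)
    rr2 = ((x - nx / 2) / (0.5 * nx)) ** 2 + ((y - ny / 2) / (0.5 * ny)) ** 2
    m0b1m = (
        1.0
        + receive_amplitude * (rr2 - 0.5)
        + 0.2 * np.sin(2 * np.pi * (x / nx) + phase) * np.cos(np.pi * (y / ny))
        + 0.1 * ((z - cz) / nz)
    )
    m0b1m = np.maximum(m0b1m, 0.15) + 0.0 * b1
    b1 = np.broadcast_to(b1, labels.shape).copy()
    m0b1m = np.broadcast_to(m0b1m, labels.shape).copy()
    return (
        ImageVolume(b1, labels.voxel_size, labels.orientation),
        ImageVolume(m0b1m, labels.voxel_size, labels.orientation),
    )


def simulate_dream(
    b1plus: ImageVolume,
    m0b1minus: ImageVolume,
    steam_angle: float = 50.0,
    imaging_angle: float = 10.0,
) -> tuple[ImageVolume, ImageVolume]:
    """Forward DREAM signal model: stimulated-echo and FID image pair.

    With actual STEAM flip ``a = b1plus * steam_angle`` and imaging flip
    ``b = b1plus * imaging_angle`` the (noiseless) signals are::

        FID = M0B1- * sin(b) * cos^2(a)
        STE = M0B1- * sin(b) * sin^2(a) / 2

    so that ``arctan(sqrt(2*STE/FID))`` recovers ``a`` exactly — the
    round-trip contract with :func:`persardose.bias.dream_maps`.
    """
    check_same_geometry(b1plus, m0b1minus, "b1plus/m0b1minus")
    if np.any(b1plus.grid < 0):
        raise ValueError("b1plus must be non-negative (relative flip-angle units)")
    a = b1plus.grid * np.deg2rad(steam_angle)
    b = b1plus.grid * np.deg2rad(imaging_angle)
    fid = m0b1minus.grid * np.sin(b) * np.cos(a) ** 2
    ste = 0.5 * m0b1minus.grid * np.sin(b) * np.sin(a) ** 2
    return b1plus.like(ste), b1plus.like(fid)


def make_efields(
    labels: LabelVolume,
    channels: int,
    seed: int,
    smoothness_mm: float = 25.0,
    rms_v_per_m: float = 20.0,
    normalization: float = 1.0,
) -> FieldSet:
    """Smooth random complex multi-channel E-fields over the body support.

    Each channel is band-limited complex Gaussian noise (Gaussian-kernel
    smoothing with correlation length ``smoothness_mm``) modulated by a
    channel-specific plane-wave phase ramp and a proximity envelope from a
    loop-array-like azimuthal channel placement around the head.  Fields
    are zero outside the body and deterministic per seed.  Not
    Maxwell-consistent by design: the dosimetry math downstream is
    field-source agnostic.
    """
    if channels < 1:
        raise ValueError("channels must be >= 1")
    nx, ny, nz = labels.shape
    vx = np.asarray(labels.voxel_size)
    rng = np.random.default_rng(seed)
    body = labels.body_mask()

    # physical coordinates (mm)
    idx = [np.arange(n, dtype=np.float64) * v for n, v in zip(labels.shape, vx)]
    x, y, z = np.meshgrid(*idx, indexing="ij", sparse=True)
    cx, cy, cz = nx * vx[0] / 2, ny * vx[1] / 2, nz * vx[2] / 2
    extent = max(nx * vx[0], ny * vx[1])
    ring_r = 0.75 * extent
    lam = 130.0  # mm, roughly the RF wavelength in tissue at 300 MHz
    # autocorrelation of Gaussian-smoothed white noise is exp(-r^2/(4 s^2));
    # s = smoothness/sqrt(2) puts the 1/sqrt(e) decay at r = smoothness_mm
    sigma_vox = (smoothness_mm / np.sqrt(2.0)) / vx

    from scipy.ndimage import gaussian_filter

    E = np.zeros((channels, 3, nx, ny, nz), dtype=np.complex128)
    for c in range(channels):
        theta = 2 * np.pi * c / channels
        ux, uy = np.cos(theta), np.sin(theta)
        px, py = cx + ring_r * ux, cy + ring_r * uy
        d2 = (x - px) ** 2 + (y - py) ** 2 + 0.0 * z
        env = 1.0 / (1.0 + d2 / (0.5 * extent) ** 2)
        ramp = np.exp(2j * np.pi * ((x - cx) * ux + (y - cy) * uy) / lam)
        mod = env * ramp
        for comp in range(3):
            g = rng.standard_normal((nx, ny, nz)) + 1j * rng.standard_normal(
                (nx, ny, nz)
            )
            g = gaussian_filter(g.real, sigma_vox) + 1j * gaussian_filter(
                g.imag, sigma_vox
            )
            E[c, comp] = g * mod
    E[:, :, ~body] = 0.0
    rms = np.sqrt(np.mean(np.sum(np.abs(E[:, :, body]) ** 2, axis=1)))
    if rms > 0:
        E *= rms_v_per_m / rms
    return FieldSet(
        E,
        voxel_volume=labels.voxel_volume_m3,
        normalization=normalization,
        voxel_size=labels.voxel_size,
    )
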