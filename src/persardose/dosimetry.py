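"""Pointwise and 10 g-averaged SAR, Q-matrices, and RF-shim exposure statistics.

Fields use the peak-amplitude phasor convention, so the pointwise specific
absorption rate is ``SAR = sigma |E|^2 / (2 rho)`` (W/kg at the field set's
declared input power).  10 g averaging grows a region around each tissue
voxel by increasing Euclidean centre distance (ties by lexicographic voxel
index) until the accumulated mass reaches exactly 0.010 kg, the final shell
voxel entering fractionally — this keeps the averaging mass-correct at the
outer borders of the body.  Background and internal air contribute neither
mass nor power.

For parallel transmit, the per-voxel Hermitian Q-matrix lets the local SAR
of an arbitrary shim vector ``w`` be evaluated as ``w^H Q w``; Q-matrices
are 10 g-averaged entry-wise over the identical regions, so the Q-matrix
path and the direct combined-field path agree to numerical precision.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .volumes import FieldSet, LabelVolume, TISSUE_NAMES

__all__ = [
    "TissueProperties",
    "TissuePropertyTable",
    "DEFAULT_PROPERTIES",
    "SarVolume",
    "QMatrixVolume",
    "ShimVector",
    "ShimStudyResult",
    "pointwise_sar",
    "average_10g",
    "build_q10g",
    "eval_shim",
    "random_shims",
    "quadrature_shim",
    "head_average_sar",
    "underestimation_error",
    "shim_study",
    "generic_margin",
]

log = logging.getLogger(__name__)

TEN_GRAMS = 0.010  # kg


@dataclass(frozen=True)
class TissueProperties:
    """Dielectric and mass properties of one tissue at 300 MHz."""

    sigma: float  # conductivity, S/m
    eps_r: float  # relative permittivity
    rho: float  # mass density, kg/m^3


#: Literature dielectric/density values at 300 MHz (Gabriel parametrization /
#: IT'IS database); editable via YAML.  Background carries no mass; internal
#: air is non-conductive and excluded from averaging mass by rule.
DEFAULT_PROPERTIES: dict[str, TissueProperties] = {
    "background": TissueProperties(0.0, 1.0, 0.0),
    "internal_air": TissueProperties(0.0, 1.0, 1.2),
    "bone": TissueProperties(0.083, 13.4, 1908.0),
    "muscle": TissueProperties(0.77, 58.2, 1090.0),
    "fat": TissueProperties(0.077, 11.7, 911.0),
    "white_matter": TissueProperties(0.41, 43.8, 1041.0),
    "gray_matter": TissueProperties(0.69, 60.0, 1045.0),
    "csf": TissueProperties(2.22, 72.7, 1007.0),
    "eye": TissueProperties(1.52, 69.0, 1005.0),
}


class TissuePropertyTable:
    """Per-tissue-class property table keyed by label code."""

    def __init__(self, table: dict[str, TissueProperties] | None = None):
        table = dict(DEFAULT_PROPERTIES) if table is None else dict(table)
        missing = [n for n in TISSUE_NAMES if n not in table]
        if missing:
            raise ValueError(f"property table missing tissues: {missing}")
        for name, p in table.items():
            if p.sigma < 0:
                raise ValueError(f"{name}: conductivity must be >= 0")
            if name not in ("background",) and p.rho <= 0:
                raise ValueError(f"{name}: density must be positive")
        self.table = table

    def __getitem__(self, name: str) -> TissueProperties:
        return self.table[name]

    def lut(self, attr: str) -> np.ndarray:
        """Length-9 lookup array of one property indexed by label code."""
        return np.array([getattr(self.table[n], attr) for n in TISSUE_NAMES])

    def to_dict(self) -> dict:
        return {
            n: {"sigma": p.sigma, "eps_r": p.eps_r, "rho": p.rho}
            for n, p in self.table.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TissuePropertyTable":
        return cls({n: TissueProperties(v["sigma"], v["eps_r"], v["rho"]) for n, v in d.items()})


@dataclass
class SarVolume:
    """Non-negative SAR grid (W/kg), zero outside tissue."""

    grid: np.ndarray
    mass_kind: str  # "pointwise" or "10g"
    normalization: float = 1.0
    voxel_size: tuple = (2.0, 2.0, 2.0)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.mass_kind not in ("pointwise", "10g"):
            raise ValueError("mass_kind must be 'pointwise' or '10g'")

    @property
    def peak(self) -> float:
        return float(self.grid.max())

    @property
    def peak_location(self) -> tuple[int, int, int]:
        return tuple(int(i) for i in np.unravel_index(np.argmax(self.grid), self.grid.shape))


@dataclass
class ShimVector:
    """Per-channel complex drive, normalized to the declared total power."""

    w: np.ndarray
    power: float = 1.0

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=np.complex128).ravel()

    @property
    def channels(self) -> int:
        return self.w.size

    def normalized(self) -> "ShimVector":
        nrm2 = float(np.sum(np.abs(self.w) ** 2))
        if abs(nrm2 - self.power) > 1e-9 * max(self.power, 1.0):
            warnings.warn("shim not power-normalized; normalizing", stacklevel=2)
            return ShimVector(self.w * np.sqrt(self.power / nrm2), self.power)
        return self


@dataclass
class QMatrixVolume:
    """10 g-averaged Q-matrices at tissue voxels, packed upper triangle.

    ``q`` has shape ``(V, C*(C+1)//2)`` complex; ``voxel_index`` holds the
    (i, j, k) grid index of each of the V tissue voxels.  Local SAR of shim
    ``w`` at voxel v is ``w^H Q(v) w``.
    """

    q: np.ndarray
    voxel_index: np.ndarray
    channels: int
    shape: tuple
    normalization: float = 1.0
    voxel_size: tuple = (2.0, 2.0, 2.0)
    seed: int | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=np.complex128)
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.int64)
        npack = self.channels * (self.channels + 1) // 2
        if self.q.ndim != 2 or self.q.shape[1] != npack:
            raise ValueError(f"packed Q must have {npack} columns")

    def matrices(self) -> np.ndarray:
        """Unpacked (V, C, C) Hermitian matrices."""
        c = self.channels
        out = np.zeros((self.q.shape[0], c, c), dtype=np.complex128)
        iu = np.triu_indices(c)
        out[:, iu[0], iu[1]] = self.q
        lo = np.tril_indices(c, -1)
        out[:, lo[0], lo[1]] = out[:, lo[1], lo[0]].conj()
        return out


@dataclass
class ShimStudyResult:
    """Per-shim peak-SAR comparison between two body models."""

    peaks_gt: np.ndarray
    peaks_gen: np.ndarray
    errors_percent: np.ndarray
    mean_error: float
    p95_error: float
    safety_margin_percent: float
    confidence: float = 0.95
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "mean_error_percent": self.mean_error,
            "p95_error_percent": self.p95_error,
            "safety_margin_percent": self.safety_margin_percent,
            "confidence": self.confidence,
            "n_shims": int(self.errors_percent.size),
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# pointwise SAR


def pointwise_sar(
    fields: FieldSet,
    labels: LabelVolume,
    props: TissuePropertyTable,
    shim: ShimVector,
) -> SarVolume:
    """SAR of the combined field ``E = sum_c w_c E_c``: ``sigma|E|^2/(2 rho)``.

    Zero wherever the conductivity is zero (background, internal air).
    """
    if shim.channels != fields.channels:
        raise ValueError(
            f"shim has {shim.channels} channels, fields have {fields.channels}"
        )
    if fields.shape != labels.shape:
        raise ValueError("field/label geometry mismatch")
    e = fields.combined(shim.w)
    mag2 = np.sum(np.abs(e) ** 2, axis=0)
    sigma = props.lut("sigma")[labels.grid]
    rho = props.lut("rho")[labels.grid]
    sar = np.zeros(labels.shape)
    ok = (sigma > 0) & (rho > 0)
    sar[ok] = sigma[ok] * mag2[ok] / (2.0 * rho[ok])
    return SarVolume(sar, "pointwise", fields.normalization, labels.voxel_size)


# ---------------------------------------------------------------------------
# 10 g region-growing averaging


@njit(cache=True)
def _grow_average(
    centers, offsets, mass, values, target
):  # pragma: no cover - numba
    """Mass-exact region-growing average at each centre voxel.

    ``offsets`` are pre-sorted by (distance, di, dj, dk); ``mass`` is the
    per-voxel mass grid (zero at voxels that contribute nothing) and
    ``values`` the (X, Y, Z, K) per-voxel quantities to average.
    """
    nx, ny, nz, nk = values.shape
    m = centers.shape[0]
    out = np.zeros((m, nk), dtype=np.complex128)
    ok = np.zeros(m, dtype=np.bool_)
    for c in range(m):
        ci, cj, ck = centers[c, 0], centers[c, 1], centers[c, 2]
        acc = 0.0
        done = False
        for o in range(offsets.shape[0]):
            i = ci + offsets[o, 0]
            j = cj + offsets[o, 1]
            k = ck + offsets[o, 2]
            if i < 0 or j < 0 or k < 0 or i >= nx or j >= ny or k >= nz:
                continue
            mv = mass[i, j, k]
            if mv <= 0.0:
                continue
            if acc + mv >= target:
                frac = (target - acc) / mv
                for q in range(nk):
                    out[c, q] += frac * mv * values[i, j, k, q]
                acc = target
                done = True
                break
            acc += mv
            for q in range(nk):
                out[c, q] += mv * values[i, j, k, q]
        if done:
            ok[c] = True
            for q in range(nk):
                out[c, q] /= target
    return out, ok


def _sorted_offsets(shape, voxel_size) -> np.ndarray:
    """All grid offsets sorted by (Euclidean distance, di, dj, dk).

    For a fixed centre voxel this ordering coincides with sorting candidate
    voxels by (distance, lexicographic absolute index).
    """
    ext = [np.arange(-(n - 1), n, dtype=np.int64) for n in shape]
    di, dj, dk = np.meshgrid(*ext, indexing="ij")
    di, dj, dk = di.ravel(), dj.ravel(), dk.ravel()
    vx, vy, vz = voxel_size
    d2 = (di * vx) ** 2 + (dj * vy) ** 2 + (dk * vz) ** 2
    order = np.lexsort((dk, dj, di, d2))
    return np.ascontiguousarray(np.stack([di, dj, dk], axis=1)[order])


def _mass_grid(labels: LabelVolume, props: TissuePropertyTable, voxel_volume: float):
    rho = props.lut("rho")[labels.grid]
    mass = rho * voxel_volume
    mass[~labels.tissue_mask()] = 0.0
    return mass


def average_10g(
    values: np.ndarray,
    labels: LabelVolume,
    props: TissuePropertyTable,
    voxel_volume: float | None = None,
    target_mass: float = TEN_GRAMS,
) -> tuple[np.ndarray, np.ndarray]:
    """Mass-weighted 10 g average of per-voxel values at every tissue voxel.

    ``values`` is ``(X, Y, Z)`` or ``(X, Y, Z, K)`` (entry-wise averaging of
    K quantities over identical regions).  Returns ``(averaged (V, K),
    voxel_index (V, 3))`` over the tissue voxels in C order.  Tissue voxels
    whose reachable mass falls short of the target (a body lighter than the
    averaging mass cannot occur here: it raises) take the whole-body average
    with a logged warning.

    Raises
    ------
    ValueError
        If the total body mass is below ``target_mass``.
    """
    if target_mass <= 0:
        raise ValueError("target_mass must be positive")
    if voxel_volume is None:
        voxel_volume = labels.voxel_volume_m3
    mass = _mass_grid(labels, props, voxel_volume)
    total = float(mass.sum())
    if total < target_mass:
        raise ValueError(
            f"total body mass {total * 1000:.2f} g is below the averaging mass "
            f"{target_mass * 1000:.0f} g"
        )
    vals = np.asarray(values)
    scalar = vals.ndim == 3
    if scalar:
        vals = vals[..., None]
    if vals.shape[:3] != labels.shape:
        raise ValueError("values/labels geometry mismatch")
    centers = np.ascontiguousarray(np.argwhere(labels.tissue_mask()))
    offsets = _sorted_offsets(labels.shape, labels.voxel_size)
    out, ok = _grow_average(
        centers,
        offsets,
        np.ascontiguousarray(mass),
        np.ascontiguousarray(vals.astype(np.complex128)),
        float(target_mass),
    )
    if not np.all(ok):
        nbad = int((~ok).sum())
        log.warning(
            "%d voxels could not accumulate %.0f g; using whole-body average",
            nbad,
            target_mass * 1000,
        )
        wb = (vals * mass[..., None]).sum(axis=(0, 1, 2)) / total
        out[~ok] = wb
    if np.all(np.abs(out.imag) < 1e-30):
        out = out.real
    if scalar:
        out = out[:, 0]
    return out, centers


def sar10g_volume(
    sar: SarVolume,
    labels: LabelVolume,
    props: TissuePropertyTable,
    voxel_volume: float | None = None,
    target_mass: float = TEN_GRAMS,
) -> SarVolume:
    """10 g-averaged SAR volume from a pointwise SAR volume."""
    avg, centers = average_10g(sar.grid, labels, props, voxel_volume, target_mass)
    grid = np.zeros(labels.shape)
    grid[centers[:, 0], centers[:, 1], centers[:, 2]] = np.asarray(avg, dtype=float)
    return SarVolume(grid, "10g", sar.normalization, labels.voxel_size)


# ---------------------------------------------------------------------------
# Q-matrices


def _pack_indices(c: int):
    return np.triu_indices(c)


def build_q10g(
    fields: FieldSet,
    labels: LabelVolume,
    props: TissuePropertyTable,
    voxel_volume: float | None = None,
    target_mass: float = TEN_GRAMS,
) -> QMatrixVolume:
    """Construct 10 g-averaged Q-matrices from per-channel E-fields.

    Raw per-voxel entries are ``Q_ab = sigma/(2 rho) * conj(E_a) . E_b``
    (dot product over the three field components), Hermitian and PSD by
    construction; 10 g averaging is applied entry-wise over the same
    regions used for scalar SAR, preserving both properties.
    """
    if fields.shape != labels.shape:
        raise ValueError("field/label geometry mismatch")
    c = fields.channels
    sigma = props.lut("sigma")[labels.grid]
    rho = props.lut("rho")[labels.grid]
    coef = np.zeros(labels.shape)
    ok = (sigma > 0) & (rho > 0)
    coef[ok] = sigma[ok] / (2.0 * rho[ok])
    iu, ju = _pack_indices(c)
    npack = iu.size
    raw = np.empty(labels.shape + (npack,), dtype=np.complex128)
    for p in range(npack):
        a, b = iu[p], ju[p]
        raw[..., p] = coef * np.sum(np.conj(fields.E[a]) * fields.E[b], axis=0)
    avg, centers = average_10g(raw, labels, props, voxel_volume, target_mass)
    return QMatrixVolume(
        np.asarray(avg, dtype=np.complex128),
        centers,
        c,
        labels.shape,
        fields.normalization,
        labels.voxel_size,
    )


def eval_shim(q: QMatrixVolume, shim: ShimVector) -> tuple[SarVolume, float, tuple]:
    """Evaluate ``SAR10g(v) = w^H Q(v) w`` for every voxel.

    Returns the 10 g SAR volume, its peak and the argmax voxel index.
    Shims that are not power-normalized are normalized with a warning.
    """
    shim = shim.normalized()
    w = shim.w
    if w.size != q.channels:
        raise ValueError("shim/Q channel mismatch")
    iu, ju = _pack_indices(q.channels)
    coef = np.conj(w[iu]) * w[ju]
    coef[iu != ju] *= 2.0  # off-diagonal pairs appear twice in w^H Q w
    sar_v = np.real(q.q @ coef)
    sar_v = np.maximum(sar_v, 0.0)
    grid = np.zeros(q.shape)
    grid[q.voxel_index[:, 0], q.voxel_index[:, 1], q.voxel_index[:, 2]] = sar_v
    vol = SarVolume(grid, "10g", q.normalization, q.voxel_size)
    return vol, vol.peak, vol.peak_location


# ---------------------------------------------------------------------------
# shims and exposure statistics


def random_shims(channels: int, n: int = 1000, seed: int = 0) -> list[ShimVector]:
    """Random RF shims: phases uniform on [0, 2pi), amplitudes uniform on
    [0, 1], normalized to 1 W total input power.  Deterministic per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    shims = []
    for _ in range(n):
        amp = rng.uniform(0.0, 1.0, channels)
        ph = rng.uniform(0.0, 2 * np.pi, channels)
        w = amp * np.exp(1j * ph)
        nrm = np.linalg.norm(w)
        if nrm == 0:  # vanishing draw; renormalize a uniform drive
            w = np.ones(channels, dtype=np.complex128)
            nrm = np.linalg.norm(w)
        shims.append(ShimVector(w / nrm))
    return shims


def quadrature_shim(channels: int = 16) -> ShimVector:
    """Circularly polarized (quadrature birdcage-like) drive: equal
    amplitudes with successive ``360/channels`` degree phase increments."""
    ph = -2 * np.pi * np.arange(channels) / channels
    w = np.exp(1j * ph) / np.sqrt(channels)
    return ShimVector(w)


def head_average_sar(
    sar: SarVolume,
    labels: LabelVolume,
    props: TissuePropertyTable,
    voxel_volume: float | None = None,
) -> float:
    """Mass-weighted mean pointwise SAR over all tissue voxels
    (= total absorbed power / total tissue mass)."""
    if voxel_volume is None:
        voxel_volume = labels.voxel_volume_m3
    mass = _mass_grid(labels, props, voxel_volume)
    total = float(mass.sum())
    if total <= 0:
        raise ValueError("body has no mass")
    return float((sar.grid * mass).sum() / total)


def underestimation_error(peak_gt: float, peak_gen: float) -> float:
    """Percent underestimation ``100 (peak_gt - peak_gen) / peak_gt``.

    Positive when the generated model underestimates the ground truth —
    the unsafe direction for compliance."""
    if peak_gt <= 0:
        raise ValueError("ground-truth peak must be positive")
    return 100.0 * (peak_gt - peak_gen) / peak_gt


def shim_study(
    q_gt: QMatrixVolume,
    q_gen: QMatrixVolume,
    shims: list[ShimVector],
    confidence: float = 0.95,
    seed: int | None = None,
) -> ShimStudyResult:
    """Compare per-shim peak SAR10g between ground-truth and generated models.

    Reports the underestimation-error distribution (mean, 95th percentile
    with linear-interpolation quantiles) and the safety margin: the
    multiplicative factor on generated-model peaks that makes the stated
    confidence fraction of shims conservative, expressed in percent.
    """
    if not shims:
        raise ValueError("empty shim list")
    if q_gt.channels != q_gen.channels:
        raise ValueError("channel count mismatch between models")
    peaks_gt = np.array([eval_shim(q_gt, s)[1] for s in shims])
    peaks_gen = np.array([eval_shim(q_gen, s)[1] for s in shims])
    errors = 100.0 * (peaks_gt - peaks_gen) / peaks_gt
    factor = float(np.percentile(peaks_gt / peaks_gen, 100.0 * confidence))
    margin = 100.0 * (factor - 1.0)
    return ShimStudyResult(
        peaks_gt,
        peaks_gen,
        errors,
        float(errors.mean()),
        float(np.percentile(errors, 100.0 * confidence)),
        margin,
        confidence,
        seed,
    )


def generic_margin(peaks: np.ndarray) -> dict:
    """One-size-fits-all overestimation statistics.

    ``peaks`` is an (M models, S shims) matrix of peak SAR10g values.  For
    each model m and shim s the generic approach would use the worst peak
    over the other models; its overestimation is
    ``100 (max_{m' != m} peaks[m', s] - peaks[m, s]) / peaks[m, s]``.
    """
    peaks = np.asarray(peaks, dtype=float)
    if peaks.ndim != 2 or peaks.shape[0] < 2:
        raise ValueError("need a (models >= 2, shims) peak matrix")
    m, s = peaks.shape
    over = np.empty((m, s))
    for i in range(m):
        others = np.delete(peaks, i, axis=0).max(axis=0)
        over[i] = 100.0 * (others - peaks[i]) / peaks[i]
    flat = over.ravel()
    return {
        "overestimation_percent": over,
        "mean": float(flat.mean()),
        "p5": float(np.percentile(flat, 5.0)),
        "p95": float(np.percentile(flat, 95.0)),
        "fraction_conservative": float((flat >= 0).mean()),
    }
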