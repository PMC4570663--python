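"""Synthetic volumes, element maps and tilted slices with known ground truth.

The generator emulates the correlative-imaging situation the package is built
for: a resin-impregnated soil volume imaged by X-ray CT (three density
phases: dark pore/resin, mid-gray mineral, sparse bright Fe-rich grains) and
per-element X-ray count maps measured on cut faces. Element concentration is
a step function of grayscale (the trend a regression tree can recover) plus
a spatially correlated residual drawn from a *single* 3D Gaussian field per
element — sampling all faces from one field gives kriging between layers a
physically consistent signal to exploit — plus i.i.d. measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.fft import fftn, next_fast_len
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from .alignment import PlaneOrientation, reconstruct_plane, _plane_zbase
from .data_model import ElementMap, Face, GrayscaleVolume, LayerSet
from .geostatistics import VariogramModel


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Gaussian random fields


def _decay_length(model: VariogramModel) -> float:
    """Distance beyond which the structural covariance is negligible."""
    pads = [r if fam == "spherical" else 7.0 * r for fam, _, r in model.components]
    return max(pads, default=1.0)


def _structural_cov(model: VariogramModel, h: np.ndarray) -> np.ndarray:
    """Covariance of the continuous part: sum_i c_i (1 - g_i(h/r_i))."""
    c = np.zeros_like(h)
    for fam, sill, r in model.components:
        u = h / r
        if fam == "exponential":
            c += sill * np.exp(-u)
        else:
            u = np.minimum(u, 1.0)
            c += sill * (1.0 - 1.5 * u + 0.5 * u**3)
    return c


def _embedding_eigenvalues(model: VariogramModel, shape: Sequence[int], dtype) -> tuple[np.ndarray, tuple[int, ...]]:
    pad = int(np.ceil(_decay_length(model)))
    eshape = tuple(next_fast_len(s + pad) for s in shape)
    axes_sq = []
    for n in eshape:
        idx = np.arange(n)
        axes_sq.append(np.minimum(idx, n - idx).astype(dtype) ** 2)
    h2 = axes_sq[0]
    for a in axes_sq[1:]:
        h2 = h2[..., None] + a
    kernel = _structural_cov(model, np.sqrt(h2)).astype(dtype)
    eig = fftn(kernel).real
    neg = eig.min()
    if neg < -1e-3 * max(eig.max(), 1e-30):
        raise SimulationError(
            f"circulant embedding failed (min eigenvalue {neg:.3g}); enlarge the grid or shorten the range"
        )
    np.clip(eig, 0.0, None, out=eig)
    return eig, eshape


def _field_pair_from_eig(
    eig: np.ndarray, eshape: tuple[int, ...], shape: Sequence[int], rng: np.random.Generator, dtype
) -> tuple[np.ndarray, np.ndarray]:
    scale = np.sqrt(eig / np.prod(eshape, dtype=float)).astype(dtype)
    eps = rng.standard_normal(eshape).astype(dtype) + 1j * rng.standard_normal(eshape).astype(dtype)
    Z = fftn(scale * eps)
    sub = tuple(slice(0, s) for s in shape)
    return np.ascontiguousarray(Z.real[sub]), np.ascontiguousarray(Z.imag[sub])


def simulate_gaussian_field(
    model: VariogramModel,
    shape: Sequence[int],
    seed: int,
    dtype=np.float64,
) -> np.ndarray:
    """Zero-mean stationary Gaussian field with the model's variogram.

    Uses circulant embedding on 2D/3D grids (the torus is padded past the
    covariance decay length so the embedding is valid for the supported
    families); falls back to exact covariance factorization for grids of at
    most 4096 points. The nugget component is added as i.i.d. noise.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) not in (2, 3):
        raise SimulationError("shape must be 2D or 3D")
    rng = np.random.default_rng(seed)
    if model.total_sill == 0 or not model.components:
        f = np.zeros(shape, dtype=dtype)
    else:
        try:
            eig, eshape = _embedding_eigenvalues(model, shape, dtype)
            f = _field_pair_from_eig(eig, eshape, shape, rng, dtype)[0]
        except SimulationError:
            if np.prod(shape) > 4096:
                raise
            grid = np.indices(shape).reshape(len(shape), -1).T.astype(float)
            f = gaussian_field_at_points(model, grid, rng).reshape(shape).astype(dtype)
    if model.nugget > 0:
        f = f + rng.standard_normal(shape).astype(dtype) * np.sqrt(model.nugget)
    return f


def gaussian_field_at_points(
    model: VariogramModel, coords: np.ndarray, rng: np.random.Generator | int
) -> np.ndarray:
    """Exact (Cholesky) sampling at arbitrary points; at most 4096 points."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    if n > 4096:
        raise SimulationError("exact factorization limited to 4096 points")
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    C = _structural_cov(model, d)
    C[np.arange(n), np.arange(n)] += model.nugget + 1e-10 * max(model.total_sill, 1.0)
    L = np.linalg.cholesky(C)
    return L @ rng.standard_normal(n)


# ---------------------------------------------------------------------------
# Soil volume


def simulate_soil_volume(
    shape: Sequence[int],
    phases: Sequence[tuple[float, float, float]],
    correlation_range: float,
    seed: int,
) -> GrayscaleVolume:
    """Phase-structured 8-bit volume.

    A correlated Gaussian field is thresholded at the normal quantiles of the
    cumulative phase proportions; each voxel's gray value is drawn from its
    phase's truncated normal (truncated to [0, 255]) and rounded.

    ``phases`` is a list of ``(proportion, gray_mean, gray_sd)``.
    """
    shape = tuple(int(s) for s in shape)
    props = np.array([p for p, _, _ in phases], dtype=float)
    if np.any(props <= 0) or abs(props.sum() - 1.0) > 1e-8:
        raise SimulationError("phase proportions must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    model = VariogramModel(components=(("spherical", 1.0, float(correlation_range)),))
    f = simulate_gaussian_field(model, shape, seed=int(rng.integers(2**31 - 1)), dtype=np.float32)
    cuts = norm.ppf(np.cumsum(props)[:-1])
    labels = np.searchsorted(cuts, f)
    gray = np.empty(shape, dtype=np.float32)
    for ph, (_, mean, sd) in enumerate(phases):
        m = labels == ph
        cnt = int(m.sum())
        if cnt == 0:
            continue
        if sd == 0:
            gray[m] = mean
        else:
            # truncated normal on [0, 255] by inverse-CDF transform
            lo, hi = ndtr((0.0 - mean) / sd), ndtr((255.0 - mean) / sd)
            u = rng.uniform(lo, hi, size=cnt)
            gray[m] = mean + sd * ndtri(u)
    return GrayscaleVolume(np.clip(np.round(gray), 0, 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# Trend and element maps


def trend_law(gray: np.ndarray, thresholds: Sequence[float], levels: Sequence[float]) -> np.ndarray:
    """Piecewise-constant lookup; value at a threshold takes the upper level."""
    thresholds = np.asarray(thresholds, dtype=float)
    levels = np.asarray(levels, dtype=float)
    if len(levels) != len(thresholds) + 1:
        raise SimulationError("need exactly one more level than thresholds")
    if len(thresholds) and np.any(np.diff(thresholds) <= 0):
        raise SimulationError("thresholds must be strictly increasing")
    gray = np.asarray(gray, dtype=float)
    return levels[np.searchsorted(thresholds, gray, side="right")]


@dataclass
class ElementTruth:
    """Generating law for one element."""

    thresholds: tuple[float, ...]
    levels: tuple[float, ...]
    residual: VariogramModel
    noise_sd: float = 0.0


@dataclass
class StudyTruth:
    """Everything needed to regenerate and score a synthetic study."""

    elements: dict[str, ElementTruth]
    phases: tuple[tuple[float, float, float], ...]
    phase_range: float
    broken_fraction: float = 0.0

    def to_dict(self) -> dict:
        return {
            "elements": {
                el: {
                    "thresholds": list(t.thresholds),
                    "levels": list(t.levels),
                    "residual": t.residual.to_dict(),
                    "noise_sd": t.noise_sd,
                }
                for el, t in self.elements.items()
            },
            "phases": [list(p) for p in self.phases],
            "phase_range": self.phase_range,
            "broken_fraction": self.broken_fraction,
        }


def _broken_mask(shape: tuple[int, int], fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Contiguous broken-slice blobs covering ~``fraction`` of the face."""
    model = VariogramModel(components=(("spherical", 1.0, 20.0),))
    f = simulate_gaussian_field(model, shape, seed=int(rng.integers(2**31 - 1)), dtype=np.float32)
    thr = np.quantile(f, fraction)
    return f >= thr  # True = valid pixel


def simulate_element_maps(
    volume: GrayscaleVolume,
    face_planes: Sequence[tuple[str, PlaneOrientation]],
    truth: StudyTruth,
    seed: int,
    map_shape: Optional[tuple[int, int]] = None,
    slice_thickness: float = 15.0,
    kerf: float = 50.0,
) -> LayerSet:
    """Generate per-face element maps consistent with one 3D residual field.

    For each face the grayscale staircase plane is reconstructed from its
    orientation; the element map is ``trend(gray) + residual(x, y, z(x, y))
    + noise`` with the residual sampled from the element's 3D field at the
    same staircase coordinates. ``face_planes`` is a list of
    ``(face_id, orientation)`` in increasing depth order.
    """
    if map_shape is None:
        map_shape = volume.shape[:2]
    rng = np.random.default_rng(seed)
    elements = sorted(truth.elements)

    # independent unit-variance 3D fields, two per FFT synthesis
    ref = truth.elements[elements[0]].residual
    shapes = {
        tuple((f, 1.0, r) for f, _, r in truth.elements[el].residual.components)
        for el in elements
    }
    if len(shapes) != 1:
        raise SimulationError("all element residual models must share correlation structure")
    unit = VariogramModel(components=tuple((f, c / ref.total_sill, r) for f, c, r in ref.components))
    eig, eshape = _embedding_eigenvalues(unit, volume.shape, np.float32)
    unit_fields: list[np.ndarray] = []
    while len(unit_fields) < len(elements):
        unit_fields.extend(_field_pair_from_eig(eig, eshape, volume.shape, rng, np.float32))
    del eig

    faces = []
    for face_id, orient in face_planes:
        maps = {}
        zbase = _plane_zbase(
            orient.a, orient.b, orient.center, map_shape, orient.crop_offset
        )
        zidx = zbase + orient.k0
        if zidx.min() < 0 or zidx.max() >= volume.n_slices:
            raise SimulationError(f"face {face_id!r}: plane infeasible in the volume")
        r0, c0 = orient.crop_offset
        jj = np.arange(r0, r0 + map_shape[0])[:, None]
        ii = np.arange(c0, c0 + map_shape[1])[None, :]
        gray = volume.data[jj, ii, zidx]
        mask = (
            _broken_mask(map_shape, truth.broken_fraction, rng)
            if truth.broken_fraction > 0
            else np.ones(map_shape, dtype=bool)
        )
        for el, ufield in zip(elements, unit_fields):
            et = truth.elements[el]
            conc = trend_law(gray, et.thresholds, et.levels)
            conc = conc + np.sqrt(et.residual.total_sill) * ufield[jj, ii, zidx]
            if et.noise_sd > 0:
                conc = conc + rng.normal(0.0, et.noise_sd, size=map_shape)
            conc = np.clip(conc, 0.0, None)  # X-ray counts are non-negative
            maps[el] = ElementMap(element=el, data=conc, pixel_size_um=volume.voxel_size_um, mask=mask)
        faces.append(Face(face_id=face_id, z=float(orient.k0), maps=maps))
    return LayerSet(faces=faces, slice_thickness=slice_thickness, kerf=kerf)


def extract_tilted_slices(
    volume: GrayscaleVolume,
    orientations: Sequence[PlaneOrientation],
    shape: Optional[tuple[int, int]] = None,
) -> tuple[list[np.ndarray], list[PlaneOrientation]]:
    """Reconstruct staircase planes for known orientations (test harness)."""
    if shape is None:
        shape = volume.shape[:2]
    planes = [
        reconstruct_plane(volume, o.a, o.b, o.k0, o.center, shape, o.crop_offset)
        for o in orientations
    ]
    return planes, list(orientations)


# ---------------------------------------------------------------------------
# Full study


@dataclass
class SyntheticStudy:
    volume: GrayscaleVolume
    layers: LayerSet
    orientations: dict[str, PlaneOrientation]
    truth: StudyTruth
    seed: int


#: Default study conditions: a 256 x 256 x 300 volume with pore/resin,
#: mineral and sparse Fe-rich phases, ten faces in the reference cutting
#: geometry (slice 15 CT layers, kerf 50, so consecutive fold layers are 65
#: apart), and four elements whose trend steps and residual structure mimic
#: the observed element-to-grayscale relationships (C in pores, Si/O on the
#: solid phase, Fe sparse and bright).
DEFAULT_SHAPE = (256, 256, 300)
DEFAULT_FACE_Z = (10, 25, 75, 90, 140, 155, 205, 220, 270, 285)
DEFAULT_PHASES = ((0.45, 60.0, 12.0), (0.50, 130.0, 18.0), (0.05, 225.0, 12.0))
DEFAULT_PHASE_RANGE = 12.0


def default_truth(broken_fraction: float = 0.0) -> StudyTruth:
    res = lambda sill: VariogramModel(components=(("exponential", sill, 22.0),))
    return StudyTruth(
        elements={
            "C": ElementTruth((95.0, 180.0), (9.0, 3.5, 2.0), res(2.0), 0.3),
            "Si": ElementTruth((95.0, 180.0), (3.5, 12.0, 6.0), res(6.0), 0.5),
            "Fe": ElementTruth((95.0, 185.0), (0.4, 0.8, 3.5), res(0.15), 0.05),
            "O": ElementTruth((95.0, 180.0), (1.8, 4.8, 3.5), res(1.2), 0.2),
        },
        phases=DEFAULT_PHASES,
        phase_range=DEFAULT_PHASE_RANGE,
        broken_fraction=broken_fraction,
    )


def make_study(
    seed: int,
    shape: Sequence[int] = DEFAULT_SHAPE,
    face_z: Sequence[int] = DEFAULT_FACE_Z,
    truth: Optional[StudyTruth] = None,
    tilt: float = 0.0,
    seed_offset: int = 0,
) -> SyntheticStudy:
    """Generate the full synthetic study (volume + faces with ground truth).

    ``tilt`` optionally gives each face small alternating slopes (for
    exercising the alignment search); the default study uses flat faces so
    the layer-gap geometry is exact. Regenerating with the same seed is
    bit-identical.
    """
    if truth is None:
        truth = default_truth()
    rng = np.random.default_rng([seed, seed_offset])
    vol_seed, map_seed = (int(s) for s in rng.integers(2**31 - 1, size=2))
    volume = simulate_soil_volume(shape, truth.phases, truth.phase_range, vol_seed)
    rows, cols = volume.shape[:2]
    center = (float((cols - 1) // 2), float((rows - 1) // 2))
    face_planes = []
    for idx, z in enumerate(face_z):
        a = tilt * (1 if idx % 2 == 0 else -1)
        b = -0.5 * tilt if idx % 3 == 0 else 0.5 * tilt
        face_planes.append(
            (f"face{idx:02d}", PlaneOrientation(a=a, b=b, k0=int(z), center=center))
        )
    layers = simulate_element_maps(volume, face_planes, truth, map_seed)
    return SyntheticStudy(
        volume=volume,
        layers=layers,
        orientations={fid: o for fid, o in face_planes},
        truth=truth,
        seed=seed,
    )
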