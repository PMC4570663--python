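"""Registration of 2D element maps inside the 3D CT volume.

A cut face is modelled as a plane tilted by small angles about the in-plane
axes. With rotation center ``(i0, j0)`` the slice index of pixel ``(i, j)``
is ``round(a (i - i0) + b (j - j0) + k0)`` — rounding to the nearest slice
produces a staircase-like discrete plane. ``a = tan(psi)`` and
``b = tan(phi) / cos(psi)`` for rotations ``psi`` about y and ``phi`` about x.

The face is located by maximizing, over ``(a, b, k0)`` and a crop offset,
the cumulative absolute Pearson correlation between the reconstructed
grayscale plane and all element maps simultaneously. The offset scan for a
given plane is exhaustive but computed with FFT cross-correlations; the
``(a, b)`` grid is searched coarse-to-fine (optionally exhaustively), and the
winning candidates are re-scored with the direct correlation formula.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.fft import irfft2, next_fast_len, rfft2

from .data_model import ElementMap, GrayscaleVolume


class AlignmentError(ValueError):
    pass


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero (unlike banker's)."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


@dataclass(frozen=True)
class PlaneOrientation:
    """Location of a cut face inside the volume.

    ``a``, ``b`` are the tilt slopes, ``k0`` the base slice index at the
    rotation center ``center = (i0, j0)`` (column, row, 0-based), and
    ``crop_offset = (row, col)`` the origin of the best-correlating window.
    """

    a: float
    b: float
    k0: int
    center: tuple[float, float]
    crop_offset: tuple[int, int] = (0, 0)

    @property
    def angles_deg(self) -> tuple[float, float]:
        """(psi, phi) in degrees, recovered from the slopes."""
        psi = np.arctan(self.a)
        phi = np.arctan(self.b * np.cos(psi))
        return float(np.degrees(psi)), float(np.degrees(phi))


@dataclass
class AlignmentResult:
    orientation: PlaneOrientation
    cumulative_corr: float
    per_element_corr: dict[str, float]
    reconstructed_plane: np.ndarray


def reconstruct_plane(
    volume: GrayscaleVolume,
    a: float,
    b: float,
    k0: int,
    center: tuple[float, float],
    shape: tuple[int, int],
    origin: tuple[int, int] = (0, 0),
) -> np.ndarray:
    """Staircase plane ``out[j, i] = volume[j, i, round(a(i-i0)+b(j-j0)+k0)]``.

    ``shape = (rows, cols)``; the window starts at ``origin`` in the volume's
    in-plane coordinates. Raises if any pixel maps outside the slice range,
    reporting the admissible ``k0`` interval.
    """
    rows, cols = shape
    r0, c0 = origin
    if rows < 1 or cols < 1 or r0 < 0 or c0 < 0 or r0 + rows > volume.shape[0] or c0 + cols > volume.shape[1]:
        raise AlignmentError(
            f"plane window origin={origin} shape={shape} exceeds volume in-plane extent {volume.shape[:2]}"
        )
    # rounding is applied to the full expression a(i-i0) + b(j-j0) + k0
    i0, j0 = center
    di = np.arange(c0, c0 + cols, dtype=float) - i0
    dj = np.arange(r0, r0 + rows, dtype=float) - j0
    zidx = round_half_away(a * di[None, :] + b * dj[:, None] + k0)
    depth = volume.n_slices
    if zidx.min() < 0 or zidx.max() >= depth:
        zbase = zidx - int(k0)
        lo, hi = -int(zbase.min()), depth - 1 - int(zbase.max())
        raise AlignmentError(
            f"plane (a={a}, b={b}, k0={k0}) maps outside the volume; "
            f"admissible k0 range is [{lo}, {hi}]"
        )
    jj = np.arange(r0, r0 + rows)[:, None]
    ii = np.arange(c0, c0 + cols)[None, :]
    return volume.data[jj, ii, zidx]


def _plane_zbase(
    a: float, b: float, center: tuple[float, float], shape: tuple[int, int], origin: tuple[int, int]
) -> np.ndarray:
    """Rounded z offsets of the tilted plane relative to k0."""
    rows, cols = shape
    i0, j0 = center
    r0, c0 = origin
    di = np.arange(c0, c0 + cols, dtype=float) - i0
    dj = np.arange(r0, r0 + rows, dtype=float) - j0
    return round_half_away(a * di[None, :] + b * dj[:, None])


def pearson_r(
    x: np.ndarray, y: np.ndarray, mask: Optional[np.ndarray] = None
) -> float:
    """Product-moment correlation over masked-in pairs.

    Constant input on the mask is an explicit error (the correlation is
    undefined, never silently zero).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise AlignmentError("inputs must have equal length")
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        if m.shape != x.shape:
            raise AlignmentError("mask must match input length")
        x, y = x[m], y[m]
    if len(x) < 2:
        raise AlignmentError("need at least 2 valid pairs")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt(xd @ xd)
    sy = np.sqrt(yd @ yd)
    if sx == 0 or sy == 0:
        raise AlignmentError("undefined correlation: constant input on the mask")
    return float(np.clip((xd @ yd) / (sx * sy), -1.0, 1.0))


def cumulative_correlation(
    plane: np.ndarray, maps: Sequence[ElementMap]
) -> tuple[float, dict[str, float]]:
    """Sum over elements of |r(plane, map)| under the joint mask."""
    plane = np.asarray(plane, dtype=float)
    if not maps:
        raise AlignmentError("need at least one element map")
    joint = np.ones(plane.shape, dtype=bool)
    for m in maps:
        if m.data.shape != plane.shape:
            raise AlignmentError(
                f"map {m.element!r} shape {m.data.shape} != plane shape {plane.shape}"
            )
        joint &= m.mask
    per = {m.element: pearson_r(plane, m.data, joint) for m in maps}
    return float(sum(abs(r) for r in per.values())), per


# ---------------------------------------------------------------------------
# Search


@dataclass(frozen=True)
class AlignmentSearch:
    """Discrete search space for one face.

    Defaults reproduce the reference setup: slopes in [-0.05, 0.05] in steps
    of 0.001 (about +/-3 degrees), an 830x880 plane window and a 750x800
    crop. ``k0_range`` is inclusive. ``coarse_step`` and ``keep`` control the
    coarse-to-fine refinement; ``exhaustive`` disables it.
    """

    a_range: tuple[float, float] = (-0.05, 0.05)
    b_range: tuple[float, float] = (-0.05, 0.05)
    step: float = 0.001
    k0_range: tuple[int, int] = (0, 0)
    plane_shape: tuple[int, int] = (830, 880)
    crop_shape: tuple[int, int] = (750, 800)
    center: Optional[tuple[float, float]] = None
    plane_origin: tuple[int, int] = (0, 0)
    coarse_step: float = 0.005
    keep: int = 25
    exhaustive: bool = False

    def resolved_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        rows, cols = self.plane_shape
        return (float((cols - 1) // 2), float((rows - 1) // 2))


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step))
    vals = lo + step * np.arange(n + 1)
    return vals[(vals >= lo - 1e-12) & (vals <= hi + 1e-12)]


def _snap(vals: np.ndarray) -> np.ndarray:
    return np.round(vals, 9)


class _OffsetScanner:
    """FFT machinery for the exhaustive crop-offset scan of one face.

    For a plane ``P`` and fixed kernels (the joint mask ``W`` and the masked
    maps ``W*M_e``), windowed sums over every offset are valid-mode
    cross-correlations, from which the Pearson correlation at every offset
    follows in closed form.
    """

    def __init__(self, maps: Sequence[ElementMap], plane_shape: tuple[int, int]):
        self.crop_shape = maps[0].data.shape
        rows_p, cols_p = plane_shape
        rows_m, cols_m = self.crop_shape
        if rows_m > rows_p or cols_m > cols_p:
            raise AlignmentError("crop_shape must fit inside plane_shape")
        self.fshape = (
            next_fast_len(rows_p + rows_m - 1),
            next_fast_len(cols_p + cols_m - 1),
        )
        self.window = (slice(rows_m - 1, rows_p), slice(cols_m - 1, cols_p))
        W = np.ones(self.crop_shape)
        for m in maps:
            W *= m.mask
        self.n_valid = float(W.sum())
        if self.n_valid < 2:
            raise AlignmentError("all-masked overlap: fewer than 2 jointly valid pixels")
        self.Wf = rfft2(W[::-1, ::-1], self.fshape)
        self.elements = [m.element for m in maps]
        self.map_sums, self.map_vars, self.WMf = [], [], []
        for m in maps:
            wm = W * np.nan_to_num(m.data)
            s = float(wm.sum())
            v = self.n_valid * float((wm * np.nan_to_num(m.data)).sum()) - s * s
            if v <= 0:
                raise AlignmentError(
                    f"map {m.element!r} is constant on the joint mask; correlation undefined"
                )
            self.map_sums.append(s)
            self.map_vars.append(v)
            self.WMf.append(rfft2(wm[::-1, ::-1], self.fshape))

    def scan(self, plane: np.ndarray) -> np.ndarray:
        """Cumulative |r| for every crop offset; -inf where undefined."""
        P = np.asarray(plane, dtype=float)
        Pf = rfft2(P, self.fshape)
        P2f = rfft2(P * P, self.fshape)
        Sp = irfft2(Pf * self.Wf, self.fshape)[self.window]
        Spp = irfft2(P2f * self.Wf, self.fshape)[self.window]
        var_p = self.n_valid * Spp - Sp * Sp
        ok = var_p > 1e-6 * self.n_valid  # guard FFT round-off on constant windows
        score = np.zeros_like(Sp)
        for sm, vm, WMf in zip(self.map_sums, self.map_vars, self.WMf):
            Spm = irfft2(Pf * WMf, self.fshape)[self.window]
            cov = self.n_valid * Spm - Sp * sm
            with np.errstate(invalid="ignore", divide="ignore"):
                score += np.abs(cov) / np.sqrt(var_p * vm)
        score[~ok] = -np.inf
        return score


def _best_offsets(score: np.ndarray, n_ties: int = 4) -> list[tuple[float, tuple[int, int]]]:
    """Top offsets of a scan, keeping row-major-ordered near-ties."""
    smax = score.max()
    if not np.isfinite(smax):
        return []
    rows, cols = np.nonzero(score >= smax - 1e-9)
    out = [(float(score[r, c]), (int(r), int(c))) for r, c in zip(rows, cols)]
    return out[:n_ties]  # nonzero() is row-major already


def align_face(
    volume: GrayscaleVolume,
    maps: Sequence[ElementMap],
    search: AlignmentSearch,
) -> AlignmentResult:
    """Locate a face by maximizing the cumulative absolute correlation.

    Deterministic: exact ties resolve to the smallest ``|a| + |b|``, then the
    smallest ``k0``, then the first crop offset in row-major order. The
    reported correlations are re-computed with the direct formula at the
    optimum (the FFT scan only ranks candidates).
    """
    center = search.resolved_center()
    for m in maps:
        if m.data.shape != search.crop_shape:
            raise AlignmentError(
                f"map {m.element!r} shape {m.data.shape} != crop_shape {search.crop_shape}"
            )
    scanner = _OffsetScanner(maps, search.plane_shape)
    k0_lo, k0_hi = search.k0_range
    depth = volume.n_slices

    evaluated: dict[tuple[float, float], None] = {}
    candidates: list[tuple[float, float, float, int, tuple[int, int]]] = []

    def eval_ab(a: float, b: float) -> None:
        key = (round(a, 9), round(b, 9))
        if key in evaluated:
            return
        evaluated[key] = None
        zbase = _plane_zbase(a, b, center, search.plane_shape, search.plane_origin)
        zmin, zmax = int(zbase.min()), int(zbase.max())
        lo = max(k0_lo, -zmin)
        hi = min(k0_hi, depth - 1 - zmax)
        if lo > hi:
            return
        rows, cols = search.plane_shape
        r0, c0 = search.plane_origin
        jj = np.arange(r0, r0 + rows)[:, None]
        ii = np.arange(c0, c0 + cols)[None, :]
        for k0 in range(lo, hi + 1):
            plane = volume.data[jj, ii, zbase + k0]
            score = scanner.scan(plane)
            for s, off in _best_offsets(score):
                candidates.append((s, key[0], key[1], k0, off))

    step = search.step
    coarse = step if search.exhaustive else max(step, search.coarse_step)
    for a in _snap(_grid(*search.a_range, coarse)):
        for b in _snap(_grid(*search.b_range, coarse)):
            eval_ab(a, b)
    if not candidates:
        raise AlignmentError(
            "empty feasible search space: no (a, b, k0) keeps the plane inside the volume"
        )

    if coarse > step:
        candidates.sort(key=lambda t: -t[0])
        seeds = []
        seen = set()
        for s, a, b, k0, off in candidates:
            if (a, b) not in seen:
                seen.add((a, b))
                seeds.append((a, b))
            if len(seeds) >= search.keep:
                break
        for a0, b0 in seeds:
            fa = _snap(_grid(max(search.a_range[0], a0 - coarse), min(search.a_range[1], a0 + coarse), step))
            fb = _snap(_grid(max(search.b_range[0], b0 - coarse), min(search.b_range[1], b0 + coarse), step))
            for a in fa:
                for b in fb:
                    eval_ab(float(a), float(b))

    # Exact re-scoring of the leading candidates with the direct formula.
    # All candidates tied with the top FFT score are kept so that the
    # deterministic tie-break sees every contender, not an arbitrary subset.
    candidates.sort(key=lambda t: -t[0])
    top = candidates[0][0]
    finalists = [c for c in candidates if c[0] >= top - 1e-9]
    finalists += [c for c in candidates if c[0] < top - 1e-9][: max(search.keep, 25)]
    best = None
    for s_fft, a, b, k0, (dr, dc) in finalists:
        plane = reconstruct_plane(
            volume, a, b, k0, center, search.plane_shape, search.plane_origin
        )
        crop = plane[dr : dr + scanner.crop_shape[0], dc : dc + scanner.crop_shape[1]]
        try:
            cum, per = cumulative_correlation(crop, maps)
        except AlignmentError:
            continue
        key = (-round(cum, 9), abs(a) + abs(b), k0, dr, dc)
        if best is None or key < best[0]:
            best = (key, a, b, k0, (dr, dc), cum, per, plane)
    if best is None:
        raise AlignmentError("no candidate produced a defined correlation")
    _, a, b, k0, off, cum, per, plane = best
    orient = PlaneOrientation(a=float(a), b=float(b), k0=int(k0), center=center, crop_offset=off)
    return AlignmentResult(
        orientation=orient,
        cumulative_corr=cum,
        per_element_corr=per,
        reconstructed_plane=plane,
    )
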