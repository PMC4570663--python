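"""Isotropic variograms, nested model fitting with AIC selection, ordinary
kriging, and the two-layer sampling-grid optimizer.

The semivariance models follow the Webster & Oliver parametrization:

* exponential: ``gamma(h) = c0 + c * (1 - exp(-h/r))`` — ``r`` is the distance
  parameter, effective range about ``3r``;
* spherical:   ``gamma(h) = c0 + c * (1.5 u - 0.5 u^3)`` for ``u = h/r <= 1``,
  else ``c0 + c`` — ``r`` is the true range.

Nested ("double") models sum two such components. The nugget ``c0`` is the
discontinuity at the origin; by definition ``gamma(0) = 0`` exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.spatial import cKDTree

FAMILIES = ("exponential", "spherical")


class GeostatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Variogram models


def _structure(family: str, u: np.ndarray) -> np.ndarray:
    """Unit-sill correlation-structure term g(u), u = h / range."""
    if family == "exponential":
        return 1.0 - np.exp(-u)
    if family == "spherical":
        u = np.minimum(u, 1.0)
        return 1.5 * u - 0.5 * u**3
    raise GeostatError(f"unknown variogram family {family!r}")


@dataclass(frozen=True)
class VariogramModel:
    """Nested isotropic semivariance model.

    ``components`` is a tuple of ``(family, sill, range)`` triples; 1 or 2
    components are supported ("double" models have 2). ``n_params`` is the
    number of parameters that were free when the model was fitted (used by
    AIC); for hand-built models it defaults to 2 per component plus 1 if the
    nugget is nonzero.
    """

    nugget: float = 0.0
    components: tuple[tuple[str, float, float], ...] = ()
    n_params: Optional[int] = None

    def __post_init__(self) -> None:
        if self.nugget < 0:
            raise GeostatError("nugget must be >= 0")
        if not 0 <= len(self.components) <= 2:
            raise GeostatError("1 or 2 components supported (0 allowed for pure nugget)")
        for fam, c, r in self.components:
            if fam not in FAMILIES:
                raise GeostatError(f"unknown family {fam!r}")
            if c <= 0 or r <= 0:
                raise GeostatError("component sill and range must be > 0")
        if self.n_params is None:
            object.__setattr__(
                self, "n_params", 2 * len(self.components) + (1 if self.nugget > 0 else 0)
            )

    @property
    def total_sill(self) -> float:
        return self.nugget + sum(c for _, c, _ in self.components)

    def __call__(self, h) -> np.ndarray:
        return model_semivariance(self, h)

    def to_dict(self) -> dict:
        return {
            "c0": self.nugget,
            "components": [
                {"family": f, "sill": c, "range": r} for f, c, r in self.components
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VariogramModel":
        return cls(
            nugget=d.get("c0", 0.0),
            components=tuple((c["family"], c["sill"], c["range"]) for c in d["components"]),
        )


def model_semivariance(model: VariogramModel, h) -> np.ndarray:
    """Evaluate ``gamma(h)``; exactly 0 at h = 0, nugget discontinuity at 0+."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise GeostatError("lag distance must be >= 0")
    g = np.full(h.shape, float(model.nugget))
    for fam, c, r in model.components:
        g += c * _structure(fam, h / r)
    g = np.where(h == 0, 0.0, g)
    return g if g.ndim else float(g)


# ---------------------------------------------------------------------------
# Empirical variogram


@dataclass
class EmpiricalVariogram:
    """Matheron method-of-moments semivariance estimates per lag bin."""

    lag_centers: np.ndarray
    gamma: np.ndarray
    pair_counts: np.ndarray
    max_lag: float
    bin_width: float

    def __post_init__(self) -> None:
        if np.any(self.gamma < 0) or np.any(self.pair_counts < 1):
            raise GeostatError("invalid empirical variogram")
        if np.any(np.diff(self.lag_centers) <= 0):
            raise GeostatError("lag centers must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.lag_centers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag": self.lag_centers, "gamma": self.gamma, "pairs": self.pair_counts}
        )


def empirical_variogram(
    coords: np.ndarray,
    values: np.ndarray,
    bin_width: float = 1.0,
    max_lag: float = 64.0,
    subsample: Optional[tuple[int, int]] = None,
) -> EmpiricalVariogram:
    """Isotropic Matheron estimator over 3D point pairs.

    ``gamma(bin) = sum (v_a - v_b)^2 / (2 N_bin)`` over pairs whose Euclidean
    separation falls in the half-open bin. ``subsample=(size, seed)`` draws a
    seeded random subset of points first (without replacement).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    values = np.asarray(values, dtype=float).ravel()
    if len(coords) != len(values):
        raise GeostatError("coords and values must have equal length")
    if len(values) < 2:
        raise GeostatError("need at least 2 points")
    if bin_width <= 0:
        raise GeostatError("bin_width must be > 0")
    if subsample is not None:
        size, seed = subsample
        if size < len(values):
            idx = np.random.default_rng(seed).choice(len(values), size=size, replace=False)
            coords, values = coords[idx], values[idx]

    pairs = cKDTree(coords).query_pairs(r=max_lag, output_type="ndarray")
    if len(pairs) == 0:
        raise GeostatError(f"no point pairs within max_lag={max_lag}")
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    keep = d > 0  # coincident points carry no lag information
    d = d[keep]
    if d.size == 0:
        raise GeostatError("all pairs are coincident points")
    sq = (values[pairs[keep, 0]] - values[pairs[keep, 1]]) ** 2
    nb = int(np.ceil(max_lag / bin_width))
    b = np.minimum((d / bin_width).astype(int), nb - 1)
    counts = np.bincount(b, minlength=nb)
    sums = np.bincount(b, weights=sq, minlength=nb)
    nonempty = counts > 0
    return EmpiricalVariogram(
        lag_centers=(np.arange(nb)[nonempty] + 0.5) * bin_width,
        gamma=sums[nonempty] / (2.0 * counts[nonempty]),
        pair_counts=counts[nonempty],
        max_lag=max_lag,
        bin_width=bin_width,
    )


# ---------------------------------------------------------------------------
# Model fitting and AIC selection


@dataclass(frozen=True)
class FamilySpec:
    """Candidate model structure: component families and nugget switch."""

    families: tuple[str, ...]
    with_nugget: bool = False

    @property
    def n_params(self) -> int:
        return 2 * len(self.families) + (1 if self.with_nugget else 0)

    @property
    def label(self) -> str:
        return "+".join(self.families) + ("+nugget" if self.with_nugget else "")


#: The candidate set considered for residual variograms: single and double
#: exponential/spherical structures and the mixed pair, with or without nugget.
DEFAULT_CANDIDATES = tuple(
    FamilySpec(f, n)
    for f in (
        ("exponential",),
        ("spherical",),
        ("exponential", "exponential"),
        ("spherical", "spherical"),
        ("exponential", "spherical"),
    )
    for n in (False, True)
)


def _wls_objective(emp: EmpiricalVariogram, spec: FamilySpec):
    h, g, w = emp.lag_centers, emp.gamma, emp.pair_counts.astype(float)
    sw = np.sqrt(w)

    def unpack(theta):
        k = 0
        c0 = 0.0
        if spec.with_nugget:
            c0 = theta[0]
            k = 1
        comps = tuple(
            (fam, theta[k + 2 * i], theta[k + 2 * i + 1]) for i, fam in enumerate(spec.families)
        )
        return c0, comps

    def residual(theta):
        c0, comps = unpack(theta)
        gm = np.full_like(h, c0)
        for fam, c, r in comps:
            gm += c * _structure(fam, h / r)
        return sw * (gm - g)

    return unpack, residual


def fit_variogram(
    emp: EmpiricalVariogram, family_spec: FamilySpec
) -> tuple[VariogramModel, float]:
    """Weighted least squares fit (weights = pair counts), multi-start.

    Returns the fitted model and the weighted residual sum of squares.
    """
    p = family_spec.n_params
    if emp.n_bins <= p:
        raise GeostatError(
            f"under-determined fit: {emp.n_bins} lag bins for {p} parameters ({family_spec.label})"
        )
    unpack, residual = _wls_objective(emp, family_spec)

    sill0 = max(float(np.mean(emp.gamma[-max(3, emp.n_bins // 4):])), 1e-12)
    hmax = float(emp.lag_centers[-1])
    ncomp = len(family_spec.families)
    starts = []
    for fracs in ([0.15], [0.4], [0.8]) if ncomp == 1 else (
        [0.1, 0.5], [0.2, 0.9], [0.05, 0.3], [0.4, 1.2]
    ):
        theta = []
        if family_spec.with_nugget:
            theta.append(0.1 * sill0)
        for fr in fracs:
            theta += [sill0 / ncomp, fr * hmax]
        starts.append(np.array(theta))

    lo = np.zeros(p)
    hi = np.full(p, np.inf)
    k = 1 if family_spec.with_nugget else 0
    for i in range(ncomp):
        lo[k + 2 * i] = 1e-10          # sill > 0
        lo[k + 2 * i + 1] = 1e-6       # range > 0
        hi[k + 2 * i + 1] = 100.0 * hmax

    best = None
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                residual, np.clip(x0, lo + 1e-12, None), bounds=(lo, hi),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, sol.x)
    if best is None:
        raise GeostatError(f"variogram fit failed to converge for {family_spec.label}")
    rss, theta = best
    c0, comps = unpack(theta)
    model = VariogramModel(nugget=float(c0), components=comps, n_params=p)
    return model, rss


def aic_select(
    emp: EmpiricalVariogram, candidates: Sequence[FamilySpec] = DEFAULT_CANDIDATES
) -> tuple[VariogramModel, pd.DataFrame]:
    """Fit each candidate and select by ``AIC = n ln(rss/n) + 2p``.

    Constant terms of the likelihood are dropped. Candidates that fail to fit
    are skipped with a warning; ties resolve to fewer parameters, then input
    order. Returns the winning model and the full audit table.
    """
    if not candidates:
        raise GeostatError("need at least one candidate")
    rows, fits = [], []
    n = emp.n_bins
    for spec in candidates:
        try:
            model, rss = fit_variogram(emp, spec)
        except GeostatError as e:
            warnings.warn(f"candidate {spec.label} skipped: {e}")
            continue
        aic = n * np.log(max(rss, 1e-300) / n) + 2 * spec.n_params
        rows.append({"candidate": spec.label, "rss": rss, "p": spec.n_params, "aic": aic})
        fits.append(model)
    if not fits:
        raise GeostatError("all candidate variogram fits failed")
    table = pd.DataFrame(rows)
    order = sorted(range(len(fits)), key=lambda i: (table.aic[i], table.p[i], i))
    return fits[order[0]], table


# ---------------------------------------------------------------------------
# Ordinary kriging


@dataclass
class KrigingResult:
    prediction: float
    variance: float
    weights: np.ndarray
    lagrange: float


def _semivariance_matrix(coords: np.ndarray, model: VariogramModel) -> np.ndarray:
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    if np.any(d[~np.eye(len(coords), dtype=bool)] == 0):
        raise GeostatError("duplicate observation coordinates; deduplicate before kriging")
    return model(d)


def solve_ok_system(
    obs_coords: np.ndarray, model: VariogramModel, target: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Solve the OK system for one target; returns (weights, mu, variance).

    The system is the semivariance matrix augmented with the unbiasedness
    constraint (weights sum to one, Lagrange multiplier ``mu``); the kriging
    variance is ``sum_i w_i gamma(x_i, x0) + mu`` and depends only on the
    geometry and the model, not on observed values.
    """
    obs_coords = np.atleast_2d(np.asarray(obs_coords, dtype=float))
    target = np.asarray(target, dtype=float).ravel()
    n = len(obs_coords)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = _semivariance_matrix(obs_coords, model)
    A[n, :] = 1.0
    A[:, n] = 1.0
    A[n, n] = 0.0
    g0 = model(np.linalg.norm(obs_coords - target, axis=1))
    b = np.concatenate([g0, [1.0]])

    def _try(M):
        try:
            sol = linalg.solve(M, b)
        except linalg.LinAlgError:
            return None
        # cheap accuracy check in place of an O(n^3) condition number
        if not np.all(np.isfinite(sol)) or np.max(np.abs(M @ sol - b)) > 1e-8 * (
            1.0 + np.abs(b).max()
        ):
            return None
        return sol

    sol = _try(A)
    if sol is None:  # ill-conditioned: jitter the semivariance diagonal
        A[np.arange(n), np.arange(n)] += 1e-10 * max(model.total_sill, 1.0)
        sol = _try(A)
        if sol is None:
            raise GeostatError("kriging system is singular or too ill-conditioned")
    w, mu = sol[:n], float(sol[n])
    return w, mu, float(w @ g0 + mu)


def ordinary_kriging(
    obs_coords: np.ndarray,
    obs_values: np.ndarray,
    model: VariogramModel,
    target: np.ndarray,
) -> KrigingResult:
    """Ordinary kriging prediction at ``target`` from scattered observations."""
    obs_values = np.asarray(obs_values, dtype=float).ravel()
    obs_coords = np.atleast_2d(np.asarray(obs_coords, dtype=float))
    if len(obs_coords) != len(obs_values):
        raise GeostatError("coords and values must have equal length")
    if len(obs_values) < 1:
        raise GeostatError("need at least one observation")
    w, mu, var = solve_ok_system(obs_coords, model, target)
    return KrigingResult(
        prediction=float(w @ obs_values), variance=var, weights=w, lagrange=mu
    )


# ---------------------------------------------------------------------------
# Two-layer sampling grid


@dataclass(frozen=True)
class GridConfig:
    """Square n-by-n sampling grid on each of two layers (2 n^2 points)."""

    n: int = 9
    spacing: int = 8
    layer_z: tuple[float, float] = (0.0, 65.0)

    def __post_init__(self) -> None:
        if self.n < 1 or self.n % 2 == 0:
            raise GeostatError("grid n must be a positive odd integer")
        if self.spacing < 1:
            raise GeostatError("grid spacing must be a positive integer")


def two_layer_grid(
    target: Sequence[float],
    cfg: GridConfig,
    layer_extent: Optional[tuple[int, int]] = None,
) -> tuple[np.ndarray, bool]:
    """Points of the two n-by-n grids centred on the target's projection.

    ``target`` is ``(row, col, z)`` in voxel units. Grids that would fall
    outside ``layer_extent = (rows, cols)`` are shifted minimally to fit; the
    returned flag reports whether any shift was applied.
    """
    r, c, _ = (float(v) for v in target)
    half = (cfg.n - 1) // 2 * cfg.spacing
    offs = (np.arange(cfg.n) - (cfg.n - 1) // 2) * cfg.spacing
    shifted = False
    rr, cc = r, c
    if layer_extent is not None:
        R, C = layer_extent
        if 2 * half + 1 > R or 2 * half + 1 > C:
            raise GeostatError(
                f"grid span {2 * half + 1} exceeds layer extent {layer_extent}"
            )
        rr = min(max(r, half), R - 1 - half)
        cc = min(max(c, half), C - 1 - half)
        shifted = (rr != r) or (cc != c)
    gr, gc = np.meshgrid(rr + offs, cc + offs, indexing="ij")
    pts = []
    for z in cfg.layer_z:
        layer = np.column_stack([gr.ravel(), gc.ravel(), np.full(cfg.n**2, float(z))])
        pts.append(layer)
    return np.vstack(pts), shifted


def kriging_variance_profile(
    model: VariogramModel,
    n: int = 9,
    spacings: Iterable[int] = range(1, 21),
    layer_gap: int = 65,
    target_offset: int = 32,
) -> pd.DataFrame:
    """Kriging variance of a mid-block target versus grid spacing.

    Data-free: the variance depends only on the grid geometry and the model.
    Defaults reproduce the reference setup (9x9 grids on layers 65 voxels
    apart, spacings 1..20, target midway at offset 32).
    """
    if not 0 < target_offset < layer_gap:
        raise GeostatError("target_offset must lie strictly between the layers")
    target = np.array([0.0, 0.0, float(target_offset)])
    rows = []
    for s in spacings:
        cfg = GridConfig(n=n, spacing=int(s), layer_z=(0.0, float(layer_gap)))
        pts, _ = two_layer_grid(target, cfg, layer_extent=None)
        _, _, var = solve_ok_system(pts, model, target)
        rows.append({"spacing": int(s), "variance": var})
    return pd.DataFrame(rows)


def optimize_grid_spacing(profile: pd.DataFrame) -> int:
    """Spacing minimizing the kriging variance; ties go to the smallest."""
    if len(profile) == 0:
        raise GeostatError("empty variance profile")
    df = profile.sort_values("spacing", kind="stable").reset_index(drop=True)
    return int(df.spacing[int(np.argmin(df.variance.to_numpy()))])
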