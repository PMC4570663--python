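"""End-to-end regression-tree kriging (RTK).

For one element and two aligned faces 65 voxels apart, the model is

    z_hat(x0) = T(gray(x0))                  (regression tree only, "rt")
    z_hat(x0) = T(gray(x0)) + eps_hat(x0)    (tree + ordinary kriging, "rtk")

where ``T`` is the grayscale regression tree fitted on the pooled pixels of
both faces and ``eps_hat`` is the ordinary-kriging prediction of the tree
residuals from two n-by-n sampling grids centred on the target's projection
onto the faces. Because the grids translate rigidly with the target, the
kriging weights depend only on the target's z-offset (and the boundary
shift), so one solve serves every interior voxel of a slice.

Validation follows the leave-middle-layer-out scheme: fit on two outer faces,
predict the face between them, score by RMSE and R^2, and compare methods
with paired t-tests across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import tree_regression as tr
from .alignment import PlaneOrientation, reconstruct_plane
from .data_model import ElementMap, Face, GrayscaleVolume, LayerSet
from .geostatistics import (
    DEFAULT_CANDIDATES,
    FamilySpec,
    GridConfig,
    VariogramModel,
    empirical_variogram,
    aic_select,
    kriging_variance_profile,
    optimize_grid_spacing,
    solve_ok_system,
)


class PipelineError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Aligned faces


@dataclass
class AlignedFace:
    """A scanned face together with its registered grayscale plane."""

    face_id: str
    z: float
    orientation: PlaneOrientation
    gray: np.ndarray
    maps: dict[str, ElementMap]

    @classmethod
    def from_face(
        cls, face: Face, volume: GrayscaleVolume, orientation: Optional[PlaneOrientation] = None
    ) -> "AlignedFace":
        shape = next(iter(face.maps.values())).shape
        if orientation is None:
            rows, cols = volume.shape[:2]
            orientation = PlaneOrientation(
                a=0.0, b=0.0, k0=int(round(face.z)),
                center=(float((cols - 1) // 2), float((rows - 1) // 2)),
            )
        gray = reconstruct_plane(
            volume, orientation.a, orientation.b, orientation.k0,
            orientation.center, shape, orientation.crop_offset,
        )
        return cls(face.face_id, float(face.z), orientation, gray, dict(face.maps))


# ---------------------------------------------------------------------------
# Config and model


@dataclass(frozen=True)
class RTKConfig:
    """Controls for one RTK fit; defaults reproduce the reference setup."""

    tree: tr.TreeConfig = field(default_factory=tr.TreeConfig)
    candidates: tuple[FamilySpec, ...] = DEFAULT_CANDIDATES
    bin_width: float = 1.0
    max_lag: float = 64.0
    subsample_per_layer: int = 5000
    trend: str = "tree"  # "linear" kept for comparison, not a supported pathway
    grid_n: int = 9
    grid_spacing: Optional[int] = None  # None: minimize the kriging variance
    spacings: tuple[int, ...] = tuple(range(1, 21))
    clamp_nonnegative: bool = False
    seed: int = 0


@dataclass
class RTKModel:
    """Fitted trend + residual model for one element between two faces."""

    element: str
    tree: "tr.RegressionTree | tr.LinearTrend"
    residual_variogram: Optional[VariogramModel]
    grid: GridConfig
    upper: AlignedFace
    lower: AlignedFace
    residual_upper: np.ndarray
    residual_lower: np.ndarray
    trend_only: bool
    cfg: RTKConfig
    aic_table: Optional[pd.DataFrame] = None
    variance_profile: Optional[pd.DataFrame] = None
    _weight_cache: dict = field(default_factory=dict, repr=False)


def _face_pixels(face: AlignedFace, element: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if element not in face.maps:
        raise PipelineError(f"face {face.face_id!r} has no map for element {element!r}")
    emap = face.maps[element]
    if emap.shape != face.gray.shape:
        raise PipelineError(f"face {face.face_id!r}: map/plane shape mismatch")
    m = emap.mask
    return face.gray[m].astype(float), emap.data[m], m


def fit_rtk(
    upper: AlignedFace, lower: AlignedFace, element: str, cfg: RTKConfig = RTKConfig()
) -> RTKModel:
    """Fit tree, residual variogram (AIC-selected) and sampling grid.

    The tree is fitted on the pooled pixels of both faces; residual
    variography uses a seeded random subsample of points per face with 3D
    distances (under isotropy inter-layer pairs are valid). If the residuals
    are numerically zero the model is flagged trend-only and kriging is
    skipped at prediction time.
    """
    if not upper.z < lower.z:
        raise PipelineError("faces must be ordered with upper.z < lower.z")
    gu, cu, mu_mask = _face_pixels(upper, element)
    gl, cl, ml_mask = _face_pixels(lower, element)
    if cfg.trend == "linear":
        tree = tr.fit_linear(np.concatenate([gu, gl]), np.concatenate([cu, cl]))
    elif cfg.trend == "tree":
        tree = tr.fit_tree(np.concatenate([gu, gl]), np.concatenate([cu, cl]), cfg.tree)
    else:
        raise PipelineError(f"unknown trend form {cfg.trend!r}")

    def resid_map(face: AlignedFace) -> np.ndarray:
        emap = face.maps[element]
        r = np.full(emap.shape, np.nan)
        m = emap.mask
        r[m] = emap.data[m] - tr.predict_trend(tree, face.gray[m].astype(float))
        return r

    ru, rl = resid_map(upper), resid_map(lower)
    pooled = np.concatenate([ru[mu_mask], rl[ml_mask]])
    scale = max(float(np.mean(np.concatenate([cu, cl]) ** 2)), 1e-30)
    trend_only = float(np.var(pooled)) < 1e-12 * scale

    variogram = None
    aic_table = None
    profile = None
    spacing = cfg.grid_spacing or 8
    if trend_only:
        warnings.warn(
            f"element {element!r}: residuals are numerically zero; model is trend-only"
        )
    else:
        rng = np.random.default_rng(cfg.seed)
        coords, vals = [], []
        for face, rmap in ((upper, ru), (lower, rl)):
            jj, ii = np.nonzero(np.isfinite(rmap))
            if len(jj) > cfg.subsample_per_layer:
                pick = rng.choice(len(jj), size=cfg.subsample_per_layer, replace=False)
                jj, ii = jj[pick], ii[pick]
            r0, c0 = face.orientation.crop_offset
            coords.append(np.column_stack([jj + r0, ii + c0, np.full(len(jj), face.z)]))
            vals.append(rmap[jj, ii])
        emp = empirical_variogram(
            np.vstack(coords), np.concatenate(vals), cfg.bin_width, cfg.max_lag
        )
        variogram, aic_table = aic_select(emp, cfg.candidates)
        if cfg.grid_spacing is None:
            gap = int(round(lower.z - upper.z))
            # only spacings whose grid fits inside both layers are candidates
            extent = min(ru.shape + rl.shape)
            feasible = [s for s in cfg.spacings if (cfg.grid_n - 1) * s + 1 <= extent]
            if not feasible:
                raise PipelineError(
                    f"no candidate grid spacing fits the layer extent {extent}"
                )
            profile = kriging_variance_profile(
                variogram, n=cfg.grid_n, spacings=feasible,
                layer_gap=gap, target_offset=gap // 2,
            )
            spacing = optimize_grid_spacing(profile)

    grid = GridConfig(n=cfg.grid_n, spacing=int(spacing), layer_z=(upper.z, lower.z))
    return RTKModel(
        element=element, tree=tree, residual_variogram=variogram, grid=grid,
        upper=upper, lower=lower, residual_upper=ru, residual_lower=rl,
        trend_only=trend_only, cfg=cfg, aic_table=aic_table, variance_profile=profile,
    )


# ---------------------------------------------------------------------------
# Prediction


def _layer_windows(model: RTKModel) -> tuple[tuple[int, int, int, int], ...]:
    """In-plane coverage (r0, c0, rows, cols) of each residual layer."""
    out = []
    for face, rmap in ((model.upper, model.residual_upper), (model.lower, model.residual_lower)):
        r0, c0 = face.orientation.crop_offset
        out.append((r0, c0, rmap.shape[0], rmap.shape[1]))
    return tuple(out)


def _grid_lu(model: RTKModel):
    """LU factorization of the augmented OK matrix for the two-layer grid.

    The grid translates rigidly with the target, so the point-to-point
    semivariance matrix — and hence this factorization — is shared by every
    target; only the right-hand sides (grid-to-target semivariances) differ.
    """
    if "lu" in model._weight_cache:
        return model._weight_cache["lu"]
    from scipy.linalg import lu_factor

    vario = model.residual_variogram
    n = model.grid.n
    offs = (np.arange(n) - (n - 1) // 2) * model.grid.spacing
    og, pg = np.meshgrid(offs, offs, indexing="ij")
    base_rc = np.column_stack([og.ravel(), pg.ravel()]).astype(float)  # (n^2, 2)
    zu, zl = model.grid.layer_z
    pts = np.vstack([
        np.column_stack([base_rc, np.full(n * n, zu)]),
        np.column_stack([base_rc, np.full(n * n, zl)]),
    ])
    m = 2 * n * n
    A = np.empty((m + 1, m + 1))
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    A[:m, :m] = vario(d)
    A[m, :] = 1.0
    A[:, m] = 1.0
    A[m, m] = 0.0
    try:
        lu = lu_factor(A)
    except Exception:
        A[np.arange(m), np.arange(m)] += 1e-10 * max(vario.total_sill, 1.0)
        lu = lu_factor(A)
    model._weight_cache["lu"] = (lu, base_rc, pts)
    return model._weight_cache["lu"]


def _kriged_residuals(model: RTKModel, rows: np.ndarray, cols: np.ndarray, z: float) -> np.ndarray:
    """OK residual prediction at targets ``(rows[i], cols[i], z)``.

    Weights are solved in one batched pass per (z-offset, boundary-shift)
    set from a single cached LU factorization; targets whose grids touch
    masked residual pixels fall back to a per-target solve on the remaining
    points (warning, not error).
    """
    if model.trend_only:
        return np.zeros(len(rows))
    vario = model.residual_variogram
    n = model.grid.n
    half = (n - 1) // 2 * model.grid.spacing
    lu, base_rc, grid_pts = _grid_lu(model)
    from scipy.linalg import lu_solve

    (ur0, uc0, urows, ucols), (lr0, lc0, lrows, lcols) = _layer_windows(model)
    rmin = max(ur0, lr0) + half
    rmax = min(ur0 + urows, lr0 + lrows) - 1 - half
    cmin = max(uc0, lc0) + half
    cmax = min(uc0 + ucols, lc0 + lcols) - 1 - half
    if rmin > rmax or cmin > cmax:
        raise PipelineError("sampling grid larger than the layers' common extent")

    cr = np.clip(rows, rmin, rmax)
    cc = np.clip(cols, cmin, cmax)
    sr, sc = cr - rows, cc - cols
    zu, zl = model.grid.layer_z
    m = 2 * n * n
    dz = np.concatenate([np.full(n * n, zu - float(z)), np.full(n * n, zl - float(z))])

    # one weight vector per distinct boundary shift, all solved at once
    key_arr = (sr.astype(np.int64) + 2048) * 4096 + (sc + 2048)
    uniq, inv = np.unique(key_arr, return_inverse=True)
    ksr = (uniq // 4096 - 2048).astype(int)
    ksc = (uniq % 4096 - 2048).astype(int)
    zcache_key = (round(float(z), 9), uniq.tobytes())
    if zcache_key in model._weight_cache:
        W = model._weight_cache[zcache_key]
    else:
        drc = np.stack([ksr, ksc], axis=1)[:, None, :] + base_rc[None, :, :]  # (K, n^2, 2)
        d2 = np.concatenate([drc, drc], axis=1) ** 2  # (K, 2 n^2, 2)
        dist = np.sqrt(d2.sum(axis=2) + dz[None, :] ** 2)
        B = np.empty((m + 1, len(uniq)))
        B[:m, :] = vario(dist).T
        B[m, :] = 1.0
        W = lu_solve(lu, B)  # rows 0..m-1: weights; row m: Lagrange mu
        model._weight_cache[zcache_key] = W

    out = np.empty(len(rows))
    for k in range(len(uniq)):
        sel = np.nonzero(inv == k)[0]
        w = W[:m, k]
        gr = rows[sel][:, None] + ksr[k] + base_rc[None, :, 0].astype(int)
        gc = cols[sel][:, None] + ksc[k] + base_rc[None, :, 1].astype(int)
        vu = model.residual_upper[gr - ur0, gc - uc0]
        vl = model.residual_lower[gr - lr0, gc - lc0]
        vals = np.concatenate([vu, vl], axis=1)  # (m_sel, 2 n^2)
        out[sel] = vals @ w
        bad = ~np.isfinite(vals).all(axis=1)
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} target(s) have masked residuals in their grid; "
                "solving those individually on the remaining points"
            )
            rel = base_rc + np.array([ksr[k], ksc[k]])
            pts_full = np.vstack([
                np.column_stack([rel, np.full(n * n, zu - float(z))]),
                np.column_stack([rel, np.full(n * n, zl - float(z))]),
            ])
            for t in np.nonzero(bad)[0]:
                good = np.isfinite(vals[t])
                if good.sum() < 1:
                    out[sel[t]] = 0.0
                    continue
                w2, _, _ = solve_ok_system(pts_full[good], vario, np.zeros(3))
                out[sel[t]] = vals[t][good] @ w2
    return out


def predict_block(
    model: RTKModel,
    volume: GrayscaleVolume,
    region: tuple[tuple[int, int], tuple[int, int], tuple[int, int]],
    method: str = "rtk",
) -> np.ndarray:
    """Predict a 3D box ``((r0, r1), (c0, c1), (z0, z1))`` (half-open).

    ``method="rt"`` is the pure grayscale lookup through the tree;
    ``"rtk"`` adds the ordinary-kriging residual from the two-layer grids.
    The box must lie between the training layers (inclusive).
    """
    if method not in ("rt", "rtk"):
        raise PipelineError(f"unknown method {method!r}")
    (r0, r1), (c0, c1), (z0, z1) = region
    if not (r0 < r1 and c0 < c1 and z0 < z1):
        raise PipelineError("empty region")
    if z0 < model.upper.z or z1 - 1 > model.lower.z:
        raise PipelineError(
            f"region z in [{z0}, {z1}) must lie between the layers "
            f"[{model.upper.z}, {model.lower.z}]"
        )
    gray = volume.data[r0:r1, c0:c1, z0:z1].astype(float)
    out = tr.predict_trend(model.tree, gray)
    if method == "rtk" and not model.trend_only:
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        rr, cc = rr.ravel(), cc.ravel()
        for kz, z in enumerate(range(z0, z1)):
            eps = _kriged_residuals(model, rr, cc, float(z))
            out[:, :, kz] += eps.reshape(r1 - r0, c1 - c0)
    if model.cfg.clamp_nonnegative:
        np.clip(out, 0.0, None, out=out)
    return out


def predict_face(model: RTKModel, face: AlignedFace, method: str = "rtk") -> np.ndarray:
    """Predict at the pixels of an aligned face (used for validation)."""
    if method not in ("rt", "rtk"):
        raise PipelineError(f"unknown method {method!r}")
    out = tr.predict_trend(model.tree, face.gray.astype(float))
    if method == "rtk" and not model.trend_only:
        rows, cols = face.gray.shape
        r0, c0 = face.orientation.crop_offset
        rr, cc = np.meshgrid(np.arange(rows) + r0, np.arange(cols) + c0, indexing="ij")
        eps = _kriged_residuals(model, rr.ravel(), cc.ravel(), face.z)
        out = out + eps.reshape(rows, cols)
    if model.cfg.clamp_nonnegative:
        out = np.clip(out, 0.0, None)
    return out


# ---------------------------------------------------------------------------
# Validation


@dataclass
class ValidationMetrics:
    element: str
    fold: int
    rmse: float
    r2: float
    n: int


def evaluate(predicted: np.ndarray, observed: ElementMap, fold: int = 0) -> ValidationMetrics:
    """RMSE and coefficient of determination over masked-in pixels.

    ``rmse = sqrt(sum (P-O)^2 / N)``; ``r2 = 1 - sum (O-P)^2 / sum (O-mean O)^2``.
    """
    predicted = np.asarray(predicted, dtype=float)
    if predicted.shape != observed.shape:
        raise PipelineError("predicted and observed shapes differ")
    m = observed.mask
    P, O = predicted[m], observed.data[m]
    if len(O) < 2:
        raise PipelineError("need at least 2 valid pixels")
    sse = float(np.sum((P - O) ** 2))
    sst = float(np.sum((O - O.mean()) ** 2))
    if sst == 0:
        raise PipelineError("R^2 undefined: observed values are constant")
    return ValidationMetrics(
        element=observed.element, fold=fold,
        rmse=float(np.sqrt(sse / len(O))), r2=1.0 - sse / sst, n=len(O),
    )


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    undefined: bool = False


def paired_ttest(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-sided paired t-test; zero-variance differences are explicitly
    undefined (never reported as p = 0)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PipelineError("paired t-test needs two equal-length vectors")
    n = len(x)
    if n < 2:
        raise PipelineError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        return TTestResult(t=np.nan, df=df, p=np.nan, undefined=True)
    t = d.mean() / (sd / np.sqrt(n))
    return TTestResult(t=float(t), df=df, p=float(2 * stats.t.sf(abs(t), df)))


def make_folds(layers: LayerSet, outer_gap: float = 65.0) -> list[tuple[int, int, int]]:
    """Leave-middle-layer-out triples of consecutive faces.

    Every triple ``(i, i+1, i+2)`` whose outer faces are ``outer_gap`` voxels
    apart, with the middle face strictly between them, forms one fold. In the
    reference cutting geometry (ten faces, slice 15 layers, kerf 50) this
    yields exactly eight folds, the middle face 15 or 50 layers from the top.
    """
    if len(layers) < 3:
        raise PipelineError("need at least 3 faces for leave-middle-out folds")
    zs = [f.z for f in layers.faces]
    folds = []
    for i in range(len(zs) - 2):
        if abs((zs[i + 2] - zs[i]) - outer_gap) < 1e-9 and zs[i] < zs[i + 1] < zs[i + 2]:
            folds.append((i, i + 1, i + 2))
    return folds


@dataclass
class CVResults:
    """Cross-validation output: per-fold metrics, summaries and paired tests."""

    metrics: pd.DataFrame      # fold, element, method, rmse, r2, n, pred_mean, pred_sd
    observed: pd.DataFrame     # fold, element, obs_mean, obs_sd
    summary: pd.DataFrame      # element, method, rmse_mean, rmse_se, r2_mean, r2_se, ...
    tests: pd.DataFrame        # element, comparison, t, df, p, undefined
    fit_log: pd.DataFrame      # fold, element, variogram, grid_spacing, n_leaves

    def metrics_csv(self) -> str:
        return self.metrics.to_csv(index=False, float_format="%.12g")


def cross_validate(
    layers: LayerSet,
    volume: GrayscaleVolume,
    elements: Optional[Sequence[str]] = None,
    cfg: RTKConfig = RTKConfig(),
    orientations: Optional[dict[str, PlaneOrientation]] = None,
    outer_gap: float = 65.0,
) -> CVResults:
    """Eight-fold (in the reference geometry) leave-middle-layer-out CV.

    Per fold and element: fit tree + variogram + grid on the outer faces,
    predict the middle face by both methods, and score it. Summaries report
    mean +/- SE over folds; paired t-tests compare rt against rtk on RMSE and
    R^2 and each method's prediction mean/SD against the observed ones.
    """
    folds = make_folds(layers, outer_gap)
    if not folds:
        raise PipelineError(f"no fold has outer faces {outer_gap} voxels apart")
    if elements is None:
        elements = list(layers.elements)
    aligned: dict[int, AlignedFace] = {}

    def get_aligned(idx: int) -> AlignedFace:
        if idx not in aligned:
            face = layers.faces[idx]
            o = (orientations or {}).get(face.face_id)
            aligned[idx] = AlignedFace.from_face(face, volume, o)
        return aligned[idx]

    rows, obs_rows, log_rows = [], [], []
    for f, (iu, im, il) in enumerate(folds):
        up, mid, low = get_aligned(iu), get_aligned(im), get_aligned(il)
        for e, el in enumerate(elements):
            sub_seed = int(
                np.random.SeedSequence([cfg.seed, f, e]).generate_state(1)[0] % (2**31)
            )
            fold_cfg = replace(cfg, seed=sub_seed)
            model = fit_rtk(up, low, el, fold_cfg)
            omap = mid.maps[el]
            O = omap.data[omap.mask]
            obs_rows.append(
                {"fold": f, "element": el,
                 "obs_mean": float(O.mean()), "obs_sd": float(O.std(ddof=1))}
            )
            for method in ("rt", "rtk"):
                pred = predict_face(model, mid, method)
                vm = evaluate(pred, omap, fold=f)
                P = pred[omap.mask]
                rows.append(
                    {"fold": f, "element": el, "method": method,
                     "rmse": vm.rmse, "r2": vm.r2, "n": vm.n,
                     "pred_mean": float(P.mean()), "pred_sd": float(P.std(ddof=1))}
                )
            log_rows.append(
                {"fold": f, "element": el,
                 "variogram": "trend-only" if model.trend_only
                 else "+".join(fam for fam, _, _ in model.residual_variogram.components)
                 + ("+nugget" if model.residual_variogram.nugget > 0 else ""),
                 "grid_spacing": model.grid.spacing,
                 "n_leaves": getattr(model.tree, "n_leaves", 1)}
            )

    metrics = pd.DataFrame(rows)
    observed = pd.DataFrame(obs_rows)
    agg = metrics.groupby(["element", "method"], sort=True)
    nfolds = len(folds)
    summary = agg.agg(
        rmse_mean=("rmse", "mean"), rmse_se=("rmse", lambda s: s.std(ddof=1) / np.sqrt(len(s))),
        r2_mean=("r2", "mean"), r2_se=("r2", lambda s: s.std(ddof=1) / np.sqrt(len(s))),
        pred_mean=("pred_mean", "mean"),
        pred_mean_se=("pred_mean", lambda s: s.std(ddof=1) / np.sqrt(len(s))),
        pred_sd=("pred_sd", "mean"),
        pred_sd_se=("pred_sd", lambda s: s.std(ddof=1) / np.sqrt(len(s))),
    ).reset_index()

    test_rows = []
    for el in elements:
        sel = metrics[metrics.element == el]
        rt = sel[sel.method == "rt"].sort_values("fold")
        rtk = sel[sel.method == "rtk"].sort_values("fold")
        ob = observed[observed.element == el].sort_values("fold")
        comparisons = {
            "rmse rt vs rtk": (rt.rmse.to_numpy(), rtk.rmse.to_numpy()),
            "r2 rt vs rtk": (rt.r2.to_numpy(), rtk.r2.to_numpy()),
            "mean rt vs observed": (rt.pred_mean.to_numpy(), ob.obs_mean.to_numpy()),
            "mean rtk vs observed": (rtk.pred_mean.to_numpy(), ob.obs_mean.to_numpy()),
            "sd rt vs observed": (rt.pred_sd.to_numpy(), ob.obs_sd.to_numpy()),
            "sd rtk vs observed": (rtk.pred_sd.to_numpy(), ob.obs_sd.to_numpy()),
        }
        for name, (x, y) in comparisons.items():
            res = paired_ttest(x, y)
            test_rows.append(
                {"element": el, "comparison": name, "t": res.t, "df": res.df,
                 "p": res.p, "undefined": res.undefined}
            )
    return CVResults(
        metrics=metrics, observed=observed, summary=summary,
        tests=pd.DataFrame(test_rows), fit_log=pd.DataFrame(log_rows),
    )
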