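"""Voxelwise GLM inference on skeletonised maps with TFCE + permutation FWE.

The analysis chain mirrors skeleton-based (TBSS-style) inference: per-voxel
ordinary-least-squares fit of a design matrix, threshold-free cluster
enhancement (TFCE) of the t map, and family-wise error control by the
permutation distribution of the image-wide maximum TFCE statistic, using
Freedman-Lane residual permutation of the reduced (nuisance-only) model.

TFCE of a non-negative statistic map is the discrete sum

    TFCE(v) = sum_{h = dh, 2dh, ..., <= max}  e(v, h)^E * h^H * dh

where e(v, h) is the size of the connected component containing v among
voxels with stat >= h.  Defaults E=1, H=2 with 26-connectivity suit thin
sheet-like skeletons; dh defaults to max(stat)/100.  The production path
is an incremental union-find sweep over descending thresholds (numba
compiled) computing the exact same discrete sum as a per-threshold
component-labelling reference.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations as _iter_permutations
from pathlib import Path

import nibabel as nib
import numba
import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError

logger = logging.getLogger(__name__)

T_CAP = 1e6  # stand-in for an infinite t under a perfect (zero-residual) fit

MODALITIES = ("FA", "MD", "NDI", "ODI", "ISO", "F", "k_f")


@dataclass(frozen=True)
class SkeletonMap:
    """One subject x one modality: 3D values restricted to a shared binary mask."""

    values: np.ndarray
    mask: np.ndarray
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)
    modality: str = "FA"
    subject_id: str = ""

    def __post_init__(self) -> None:
        v, m = np.asarray(self.values, dtype=float), np.asarray(self.mask, dtype=bool)
        if v.ndim != 3 or v.shape != m.shape:
            raise InvalidInputError(f"values {v.shape} and mask {m.shape} must be matching 3D arrays")
        if not np.isfinite(v[m]).all():
            raise InvalidInputError("non-finite values inside the mask")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class DesignMatrix:
    """Subjects-by-predictors design with named contrast vectors."""

    frame: pd.DataFrame
    contrasts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        X = self.frame.to_numpy(dtype=float)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise InvalidInputError(
                f"design matrix is rank deficient (columns: {list(self.frame.columns)})"
            )
        for name, c in self.contrasts.items():
            if len(np.atleast_1d(c)) != X.shape[1]:
                raise InvalidInputError(f"contrast {name!r} length != number of design columns")

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)


@dataclass(frozen=True)
class TFCEResult:
    """Observed maps plus the permutation null of the image-wide max TFCE."""

    t_map: np.ndarray
    tfce_map: np.ndarray
    fwe_p_map: np.ndarray
    n_permutations: int
    seed: int
    max_null_distribution: np.ndarray
    significance_mask: np.ndarray
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def read_skeleton_set(paths, mask_path, modality: str = "FA") -> list[SkeletonMap]:
    """Load a study set of skeletonised volumes sharing one mask.

    All volumes must match the mask's grid shape and affine; NaNs inside
    the mask are rejected.  Voxel indices are 0-based in array order.
    """
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    if mask.sum() == 0:
        raise InvalidInputError(f"{mask_path}: mask has no voxels")
    vox = tuple(float(z) for z in mask_img.header.get_zooms()[:3])
    maps = []
    for p in paths:
        img = nib.load(str(p))
        data = np.asarray(img.dataobj, dtype=float)
        if data.shape != mask.shape:
            raise InvalidInputError(f"{p}: shape {data.shape} != mask shape {mask.shape}")
        if not np.allclose(img.affine, mask_img.affine, atol=1e-4):
            raise InvalidInputError(f"{p}: affine differs from the mask volume")
        if np.isnan(data[mask]).any():
            raise InvalidInputError(f"{p}: NaNs inside the mask")
        maps.append(
            SkeletonMap(values=data, mask=mask, voxel_size_mm=vox,
                        modality=modality, subject_id=Path(p).stem.replace(".nii", ""))
        )
    return maps


def write_volume(data: np.ndarray, path, voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    """Write a 3D array as NIfTI-1 with a diagonal affine."""
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine).to_filename(str(path))


def write_skeleton_set(maps: list[SkeletonMap], out_dir) -> tuple[list[Path], Path]:
    """Write one NIfTI per subject plus the shared mask; returns (paths, mask_path)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for m in maps:
        p = out_dir / f"{m.subject_id}_{m.modality}.nii"
        write_volume(m.values, p, m.voxel_size_mm)
        paths.append(p)
    mask_path = out_dir / "mask.nii"
    write_volume(maps[0].mask.astype(np.float32), mask_path, maps[0].voxel_size_mm)
    return paths, mask_path


def _stack(maps: list[SkeletonMap]) -> tuple[np.ndarray, np.ndarray]:
    """Stack a study set into (n_subjects, n_mask_voxels) plus the shared mask."""
    if not maps:
        raise InvalidInputError("empty map list")
    mask = maps[0].mask
    for m in maps[1:]:
        if m.values.shape != mask.shape or not np.array_equal(m.mask, mask):
            raise InvalidInputError(f"subject {m.subject_id}: grid or mask mismatch")
    Y = np.stack([m.values[mask] for m in maps])
    return Y, mask


# ---------------------------------------------------------------------------
# Per-voxel GLM
# ---------------------------------------------------------------------------


def _tstat(Y: np.ndarray, X: np.ndarray, c: np.ndarray) -> np.ndarray:
    """OLS t statistics for contrast c at every column of Y (n x V)."""
    n, k = X.shape
    pinv_xtx = np.linalg.inv(X.T @ X)
    beta = pinv_xtx @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - k
    sigma2 = (resid**2).sum(axis=0) / df
    c = np.asarray(c, dtype=float)
    num = c @ beta
    cvc = float(c @ pinv_xtx @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / np.sqrt(sigma2 * cvc)
    bad = ~np.isfinite(t) | (np.abs(t) > T_CAP)  # zero residual variance up to round-off
    if bad.any():
        logger.warning("%d voxels with zero residual variance; t capped at %.0e", bad.sum(), T_CAP)
        t[bad] = np.sign(num[bad]) * T_CAP
        t[bad & (num == 0)] = 0.0
    return t


def glm_tstat_map(maps: list[SkeletonMap], design: DesignMatrix, contrast) -> np.ndarray:
    """Per-voxel OLS t map for a contrast (3D array, zero off-mask).

    t = c'beta / sqrt(sigma^2 c'(X'X)^-1 c) with residual df = n - rank(X).
    ``contrast`` may be a contrast name from the design or an explicit vector.
    """
    Y, mask = _stack(maps)
    X = design.matrix
    if X.shape[0] != Y.shape[0]:
        raise InvalidInputError("design rows do not match the number of maps")
    if X.shape[0] <= X.shape[1]:
        raise InvalidInputError("need more subjects than design columns")
    c = design.contrasts[contrast] if isinstance(contrast, str) else np.asarray(contrast, float)
    if len(c) != X.shape[1]:
        raise InvalidInputError("contrast length != number of design columns")
    out = np.zeros(mask.shape)
    out[mask] = _tstat(Y, X, c)
    return out


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------


def _neighbour_offsets(connectivity: int) -> np.ndarray:
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return np.array(offs, dtype=np.int64)


@numba.njit(cache=True)
def _find(parent, delta, x):
    # root + accumulated delta along the path, with path compression
    r = x
    dsum = 0.0
    while parent[r] != r:
        dsum += delta[r]
        r = parent[r]
    c = x
    csum = dsum
    while parent[c] != r:
        nxt = parent[c]
        nd = delta[c]
        parent[c] = r
        delta[c] = csum
        csum -= nd
        c = nxt
    return r, dsum


@numba.njit(cache=True)
def _tfce_sweep(stat, nx, ny, nz, order, offsets, E, H, dh, n_steps):
    """Exact discrete-sum TFCE by an incremental union-find over descending
    thresholds.  ``stat`` is the flattened map (non-mask voxels already 0),
    ``order`` lists voxel indices by decreasing stat."""
    n = stat.size
    parent = np.full(n, -1, dtype=np.int64)
    delta = np.zeros(n, dtype=np.float64)
    val = np.zeros(n, dtype=np.float64)
    size = np.zeros(n, dtype=np.int64)
    active = np.empty(n, dtype=np.int64)
    n_active = 0
    ptr = 0
    n_off = offsets.shape[0]

    for i in range(n_steps, 0, -1):
        h = i * dh
        # activate voxels with stat >= h and union with active neighbours
        while ptr < order.size and stat[order[ptr]] >= h:
            v = order[ptr]
            ptr += 1
            parent[v] = v
            size[v] = 1
            active[n_active] = v
            n_active += 1
            vz = v % nz
            vy = (v // nz) % ny
            vx = v // (nz * ny)
            for j in range(n_off):
                qx = vx + offsets[j, 0]
                qy = vy + offsets[j, 1]
                qz = vz + offsets[j, 2]
                if qx < 0 or qx >= nx or qy < 0 or qy >= ny or qz < 0 or qz >= nz:
                    continue
                q = (qx * ny + qy) * nz + qz
                if parent[q] == -1:
                    continue
                ra, _ = _find(parent, delta, v)
                rb, _ = _find(parent, delta, q)
                if ra == rb:
                    continue
                if size[ra] < size[rb]:
                    ra, rb = rb, ra
                parent[rb] = ra
                delta[rb] = val[rb] - val[ra]
                size[ra] += size[rb]
        # accumulate this threshold's contribution at every current root
        inc_h = h**H * dh
        for a in range(n_active):
            v = active[a]
            if parent[v] == v:
                val[v] += float(size[v]) ** E * inc_h

    out = np.zeros(n, dtype=np.float64)
    for a in range(n_active):
        v = active[a]
        r, dsum = _find(parent, delta, v)
        out[v] = val[r] + dsum
    return out


def tfce_transform(
    stat_map: np.ndarray,
    mask: np.ndarray,
    E: float = 1.0,
    H: float = 2.0,
    dh: float | None = None,
    connectivity: int = 26,
) -> np.ndarray:
    """Threshold-free cluster enhancement of the positive tail of a stat map.

    Negative contrasts are handled by the caller negating the map.  ``dh``
    defaults to max(stat)/100; voxels below dh receive 0.
    """
    if connectivity not in (6, 18, 26):
        raise InvalidParameterError("connectivity must be 6, 18 or 26")
    if dh is not None and dh <= 0:
        raise InvalidParameterError("dh must be positive")
    stat = np.where(np.asarray(mask, bool), np.asarray(stat_map, float), 0.0)
    mx = float(stat.max(initial=0.0))
    if mx <= 0:
        return np.zeros_like(stat)
    step = mx / 100.0 if dh is None else float(dh)
    n_steps = int(math.floor(mx / step))
    if n_steps < 1:
        return np.zeros_like(stat)
    flat = stat.ravel()
    pos = np.flatnonzero(flat >= step)
    order = pos[np.argsort(-flat[pos], kind="stable")]
    out = _tfce_sweep(
        flat, *stat.shape, order, _neighbour_offsets(connectivity),
        float(E), float(H), step, n_steps,
    )
    return out.reshape(stat.shape)


# ---------------------------------------------------------------------------
# Permutation inference (Freedman-Lane)
# ---------------------------------------------------------------------------


def _all_or_random_perms(n: int, n_perm: int, rng: np.random.Generator):
    """Random row permutations, or full enumeration when n! <= n_perm."""
    if math.factorial(n) <= n_perm:
        warnings.warn(
            f"only {math.factorial(n)} distinct permutations for n={n}; enumerating all",
            stacklevel=3,
        )
        return [np.array(p) for p in _iter_permutations(range(n))], True
    return [rng.permutation(n) for _ in range(n_perm)], False


def permutation_inference(
    maps: list[SkeletonMap],
    design: DesignMatrix,
    contrast,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "freedman-lane",
    tail: str = "pos",
    alpha: float = 0.05,
    E: float = 1.0,
    H: float = 2.0,
    dh: float | None = None,
    connectivity: int = 26,
) -> TFCEResult:
    """Max-statistic TFCE permutation test for one contrast.

    Freedman-Lane: residuals of the nuisance-only (contrast-zero columns)
    model are row-permuted, the nuisance fit is added back, and the full
    model is refitted; the maximum TFCE statistic over the mask per
    permutation forms the FWE null.  ``fwe_p(v) = (1 + #{max* >=
    TFCE_obs(v)}) / (n_perm + 1)``.  ``tail`` is "pos" (default), "neg",
    or "two" (both tails enhanced, null is the max over both).
    """
    if n_perm < 100:
        raise InvalidParameterError("n_perm must be >= 100")
    if method not in ("freedman-lane", "labels"):
        raise InvalidParameterError(f"unknown permutation method {method!r}")
    if tail not in ("pos", "neg", "two"):
        raise InvalidParameterError("tail must be 'pos', 'neg' or 'two'")

    Y, mask = _stack(maps)
    X = design.matrix
    c = design.contrasts[contrast] if isinstance(contrast, str) else np.asarray(contrast, float)
    n = X.shape[0]
    rng = np.random.default_rng(seed)

    def enhance(t_flat: np.ndarray) -> np.ndarray:
        vol = np.zeros(mask.shape)
        vol[mask] = t_flat if tail != "neg" else -t_flat
        enh = tfce_transform(vol, mask, E=E, H=H, dh=dh, connectivity=connectivity)
        if tail == "two":
            vol[mask] = -t_flat
            enh = np.maximum(enh, tfce_transform(vol, mask, E=E, H=H, dh=dh, connectivity=connectivity))
        return enh

    t_obs = _tstat(Y, X, c)
    tfce_obs = enhance(t_obs)

    nuisance = np.flatnonzero(np.asarray(c) == 0)
    if method == "freedman-lane" and nuisance.size:
        Z = X[:, nuisance]
        gamma, *_ = np.linalg.lstsq(Z, Y, rcond=None)
        fitted = Z @ gamma
        resid = Y - fitted
    else:
        fitted, resid = 0.0, Y

    perms, enumerated = _all_or_random_perms(n, n_perm, rng)
    maxima = np.empty(len(perms))
    for i, p in enumerate(perms):
        Yp = fitted + resid[p]
        maxima[i] = enhance(_tstat(Yp, X, c)).max()

    null = np.sort(maxima)
    obs_vals = tfce_obs[mask]
    # count of null maxima >= observed, via searchsorted on the sorted null
    ge = len(null) - np.searchsorted(null, obs_vals, side="left")
    if enumerated:
        p_vals = ge / len(null)
    else:
        p_vals = (1.0 + ge) / (len(null) + 1.0)
    fwe_p = np.ones(mask.shape)
    fwe_p[mask] = p_vals

    t_map = np.zeros(mask.shape)
    t_map[mask] = t_obs
    sig = (fwe_p <= alpha) & mask
    return TFCEResult(
        t_map=t_map,
        tfce_map=tfce_obs,
        fwe_p_map=fwe_p,
        n_permutations=len(perms),
        seed=seed,
        max_null_distribution=null,
        significance_mask=sig,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Interaction design and cluster means
# ---------------------------------------------------------------------------


def interaction_design(
    cohort: pd.DataFrame,
    behavioural_variable: str,
    split: str = "median",
    covariates: list[str] | None = None,
    fatigue_variable: str = "mfis_cog",
) -> DesignMatrix:
    """Fatigue x insight interaction design for the imaged cohort.

    Columns: intercept, mean-centred fatigue score, binary insight level
    (median split of the behavioural variable; label 1 iff value >= median),
    their product, then mean-centred covariates.  Contrasts "fatigue",
    "insight" and "interaction" target the respective columns.
    """
    covariates = covariates or []
    beh = cohort[behavioural_variable]
    if beh.isna().any():
        missing = cohort.loc[beh.isna(), "subject_id"].tolist()
        raise InvalidInputError(f"missing {behavioural_variable} for subjects: {missing}")
    if split == "median":
        cutoff = float(beh.median())
    else:
        cutoff = float(split)
    level = (beh >= cutoff).astype(float).to_numpy()
    if np.ptp(level) == 0:
        raise InvalidInputError(
            f"insight split of {behavioural_variable!r} is constant; design would be rank deficient"
        )
    fat = cohort[fatigue_variable].to_numpy(dtype=float)
    fat_c = fat - fat.mean()
    cols = {
        "intercept": np.ones(len(cohort)),
        "fatigue": fat_c,
        "insight_level": level,
        "interaction": fat_c * level,
    }
    for cv in covariates:
        v = cohort[cv].to_numpy(dtype=float)
        cols[cv] = v - v.mean()
    frame = pd.DataFrame(cols, index=cohort.index)
    k = frame.shape[1]
    eye = np.eye(k)
    contrasts = {
        "fatigue": eye[1],
        "insight": eye[2],
        "interaction": eye[3],
    }
    return DesignMatrix(frame=frame, contrasts=contrasts)


def extract_cluster_means(maps: list[SkeletonMap], significance_mask: np.ndarray) -> pd.DataFrame:
    """Mean map value over the significant voxels, one row per subject."""
    sig = np.asarray(significance_mask, bool)
    if sig.sum() == 0:
        raise InvalidInputError("empty significance mask")
    _, mask = _stack(maps)
    if not (sig <= mask).all():
        raise InvalidInputError("significance mask extends outside the study mask")
    rows = [
        {"subject_id": m.subject_id, "modality": m.modality, "cluster_mean": float(m.values[sig].mean())}
        for m in maps
    ]
    return pd.DataFrame(rows)
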