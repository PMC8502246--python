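"""Band-to-band registration against the green reference band.

The five lenses are not hardware aligned, so each non-green band is warped
into the green band's pixel frame.  The transform is estimated by iterative
maximisation of an enhanced correlation criterion between gradient-magnitude
images (cross-band intensities are not directly comparable, gradients are),
with a coarse-to-fine pyramid for larger displacements.

Matrix convention: ``matrix`` maps reference-frame (x=col, y=row) homogeneous
pixel coordinates into the source band's frame, i.e. it is the inverse map
used to resample the source band onto the reference grid.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.transform import ProjectiveTransform, rescale, warp

from .errors import ConfigurationError, ContractError, DegenerateInputError
from .radiometry import BANDS, ReflectanceStack

#: Default optimizer settings (exposed through the pipeline config).
MAX_ITERATIONS = 200
EPSILON = 1e-6
MIN_CORRELATION = 0.4


@dataclass
class BandHomography:
    matrix: np.ndarray  # 3x3, element (3,3) == 1
    source_band: str
    reference_band: str = "green"
    converged: bool = False
    correlation: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (3, 3):
            raise ContractError("homography matrix must be 3x3")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ContractError("homography matrix must be invertible")
        if self.matrix[2, 2] != 0:
            self.matrix = self.matrix / self.matrix[2, 2]
        if self.reference_band != "green":
            raise ContractError("reference band must be green")


def _gradient_image(image: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    img = ndimage.gaussian_filter(np.asarray(image, dtype=np.float64), sigma)
    gy, gx = np.gradient(img)
    g = np.hypot(gx, gy)
    sd = g.std()
    if sd == 0:
        raise DegenerateInputError("constant image: cannot estimate an alignment")
    return (g - g.mean()) / sd


def _ecc_affine(ref: np.ndarray, tgt: np.ndarray, p: np.ndarray,
                max_iter: int, eps: float) -> tuple[np.ndarray, float, bool]:
    """One pyramid level of forward-additive ECC maximisation (affine warp).

    ``p`` packs the affine as [a00-1, a01, a02, a10, a11-1, a12]; the warp
    maps reference (x, y) to target coordinates.
    """
    rows, cols = ref.shape
    m = 3  # border margin excluded from the support
    # Subsample the support so the normal equations stay cheap at fine levels.
    n_full = (rows - 2 * m) * (cols - 2 * m)
    stride = max(1, int(np.sqrt(n_full / 60_000)) if n_full > 60_000 else 1)
    ys, xs = np.mgrid[m:rows - m:stride, m:cols - m:stride]
    xs = xs.ravel().astype(np.float64)
    ys = ys.ravel().astype(np.float64)
    r = ref[m:rows - m:stride, m:cols - m:stride].ravel()

    gy_t, gx_t = np.gradient(tgt)
    rho_prev = -np.inf
    best_rho = -np.inf
    best_p = p.copy()
    stall = 0
    ok = False
    for _ in range(max_iter):
        wx = (1.0 + p[0]) * xs + p[1] * ys + p[2]
        wy = p[3] * xs + (1.0 + p[4]) * ys + p[5]
        inb = (wx >= 1) & (wx <= cols - 2) & (wy >= 1) & (wy <= rows - 2)
        if inb.sum() < 64:
            return p, 0.0, False
        coords = np.vstack([wy[inb], wx[inb]])
        iw = ndimage.map_coordinates(tgt, coords, order=1, mode="nearest")
        gx = ndimage.map_coordinates(gx_t, coords, order=1, mode="nearest")
        gy = ndimage.map_coordinates(gy_t, coords, order=1, mode="nearest")
        xv, yv = xs[inb], ys[inb]
        ir = r[inb]

        ir = ir - ir.mean()
        iw = iw - iw.mean()
        nr = np.linalg.norm(ir)
        nw = np.linalg.norm(iw)
        if nr == 0 or nw == 0:
            return p, 0.0, False
        rho = float(ir @ iw / (nr * nw))
        if rho > best_rho:
            best_rho, best_p = rho, p.copy()
            stall = 0
        else:
            stall += 1
            if stall >= 5:  # oscillating around the optimum
                return best_p, best_rho, True

        G = np.column_stack([gx * xv, gx * yv, gx, gy * xv, gy * yv, gy])
        G = G - G.mean(axis=0)
        GtG = G.T @ G
        try:
            inv = np.linalg.inv(GtG)
        except np.linalg.LinAlgError:
            return p, rho, False
        Gw = G.T @ iw
        Gr = G.T @ ir
        num = iw @ iw - Gw @ inv @ Gw
        den = ir @ iw - Gr @ inv @ Gw
        if den <= 0:
            # Projected images anti-correlated: no meaningful ascent direction.
            return p, rho, False
        lam = num / den
        error = lam * ir - iw
        dp = inv @ (G.T @ error)
        p = p + dp
        # Stop on a stagnant correlation or a negligible parameter update.
        step_px = abs(dp[2]) + abs(dp[5]) + (abs(dp[0]) + abs(dp[1]) + abs(dp[3]) + abs(dp[4])) * max(rows, cols)
        if abs(rho - rho_prev) < eps or step_px < 5e-3:
            if rho >= best_rho:
                best_rho, best_p = rho, p.copy()
            ok = True
            break
        rho_prev = rho
    else:
        ok = True  # hit the iteration cap; keep the best iterate seen
    return best_p, best_rho, ok


def _pyramid_levels(shape: tuple[int, int]) -> int:
    levels = 1
    d = min(shape)
    while d >= 80 and levels < 4:
        d //= 2
        levels += 1
    return levels


def estimate_homography(reference: np.ndarray, target: np.ndarray,
                        max_iter: int = MAX_ITERATIONS, eps: float = EPSILON,
                        source_band: str = "", ) -> BandHomography:
    """Estimate the transform that resamples ``target`` onto ``reference``.

    Returns an identity matrix with ``converged=False`` when the optimiser
    fails or the final correlation is too low to trust.
    """
    reference = np.asarray(reference, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if reference.shape != target.shape:
        raise ContractError("reference and target must share a shape")
    gr = _gradient_image(reference)
    gt = _gradient_image(target)

    levels = _pyramid_levels(reference.shape)
    p = np.zeros(6)
    # Seed the translation with phase correlation so large shifts start
    # inside the ECC basin of attraction.
    try:
        shift, _, _ = phase_cross_correlation(gr, gt, upsample_factor=4)
        p[2], p[5] = -shift[1], -shift[0]
    except (ValueError, ZeroDivisionError):
        pass
    rho = 0.0
    ok = True
    for level in range(levels - 1, -1, -1):
        scale = 2**level
        if scale > 1:
            rl = rescale(gr, 1.0 / scale, anti_aliasing=True)
            tl = rescale(gt, 1.0 / scale, anti_aliasing=True)
        else:
            rl, tl = gr, gt
        p_level = p.copy()
        p_level[2] /= scale
        p_level[5] /= scale
        # Coarse levels do the bulk of the search; fine (expensive) levels
        # only need a handful of refinement steps.
        level_iter = max_iter if scale >= 4 else min(max_iter, 40 if scale == 2 else 25)
        p_level, rho, ok = _ecc_affine(rl, tl, p_level, level_iter, eps)
        p = p_level
        p[2] *= scale
        p[5] *= scale
        if not ok:
            break

    matrix = np.array([
        [1.0 + p[0], p[1], p[2]],
        [p[3], 1.0 + p[4], p[5]],
        [0.0, 0.0, 1.0],
    ])
    converged = bool(ok and rho >= MIN_CORRELATION)
    if not converged:
        matrix = np.eye(3)
    return BandHomography(matrix=matrix, source_band=source_band, converged=converged,
                          correlation=float(np.clip(rho, -1.0, 1.0)))


def median_homography(homographies: list[BandHomography]) -> BandHomography:
    """Element-wise median matrix, renormalised so element (3,3) = 1."""
    if not homographies:
        raise ContractError("need at least one homography")
    bands = {h.source_band for h in homographies}
    if len(bands) > 1:
        raise ContractError(f"cannot pool homographies across bands {bands}")
    stackmat = np.stack([h.matrix for h in homographies])
    med = np.median(stackmat, axis=0)
    med /= med[2, 2]
    return BandHomography(matrix=med, source_band=homographies[0].source_band,
                          converged=all(h.converged for h in homographies),
                          correlation=float(np.median([h.correlation for h in homographies])))


def align_capture(stack: ReflectanceStack,
                  homographies: dict[str, BandHomography]) -> ReflectanceStack:
    """Warp every non-green band onto the green band's pixel grid.

    Bilinear resampling; pixels resampled from outside the source frame are
    marked invalid in the output stack's ``valid_mask``.
    """
    for band in BANDS:
        if band != "green" and band not in homographies:
            raise ConfigurationError(f"missing homography for band {band}")
    out: dict[str, np.ndarray] = {"green": stack.bands["green"].copy()}
    valid = np.ones(stack.shape, dtype=bool)
    if stack.valid_mask is not None:
        valid &= stack.valid_mask
    for band in BANDS:
        if band == "green":
            continue
        h = homographies[band]
        if np.allclose(h.matrix, np.eye(3)):
            out[band] = stack.bands[band].copy()
            continue
        tform = ProjectiveTransform(matrix=h.matrix)
        warped = warp(stack.bands[band].astype(np.float64), tform, order=1,
                      cval=np.nan, preserve_range=True)
        bad = ~np.isfinite(warped)
        warped[bad] = 0.0
        valid &= ~bad
        out[band] = warped
    return ReflectanceStack(bands=out, capture_id=stack.capture_id, aligned=True,
                            valid_mask=valid)
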