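"""Image-quality metrics (MSE, peak SNR, SSIM, multi-scale SSIM) and the
FIBIS-vs-raw-baseline benchmark harness.

MSE is the mean squared pixel-wise error over the M x N image,
``(1/MN) sum (R_ij - F_ij)^2``; PSNR is ``10 log10(L^2 / MSE)`` with L the
maximum pixel value of the 0-255 scale.  SSIM uses the standard windowed
luminance/contrast/structure comparison with a uniform 7x7 window and
stabilizers C1 = (k1 L)^2, C2 = (k2 L)^2; MS-SSIM combines the
contrast-structure terms over dyadic downsamplings with the canonical
five-scale exponent weights.  Segmentation masks are compared as 0/255
images so L is meaningful for binary content.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import TCSPCStack
from .segment import FibisConfig, baseline_raw_threshold, fibis_pipeline
from .synth import GroundTruth

MS_SSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


@dataclasses.dataclass
class MetricReport:
    mse: float
    psnr_db: float
    ssim: float
    ms_ssim: float
    dims: tuple[int, int]


def _check_pair(reference: np.ndarray, sample: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    r = np.asarray(reference, dtype=float)
    f = np.asarray(sample, dtype=float)
    if r.shape != f.shape:
        raise ValueError(f"shape mismatch: {r.shape} vs {f.shape}")
    return r, f


def mse(reference: np.ndarray, sample: np.ndarray) -> float:
    r, f = _check_pair(reference, sample)
    return float(np.mean((r - f) ** 2))


def psnr(reference: np.ndarray, sample: np.ndarray, L: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; identical images give +inf."""
    if L <= 0:
        raise ValueError("L must be positive")
    err = mse(reference, sample)
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10(L * L / err))


def _ssim_components(
    r: np.ndarray,
    f: np.ndarray,
    window: int,
    k1: float,
    k2: float,
    L: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window luminance and contrast-structure maps (full windows only).

    Moments are plain (biased) window averages, matching the definitional
    double-loop computation.
    """
    if min(r.shape) < window:
        raise ValueError("window larger than image")
    c1 = (k1 * L) ** 2
    c2 = (k2 * L) ** 2
    m = window // 2

    def wmean(x: np.ndarray) -> np.ndarray:
        return ndimage.uniform_filter(x, size=window, mode="constant")[
            m : x.shape[0] - m, m : x.shape[1] - m
        ]

    mu_r, mu_f = wmean(r), wmean(f)
    var_r = wmean(r * r) - mu_r**2
    var_f = wmean(f * f) - mu_f**2
    cov = wmean(r * f) - mu_r * mu_f
    lum = (2 * mu_r * mu_f + c1) / (mu_r**2 + mu_f**2 + c1)
    cs = (2 * cov + c2) / (var_r + var_f + c2)
    return lum, cs


def ssim(
    reference: np.ndarray,
    sample: np.ndarray,
    window: int = 7,
    k1: float = 0.01,
    k2: float = 0.03,
    L: float = 255.0,
) -> float:
    """Mean structural similarity over all full sliding windows."""
    r, f = _check_pair(reference, sample)
    lum, cs = _ssim_components(r, f, window, k1, k2, L)
    return float(np.mean(lum * cs))


def _downsample2(x: np.ndarray) -> np.ndarray:
    """2x2 average pooling (trailing odd row/column dropped)."""
    H, W = (x.shape[0] // 2) * 2, (x.shape[1] // 2) * 2
    x = x[:H, :W]
    return 0.25 * (x[0::2, 0::2] + x[1::2, 0::2] + x[0::2, 1::2] + x[1::2, 1::2])


def ms_ssim(
    reference: np.ndarray,
    sample: np.ndarray,
    scales: int = 5,
    window: int = 7,
    k1: float = 0.01,
    k2: float = 0.03,
    L: float = 255.0,
    weights: Sequence[float] = MS_SSIM_WEIGHTS,
) -> float:
    """Multi-scale SSIM with the canonical exponent weights.

    Contrast-structure terms are accumulated at every dyadic scale and the
    luminance term only at the coarsest; if the image is too small for the
    requested number of scales, fewer are used with a warning.  ``scales=1``
    reduces exactly to :func:`ssim`.
    """
    r, f = _check_pair(reference, sample)
    max_scales = 1
    side = min(r.shape)
    while max_scales < scales and (side // 2) >= window:
        side //= 2
        max_scales += 1
    if max_scales < scales:
        warnings.warn(
            f"image too small for {scales} scales; using {max_scales}"
        )
        scales = max_scales
    w = np.asarray(weights[:scales], dtype=float)
    w = w / w.sum()

    vals = 1.0
    for j in range(scales):
        lum, cs = _ssim_components(r, f, window, k1, k2, L)
        if j == scales - 1:
            vals *= max(float(np.mean(lum * cs)) if scales == 1 else float(np.mean(lum)), 0.0) ** w[j]
            if scales > 1:
                vals *= max(float(np.mean(cs)), 0.0) ** w[j]
        else:
            vals *= max(float(np.mean(cs)), 0.0) ** w[j]
            r, f = _downsample2(r), _downsample2(f)
    return float(np.clip(vals, 0.0, 1.0))


def metric_report(
    reference: np.ndarray, sample: np.ndarray, L: float = 255.0
) -> MetricReport:
    r, f = _check_pair(reference, sample)
    return MetricReport(
        mse=mse(r, f),
        psnr_db=psnr(r, f, L=L),
        ssim=ssim(r, f, L=L),
        ms_ssim=ms_ssim(r, f, L=L),
        dims=r.shape,
    )


# ---------------------------------------------------------------------------
# FIBIS vs baseline benchmark
# ---------------------------------------------------------------------------

def _as_255(binary: np.ndarray) -> np.ndarray:
    return np.where(np.asarray(binary, bool), 255.0, 0.0)


def benchmark_similarity(
    pairs: Iterable[tuple[TCSPCStack, GroundTruth]],
    config: FibisConfig,
) -> tuple[pd.DataFrame, dict]:
    """Score FIBIS and the raw-intensity baseline against reference masks.

    For every acquisition both segmentations are computed and compared with
    the ground-truth mask as 0/255 images.  Returns per-trial rows
    (trial, method, mse, psnr_db, ssim, ms_ssim) and a summary with means,
    standard errors and the relative improvement percentages of FIBIS over
    the baseline per metric (sign oriented so that positive = FIBIS better;
    undefined improvements, e.g. infinite PSNR, are flagged as NaN).
    """
    rows = []
    n = 0
    for trial, (stack, truth) in enumerate(pairs):
        n += 1
        ref = _as_255(truth.mask > 0)
        fib = _as_255(fibis_pipeline(stack, config).binary())
        base = _as_255(
            baseline_raw_threshold(stack, quantile=config.baseline_quantile).binary()
        )
        for method, img in (("fibis", fib), ("baseline", base)):
            rows.append(
                {
                    "trial": trial,
                    "method": method,
                    "mse": mse(ref, img),
                    "psnr_db": psnr(ref, img),
                    "ssim": ssim(ref, img),
                    "ms_ssim": ms_ssim(ref, img),
                }
            )
    if n < 2:
        raise ValueError("benchmark needs at least 2 acquisitions")
    df = pd.DataFrame(rows)
    summary: dict = {"n_trials": n}
    for metric in ("mse", "psnr_db", "ssim", "ms_ssim"):
        a = df.loc[df["method"] == "fibis", metric].to_numpy()
        b = df.loc[df["method"] == "baseline", metric].to_numpy()
        summary[f"{metric}_fibis_mean"] = float(np.mean(a))
        summary[f"{metric}_fibis_sem"] = float(np.std(a, ddof=1) / np.sqrt(n))
        summary[f"{metric}_baseline_mean"] = float(np.mean(b))
        summary[f"{metric}_baseline_sem"] = float(np.std(b, ddof=1) / np.sqrt(n))
        ma, mb = np.mean(a), np.mean(b)
        if not np.isfinite(ma) or not np.isfinite(mb) or mb == 0:
            imp = float("nan")
        elif metric == "mse":  # lower is better
            imp = 100.0 * (mb - ma) / mb
        else:
            imp = 100.0 * (ma - mb) / mb
        summary[f"{metric}_improvement_pct"] = float(imp)
    return df, summary
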