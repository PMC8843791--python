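"""Fusion-quality diagnostics: PSNR, SSIM, and normalized correlation.

These scores compare the fused output against each source image.  They are
gatekeeping diagnostics (a fused image should remain correlated with both
inputs), not classification metrics.  PSNR and SSIM use the standard
definitions on the [0, 1] intensity scale; NC is the Pearson correlation
of the pixel vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from skimage import metrics as skmetrics


@dataclass(frozen=True)
class QualityReport:
    """PSNR (dB, ``inf`` for identical images), SSIM and NC in [-1, 1]."""

    psnr: float
    ssim: float
    ncc: float

    def as_dict(self) -> dict:
        return asdict(self)


def _check_shapes(reference: np.ndarray, test: np.ndarray) -> tuple:
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError("images must have identical dimensions")
    return reference, test


def psnr(reference: np.ndarray, test: np.ndarray) -> float:
    """Peak signal-to-noise ratio, 10*log10(1 / MSE) dB on the [0,1] scale.

    Returns ``math.inf`` when the images are identical (zero MSE).
    """
    reference, test = _check_shapes(reference, test)
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(1.0 / mse)


def ssim(reference: np.ndarray, test: np.ndarray) -> float:
    """Mean local structural similarity (11x11 Gaussian window, sigma 1.5).

    Stability constants C1=(0.01)^2, C2=(0.03)^2 on the [0,1] scale; the
    value lies in [-1, 1] and equals 1 only for identical images.
    """
    reference, test = _check_shapes(reference, test)
    if min(reference.shape) < 11:
        raise ValueError("images must be at least 11x11 for SSIM")
    return float(skmetrics.structural_similarity(
        reference, test, win_size=11, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, data_range=1.0,
    ))


def ncc(reference: np.ndarray, test: np.ndarray) -> float:
    """Zero-mean normalized cross-correlation (Pearson r of pixel vectors)."""
    reference, test = _check_shapes(reference, test)
    a = reference.ravel()
    b = test.ravel()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a constant image")
    return float(np.corrcoef(a, b)[0, 1])


def quality_report(reference: np.ndarray, test: np.ndarray) -> QualityReport:
    """All three scores of ``test`` against ``reference``."""
    return QualityReport(psnr=psnr(reference, test),
                         ssim=ssim(reference, test),
                         ncc=ncc(reference, test))
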