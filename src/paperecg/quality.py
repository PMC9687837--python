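"""Image fidelity metrics between original and processed sheets.

MSE and RMSE are computed on intensities rescaled to [0, 1]; PSNR uses the
8-bit convention ``10*log10(255^2 / MSE_8bit)`` so both printed scales are
reproduced from one pair of images. SSIM is the standard mean local
structural similarity with a uniform 7x7 window. Reports aggregate
per-image records into arithmetic means and PSNR range bins of 1 dB
(``x.01 .. (x+1).00``), the binning used to summarize batch quality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from .errors import InputError


@dataclass(frozen=True)
class QualityRecord:
    image_id: str
    mse: float      # [0, 1] intensity scale
    psnr: float     # dB; +inf for identical images
    ssim: float
    rmse: float


@dataclass
class QualityReport:
    records: list[QualityRecord]
    averages: dict[str, float]
    psnr_bins: list[tuple[str, int, float]] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(
            [(r.image_id, r.mse, r.psnr, r.ssim, r.rmse) for r in self.records],
            columns=["image_id", "mse", "psnr", "ssim", "rmse"],
        )


def _pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise InputError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mse(a, b) -> float:
    """Mean squared difference on the [0, 1] intensity scale."""
    a, b = _pair(a, b)
    return float(np.mean(((a - b) / 255.0) ** 2))


def rmse(a, b) -> float:
    return math.sqrt(mse(a, b))


def psnr(a, b) -> float:
    """Peak signal-to-noise ratio in dB (MAX = 255); +inf if identical."""
    a, b = _pair(a, b)
    err = float(np.mean((a - b) ** 2))
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(255.0**2 / err)


def ssim(a, b, window: int = 7, k1: float = 0.01, k2: float = 0.03,
         data_range: float = 255.0) -> float:
    """Mean local SSIM over uniform sliding windows."""
    a, b = _pair(a, b)
    if min(a.shape) < window:
        raise InputError(f"image smaller than the {window}x{window} window")
    return float(structural_similarity(
        a, b, win_size=window, gaussian_weights=False,
        K1=k1, K2=k2, data_range=data_range,
    ))


def psnr_bin_label(value: float) -> str:
    """1-dB bin label, upper-inclusive: 36.5 and 37.0 both fall in 36.01-37.00."""
    if math.isinf(value):
        return "identical"
    hi = max(math.ceil(value), 1)
    return f"{hi - 1 + 0.01:.2f}-{hi:.2f}"


def quality_report(pairs, image_ids=None) -> QualityReport:
    """Per-image records, means, and PSNR bin percentages for (orig, proc) pairs.

    Averages of PSNR are taken over finite values; identical pairs are
    counted in their own ``identical`` bin.
    """
    pairs = list(pairs)
    if not pairs:
        raise InputError("quality_report requires at least one image pair")
    if image_ids is None:
        image_ids = [f"image_{i + 1}" for i in range(len(pairs))]
    records = []
    for image_id, (a, b) in zip(image_ids, pairs):
        records.append(QualityRecord(
            image_id=image_id,
            mse=mse(a, b), psnr=psnr(a, b), ssim=ssim(a, b), rmse=rmse(a, b),
        ))
    finite_psnr = [r.psnr for r in records if math.isfinite(r.psnr)]
    averages = {
        "mse": float(np.mean([r.mse for r in records])),
        "psnr": float(np.mean(finite_psnr)) if finite_psnr else math.inf,
        "ssim": float(np.mean([r.ssim for r in records])),
        "rmse": float(np.mean([r.rmse for r in records])),
    }
    labels = [psnr_bin_label(r.psnr) for r in records]
    bins = []
    for label in sorted(set(labels)):
        n = labels.count(label)
        bins.append((label, n, 100.0 * n / len(records)))
    return QualityReport(records=records, averages=averages, psnr_bins=bins)
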