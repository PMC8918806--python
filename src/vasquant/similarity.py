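"""Overlap and intensity similarity metrics between two images or masks.

Binary metrics (Dice, Jaccard, target overlap) operate on {0,1} masks;
intensity metrics (mutual information, SSD, MSE, SSIM) operate on scalar
volumes.  Conventions: M is the moving/test image, T the target/reference;
Dice and Jaccard are symmetric, target overlap TO = |M∩T|/|T| is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .core_io import BinaryMask, VoxelGrid

__all__ = [
    "SimilarityReport",
    "binary_overlap_metrics",
    "intensity_similarity_metrics",
    "dice_coefficient",
]


@dataclass
class SimilarityReport:
    """Container for all seven similarity measures; unset fields are None.

    Invariants when set: ``jaccard <= dice``; ``dice = 2*jaccard/(1+jaccard)``;
    ``mse = ssd / n_voxels``.
    """

    dice: float | None = None
    jaccard: float | None = None
    total_overlap: float | None = None
    mutual_information: float | None = None
    ssd: float | None = None
    mse: float | None = None
    ssim: float | None = None
    degenerate: bool = False
    notes: str = ""

    def as_dict(self) -> dict:
        return {
            "dice": self.dice,
            "jaccard": self.jaccard,
            "total_overlap": self.total_overlap,
            "mutual_information": self.mutual_information,
            "ssd": self.ssd,
            "mse": self.mse,
            "ssim": self.ssim,
            "degenerate": self.degenerate,
            "notes": self.notes,
        }


def _bool_pair(M, T) -> tuple[np.ndarray, np.ndarray]:
    m = M.astype_bool() if isinstance(M, BinaryMask) else np.asarray(M, dtype=bool)
    t = T.astype_bool() if isinstance(T, BinaryMask) else np.asarray(T, dtype=bool)
    if m.shape != t.shape:
        raise ValueError(f"shape mismatch: {m.shape} vs {t.shape}")
    return m, t


def dice_coefficient(M, T) -> float:
    """DC = 2|M∩T| / (|M|+|T|); 0 when both masks are empty."""
    m, t = _bool_pair(M, T)
    denom = int(m.sum()) + int(t.sum())
    if denom == 0:
        return 0.0
    return 2.0 * int((m & t).sum()) / denom


def binary_overlap_metrics(M, T) -> SimilarityReport:
    """Dice, Jaccard and target overlap of two same-shape binary masks.

    DC = 2|M∩T|/(|M|+|T|), JI = |M∩T|/|M∪T|, TO = |M∩T|/|T| with T the
    reference.  Empty∩empty is reported as 0 with the degenerate flag; an
    empty T leaves TO as None (undefined), flagged.
    """
    m, t = _bool_pair(M, T)
    nm, nt = int(m.sum()), int(t.sum())
    inter = int((m & t).sum())
    union = int((m | t).sum())
    rep = SimilarityReport()
    if nm + nt == 0:
        rep.dice = 0.0
        rep.jaccard = 0.0
        rep.degenerate = True
        rep.notes = "both masks empty"
        return rep
    rep.dice = 2.0 * inter / (nm + nt)
    rep.jaccard = inter / union
    if nt == 0:
        rep.degenerate = True
        rep.notes = "empty target: total overlap undefined"
    else:
        rep.total_overlap = inter / nt
    return rep


def _mutual_information(m: np.ndarray, t: np.ndarray, bins: int = 64) -> float:
    """MI in bits from a joint histogram.

    Binary inputs use the exact 2×2 table; continuous inputs are min–max
    normalised and binned to ``bins`` levels.
    """

    def quantise(a: np.ndarray) -> np.ndarray:
        vals = np.unique(a)
        if len(vals) <= 2:
            return np.searchsorted(vals, a).ravel()
        lo, hi = a.min(), a.max()
        if hi == lo:
            return np.zeros(a.size, dtype=np.int64)
        q = ((a - lo) / (hi - lo) * bins).astype(np.int64)
        return np.clip(q, 0, bins - 1).ravel()

    qm, qt = quantise(m), quantise(t)
    joint = np.zeros((qm.max() + 1, qt.max() + 1))
    np.add.at(joint, (qm, qt), 1.0)
    p = joint / joint.sum()
    pm = p.sum(axis=1, keepdims=True)
    pt = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log2(p[nz] / (pm @ pt)[nz])).sum())


def intensity_similarity_metrics(
    M: VoxelGrid, T: VoxelGrid, mi_bins: int = 64, data_range: float | None = None
) -> SimilarityReport:
    """Mutual information (bits), SSD, MSE and SSIM between two volumes.

    SSIM follows the Wang et al. formulation (K1=0.01, K2=0.03, Gaussian
    window σ=1.5) computed on each z-slice and averaged; the dynamic range
    defaults to the dtype range of T.  MSE = SSD / N exactly.
    """
    m = np.asarray(M.data, dtype=np.float64)
    t = np.asarray(T.data, dtype=np.float64)
    if m.shape != t.shape:
        raise ValueError(f"shape mismatch: {m.shape} vs {t.shape}")
    rep = SimilarityReport()
    diff = m - t
    rep.ssd = float((diff**2).sum())
    rep.mse = rep.ssd / m.size
    rep.mutual_information = _mutual_information(m, t, bins=mi_bins)

    if data_range is None:
        lo, hi = T.dtype_range
        data_range = hi - lo
    if t.std() == 0 or m.std() == 0:
        rep.degenerate = True
        rep.notes = "zero-variance image: SSIM unreliable"
    # Gaussian window σ=1.5 implies an 11-pixel window; clamp for tiny slices
    win = min(11, m.shape[1] - (m.shape[1] + 1) % 2, m.shape[2] - (m.shape[2] + 1) % 2)
    if win < 3:
        rep.degenerate = True
        rep.notes = (rep.notes + "; " if rep.notes else "") + "slices too small for SSIM"
        return rep
    ssims = []
    for k in range(m.shape[0]):
        ssims.append(
            structural_similarity(
                m[k],
                t[k],
                gaussian_weights=True,
                sigma=1.5,
                use_sample_covariance=False,
                K1=0.01,
                K2=0.03,
                win_size=win,
                data_range=data_range,
            )
        )
    rep.ssim = float(np.mean(ssims))
    return rep
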