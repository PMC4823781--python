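"""Evaluation of predicted tracks against experimental data.

Pearson correlation on jointly valid positions, rank-based ROC/AUC for
nucleosome-forming vs nucleosome-inhibiting region classification, and
anchor-centred meta-profiles (TSS/TES/origin/hotspot style analyses).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata


@dataclass
class LabeledRegion:
    """A scored genomic interval with a forming/inhibiting class label."""

    sequence_id: str
    start: int
    end: int
    label: str  # "forming" | "inhibiting"
    score: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty region {self.start}..{self.end}")
        if self.label not in ("forming", "inhibiting"):
            raise ValueError(f"label must be forming/inhibiting, got {self.label!r}")


def pearson(track_a: np.ndarray, track_b: np.ndarray,
            mask: np.ndarray | None = None) -> float:
    """Sample Pearson r over jointly valid (finite, masked-in) positions."""
    a = np.asarray(track_a, dtype=float)
    b = np.asarray(track_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"track shapes differ: {a.shape} vs {b.shape}")
    ok = np.isfinite(a) & np.isfinite(b)
    if mask is not None:
        ok &= np.asarray(mask, dtype=bool)
    if ok.sum() < 3:
        raise ValueError(f"fewer than 3 jointly valid positions ({ok.sum()})")
    a, b = a[ok], b[ok]
    da, db = a - a.mean(), b - b.mean()
    va, vb = np.dot(da, da), np.dot(db, db)
    if va == 0 or vb == 0:
        raise ValueError("zero variance in one of the tracks; r undefined")
    return float(np.dot(da, db) / np.sqrt(va * vb))


def roc_auc(regions: Sequence[LabeledRegion]) -> float:
    """AUC for forming (positive) vs inhibiting (negative) region scores.

    Computed via the rank (Mann-Whitney) statistic; tied scores contribute
    one half.
    """
    scores = np.array([r.score for r in regions], dtype=float)
    pos = np.array([r.label == "forming" for r in regions])
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both forming and inhibiting regions are required")
    if not np.isfinite(scores).all():
        raise ValueError("non-finite region scores")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc)


def roc_curve_points(regions: Sequence[LabeledRegion]
                     ) -> tuple[np.ndarray, np.ndarray]:
    """(false positive rate, true positive rate) at every score threshold."""
    scores = np.array([r.score for r in regions], dtype=float)
    pos = np.array([r.label == "forming" for r in regions])
    order = np.argsort(-scores, kind="stable")
    tp = np.concatenate([[0], np.cumsum(pos[order])])
    fp = np.concatenate([[0], np.cumsum(~pos[order])])
    return fp / max(fp[-1], 1), tp / max(tp[-1], 1)


def score_regions(track: np.ndarray, regions, valid: np.ndarray | None = None,
                  sequence_id: str = "") -> list[LabeledRegion]:
    """Score (sequence_id, start, end, label) region rows by mean track value.

    Regions with no valid overlapping positions are dropped with a warning.
    """
    track = np.asarray(track, dtype=float)
    if valid is None:
        valid = np.isfinite(track)
    out: list[LabeledRegion] = []
    dropped = 0
    for seq_id, start, end, label in regions:
        lo, hi = max(0, int(start)), min(len(track), int(end))
        sel = valid[lo:hi]
        if lo >= hi or not sel.any():
            dropped += 1
            continue
        out.append(LabeledRegion(seq_id or sequence_id, int(start), int(end),
                                 label, float(track[lo:hi][sel].mean())))
    if dropped:
        warnings.warn(f"dropped {dropped} region(s) with no valid positions")
    return out


def meta_profile(track: np.ndarray, anchors, halfwidth: int,
                 valid: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Positionwise mean of the track aligned on anchor positions.

    Anchors closer than ``halfwidth`` to either end are trimmed; invalid
    positions are excluded column-wise.  Returns (offsets, mean, counts).
    """
    track = np.asarray(track, dtype=float)
    if valid is None:
        valid = np.isfinite(track)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(track)
    anchors = [int(a) for a in anchors
               if halfwidth <= int(a) < len(track) - halfwidth]
    if not anchors:
        raise ValueError("no anchors usable after trimming to track bounds")
    width = 2 * halfwidth + 1
    acc = np.zeros(width)
    counts = np.zeros(width, dtype=int)
    for a in anchors:
        seg = track[a - halfwidth : a + halfwidth + 1]
        ok = valid[a - halfwidth : a + halfwidth + 1]
        acc[ok] += seg[ok]
        counts += ok
    mean = np.where(counts > 0, acc / np.maximum(counts, 1), np.nan)
    offsets = np.arange(-halfwidth, halfwidth + 1)
    return offsets, mean, counts


def normalize01(track: np.ndarray) -> np.ndarray:
    """Affine rescale of the finite values to [0, 1]."""
    track = np.asarray(track, dtype=float)
    finite = track[np.isfinite(track)]
    if len(finite) == 0:
        raise ValueError("no finite values to normalize")
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        raise ValueError("constant track cannot be normalized to [0, 1]")
    return (track - lo) / (hi - lo)
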