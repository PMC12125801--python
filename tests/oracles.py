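"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive: explicit set arithmetic over pixel
coordinate tuples and all-pairs distance scans. None of it shares code with
msaunet.
"""

from __future__ import annotations

import numpy as np


def pixel_set(mask) -> set[tuple[int, int]]:
    return {(int(r), int(c)) for r, c in zip(*np.nonzero(np.asarray(mask)))}


def overlap_oracle(gt, pred):
    """(dsc, jsc, ppv, se) by explicit set arithmetic; None where undefined."""
    g = pixel_set(gt)
    p = pixel_set(pred)
    inter = len(g & p)
    union = len(g | p)
    dsc = 2 * inter / (len(g) + len(p)) if (len(g) + len(p)) else None
    jsc = inter / union if union else None
    ppv = inter / len(p) if len(p) else None
    se = inter / len(g) if len(g) else None
    return dsc, jsc, ppv, se


def boundary_set(mask) -> set[tuple[int, int]]:
    """Mask pixels with at least one 8-neighbor (or edge) outside the mask."""
    m = np.asarray(mask).astype(bool)
    h, w = m.shape
    out = set()
    for r, c in pixel_set(m):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if rr < 0 or rr >= h or cc < 0 or cc >= w or not m[rr, cc]:
                    out.add((r, c))
                    break
            else:
                continue
            break
    return out


def hausdorff_oracle(gt, pred, percentile: float = 100.0) -> float:
    """All-pairs symmetric Hausdorff distance over boundary pixels."""
    a = boundary_set(gt)
    b = boundary_set(pred)
    if not a or not b:
        raise ValueError("empty mask")

    pa = np.array(sorted(a), dtype=float)
    pb = np.array(sorted(b), dtype=float)
    # explicit all-pairs distance matrix
    dmat = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2))

    def directed(dists_min):
        if percentile >= 100.0:
            return float(dists_min.max())
        return float(np.percentile(dists_min, percentile))

    return max(directed(dmat.min(axis=1)), directed(dmat.min(axis=0)))


def volume_oracle(gt, pred):
    g = pixel_set(gt)
    p = pixel_set(pred)
    if not g:
        raise ValueError("empty gt")
    rvd = abs(len(p) - len(g)) / len(g)
    union = len(g | p)
    voe = 1 - len(g & p) / union if union else None
    return rvd, voe


def dice_loss_oracle(gt, pred, eps: float, symmetric: bool = False) -> float:
    gt = np.asarray(gt, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    inter = float(sum(a * b for a, b in zip(gt, pred)))
    if symmetric:
        return 1.0 - (2.0 * inter + eps) / (gt.sum() + pred.sum() + eps)
    return 1.0 - 2.0 * (inter + eps) / (gt.sum() + pred.sum() + eps)


def anova_oracle(groups):
    """F statistic via direct sums of squares (no library calls)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = len(allv) - len(groups)
    if ssw == 0 and ssb == 0:
        return 0.0, dfb, dfw
    return (ssb / dfb) / (ssw / dfw), dfb, dfw
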