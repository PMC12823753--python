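"""Independent brute-force oracles used to validate the metric battery.

These are deliberately naive O(n²) / per-pixel-loop implementations that
share no code with the package's metric paths.
"""

from __future__ import annotations

import numpy as np


def brute_confusion(pred: np.ndarray, ref: np.ndarray) -> tuple[int, int, int, int]:
    """Per-pixel loop tally of (tp, fp, fn, tn)."""
    tp = fp = fn = tn = 0
    H, W = ref.shape
    for i in range(H):
        for j in range(W):
            p, r = bool(pred[i, j]), bool(ref[i, j])
            if p and r:
                tp += 1
            elif p:
                fp += 1
            elif r:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def brute_boundary(mask: np.ndarray) -> np.ndarray:
    """4-neighbor boundary pixels; the frame edge counts as outside."""
    H, W = mask.shape
    coords = []
    for i in range(H):
        for j in range(W):
            if not mask[i, j]:
                continue
            on_edge = False
            for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ni, nj = i + di, j + dj
                if not (0 <= ni < H and 0 <= nj < W) or not mask[ni, nj]:
                    on_edge = True
                    break
            if on_edge:
                coords.append((i, j))
    return np.asarray(coords, dtype=np.int64).reshape(-1, 2)


def brute_directed_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """For each point of a, the min Euclidean distance to b (O(n²) pairwise)."""
    diffs = a[:, None, :].astype(float) - b[None, :, :].astype(float)
    return np.sqrt((diffs**2).sum(-1)).min(axis=1)


def brute_surface_distances(pred: np.ndarray, ref: np.ndarray):
    bp = brute_boundary(pred)
    br = brute_boundary(ref)
    return brute_directed_distances(bp, br), brute_directed_distances(br, bp)


def brute_boundary_band(mask: np.ndarray, width: int) -> np.ndarray:
    """Mask pixels within Euclidean distance `width` of the mask boundary."""
    boundary = brute_boundary(mask)
    band = np.zeros_like(mask, dtype=bool)
    for i, j in np.argwhere(mask):
        d = np.sqrt(((boundary - (i, j)) ** 2).sum(-1)).min()
        band[i, j] = d <= width
    return band


def brute_boundary_iou(pred: np.ndarray, ref: np.ndarray, width: int) -> float:
    bp = pred & brute_boundary_band(pred, width)
    br = ref & brute_boundary_band(ref, width)
    inter = np.count_nonzero(bp & br)
    union = np.count_nonzero(bp | br)
    return inter / union


def average_ranks(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with tied values receiving the mean of their positions."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        mean_rank = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return ranks


def brute_spearman_abs(x, y) -> float:
    """|Pearson correlation of average ranks| — tie-aware Spearman oracle."""
    rx = average_ranks(np.asarray(x))
    ry = average_ranks(np.asarray(y))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return abs(float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum())))


def spearman_untied_closed_form(x, y) -> float:
    """1 − 6Σd²/(n(n²−1)); valid only for tie-free data."""
    x = np.asarray(x)
    y = np.asarray(y)
    n = len(x)
    rx = average_ranks(x)
    ry = average_ranks(y)
    d2 = ((rx - ry) ** 2).sum()
    return 1 - 6 * d2 / (n * (n**2 - 1))


def random_blob_mask(rng: np.random.Generator, shape: tuple[int, int],
                     ensure_nonempty: bool = False) -> np.ndarray:
    """A random mask with spatial structure: union of a few random boxes."""
    H, W = shape
    while True:
        mask = np.zeros(shape, dtype=bool)
        for _ in range(int(rng.integers(0, 4))):
            h = int(rng.integers(1, max(2, H // 2)))
            w = int(rng.integers(1, max(2, W // 2)))
            i = int(rng.integers(0, H - h + 1))
            j = int(rng.integers(0, W - w + 1))
            mask[i : i + h, j : j + w] = True
        if mask.any() or not ensure_nonempty:
            return mask
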