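"""Independent brute-force reference implementations used only by tests.

These are deliberately naive (BFS flood fill, all-pairs distances,
pixel loops) so they share no code path with the package.
"""

from __future__ import annotations

import numpy as np


def bfs_components(binary: np.ndarray, connectivity: int = 8) -> list[set]:
    """Connected components of a boolean image by explicit BFS."""
    if connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    rows, cols = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    components = []
    for r in range(rows):
        for c in range(cols):
            if binary[r, c] and not seen[r, c]:
                comp, queue = set(), [(r, c)]
                seen[r, c] = True
                while queue:
                    cr, cc = queue.pop()
                    comp.add((cr, cc))
                    for dr, dc in nbrs:
                        nr, nc = cr + dr, cc + dc
                        if 0 <= nr < rows and 0 <= nc < cols and binary[nr, nc] \
                                and not seen[nr, nc]:
                            seen[nr, nc] = True
                            queue.append((nr, nc))
                components.append(comp)
    return components


def brute_filter(labels: np.ndarray, threshold_fraction: float = 0.6,
                 connectivity: int = 8) -> np.ndarray:
    """Size-relative component filter via BFS labelling."""
    out = labels.copy()
    for code in (1, 2, 3):
        comps = bfs_components(labels == code, connectivity)
        if not comps:
            continue
        largest = max(len(c) for c in comps)
        for comp in comps:
            if len(comp) < threshold_fraction * largest:
                for r, c in comp:
                    out[r, c] = 0
    return out


def brute_confusion(pred: np.ndarray, ref: np.ndarray, code: int) -> tuple[int, int, int]:
    tp = fp = fn = 0
    for p, g in zip(pred.ravel(), ref.ravel()):
        if p == code and g == code:
            tp += 1
        elif p == code:
            fp += 1
        elif g == code:
            fn += 1
    return tp, fp, fn


def brute_boundary(binary: np.ndarray) -> list[tuple[int, int]]:
    """Foreground pixels with a 4-neighbour outside the foreground (or the frame)."""
    rows, cols = binary.shape
    pts = []
    for r in range(rows):
        for c in range(cols):
            if not binary[r, c]:
                continue
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                nr, nc = r + dr, c + dc
                if not (0 <= nr < rows and 0 <= nc < cols) or not binary[nr, nc]:
                    pts.append((r, c))
                    break
    return pts


def brute_hausdorff(pred: np.ndarray, ref: np.ndarray, code: int,
                    spacing=(1.0, 1.0)) -> float:
    """All-pairs symmetric Hausdorff distance between boundary point sets."""
    p = np.array(brute_boundary(pred == code), dtype=float)
    g = np.array(brute_boundary(ref == code), dtype=float)
    if p.size == 0 and g.size == 0:
        return 0.0
    if p.size == 0 or g.size == 0:
        return float("nan")
    p *= np.asarray(spacing)
    g *= np.asarray(spacing)
    d = np.sqrt(((p[:, None, :] - g[None, :, :]) ** 2).sum(-1))
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def random_mask(rng: np.random.Generator, shape=(16, 16), p_fg: float = 0.35) -> np.ndarray:
    """Random multi-class mask with blobby structure (smoothed noise argmax)."""
    labels = np.zeros(shape, dtype=np.uint8)
    fg = rng.random(shape) < p_fg
    labels[fg] = rng.integers(1, 4, size=int(fg.sum()))
    return labels


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
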