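"""Brute-force reference implementations used only by the tests.

Each oracle recomputes a quantity by the most literal method available —
flood fill, pair enumeration, direct filter evaluation, exhaustive
active-set enumeration — sharing no code with the package paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def window_sum_3x3(channel: np.ndarray) -> np.ndarray:
    """3x3 window sum with edge-replicating borders, by explicit loops."""
    h, w = channel.shape
    padded = np.pad(channel.astype(np.int64), 1, mode="symmetric")
    out = np.empty((h, w), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            out[r, c] = padded[r : r + 3, c : c + 3].sum()
    return out


def quantize_colors(patch: np.ndarray, bins: int, blur: bool) -> np.ndarray:
    if blur:
        sums = np.stack([window_sum_3x3(patch[:, :, ch]) for ch in range(3)], axis=2)
        q = np.clip(sums * bins // (256 * 9), 0, bins - 1)
    else:
        q = np.clip(patch.astype(np.int64) * bins // 256, 0, bins - 1)
    return q[:, :, 0] * bins * bins + q[:, :, 1] * bins + q[:, :, 2]


def _components_8(binary: np.ndarray) -> list[int]:
    """Sizes of 8-connected components via BFS flood fill."""
    h, w = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    sizes = []
    for r0 in range(h):
        for c0 in range(w):
            if binary[r0, c0] and not seen[r0, c0]:
                stack = [(r0, c0)]
                seen[r0, c0] = True
                size = 0
                while stack:
                    r, c = stack.pop()
                    size += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and binary[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                sizes.append(size)
    return sizes


def ccv_oracle(patch: np.ndarray, bins: int, tau: int, blur: bool) -> np.ndarray:
    colors = quantize_colors(patch, bins, blur)
    out = np.zeros(2 * bins**3)
    for color in np.unique(colors):
        for size in _components_8(colors == color):
            if size >= tau:
                out[2 * color] += size
            else:
                out[2 * color + 1] += size
    return out


# skimage convention: offset = (round(d sin a), round(d cos a))
_ANGLE_OFFSETS = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}


def glcm_oracle(gray: np.ndarray, distance: int, angle_deg: int,
                levels: int) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix by explicit pair listing."""
    dr, dc = _ANGLE_OFFSETS[angle_deg]
    dr, dc = dr * distance, dc * distance
    h, w = gray.shape
    p = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                p[gray[r, c], gray[rr, cc]] += 1
                p[gray[rr, cc], gray[r, c]] += 1
    total = p.sum()
    return p / total if total > 0 else p


def glcm_stats_oracle(p: np.ndarray) -> dict[str, float]:
    levels = p.shape[0]
    contrast = energy = homogeneity = entropy = 0.0
    mi = mj = 0.0
    for i in range(levels):
        for j in range(levels):
            contrast += p[i, j] * (i - j) ** 2
            energy += p[i, j] ** 2
            homogeneity += p[i, j] / (1.0 + (i - j) ** 2)
            if p[i, j] > 0:
                entropy -= p[i, j] * np.log2(p[i, j])
            mi += i * p[i, j]
            mj += j * p[i, j]
    vi = sum((i - mi) ** 2 * p[i, j] for i in range(levels) for j in range(levels))
    vj = sum((j - mj) ** 2 * p[i, j] for i in range(levels) for j in range(levels))
    if vi <= 0 or vj <= 0:
        correlation = 0.0
    else:
        correlation = sum(
            (i - mi) * (j - mj) * p[i, j] for i in range(levels) for j in range(levels)
        ) / np.sqrt(vi * vj)
    return {"contrast": contrast, "correlation": correlation, "energy": energy,
            "homogeneity": homogeneity, "entropy": entropy}


_EHD_FILTERS = {
    0: np.array([[1.0, -1.0], [1.0, -1.0]]),
    1: np.array([[1.0, 1.0], [-1.0, -1.0]]),
    2: np.array([[np.sqrt(2), 0.0], [0.0, -np.sqrt(2)]]),
    3: np.array([[0.0, np.sqrt(2)], [-np.sqrt(2), 0.0]]),
    4: np.array([[2.0, -2.0], [-2.0, 2.0]]),
}


def ehd_oracle(lum: np.ndarray, grid: int, threshold: float) -> np.ndarray:
    size = lum.shape[0] // grid
    nb = size // 2
    hist = np.zeros((grid * grid, 5))
    for si in range(grid):
        for sj in range(grid):
            for bi in range(nb):
                for bj in range(nb):
                    r = si * size + 2 * bi
                    c = sj * size + 2 * bj
                    block = lum[r : r + 2, c : c + 2]
                    responses = [abs((f * block).sum()) for f in _EHD_FILTERS.values()]
                    k = int(np.argmax(responses))
                    if responses[k] >= threshold:
                        hist[si * grid + sj, k] += 1
    return (hist / (nb * nb)).ravel()


def brute_box_qp(q: np.ndarray, ub: float) -> np.ndarray:
    """Exact box-QP minimizer by enumerating every active-set pattern.

    Feasible only for ~12 variables; each coordinate is at 0, at ub, or
    free with zero gradient; candidates failing primal or dual feasibility
    are discarded and the best remaining objective wins.
    """
    m = q.shape[0]
    e = np.ones(m)
    best = None
    for states in itertools.product((0, 1, 2), repeat=m):
        states = np.array(states)
        a = np.zeros(m)
        a[states == 1] = ub
        free = states == 2
        if free.any():
            try:
                a[free] = np.linalg.solve(
                    q[np.ix_(free, free)],
                    e[free] - q[np.ix_(free, ~free)] @ a[~free],
                )
            except np.linalg.LinAlgError:
                continue
            if (a[free] < -1e-9).any() or (a[free] > ub + 1e-9).any():
                continue
        grad = q @ a - e
        if (grad[states == 0] < -1e-6).any() or (grad[states == 1] > 1e-6).any():
            continue
        value = 0.5 * a @ q @ a - a.sum()
        if best is None or value < best[0]:
            best = (value, a.copy())
    assert best is not None, "enumeration found no KKT point"
    return best[1]


def flood_count(mask: np.ndarray, connectivity: int = 8) -> int:
    """Connected-component count by BFS flood fill."""
    if connectivity == 8:
        neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    count = 0
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                count += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr, dc in neigh:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
    return count
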