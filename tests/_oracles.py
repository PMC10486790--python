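"""Brute-force reference implementations used only by the test suite.

Every function here recomputes a pipeline primitive with plain per-pixel
loops (or a different linear-algebra route), independent of the vectorized
package code, so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np

ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def mean_filter_bruteforce(pixels: np.ndarray, k: int) -> np.ndarray:
    """Per-pixel double loop mean over the k x k reflect-padded window."""
    before = (k - 1) // 2
    after = k - 1 - before
    padded = np.pad(pixels, ((before, after), (before, after)), mode="symmetric")
    H, W = pixels.shape
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            acc = 0.0
            for di in range(k):
                for dj in range(k):
                    acc += padded[i + di, j + dj]
            out[i, j] = acc / (k * k)
    return out


def laplacian_bruteforce(pixels: np.ndarray) -> np.ndarray:
    padded = np.pad(pixels, 1, mode="symmetric")
    H, W = pixels.shape
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            ci, cj = i + 1, j + 1
            out[i, j] = (padded[ci - 1, cj] + padded[ci + 1, cj]
                         + padded[ci, cj - 1] + padded[ci, cj + 1]
                         - 4.0 * padded[ci, cj])
    return out


def glcm_matrix_bruteforce(q: np.ndarray, levels: int, distance: int,
                           angle: int) -> np.ndarray:
    """Enumerate every pixel pair for one offset; symmetric, normalized."""
    dr, dc = ANGLE_OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    H, W = q.shape
    P = np.zeros((levels, levels))
    for i in range(H):
        for j in range(W):
            i2, j2 = i + dr, j + dc
            if 0 <= i2 < H and 0 <= j2 < W:
                P[q[i, j], q[i2, j2]] += 1.0
                P[q[i2, j2], q[i, j]] += 1.0  # symmetric counterpart
    total = P.sum()
    return P / total if total > 0 else P


def haralick_bruteforce(P: np.ndarray) -> np.ndarray:
    """The 13 Haralick statistics via scalar loops."""
    L = P.shape[0]
    px = [sum(P[i, j] for j in range(L)) for i in range(L)]
    py = [sum(P[i, j] for i in range(L)) for j in range(L)]
    mu_x = sum(i * px[i] for i in range(L))
    mu_y = sum(j * py[j] for j in range(L))
    sd_x = np.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(L)))
    sd_y = np.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(L)))

    p_sum = [0.0] * (2 * L - 1)
    p_diff = [0.0] * L
    for i in range(L):
        for j in range(L):
            p_sum[i + j] += P[i, j]
            p_diff[abs(i - j)] += P[i, j]

    def ent(values):
        return -sum(v * np.log(v) for v in values if v > 0)

    asm = sum(P[i, j] ** 2 for i in range(L) for j in range(L))
    contrast = sum(d * d * p_diff[d] for d in range(L))
    if sd_x > 0 and sd_y > 0:
        correlation = (sum(i * j * P[i, j] for i in range(L) for j in range(L))
                       - mu_x * mu_y) / (sd_x * sd_y)
    else:
        correlation = 0.0
    variance = sum((i - mu_x) ** 2 * P[i, j] for i in range(L) for j in range(L))
    idm = sum(P[i, j] / (1.0 + (i - j) ** 2) for i in range(L) for j in range(L))
    sum_average = sum(k * p_sum[k] for k in range(2 * L - 1))
    sum_variance = sum((k - sum_average) ** 2 * p_sum[k] for k in range(2 * L - 1))
    sum_entropy = ent(p_sum)
    entropy = ent(P.ravel())
    diff_avg = sum(d * p_diff[d] for d in range(L))
    difference_variance = sum((d - diff_avg) ** 2 * p_diff[d] for d in range(L))
    difference_entropy = ent(p_diff)

    hx, hy = ent(px), ent(py)
    hxy1 = -sum(P[i, j] * np.log(px[i] * py[j])
                for i in range(L) for j in range(L) if px[i] * py[j] > 0)
    hxy2 = -sum(px[i] * py[j] * np.log(px[i] * py[j])
                for i in range(L) for j in range(L) if px[i] * py[j] > 0)
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy))))

    return np.array([asm, contrast, correlation, variance, idm, sum_average,
                     sum_variance, sum_entropy, entropy, difference_variance,
                     difference_entropy, imc1, imc2])


def lbp_codes_bruteforce(pixels: np.ndarray, n_points: int, radius: float
                         ) -> np.ndarray:
    """Per-pixel LBP labels: explicit neighbor sampling and run-labeling."""
    H, W = pixels.shape
    pad = int(np.ceil(radius)) + 1
    padded = np.pad(pixels, pad, mode="symmetric")
    labels = np.zeros((H, W), dtype=int)
    non_uniform = n_points * (n_points - 1) + 2
    for i in range(H):
        for j in range(W):
            bits = []
            for k in range(n_points):
                angle = 2.0 * np.pi * k / n_points
                dr = -radius * np.sin(angle)
                dc = radius * np.cos(angle)
                rr, cc = i + pad + dr, j + pad + dc
                r0, c0 = int(np.floor(rr)), int(np.floor(cc))
                fr, fc = rr - r0, cc - c0
                val = ((1 - fr) * (1 - fc) * padded[r0, c0]
                       + (1 - fr) * fc * padded[r0, c0 + 1]
                       + fr * (1 - fc) * padded[r0 + 1, c0]
                       + fr * fc * padded[r0 + 1, c0 + 1])
                bits.append(1 if val >= pixels[i, j] else 0)
            transitions = sum(bits[k] != bits[k - 1] for k in range(n_points))
            ones = sum(bits)
            if transitions > 2:
                labels[i, j] = non_uniform
            elif ones == 0:
                labels[i, j] = 0
            elif ones == n_points:
                labels[i, j] = non_uniform - 1
            else:
                start = next(k for k in range(n_points)
                             if bits[k] == 1 and bits[k - 1] == 0)
                labels[i, j] = 1 + (ones - 1) * n_points + start
    return labels


def pool_bruteforce(pixels: np.ndarray, window: int, stride: int,
                    mode: str) -> np.ndarray:
    H, W = pixels.shape
    oh = (H - window) // stride + 1
    ow = (W - window) // stride + 1
    out = np.zeros((oh, ow))
    for i in range(oh):
        for j in range(ow):
            block = [pixels[i * stride + m, j * stride + n]
                     for m in range(window) for n in range(window)]
            out[i, j] = (sum(block) / len(block)) if mode == "average" \
                else max(block)
    return out


def conv2d_bruteforce(pixels: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Zero-padded 'same' cross-correlation via explicit loops (odd kernel)."""
    k = weights.shape[0]
    half = k // 2
    H, W = pixels.shape
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            acc = 0.0
            for di in range(k):
                for dj in range(k):
                    ii, jj = i + di - half, j + dj - half
                    if 0 <= ii < H and 0 <= jj < W:
                        acc += weights[di, dj] * pixels[ii, jj]
            out[i, j] = acc
    return out


def pca_eigh_bruteforce(X: np.ndarray, k: int):
    """PCA by explicit covariance eigendecomposition (independent route)."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:k]
    return vals[order], vecs[:, order].T
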