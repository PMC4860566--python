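"""Independent brute-force oracles used by the test suite.

Everything here is written as plain loops / exhaustive enumeration, kept
deliberately independent of the package's vectorized implementations.
"""

import numpy as np

from ezdetect import features as F


def bilateral_direct(img, sigma_s, sigma_r):
    """Double-loop bilateral filter over the whole slice (no approximation)."""
    img = np.asarray(img, dtype=float)
    out = np.empty_like(img)
    nx, nz = img.shape
    for i in range(nx):
        for k in range(nz):
            num = den = 0.0
            for i2 in range(nx):
                for k2 in range(nz):
                    w = np.exp(
                        -((i - i2) ** 2 + (k - k2) ** 2) / (2 * sigma_s**2)
                    ) * np.exp(-((img[i, k] - img[i2, k2]) ** 2) / (2 * sigma_r**2))
                    num += w * img[i2, k2]
                    den += w
            out[i, k] = num / den
    return out


def block_stats_direct(arr, centre, radius=2):
    """Triple-loop block mean / population std with edge cropping."""
    vals = []
    for i in range(max(0, centre[0] - radius), min(arr.shape[0], centre[0] + radius + 1)):
        for j in range(max(0, centre[1] - radius), min(arr.shape[1], centre[1] + radius + 1)):
            for k in range(max(0, centre[2] - radius), min(arr.shape[2], centre[2] + radius + 1)):
                vals.append(arr[i, j, k])
    vals = np.array(vals)
    return vals.mean(), vals.std()


def glcm_direct(block, direction, n_levels):
    """Pair-enumeration GLCM, symmetric accumulation, normalized."""
    block = np.asarray(block)
    counts = np.zeros((n_levels, n_levels))
    shape = block.shape
    for idx in np.ndindex(shape):
        q = tuple(np.add(idx, direction))
        if all(0 <= qi < ni for qi, ni in zip(q, shape)):
            counts[block[idx], block[q]] += 1
            counts[block[q], block[idx]] += 1
    s = counts.sum()
    return counts / s if s else counts


def glcm_props_direct(p):
    """Loop-based Haralick properties of a normalized GLCM."""
    n = p.shape[0]
    if p.sum() == 0:
        return 0.0, 0.0, 1.0, 1.0
    contrast = homog = energy = 0.0
    mx = my = 0.0
    for x in range(n):
        for y in range(n):
            contrast += p[x, y] * (x - y) ** 2
            homog += p[x, y] / (1 + abs(x - y))
            energy += p[x, y] ** 2
            mx += x * p[x, y]
            my += y * p[x, y]
    vx = vy = cov = 0.0
    for x in range(n):
        for y in range(n):
            vx += (x - mx) ** 2 * p[x, y]
            vy += (y - my) ** 2 * p[x, y]
            cov += (x - mx) * (y - my) * p[x, y]
    sd = np.sqrt(vx * vy)
    corr = cov / sd if sd > 0 else 0.0
    return contrast, corr, energy, homog


def feature_row_direct(I, voi_mask, centre, n_levels=8):
    """Full 57-feature vector of one voxel, composed from per-feature oracles."""
    voi_vals = I[voi_mask]
    lo, hi = voi_vals.min(), voi_vals.max()
    norm = (I - lo) / (hi - lo) if hi > lo else np.zeros_like(I)
    row = [norm[centre]]
    row.extend(block_stats_direct(norm, centre))
    for step in (1, 2):
        total = 0.0
        for d in F.direction_offsets():
            nb = tuple(
                min(max(c + step * dd, 0), n - 1)
                for c, dd, n in zip(centre, d, I.shape)
            )
            total += abs(norm[centre] - norm[nb])
        row.append(total / 13)
    q = np.minimum((np.clip(norm, 0, 1) * n_levels).astype(int), n_levels - 1)
    sl = tuple(
        slice(max(0, c - 2), min(n, c + 3)) for c, n in zip(centre, I.shape)
    )
    block = q[sl]
    props = [glcm_props_direct(glcm_direct(block, d, n_levels))
             for d in F.direction_offsets()]
    for k in range(4):
        row.extend(pr[k] for pr in props)
    return np.array(row)


def dp_path_direct(cost, lo, hi, bound):
    """Exhaustive max-sum column path search (tiny inputs only)."""
    nx, nz = cost.shape
    best = -np.inf

    def rec(x, z, total):
        nonlocal best
        if x == nx:
            best = max(best, total)
            return
        for znew in range(max(lo[x], z - bound), min(hi[x], z + bound) + 1):
            rec(x + 1, znew, total + cost[x, znew])

    for z0 in range(lo[0], hi[0] + 1):
        rec(1, z0, cost[0, z0])
    return best
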