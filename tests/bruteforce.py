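"""Independent brute-force landmark oracle.

Re-implements the landmark definitions with plain Python loops — exhaustive
enumeration over boundary pixels for a, b, c and a step-by-step discretized
walk (manual bilinear interpolation) for the opposite-border points.  Kept
deliberately free of the vectorised production code paths so agreement is a
genuine cross-check.
"""

from __future__ import annotations

import numpy as np

STEP_PX = 0.1


def boundary_pixels(mask: np.ndarray) -> list[tuple[int, int]]:
    """Foreground pixels with a 4-neighbour background (or image edge)."""
    ny, nz = mask.shape
    out = []
    for j in range(ny):  # C order == raveled-index order
        for k in range(nz):
            if not mask[j, k]:
                continue
            for dj, dk in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                jj, kk = j + dj, k + dk
                if not (0 <= jj < ny and 0 <= kk < nz) or not mask[jj, kk]:
                    out.append((j, k))
                    break
    return out


def bilinear(mask: np.ndarray, pj: float, pk: float) -> float:
    ny, nz = mask.shape
    j0, k0 = int(np.floor(pj)), int(np.floor(pk))
    total = 0.0
    for dj in (0, 1):
        for dk in (0, 1):
            w = (1 - abs(pj - (j0 + dj))) * (1 - abs(pk - (k0 + dk)))
            if w <= 0:
                continue
            j, k = j0 + dj, k0 + dk
            val = float(mask[j, k]) if 0 <= j < ny and 0 <= k < nz else 0.0
            total += w * val
    return total


def walk(mask, start_mm, direction, spacing, origin):
    u = np.asarray(direction, float)
    u = u / np.linalg.norm(u)
    step = STEP_PX * min(spacing)
    diag = float(np.hypot(mask.shape[0] * spacing[0], mask.shape[1] * spacing[1]))

    def occ(t):
        p = start_mm + t * u
        return bilinear(mask, (p[0] - origin[0]) / spacing[0], (p[1] - origin[1]) / spacing[1])

    t_prev, t = 0.0, step
    while t <= diag + 2 * step:
        if occ(t) < 0.5:
            lo, hi = t_prev, t
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                if occ(mid) >= 0.5:
                    lo = mid
                else:
                    hi = mid
            return start_mm + 0.5 * (lo + hi) * u
        t_prev, t = t, t + step
    raise RuntimeError("walk never left the mask")


def landmarks_bruteforce(mask: np.ndarray, spacing, origin=(0.0, 0.0)) -> dict[str, np.ndarray]:
    """All six landmarks by exhaustive search + discretized walks, world mm."""
    spacing = np.asarray(spacing, float)
    origin = np.asarray(origin, float)
    bpix = boundary_pixels(mask)
    pts = [origin + np.array(p) * spacing for p in bpix]

    a = None
    for p in pts:  # lexicographic max (y, z); first occurrence = min index
        if a is None or p[0] > a[0] or (p[0] == a[0] and p[1] > a[1]):
            a = p
    b = None
    for p in pts:
        if b is None or p[0] < b[0] or (p[0] == b[0] and p[1] > b[1]):
            b = p

    d = b - a
    n_vec = np.array([-d[1], d[0]])
    if n_vec[1] < 0 or (n_vec[1] == 0 and n_vec[0] < 0):
        n_vec = -n_vec
    n_hat = n_vec / np.linalg.norm(n_vec)
    c, best = None, 1e-9
    for p in pts:
        sd = float((p - a) @ n_hat)
        if sd > best:
            c, best = p, sd
    if c is None:
        raise RuntimeError("no superior boundary point")

    maskf = mask.astype(float)
    return {
        "a": a,
        "b": b,
        "c": c,
        "a_prime": walk(maskf, a, d, spacing, origin),
        "b_prime": walk(maskf, b, -d, spacing, origin),
        "c_prime": walk(maskf, c, -n_hat, spacing, origin),
    }


def random_arch_mask(rng: np.random.Generator, size: int = 64) -> np.ndarray:
    """Random connected arch-like blob fitting a ≤64×64 grid, ≥10 px.

    A half-annulus with randomised radii, centre offset and in-plane tilt,
    voxelised at unit spacing with a guaranteed background border.
    """
    from scipy import ndimage

    while True:
        R = rng.uniform(12, size / 2 - 4)
        t = rng.uniform(3, max(3.5, R / 2))
        phi = rng.uniform(-0.4, 0.4)
        cy = size / 2 + rng.uniform(-3, 3)
        cz = size / 2 - R / 2 + rng.uniform(-2, 2)
        jj, kk = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
        y, z = jj - cy, kk - cz
        yr = np.cos(phi) * y + np.sin(phi) * z
        zr = -np.sin(phi) * y + np.cos(phi) * z
        rho = np.hypot(yr, zr)
        mask = (rho <= R) & (rho >= R - t) & (zr >= 0)
        mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = False
        lab, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
        if n != 1 or mask.sum() < 10:
            continue
        return mask
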