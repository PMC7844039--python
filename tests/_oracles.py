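"""Independent brute-force implementations of the texture parameters.

Everything here is written with naive loops, explicit sorts and direct
integration, deliberately sharing no code with the package, so that
agreement on small grids is evidence of correctness rather than tautology.
Only used on tiny surfaces (8x8, 16x16).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage


def height_params(z: np.ndarray) -> dict:
    n = z.size
    total = 0.0
    for v in z.ravel():
        total += v
    mean = total / n
    zc = z - mean
    s2 = s3 = s4 = sabs = 0.0
    zmax = -math.inf
    zmin = math.inf
    for v in zc.ravel():
        s2 += v * v
        s3 += v ** 3
        s4 += v ** 4
        sabs += abs(v)
        zmax = max(zmax, v)
        zmin = min(zmin, v)
    sq = math.sqrt(s2 / n)
    return {
        "Sq": sq,
        "Sa": sabs / n,
        "Ssk": (s3 / n) / sq ** 3 if sq > 0 else float("nan"),
        "Sku": (s4 / n) / sq ** 4 if sq > 0 else float("nan"),
        "Sp": zmax,
        "Sv": -zmin,
        "Sz": zmax - zmin,
    }


def material_curve(z: np.ndarray, n_points: int = 2001):
    """c(p) by explicit order statistics and linear interpolation."""
    zs = sorted(z.ravel(), reverse=True)  # descending: material from the top
    n = len(zs)
    p = [100.0 * i / (n_points - 1) for i in range(n_points)]
    c = []
    for pi in p:
        # position in the descending order statistics, 0..n-1
        t = pi / 100.0 * (n - 1)
        lo = int(math.floor(t))
        hi = min(lo + 1, n - 1)
        frac = t - lo
        c.append(zs[lo] * (1 - frac) + zs[hi] * frac)
    return np.array(p), np.array(c)


def _trapz(y, x) -> float:
    total = 0.0
    for i in range(1, len(x)):
        total += 0.5 * (y[i] + y[i - 1]) * (x[i] - x[i - 1])
    return total


def volume_params(z: np.ndarray, p: float = 10.0, q: float = 80.0) -> dict:
    pg, c = material_curve(z)

    def c_at(r):
        return float(np.interp(r, pg, c))

    def vm(r):
        cr = c_at(r)
        xs = [u for u in pg if u <= r] + [r]
        ys = [c[i] - cr for i, u in enumerate(pg) if u <= r] + [0.0]
        return _trapz(ys, xs) / 100.0

    def vv(r):
        cr = c_at(r)
        xs = [r] + [u for u in pg if u >= r]
        ys = [0.0] + [cr - c[i] for i, u in enumerate(pg) if u >= r]
        return _trapz(ys, xs) / 100.0

    return {"Vmp": vm(p), "Vmc": vm(q) - vm(p),
            "Vvc": vv(p) - vv(q), "Vvv": vv(q)}


def core_params(z: np.ndarray, width: float = 40.0) -> dict:
    pg, c = material_curve(z)
    dp = pg[1] - pg[0]
    w = int(round(width / dp))
    best_i, best_drop = 0, math.inf
    for i in range(len(c) - w):
        drop = c[i] - c[i + w]
        if drop < best_drop - 1e-15:
            best_drop = drop
            best_i = i
    slope = -best_drop / width
    z1 = c[best_i] + slope * (0.0 - pg[best_i])
    z2 = c[best_i] + slope * (100.0 - pg[best_i])
    sk = z1 - z2
    smr1 = 0.0 if c[0] <= z1 else None
    if smr1 is None:
        for i in range(1, len(c)):
            if c[i] <= z1:
                f = (c[i - 1] - z1) / (c[i - 1] - c[i])
                smr1 = pg[i - 1] + f * dp
                break
    smr2 = 100.0 if c[-1] >= z2 else None
    if smr2 is None:
        for i in range(len(c) - 2, -1, -1):
            if c[i] >= z2:
                f = (c[i] - z2) / (c[i] - c[i + 1])
                smr2 = pg[i] + f * dp
                break
    if smr1 <= 0:
        spk = 0.0
    else:
        xs = [u for u in pg if u <= smr1] + [smr1]
        ys = [c[i] - z1 for i, u in enumerate(pg) if u <= smr1] + [0.0]
        spk = 2.0 * (_trapz(ys, xs) / 100.0) / (smr1 / 100.0)
    if smr2 >= 100:
        svk = 0.0
    else:
        xs = [smr2] + [u for u in pg if u >= smr2]
        ys = [0.0] + [z2 - c[i] for i, u in enumerate(pg) if u >= smr2]
        svk = 2.0 * (_trapz(ys, xs) / 100.0) / ((100.0 - smr2) / 100.0)
    return {"Sk": sk, "Spk": spk, "Svk": svk, "Smr1": smr1, "Smr2": smr2}


def hybrid_params(z: np.ndarray, dx: float, dy: float) -> dict:
    ny, nx = z.shape
    g2sum = 0.0
    area_sum = 0.0
    for r in range(ny):
        for c in range(nx):
            if c == 0:
                zx = (z[r, 1] - z[r, 0]) / dx
            elif c == nx - 1:
                zx = (z[r, -1] - z[r, -2]) / dx
            else:
                zx = (z[r, c + 1] - z[r, c - 1]) / (2 * dx)
            if r == 0:
                zy = (z[1, c] - z[0, c]) / dy
            elif r == ny - 1:
                zy = (z[-1, c] - z[-2, c]) / dy
            else:
                zy = (z[r + 1, c] - z[r - 1, c]) / (2 * dy)
            g2 = zx * zx + zy * zy
            g2sum += g2
            area_sum += math.sqrt(1.0 + g2) - 1.0
    n = nx * ny
    return {"Sdq": math.sqrt(g2sum / n), "Sdr": 100.0 * area_sum / n}


def spatial_params(z: np.ndarray, dx: float, dy: float,
                   s: float = 0.2, n_directions: int = 360) -> dict:
    """Direct O(N^2) circular ACF plus a manual bilinear ray march."""
    ny, nx = z.shape
    zc = z - z.mean()
    acf = np.zeros((ny, nx))
    for dr in range(ny):
        for dc in range(nx):
            total = 0.0
            for r in range(ny):
                for c in range(nx):
                    total += zc[r, c] * zc[(r + dr) % ny, (c + dc) % nx]
            acf[dr, dc] = total
    acf /= acf[0, 0]
    R = np.fft.fftshift(acf)
    cy, cx = ny // 2, nx // 2

    def bilinear(yy, xx):
        y0, x0 = int(math.floor(yy)), int(math.floor(xx))
        y0 = min(max(y0, 0), ny - 2)
        x0 = min(max(x0, 0), nx - 2)
        fy, fx = yy - y0, xx - x0
        fy = min(max(fy, 0.0), 1.0)
        fx = min(max(fx, 0.0), 1.0)
        return ((1 - fy) * (1 - fx) * R[y0, x0]
                + (1 - fy) * fx * R[y0, x0 + 1]
                + fy * (1 - fx) * R[y0 + 1, x0]
                + fy * fx * R[y0 + 1, x0 + 1])

    r_max = min(cx * dx, cy * dy)
    step = 0.5 * min(dx, dy)
    crossings = []
    capped = []
    for j in range(n_directions):
        theta = 2.0 * math.pi * j / n_directions
        prev_r, prev_v = 0.0, bilinear(cy, cx)
        hit = None
        r = step
        while r <= r_max + 1e-12:
            v = bilinear(cy + r * math.sin(theta) / dy,
                         cx + r * math.cos(theta) / dx)
            if v <= s:
                hit = prev_r + (prev_v - s) / (prev_v - v) * (r - prev_r)
                break
            prev_r, prev_v = r, v
            r += step
        if hit is None:
            capped.append(r_max)
        else:
            crossings.append(hit)
    if not crossings:
        return {"Sal": float("nan"), "Str": float("nan")}
    sal = min(crossings)
    return {"Sal": sal, "Str": sal / max(crossings + capped)}


def _prominence_bruteforce(z: np.ndarray, peak: tuple) -> float:
    """Prominence by flood-fill over descending water levels."""
    h_peak = z[peak]
    levels = sorted(np.unique(z.ravel()), reverse=True)
    for level in levels:
        if level > h_peak:
            continue
        mask = z >= level
        labels, _ = ndimage.label(mask, structure=np.ones((3, 3)))
        comp = labels == labels[peak]
        if np.any(z[comp] > h_peak):
            return float(h_peak - level)
    return float(h_peak - z.min())


def feature_params(z: np.ndarray, dx: float, dy: float,
                   pruning_pct: float = 5.0) -> dict:
    ny, nx = z.shape
    sz = float(z.max() - z.min())
    threshold = pruning_pct / 100.0 * sz

    def summits_of(surface):
        out = []
        for r in range(1, ny - 1):
            for c in range(1, nx - 1):
                v = surface[r, c]
                if all(v > surface[r + dr, c + dc]
                       for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                       if (dr, dc) != (0, 0)):
                    prom = _prominence_bruteforce(surface, (r, c))
                    if prom >= threshold and prom > 0:
                        out.append((r, c))
        return out

    summits = summits_of(z)
    dales = summits_of(-z)
    area = nx * dx * ny * dy
    if summits:
        curv = []
        for r, c in summits:
            zxx = (z[r, c + 1] - 2 * z[r, c] + z[r, c - 1]) / dx ** 2
            zyy = (z[r + 1, c] - 2 * z[r, c] + z[r - 1, c]) / dy ** 2
            curv.append(-(zxx + zyy) / 2.0)
        ssc = float(np.mean(curv))
    else:
        ssc = float("nan")
    peaks = sorted((z[r, c] for r, c in summits), reverse=True)
    valleys = sorted((-z[r, c] for r, c in dales), reverse=True)
    top = float(np.mean(peaks[:5])) if peaks else 0.0
    bot = float(np.mean(valleys[:5])) if valleys else 0.0
    return {"Sds": len(summits) / area, "Ssc": ssc, "S5z": top + bot}


def spearman_rho_midranks(x, y) -> float:
    """Spearman rho via explicit midranks and Pearson on the ranks."""
    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx)
                    * sum((b - my) ** 2 for b in ry))
    return num / den
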