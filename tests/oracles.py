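"""Independent brute-force oracles for the texture features.

Deliberately naive implementations (explicit loops, no shared code with
the package) used to verify the vectorized feature extractors.
"""

import math

import numpy as np

HU_WINDOW = (-1024.0, 200.0)


def quantize(values, n_levels):
    lo, hi = HU_WINDOW
    out = []
    for v in np.asarray(values, dtype=float).ravel():
        q = int((v - lo) / (hi - lo) * n_levels)
        out.append(min(max(q, 0), n_levels - 1))
    return np.asarray(out).reshape(np.asarray(values).shape)


def first_order(block, n_levels):
    x = [float(v) for v in np.asarray(block).ravel()]
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    if var > 0:
        sd = math.sqrt(var)
        skew = sum(((v - mean) / sd) ** 3 for v in x) / n
        kurt = sum(((v - mean) / sd) ** 4 for v in x) / n
    else:
        skew = kurt = 0.0
    counts = {}
    for q in quantize(x, n_levels).ravel():
        counts[int(q)] = counts.get(int(q), 0) + 1
    ent = 0.0
    for c in counts.values():
        p = c / n
        ent -= p * math.log2(p)
    return np.array([mean, var, skew, kurt, ent])


def glcm_matrix(levels, n_levels, offsets):
    g = np.asarray(levels)
    m = np.zeros((n_levels, n_levels))
    nx, ny, nz = g.shape
    for dx, dy, dz in offsets:
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    X, Y, Z = x + dx, y + dy, z + dz
                    if 0 <= X < nx and 0 <= Y < ny and 0 <= Z < nz:
                        a, b = int(g[x, y, z]), int(g[X, Y, Z])
                        m[a, b] += 1
                        m[b, a] += 1
    if m.sum() > 0:
        m = m / m.sum()
    return m


def glcm_features(block, n_levels, offsets):
    p = glcm_matrix(quantize(block, n_levels), n_levels, offsets)
    asm = ent = inertia = contrast = idm = 0.0
    mu = 0.0
    px = p.sum(axis=1)
    for i in range(n_levels):
        mu += i * px[i]
    sig2 = 0.0
    for i in range(n_levels):
        sig2 += (i - mu) ** 2 * px[i]
    cross = 0.0
    for i in range(n_levels):
        for j in range(n_levels):
            v = p[i, j]
            asm += v * v
            if v > 0:
                ent -= v * math.log2(v)
            inertia += (i - j) ** 2 * v
            contrast += abs(i - j) * v
            idm += v / (1 + (i - j) ** 2)
            cross += i * j * v
    corr = (cross - mu * mu) / sig2 if sig2 > 1e-12 else 0.0
    return np.array([asm, ent, inertia, contrast, corr, idm])


def rlm_features(block, n_levels, directions):
    g = quantize(block, n_levels)
    nx, ny, nz = g.shape
    runs = []  # (level, length)
    for d in directions:
        dx, dy, dz = d
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    px, py, pz = x - dx, y - dy, z - dz
                    if 0 <= px < nx and 0 <= py < ny and 0 <= pz < nz:
                        continue  # not a line start
                    cx, cy, cz = x, y, z
                    line = []
                    while 0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz:
                        line.append(int(g[cx, cy, cz]))
                        cx, cy, cz = cx + dx, cy + dy, cz + dz
                    i = 0
                    while i < len(line):
                        j = i
                        while j < len(line) and line[j] == line[i]:
                            j += 1
                        runs.append((line[i], j - i))
                        i = j
    n_runs = len(runs)
    sre = sum(1.0 / (l * l) for _, l in runs) / n_runs
    lre = sum(float(l * l) for _, l in runs) / n_runs
    by_level = {}
    by_len = {}
    n_samples = 0
    for g_, l in runs:
        by_level[g_] = by_level.get(g_, 0) + 1
        by_len[l] = by_len.get(l, 0) + 1
        n_samples += l
    gln = sum(c * c for c in by_level.values()) / n_runs
    rln = sum(c * c for c in by_len.values()) / n_runs
    rp = n_runs / n_samples
    return np.array([sre, lre, gln, rln, rp])


def box_counting_dimension(edge_map, box_edges=(1, 2, 4, 8)):
    e = np.asarray(edge_map).astype(bool)
    if not e.any():
        return 0.0
    pts = []
    for s in box_edges:
        boxes = set()
        for x, y, z in np.argwhere(e):
            boxes.add((x // s, y // s, z // s))
        pts.append((math.log(1.0 / s), math.log(max(len(boxes), 1))))
    xb = sum(p[0] for p in pts) / len(pts)
    yb = sum(p[1] for p in pts) / len(pts)
    sxx = sum((p[0] - xb) ** 2 for p in pts)
    sxy = sum((p[0] - xb) * (p[1] - yb) for p in pts)
    return sxy / sxx
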