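"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import numpy as np


def union_find_components(d: np.ndarray, cutoff: float) -> np.ndarray:
    """Connected components of the strict-threshold graph via union-find."""
    n = d.shape[0]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] < cutoff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    roots = [find(i) for i in range(n)]
    remap: dict[int, int] = {}
    return np.array([remap.setdefault(r, len(remap)) for r in roots])


def partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two labelings induce the same partition."""
    a = np.asarray(a)
    b = np.asarray(b)
    pairs_a = {tuple(np.where(a == c)[0]) for c in np.unique(a)}
    pairs_b = {tuple(np.where(b == c)[0]) for c in np.unique(b)}
    return pairs_a == pairs_b


def quaternion_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Minimum RMSD superposing q onto p by Horn's quaternion method."""
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)
    m = q.T @ p
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    sq = (p**2).sum() + (q**2).sum() - 2.0 * lam
    return float(np.sqrt(max(sq, 0.0) / p.shape[0]))


def brute_min_distance(coords: np.ndarray, ga, gb) -> float:
    best = np.inf
    for i in ga:
        for j in gb:
            best = min(best, float(np.linalg.norm(coords[i] - coords[j])))
    return best


def random_rigid_transform(rng: np.random.Generator):
    """Uniform random proper rotation plus a translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    trans = rng.normal(scale=5.0, size=3)
    return rot, trans
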