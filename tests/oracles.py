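"""Independent brute-force oracles used to validate the texture matrices,
the AUC, and the signed-rank test.  These deliberately use naive
enumeration, not the implementation's algorithms."""

from itertools import product

import numpy as np

OFFSETS_13 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]


def glcm_probs_bruteforce(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence probabilities by checking every voxel pair."""
    counts = np.zeros((n_levels, n_levels))
    voxels = list(zip(*np.nonzero(levels)))
    for a in voxels:
        for off in OFFSETS_13:
            b = (a[0] + off[0], a[1] + off[1], a[2] + off[2])
            if all(0 <= b[k] < levels.shape[k] for k in range(3)) and levels[b] > 0:
                la, lb = levels[a] - 1, levels[b] - 1
                counts[la, lb] += 1
                counts[lb, la] += 1
    total = counts.sum()
    return counts / total if total else counts


def glrlm_bruteforce(levels: np.ndarray, off) -> np.ndarray:
    """Run-length matrix by testing every (start, length) candidate."""
    shape = levels.shape
    nlev = int(levels.max())
    max_len = max(shape) * 2
    r = np.zeros((nlev, max_len + 1))

    def same(p, lev):
        return (
            all(0 <= p[k] < shape[k] for k in range(3)) and levels[tuple(p)] == lev
        )

    for v in product(*(range(s) for s in shape)):
        lev = levels[v]
        if lev == 0:
            continue
        prev = tuple(v[k] - off[k] for k in range(3))
        if same(prev, lev):
            continue  # not a run start
        length = 0
        while same(tuple(v[k] + length * off[k] for k in range(3)), lev):
            length += 1
        r[lev - 1, length] += 1
    return r


def glszm_zones_bruteforce(levels: np.ndarray) -> dict:
    """{(level, size): count} via explicit 26-connected flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones: dict = {}
    neigh = [n for n in product((-1, 0, 1), repeat=3) if n != (0, 0, 0)]
    for v in product(*(range(s) for s in shape)):
        if levels[v] == 0 or seen[v]:
            continue
        lev = levels[v]
        queue = [v]
        seen[v] = True
        size = 0
        while queue:
            p = queue.pop()
            size += 1
            for d in neigh:
                q = tuple(p[k] + d[k] for k in range(3))
                if (
                    all(0 <= q[k] < shape[k] for k in range(3))
                    and not seen[q]
                    and levels[q] == lev
                ):
                    seen[q] = True
                    queue.append(q)
        zones[(int(lev), size)] = zones.get((int(lev), size), 0) + 1
    return zones


def auc_pair_counting(values, labels) -> float:
    """AUC as (concordant + 0.5*ties) / (n1*n0) over all class pairs."""
    pos = [v for v, l in zip(values, labels) if l == 1]
    neg = [v for v, l in zip(values, labels) if l == 0]
    score = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                score += 1.0
            elif p == n:
                score += 0.5
    return score / (len(pos) * len(neg))


def signed_rank_p_enumeration(d: np.ndarray) -> tuple:
    """Exact two-tailed p by enumerating all 2^n sign patterns (n small)."""
    from scipy.stats import rankdata

    d = np.asarray(d, dtype=float)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for bits in range(2**n):
        signs = [(bits >> k) & 1 for k in range(n)]
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs)
    p_ge = np.mean(ws >= w_obs)
    return w_obs, min(1.0, 2 * min(p_le, p_ge))
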