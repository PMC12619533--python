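"""Independent reference implementations used only to check the package."""

from __future__ import annotations

import numpy as np


def brute_force_modified_cosine(a, b, fragment_tol: float = 0.01, sqrt_intensity: bool = True):
    """Exhaustive maximum over all one-to-one peak pairings.

    Dynamic program over (peak of a, bitmask of used peaks of b) — an exact
    enumeration of every conflict-free pairing, feasible for spectra with at
    most ~10 peaks each. Returns (score, n_matched of the best pairing).
    """
    wa = np.sqrt(a.intensities) if sqrt_intensity else a.intensities.astype(float)
    wb = np.sqrt(b.intensities) if sqrt_intensity else b.intensities.astype(float)
    wa = wa / np.linalg.norm(wa)
    wb = wb / np.linalg.norm(wb)
    mza, mzb = a.mz, b.mz
    shift = a.precursor_mz - b.precursor_mz
    cands = [
        [
            j
            for j in range(len(mzb))
            if abs(mza[i] - mzb[j]) <= fragment_tol
            or abs(mza[i] - mzb[j] - shift) <= fragment_tol
        ]
        for i in range(len(mza))
    ]
    memo: dict[tuple[int, int], tuple[float, int]] = {}

    def best(i: int, mask: int) -> tuple[float, int]:
        if i == len(mza):
            return 0.0, 0
        key = (i, mask)
        if key in memo:
            return memo[key]
        res = best(i + 1, mask)
        for j in cands[i]:
            if not mask >> j & 1:
                s, n = best(i + 1, mask | 1 << j)
                cand = (s + wa[i] * wb[j], n + 1)
                if cand[0] > res[0]:
                    res = cand
        memo[key] = res
        return res

    score, n = best(0, 0)
    return min(score, 1.0), n


class UnionFind:
    """Minimal union-find for reference connected-component labelling."""

    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra

    def groups(self):
        out = {}
        for x in self.parent:
            out.setdefault(self.find(x), set()).add(x)
        return list(out.values())
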