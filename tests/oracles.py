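"""Independent oracles used to cross-check the package's implementations.

These deliberately use different algorithms from the library code:
quaternion characteristic polynomial for superposition RMSD, bisection
on the mass-action equilibrium for fraction bound, all-pairs O(N²)
scanning for clash counts, and direct enumeration for region calls.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np


def qcp_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal superposition RMSD via the quaternion method.

    Builds the 4x4 key matrix of the quaternion characteristic
    polynomial approach and takes its largest eigenvalue; never forms a
    rotation matrix, so it is independent of the SVD-based path.
    """
    p = np.asarray(mobile, float)
    q = np.asarray(reference, float)
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    n = len(p)
    ga = np.sum(pc * pc)
    gb = np.sum(qc * qc)
    m = pc.T @ qc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(key).max()
    msd = max((ga + gb - 2.0 * lam) / n, 0.0)
    return float(np.sqrt(msd))


def bisect_fraction_bound(p_total: float, l_total: float, kd: float,
                          tol: float = 1e-14, iters: int = 200) -> float:
    """Fraction bound by bisection on Kd = (P-C)(L-C)/C for the complex C."""
    if l_total == 0:
        return 0.0
    lo, hi = 0.0, min(p_total, l_total)

    def g(c: float) -> float:
        return (p_total - c) * (l_total - c) - kd * c

    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, hi):
            break
    return 0.5 * (lo + hi) / p_total


def brute_force_clash_counts(structure, cutoff: float):
    """All-pairs inter-chain heavy-atom contact counts per chain pair."""
    heavy = [a for a in structure.atoms if a.element != "H"]
    counts: dict = {}
    for i in range(len(heavy)):
        for j in range(i + 1, len(heavy)):
            a, b = heavy[i], heavy[j]
            if a.chain == b.chain:
                continue
            d = np.linalg.norm(a.coords - b.coords)
            if d < cutoff:
                pair = tuple(sorted((a.chain, b.chain)))
                counts[pair] = counts.get(pair, 0) + 1
    return counts


def enumerate_regions(residues: Sequence[int], max_gap: int
                      ) -> List[Tuple[int, int]]:
    """Region calls by direct enumeration over the integer line."""
    if not residues:
        return []
    present = set(residues)
    lo, hi = min(present), max(present)
    regions: List[Tuple[int, int]] = []
    start = None
    last = None
    for r in range(lo, hi + 1):
        if r in present:
            if start is None:
                start = r
            elif last is not None and r - last > max_gap + 1:
                regions.append((start, last))
                start = r
            last = r
    regions.append((start, last))
    return regions
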