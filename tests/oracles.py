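"""Independent reference implementations used only to check the package.

These are deliberately written in a different style from the library code
(memoized recursion instead of iterative DP, quaternion eigendecomposition
instead of SVD, plain triple loops instead of vectorized distances) so that
agreement between the two routes is meaningful.
"""

from __future__ import annotations

import sys
from functools import lru_cache

import numpy as np


def nw_score_oracle(seq_a: str, seq_b: str, sub: dict, gap_open: float,
                    gap_extend: float) -> float:
    """Optimal global alignment score by memoized recursion over the three
    affine-gap states.  A gap run of length k costs gap_open + k*gap_extend."""
    n, m = len(seq_a), len(seq_b)
    sys.setrecursionlimit(max(10000, 10 * (n + m)))

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if i == n and j == m:
            return 0.0
        cands = []
        if i < n and j < m:
            cands.append(sub[(seq_a[i], seq_b[j])] + best(i + 1, j + 1, "M"))
        if i < n:
            cost = gap_extend if state == "A" else gap_open + gap_extend
            cands.append(-cost + best(i + 1, j, "A"))
        if j < m:
            cost = gap_extend if state == "B" else gap_open + gap_extend
            cands.append(-cost + best(i, j + 1, "B"))
        return max(cands)

    result = best(0, 0, "S")
    best.cache_clear()
    return result


def quaternion_rmsd(ref: np.ndarray, target: np.ndarray) -> float:
    """Minimum RMSD of target onto ref via the quaternion (Horn) method:
    the optimal rotation corresponds to the largest eigenvalue of the 4x4
    key matrix; no rotation matrix is ever formed."""
    P = np.asarray(ref, float)
    Q = np.asarray(target, float)
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    S = Q0.T @ P0
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    e = (P0 ** 2).sum() + (Q0 ** 2).sum() - 2.0 * lam
    return float(np.sqrt(max(e, 0.0) / len(P)))


def brute_force_contacts(structure, member_uid: str, cutoff: float):
    """(seq_pos, comp_id, min_distance) by plain triple loops."""
    out = {}
    for lig in structure.ligands:
        for chain in structure.chains:
            if chain.entity_uid != member_uid:
                continue
            for rec in chain.residues:
                if not rec.modeled:
                    continue
                dmin = None
                for a in rec.atoms:
                    if a.element.upper() == "H":
                        continue
                    for b in lig.atoms:
                        if b.element.upper() == "H":
                            continue
                        d = ((a.x - b.x) ** 2 + (a.y - b.y) ** 2
                             + (a.z - b.z) ** 2) ** 0.5
                        if dmin is None or d < dmin:
                            dmin = d
                if dmin is not None and dmin <= cutoff:
                    key = (rec.seq_pos, lig.comp_id)
                    out[key] = min(dmin, out.get(key, float("inf")))
    return sorted((p, c, d) for (p, c), d in out.items())


def greedy_cluster_oracle(entities, threshold: float, identity_fn):
    """Assign-to-first-qualifying-representative clustering, re-stated as a
    plain loop over (rep, members) lists."""
    ordered = sorted(entities, key=lambda e: (-len(e.sequence), e.entity_uid))
    clusters: list[tuple[object, list[str]]] = []
    for ent in ordered:
        for rep, members in clusters:
            if identity_fn(rep.sequence, ent.sequence) >= threshold:
                members.append(ent.entity_uid)
                break
        else:
            clusters.append((ent, [ent.entity_uid]))
    return [(rep.entity_uid, members) for rep, members in clusters]
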