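"""Independent numerical oracles used only by the tests.

These deliberately avoid the code paths they check: the quaternion (Horn)
superposition solves the same least-squares problem as the SVD-based Kabsch
routine by an eigenvalue method, and the threshold-cut partition clusters a
distance matrix by connected components instead of Ward linkage.
"""

from __future__ import annotations

import numpy as np


def horn_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimal RMSD between paired point sets via Horn's quaternion method.

    The optimal rotation's quaternion is the eigenvector of the 4x4 key
    matrix with the largest eigenvalue λ_max, and the residual is
    ``sqrt((G_a + G_b - 2 λ_max) / N)``.
    """
    a = np.asarray(a, float) - np.mean(a, axis=0)
    b = np.asarray(b, float) - np.mean(b, axis=0)
    n = a.shape[0]
    m = b.T @ a   # correlation matrix of mobile vs fixed
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam_max = np.linalg.eigvalsh(key)[-1]
    ga = np.sum(a * a)
    gb = np.sum(b * b)
    return float(np.sqrt(max(0.0, (ga + gb - 2.0 * lam_max) / n)))


def threshold_cut_partition(distance: np.ndarray, threshold: float) -> np.ndarray:
    """Connected-component labels after cutting all edges above ``threshold``."""
    n = distance.shape[0]
    labels = -np.ones(n, dtype=int)
    current = 0
    for start in range(n):
        if labels[start] >= 0:
            continue
        stack = [start]
        labels[start] = current
        while stack:
            i = stack.pop()
            neighbors = np.flatnonzero((distance[i] <= threshold) & (labels < 0))
            labels[neighbors] = current
            stack.extend(neighbors.tolist())
        current += 1
    return labels


def two_stage_bernoulli_mean(p_low: float, p_high: float, n_draws: int, seed: int) -> float:
    """Monte-Carlo mean substitution probability of the two-stage process
    (p_i ~ U(p_low, p_high), then Bernoulli(p_i))."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(p_low, p_high, size=n_draws)
    return float(np.mean(rng.random(n_draws) < p))
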