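"""Independent small-system oracles for the translation dynamics.

The stationary solver below enumerates every admissible ribosome
configuration of a short transcript and solves the master equation
exactly.  It is written directly from the model rules (initiation blocked
while any A-site sits within the first ell+1 codons; a hop from j blocked
by an A-site at j+ell; termination from the stop codon) and shares no
code with the simulation kernels it is used to check.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np


def enumerate_configurations(n_codons: int, ell: int) -> List[Tuple[int, ...]]:
    """All sets of A-site positions with pairwise gaps >= ell (ascending)."""
    configs: List[Tuple[int, ...]] = []

    def rec(start: int, current: List[int]) -> None:
        configs.append(tuple(current))
        for p in range(start, n_codons + 1):
            current.append(p)
            rec(p + ell, current)
            current.pop()

    rec(1, [])
    return configs


def stationary_occupancy(
    n_codons: int, ell: int, alpha: float, omega: np.ndarray, beta: float
) -> np.ndarray:
    """Exact steady-state per-codon occupancy of the finite l-TASEP chain."""
    configs = enumerate_configurations(n_codons, ell)
    index: Dict[Tuple[int, ...], int] = {c: i for i, c in enumerate(configs)}
    n = len(configs)
    Q = np.zeros((n, n))

    for c in configs:
        i = index[c]
        occupied = set(c)
        # initiation
        if all(p > ell + 1 for p in c):
            target = tuple(sorted(c + (1,)))
            Q[i, index[target]] += alpha
        for k, p in enumerate(c):
            if p == n_codons:
                # termination of the leading ribosome
                target = tuple(q for q in c if q != p)
                Q[i, index[target]] += beta
            elif (p + ell) not in occupied:
                target = tuple(sorted(q if q != p else p + 1 for q in c))
                Q[i, index[target]] += omega[p - 1]

    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    # solve pi Q = 0 with sum(pi) = 1
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    rho = np.zeros(n_codons)
    for c, p_c in zip(configs, pi):
        for pos in c:
            rho[pos - 1] += p_c
    return rho
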