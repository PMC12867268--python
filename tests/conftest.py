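"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import math

import numpy as np
import pytest

from chemtwas.io import LdMatrix
from chemtwas.simulate import SimConfig, simulate_all


def random_psd_corr(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random valid correlation matrix (PSD, unit diagonal)."""
    a = rng.standard_normal((n, n + 2))
    cov = a @ a.T + 1e-3 * np.eye(n)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def naive_twas_z(w, z, L) -> float:
    """Double-loop evaluation of (w·z)/sqrt(w·(Lw)) — oracle for twas_zscore."""
    num = 0.0
    for wi, zi in zip(w, z):
        num += wi * zi
    quad = 0.0
    for i in range(len(w)):
        for j in range(len(w)):
            quad += w[i] * L[i][j] * w[j]
    return num / math.sqrt(quad)


def brute_force_es(ranked_abs_scores, hit_flags, p: float):
    """Exhaustive prefix scan of the weighted KS running sum."""
    n = len(hit_flags)
    n_hit = sum(hit_flags)
    weights = [abs(s) ** p for s in ranked_abs_scores]
    hit_sum = sum(w for w, h in zip(weights, hit_flags) if h)
    best = 0.0
    running = 0.0
    for i in range(n):
        if hit_flags[i]:
            running += weights[i] / hit_sum if hit_sum > 0 else 1.0 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


def brute_force_mcc(nodes, edges) -> dict:
    """MCC by subset scan: enumerate all maximal cliques explicitly."""
    nodes = list(nodes)
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def is_clique(sub):
        return all(b in adj[a] for i, a in enumerate(sub) for b in sub[i + 1 :])

    cliques = []
    n = len(nodes)
    for mask in range(1, 2**n):
        sub = [nodes[i] for i in range(n) if mask >> i & 1]
        if is_clique(sub):
            cliques.append(set(sub))
    maximal = [c for c in cliques if not any(c < other for other in cliques)]
    scores = {v: 0 for v in nodes}
    for c in maximal:
        if len(c) == 1:  # isolated node: no clique contribution
            continue
        for v in c:
            scores[v] += math.factorial(len(c) - 1)
    return scores


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact P(X >= k) by direct pmf enumeration."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, x) * math.comb(N - K, n - x) / total
        for x in range(k, min(K, n) + 1)
    )


@pytest.fixture(scope="session")
def small_bundle():
    """Compact multi-tissue world with planted signal at every stage."""
    config = SimConfig(
        seed=11,
        n_blocks=30,
        block_size=20,
        n_genes=30,
        snps_per_gene=5,
        n_tissues=3,
        causal_genes={"G01": 6.0, "G07": 6.0},
        planted_lfc={"G01": 2.0, "G03": -2.0},
        n_chemicals=20,
        active_chemicals={"C01": 0.9},
        set_size_range=(5, 10),
        ppi_planted_modules=[(6, 1.0), (4, 1.0)],
        ppi_background_prob=0.02,
    )
    return simulate_all(config)
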