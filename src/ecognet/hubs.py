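"""Weighted-degree hub centrality and the edge-swap permutation hub test.

Hub strength (HS) of a node is the sum of its incident directed edge weights
(inflow + outflow). The hub hypothesis for a target node is tested against
the median HS of the remaining nodes, with an empirical null built by
permuting the off-diagonal edge weights over off-diagonal positions (the
weight multiset is preserved exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ecognet.stats import bh_fdr


def weighted_degree(
    matrix: np.ndarray,
    target: int | None = None,
    others: list[int] | None = None,
) -> tuple[np.ndarray, float | None]:
    """Hub strength per node and, optionally, the target-vs-median statistic.

    ``HS(i) = sum_j (w(i->j) + w(j->i))``; the statistic is
    ``HS(target) - median(HS(others))``.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    off = M.copy()
    np.fill_diagonal(off, 0.0)
    hs = off.sum(axis=1) + off.sum(axis=0)
    stat = None
    if target is not None:
        if others is None:
            others = [i for i in range(M.shape[0]) if i != target]
        stat = float(hs[target] - np.median(hs[list(others)]))
    return hs, stat


def _incidence(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Off-diagonal positions and the node-incidence matrix.

    Returns ``pos`` (n_off, 2) of (row, col) indices and ``inc``
    (n, n_off) where ``inc[k, e]`` counts how many times edge slot ``e``
    contributes to node ``k``'s hub strength (1 for row or column match).
    """
    pos = np.array([(i, j) for i in range(n) for j in range(n) if i != j])
    inc = np.zeros((n, len(pos)))
    for e, (i, j) in enumerate(pos):
        inc[i, e] += 1.0
        inc[j, e] += 1.0
    return pos, inc


@dataclass
class HubnessResult:
    """Hub test over one or more bands.

    ``table`` has one row per band: observed statistic, permutation p
    (count / n_swaps), and — when several bands are tested — BH-FDR flags
    across bands at ``q``. ``hub_strength`` holds HS per node and band.
    """

    table: pd.DataFrame
    hub_strength: pd.DataFrame
    target: str | int
    n_swaps: int
    seed: int | None
    q: float = 0.05
    degenerate: dict = field(default_factory=dict)


def _surrogate_stats(
    M: np.ndarray,
    target: int,
    others: list[int],
    n_swaps: int,
    rng: np.random.Generator,
    scheme: str = "permute",
    chunk: int = 20_000,
) -> np.ndarray:
    n = M.shape[0]
    pos, inc = _incidence(n)
    w = M[pos[:, 0], pos[:, 1]]
    stats = np.empty(n_swaps)
    done = 0
    while done < n_swaps:
        k = min(chunk, n_swaps - done)
        if scheme == "permute":
            W = rng.permuted(np.broadcast_to(w, (k, len(w))).copy(), axis=1)
        elif scheme == "pairwise":
            # chain of 10*E random transpositions per surrogate
            W = np.broadcast_to(w, (k, len(w))).copy()
            n_tr = 10 * len(w)
            ii = rng.integers(0, len(w), size=(k, n_tr))
            jj = rng.integers(0, len(w), size=(k, n_tr))
            for r in range(k):
                row = W[r]
                for a, b in zip(ii[r], jj[r]):
                    row[a], row[b] = row[b], row[a]
        else:
            raise ValueError("scheme must be 'permute' or 'pairwise'")
        hs = W @ inc.T  # (k, n)
        stats[done : done + k] = hs[:, target] - np.median(hs[:, others],
                                                           axis=1)
        done += k
    return stats


def hub_test(
    matrix: np.ndarray,
    target: int,
    others: list[int] | None = None,
    n_swaps: int = 100_000,
    seed: int | None = 0,
    scheme: str = "permute",
) -> tuple[float, float, dict]:
    """Edge-swap permutation test of hubness for one weight matrix.

    Returns ``(statistic, p, info)``. The null permutes the off-diagonal
    weight multiset over off-diagonal positions; ``p`` is the fraction of
    surrogate statistics at least as large as the observed one. All-equal
    weights give ``p = 1`` and are flagged degenerate.
    """
    if n_swaps < 1000:
        raise ValueError("n_swaps must be >= 1000")
    M = np.asarray(matrix, dtype=float)
    n = M.shape[0]
    if others is None:
        others = [i for i in range(n) if i != target]
    _, stat = weighted_degree(M, target, others)
    off = M[~np.eye(n, dtype=bool)]
    info: dict = {}
    if np.allclose(off, off[0]):
        info["degenerate"] = "all edge weights equal"
        return stat, 1.0, info
    rng = np.random.default_rng(seed)
    null = _surrogate_stats(M, target, list(others), n_swaps, rng, scheme)
    p = float(np.mean(null >= stat))
    return stat, p, info


def hub_test_bands(
    matrices: dict[str, np.ndarray],
    target: int,
    labels: list[str],
    others: list[int] | None = None,
    n_swaps: int = 100_000,
    seed: int | None = 0,
    q: float = 0.05,
    scheme: str = "permute",
) -> HubnessResult:
    """Hub test per band with BH-FDR correction across bands."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(matrices))
    rows, hs_rows, degenerate = [], [], {}
    for (band, M), child in zip(matrices.items(), children):
        stat, p, info = hub_test(M, target, others, n_swaps,
                                 child, scheme)
        if info:
            degenerate[band] = info
        hs, _ = weighted_degree(M)
        for k, lab in enumerate(labels):
            hs_rows.append(dict(band=band, node=lab, HS=float(hs[k])))
        rows.append(dict(band=band, statistic=stat, p=p))
    table = pd.DataFrame(rows)
    fdr = bh_fdr(table["p"].to_numpy(), q)
    table["p_adjusted"] = fdr.p_adjusted
    table["fdr_sig"] = fdr.reject
    return HubnessResult(
        table, pd.DataFrame(hs_rows), labels[target], n_swaps, seed, q,
        degenerate,
    )
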