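"""Independent brute-force oracles used by the test suite.

Deliberately written along different computational paths than the package:
the MaxLFQ oracle assembles the graph-Laplacian normal equations pair by
pair and solves them with a pseudo-inverse; the digestion oracle walks the
sequence character by character.
"""

from __future__ import annotations

import numpy as np


def maxlfq_oracle(x: np.ndarray, min_shared: int = 1) -> np.ndarray:
    """Dense least-squares solution of the pairwise-median ratio system."""
    x = np.asarray(x, dtype=float)
    n_prec, n_cells = x.shape
    obs = ~np.isnan(x)

    ratios = np.full((n_cells, n_cells), np.nan)
    for a in range(n_cells):
        for b in range(n_cells):
            if a == b:
                continue
            both = obs[:, a] & obs[:, b]
            if both.sum() >= max(1, min_shared):
                ratios[a, b] = float(np.median(x[both, b] - x[both, a]))

    # connected components by breadth-first search over defined ratios
    labels = -np.ones(n_cells, dtype=int)
    comp = 0
    for start in range(n_cells):
        if labels[start] >= 0:
            continue
        queue = [start]
        labels[start] = comp
        while queue:
            a = queue.pop()
            for b in range(n_cells):
                if labels[b] < 0 and not np.isnan(ratios[a, b]):
                    labels[b] = comp
                    queue.append(b)
        comp += 1

    result = np.full(n_cells, np.nan)
    for c in range(comp):
        cells = np.flatnonzero(labels == c)
        if not obs[:, cells].any():
            continue
        anchor = float(np.nanmean(x[:, cells]))
        if len(cells) == 1:
            result[cells[0]] = anchor
            continue
        m = len(cells)
        lap = np.zeros((m, m))
        rhs = np.zeros(m)
        for ia in range(m):
            for ib in range(ia + 1, m):
                r = ratios[cells[ia], cells[ib]]
                if np.isnan(r):
                    continue
                lap[ia, ia] += 1
                lap[ib, ib] += 1
                lap[ia, ib] -= 1
                lap[ib, ia] -= 1
                rhs[ib] += r
                rhs[ia] -= r
        w = np.linalg.pinv(lap) @ rhs
        result[cells] = w - w.mean() + anchor
    return result


def digest_count_oracle(
    sequence: str,
    min_len: int = 6,
    max_len: int = 50,
    missed_cleavages: int = 0,
    proline_rule: bool = False,
) -> int:
    """Count observable tryptic peptides by an explicit character walk."""
    seq = sequence.strip().upper()
    cuts = []  # cut after index i
    for i, aa in enumerate(seq[:-1]):
        if aa in "KR":
            if proline_rule and seq[i + 1] == "P":
                continue
            cuts.append(i + 1)
    bounds = [0] + cuts + [len(seq)]
    fragments = [seq[bounds[i] : bounds[i + 1]] for i in range(len(bounds) - 1)]
    count = 0
    for i in range(len(fragments)):
        for mc in range(missed_cleavages + 1):
            if i + mc >= len(fragments):
                break
            peptide = "".join(fragments[i : i + mc + 1])
            if min_len <= len(peptide) <= max_len:
                count += 1
    return count


def random_maxlfq_instance(rng: np.random.Generator, max_cells: int = 6, max_prec: int = 8):
    """Random small instance whose cell-pair graph is connected (one fully
    observed precursor guarantees it)."""
    n_cells = int(rng.integers(2, max_cells + 1))
    n_prec = int(rng.integers(1, max_prec + 1))
    x = rng.normal(10.0, 2.0, (n_prec, n_cells))
    mask = rng.random((n_prec, n_cells)) < 0.35
    mask[0, :] = False  # fully observed anchor row keeps the graph connected
    x[mask] = np.nan
    return x
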