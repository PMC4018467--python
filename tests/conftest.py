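"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from drbstr.panel import default_panel_config, generate_panel


@pytest.fixture(scope="session")
def default_panel():
    """One default 34-record panel (records, truth, config)."""
    cfg = default_panel_config(seed=11)
    records, truth = generate_panel(cfg)
    return records, truth, cfg


# ---------------------------------------------------------------------------
# brute-force repeat-scanner oracle (window enumeration)
# ---------------------------------------------------------------------------

def _oracle_canonical(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _oracle_primitive(motif: str) -> bool:
    return all(
        not (len(motif) % d == 0 and motif == motif[:d] * (len(motif) // d))
        for d in range(1, len(motif))
    )


def oracle_perfect_runs(seq: str, k: int):
    """All maximal period-k perfect stretches, enumerating every start."""
    n = len(seq)
    runs = []
    for i in range(n - 2 * k + 1):
        motif = seq[i : i + k]
        if "N" in motif or not _oracle_primitive(motif):
            continue
        j = i + k
        while j < n and seq[j] != "N" and seq[j] == seq[j - k]:
            j += 1
        if j - i >= 2 * k:
            runs.append((i, j, _oracle_canonical(motif)))
    # keep only runs not contained in another run of the same canonical motif
    out = []
    for r in sorted(set(runs)):
        if any(
            o[0] <= r[0] and r[1] <= o[1] and o != r and o[2] == r[2] for o in runs
        ):
            continue
        out.append(r)
    return out


def oracle_find_repeats(seq, min_mono=12, min_multi=4, max_gap=4, min_purity=0.85):
    """Independent reference for find_repeats: enumerate, merge, filter."""
    candidates = []
    for k in range(1, 7):
        runs = oracle_perfect_runs(seq, k)
        runs.sort()
        merged = []
        last_by_motif = {}
        for start, end, motif in runs:
            prev = last_by_motif.get(motif)
            if (
                prev is not None
                and prev[1] <= start <= prev[1] + max_gap
                and "N" not in seq[prev[1] : start]
            ):
                prev[1] = end
                prev[3] += end - start
                prev[4] += 1
            else:
                cur = [start, end, motif, end - start, 0]
                merged.append(cur)
                last_by_motif[motif] = cur
        merged += [[s, e, m, e - s, 0] for s, e, m in runs]
        for start, end, motif, matched, inter in merged:
            span = end - start
            copies = span / k
            purity = matched / span
            thr = min_mono if k == 1 else min_multi
            if int(copies) >= thr and purity >= min_purity:
                candidates.append(
                    (span, start, motif, k, end, copies, purity, inter)
                )
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    chosen = []
    for span, start, motif, k, end, copies, purity, inter in candidates:
        if all(end <= c[0] or start >= c[1] for c in chosen):
            chosen.append((start, end, motif, k, copies, purity, inter))
    return sorted(chosen)


# ---------------------------------------------------------------------------
# random additive trees for NJ exactness
# ---------------------------------------------------------------------------

def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random binary topology + positive branch lengths; returns
    (taxa, distance matrix, set of nontrivial splits)."""
    import itertools

    taxa = [f"t{i}" for i in range(n_taxa)]
    # grow an unrooted tree by attaching taxa to random edges of a graph
    # nodes: taxa plus internal; edges dict with lengths
    next_internal = [0]

    def new_internal():
        next_internal[0] += 1
        return f"x{next_internal[0]}"

    edges = {}

    def add_edge(a, b, ln):
        edges[frozenset((a, b))] = ln

    def del_edge(a, b):
        return edges.pop(frozenset((a, b)))

    blen = lambda: float(rng.uniform(0.5, 3.0))
    add_edge(taxa[0], taxa[1], blen())
    for taxon in taxa[2:]:
        edge = list(edges)[int(rng.integers(0, len(edges)))]
        a, b = tuple(edge)
        ln = del_edge(a, b)
        mid = new_internal()
        u = float(rng.uniform(0.2, 0.8))
        add_edge(a, mid, ln * u)
        add_edge(mid, b, ln * (1 - u))
        add_edge(mid, taxon, blen())

    # path lengths by BFS
    adj = {}
    for e, ln in edges.items():
        a, b = tuple(e)
        adj.setdefault(a, []).append((b, ln))
        adj.setdefault(b, []).append((a, ln))

    def dists_from(src):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nxt, ln in adj[cur]:
                if nxt not in seen:
                    seen[nxt] = seen[cur] + ln
                    stack.append(nxt)
        return seen

    dm = np.zeros((n_taxa, n_taxa))
    for i, t in enumerate(taxa):
        d = dists_from(t)
        for j, u in enumerate(taxa):
            dm[i, j] = d[u]
    dm = (dm + dm.T) / 2.0  # wash out float asymmetry from per-source sums

    # splits: removing each edge partitions the leaves
    splits = set()
    for e in edges:
        a, b = tuple(e)
        # leaves on a's side without crossing edge e
        seen = {a}
        stack = [a]
        while stack:
            cur = stack.pop()
            for nxt, _ln in adj[cur]:
                if frozenset((cur, nxt)) == e or nxt in seen:
                    continue
                seen.add(nxt)
                stack.append(nxt)
        side = frozenset(t for t in taxa if t in seen)
        if 1 < len(side) < n_taxa - 1:
            splits.add(frozenset([side, frozenset(taxa) - side]))
    return taxa, dm, splits
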