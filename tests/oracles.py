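"""Independent oracles: brute-force implementations used only to check the
package's fast paths.  Nothing here imports the code path it verifies."""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
from scipy.linalg import expm

from phylostab._treeindex import IndexedTree
from phylostab.matrix import ABSENT, MISSING, PRESENT


def expm_taylor(Q: np.ndarray, t: float, terms: int = 60) -> np.ndarray:
    """Truncated Taylor series for exp(Qt) (small matrices, small t)."""
    A = Q * t
    out = np.eye(Q.shape[0])
    term = np.eye(Q.shape[0])
    for k in range(1, terms):
        term = term @ A / k
        out = out + term
    return out


def _tip_allowed(state: str) -> list[int]:
    return {PRESENT: [2, 3], ABSENT: [0, 1], MISSING: [0, 1, 2, 3]}[state]


def enumerate_likelihood(
    idx: IndexedTree, trait: dict[str, str], Q: np.ndarray
) -> tuple[float, dict[int, np.ndarray]]:
    """Exhaustive 4-state likelihood and node marginals with the
    conditional-likelihood (FitzJohn-style) root weighting.

    Sums over every assignment of hidden states to internal nodes and every
    admissible tip state.  Returns (log-likelihood, marginals per node
    including tips).  Exponential in the node count: fixtures only.
    """
    P = {i: expm(Q * idx.blen[i]) for i in range(idx.n_nodes)}
    tipmap = {lab: i for i, lab in enumerate(idx.tip_labels)}
    allowed = {tipmap[k]: _tip_allowed(v) for k, v in trait.items()}
    internals = list(idx.internal_postorder)
    root = idx.root

    def joint(assign: dict[int, int]) -> float:
        p = 1.0
        for i in internals:
            for c in idx.children[i]:
                if c < idx.n_tips:
                    p *= P[c][assign[i], assign[c]]
                else:
                    p *= P[c][assign[i], assign[c]]
        return p

    tips = sorted(allowed)
    total_by_root = np.zeros(4)
    weights: list[tuple[dict[int, int], float]] = []
    for int_states in itertools.product(range(4), repeat=len(internals)):
        a_int = dict(zip(internals, int_states))
        for tip_states in itertools.product(*(allowed[t] for t in tips)):
            a = dict(a_int)
            a.update(zip(tips, tip_states))
            w = joint(a)
            weights.append((a, w))
            total_by_root[a[root]] += w
    prior = total_by_root / total_by_root.sum()
    total = float(prior @ total_by_root)

    marg = {i: np.zeros(4) for i in range(idx.n_nodes)}
    for a, w in weights:
        ww = w * prior[a[root]]
        for i, s in a.items():
            marg[i][s] += ww
    for i in marg:
        marg[i] = marg[i] / marg[i].sum()
    return float(np.log(total)), marg


def two_state_loglik(idx: IndexedTree, trait: dict[str, str], gain: float, loss: float) -> float:
    """Plain 2-state ARD pruning likelihood with the same root treatment
    (straightforward per-node loop, scipy expm)."""
    Q = np.array([[-gain, gain], [loss, -loss]])
    P = {i: expm(Q * idx.blen[i]) for i in range(idx.n_nodes)}
    part = np.zeros((idx.n_nodes, 2))
    for i, lab in enumerate(idx.tip_labels):
        part[i] = {PRESENT: (0, 1), ABSENT: (1, 0), MISSING: (1, 1)}[trait[lab]]
    ls = 0.0
    for i in idx.internal_postorder:
        c1, c2 = idx.children[i]
        part[i] = (P[c1] @ part[c1]) * (P[c2] @ part[c2])
        m = part[i].max()
        part[i] /= m
        ls += np.log(m)
    prior = part[idx.root] / part[idx.root].sum()
    return float(np.log(prior @ part[idx.root]) + ls)


def _canon(t):
    """Canonical form of an unordered binary topology over hashables."""
    if isinstance(t, tuple):
        a, b = (_canon(t[0]), _canon(t[1]))
        return tuple(sorted((a, b), key=repr))
    return t


def labeled_history_distribution(tips: list[str]) -> dict:
    """Exact topology distribution under uniform sequential pair joining.

    Enumerates every join sequence (labeled history) of the free lineages
    and tallies the resulting unordered topologies.  Returns topology ->
    probability.
    """
    counts: Counter = Counter()

    def rec(lineages: tuple, weight: float) -> None:
        if len(lineages) == 1:
            counts[_canon(lineages[0])] += weight
            return
        m = len(lineages)
        npairs = m * (m - 1) // 2
        for i in range(m):
            for j in range(i + 1, m):
                rest = tuple(
                    lineages[k] for k in range(m) if k not in (i, j)
                ) + ((lineages[i], lineages[j]),)
                rec(rest, weight / npairs)

    rec(tuple(tips), 1.0)
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def newick_topology(newick: str):
    """Parse a (possibly nested) Newick string into the canonical tuple form
    used by :func:`labeled_history_distribution` (branch lengths ignored)."""
    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)

    def conv(nd):
        if nd.is_leaf():
            return nd.taxon.label
        kids = [conv(c) for c in nd.child_nodes()]
        assert len(kids) == 2, "topology oracle needs binary trees"
        return (kids[0], kids[1])

    return _canon(conv(t.seed_node))


def kendall_tau_brute(x, y) -> float:
    """O(n^2) tau-b: pairwise concordant/discordant counting with the
    standard tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[i] - x[j])
            dy = np.sign(y[i] - y[j])
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx == dy:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    return (conc - disc) / denom


def _tie_term(v: np.ndarray) -> float:
    _, counts = np.unique(v, return_counts=True)
    return float(sum(c * (c - 1) / 2 for c in counts))
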