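"""Fritz–Purvis D: phylogenetic signal for a binary trait on a tree.

The observed statistic d_obs is the sum, over internal nodes, of the absolute
difference between the two daughter nodal values, where nodal values are
filled bottom-up as the unweighted mean of the daughters (tips carry their
0/1 value).  d_obs is scaled between two null expectations:

* the *shuffle* null — tip values permuted at random, prevalence preserved —
  which models no phylogenetic structure (D = 1 on average), and
* the *Brownian threshold* null — a continuous character evolved by Brownian
  motion and cut at the rank reproducing the observed prevalence — which
  models the strongest gradual phylogenetic structuring (D = 0 on average):

    D = (d_obs - mean d_Brownian) / (mean d_shuffle - mean d_Brownian).

D below 0 indicates a trait more aggregated than the Brownian expectation
("overclumped"); D above 1 a trait more dispersed than random
("overdispersed").  Tips with missing values are pruned per trait before any
computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np

from ._treeindex import IndexedTree, as_indexed
from .matrix import ABSENT, MISSING, PRESENT

__all__ = [
    "DResult",
    "MedianD",
    "sister_diff_sum",
    "shuffle_null",
    "brownian_threshold_null",
    "compute_D",
    "median_D",
]

STATUS_OK = "ok"
STATUS_CONSTANT = "undefined_constant"
STATUS_DEGENERATE = "undefined_degenerate"

_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class DResult:
    d_obs: float
    d_random_mean: float
    d_brownian_mean: float
    D: float | None
    n_sim: int
    status: str
    n_tips_used: int = 0

    def __post_init__(self) -> None:
        if self.status == STATUS_OK and self.D is None:
            raise ValueError("status ok requires a D value")
        if self.status != STATUS_OK and self.D is not None:
            raise ValueError("non-ok status must carry no D value")


@dataclass(frozen=True)
class MedianD:
    """Per-tree D values over a posterior and their median."""

    median: float | None
    per_tree: list[DResult]
    n_ok: int
    n_not_ok: int
    reason: str | None = None


def _tip_values(idx: IndexedTree, trait: Mapping[str, int | float]) -> np.ndarray:
    vals = np.empty(idx.n_tips)
    for i, label in enumerate(idx.tip_labels):
        if label not in trait:
            raise ValueError(f"tip {label!r} has no trait value")
        vals[i] = float(trait[label])
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("trait values must be 0 or 1")
    return vals


def _sister_diff_many(idx: IndexedTree, tipvals: np.ndarray) -> np.ndarray:
    """Sister-difference sums for many traits at once.

    ``tipvals`` is (n_tips, m); returns (m,).  Nodal values are the unweighted
    mean of the two daughters, filled in postorder.
    """
    m = tipvals.shape[1]
    vals = np.empty((idx.n_nodes, m))
    vals[: idx.n_tips] = tipvals
    d = np.zeros(m)
    for i in idx.internal_postorder:
        c1, c2 = idx.children[i]
        d += np.abs(vals[c1] - vals[c2])
        vals[i] = 0.5 * (vals[c1] + vals[c2])
    return d


def sister_diff_sum(tree: "dendropy.Tree | IndexedTree", trait: Mapping[str, int | float]) -> float:
    """Observed sum of sister-clade differences for a fully coded binary trait."""
    idx = as_indexed(tree)
    vals = _tip_values(idx, trait)
    return float(_sister_diff_many(idx, vals[:, None])[0])


def shuffle_null(
    tree: "dendropy.Tree | IndexedTree",
    trait: Mapping[str, int | float],
    n_sim: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Null d values under random permutation of tip values (fixed prevalence)."""
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    idx = as_indexed(tree)
    vals = _tip_values(idx, trait)
    rng = np.random.default_rng(seed)
    perms = np.empty((idx.n_tips, n_sim))
    for r in range(n_sim):
        perms[:, r] = rng.permutation(vals)
    return _sister_diff_many(idx, perms)


def brownian_threshold_null(
    tree: "dendropy.Tree | IndexedTree",
    trait: Mapping[str, int | float],
    n_sim: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Null d values under unit-rate Brownian evolution cut at the observed
    prevalence.

    Each replicate evolves a continuous value down the tree (variance equal
    to branch length), then marks the k tips with the largest values present,
    k being the observed number of present tips.  Rank ties (possible only
    with zero-length branches) are broken by a deterministic sub-numerical
    jitter drawn from the replicate generator.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    idx = as_indexed(tree)
    vals = _tip_values(idx, trait)
    if not (idx.blen[np.arange(idx.n_nodes) != idx.root] > 0).any():
        raise ValueError("all branch lengths are zero; Brownian null undefined")
    k = int(vals.sum())
    rng = np.random.default_rng(seed)
    x = np.zeros((idx.n_nodes, n_sim))
    sd = np.sqrt(np.maximum(idx.blen, 0.0))
    for i in idx.preorder:
        p = idx.parent[i]
        if p >= 0:
            x[i] = x[p] + sd[i] * rng.standard_normal(n_sim)
    tips = x[: idx.n_tips]
    tips = tips + rng.uniform(0.0, 1e-12, size=tips.shape)  # deterministic tie-break
    # mark the k largest values per replicate as present
    order = np.argsort(tips, axis=0)
    binary = np.zeros_like(tips)
    if k > 0:
        top = order[idx.n_tips - k :, :]
        np.put_along_axis(binary, top, 1.0, axis=0)
    return _sister_diff_many(idx, binary)


def _prune_missing(
    tree: dendropy.Tree, trait: Mapping[str, str]
) -> tuple[dendropy.Tree | None, dict[str, int], int]:
    keep = {
        t: (1 if v == PRESENT else 0)
        for t, v in trait.items()
        if v in (PRESENT, ABSENT)
    }
    all_labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    labels = [l for l in all_labels if l in keep]
    keep = {l: keep[l] for l in labels}
    if len(labels) < 2:
        return None, keep, len(labels)
    if len(labels) == len(all_labels):
        return tree, keep, len(labels)
    pruned = tree.extract_tree_with_taxa_labels(labels, suppress_unifurcations=True)
    return pruned, keep, len(labels)


def _coerce_binary_trait(trait: Mapping[str, object]) -> dict[str, str]:
    """Accept either categorical states or 0/1/None values."""
    out: dict[str, str] = {}
    for t, v in trait.items():
        if v in (PRESENT, ABSENT, MISSING):
            out[t] = str(v)
        elif v is None or (isinstance(v, float) and np.isnan(v)):
            out[t] = MISSING
        elif v in (0, 0.0):
            out[t] = ABSENT
        elif v in (1, 1.0):
            out[t] = PRESENT
        else:
            raise ValueError(f"invalid trait value {v!r} for taxon {t!r}")
    return out


def compute_D(
    tree: dendropy.Tree,
    trait: Mapping[str, object],
    n_sim: int = 1000,
    seed: int = 0,
) -> DResult:
    """D for one binary trait on one tree, pruning missing-value tips.

    Requires at least 4 informative tips and both states present after
    pruning; otherwise the result carries an explanatory non-ok status and
    no D value.
    """
    states = _coerce_binary_trait(trait)
    pruned, keep, n_used = _prune_missing(tree, states)
    if pruned is None or n_used < 4:
        return DResult(np.nan, np.nan, np.nan, None, n_sim, STATUS_DEGENERATE, n_used)
    counts = sum(keep.values())
    if counts == 0 or counts == n_used:
        return DResult(np.nan, np.nan, np.nan, None, n_sim, STATUS_CONSTANT, n_used)
    idx = as_indexed(pruned)
    vals = _tip_values(idx, keep)
    d_obs = float(_sister_diff_many(idx, vals[:, None])[0])
    d_rand = shuffle_null(idx, keep, n_sim=n_sim, seed=seed)
    d_brown = brownian_threshold_null(idx, keep, n_sim=n_sim, seed=seed + 1)
    mean_rand = float(d_rand.mean())
    mean_brown = float(d_brown.mean())
    denom = mean_rand - mean_brown
    if abs(denom) < _DEGENERATE_TOL:
        return DResult(d_obs, mean_rand, mean_brown, None, n_sim, STATUS_DEGENERATE, n_used)
    D = (d_obs - mean_brown) / denom
    return DResult(d_obs, mean_rand, mean_brown, float(D), n_sim, STATUS_OK, n_used)


def median_D(
    posterior,
    trait: Mapping[str, object],
    n_sim: int = 1000,
    seed: int = 0,
) -> MedianD:
    """Per-tree D over a posterior sample; the summary is the median of the
    trees with a defined value."""
    results = [
        compute_D(t, trait, n_sim=n_sim, seed=seed + 1000 * k)
        for k, t in enumerate(posterior)
    ]
    ok = [r.D for r in results if r.status == STATUS_OK]
    if not ok:
        reasons = {r.status for r in results}
        return MedianD(None, results, 0, len(results), reason=",".join(sorted(reasons)))
    return MedianD(float(np.median(ok)), results, len(ok), len(results) - len(ok))
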