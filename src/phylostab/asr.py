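"""Marginal ancestral state reconstruction and reconstructability summaries.

For a fitted hidden-rates generator, the marginal probability of each hidden
state at each node integrates over the states of all other nodes: it is
proportional to the product of the postorder (down) partial and the preorder
(up) partial at that node, with the conditional-likelihood root weighting.
The observed-state probability of "present" collapses the two hidden rate
classes: p_present = P(1S) + P(1F).

The summaries then ask, per language family, how often the trait can be
placed at the family's proto-language (its most recent common ancestor) with
high certainty, and how those reconstructable features are shared across
families and distributed over catalogue categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._treeindex import IndexedTree, as_indexed
from .hmm import RateMatrix, _coerce_states, _down_pass, root_weighting
from .matrix import ABSENT, FeatureCatalog, FeatureMatrix, MISSING

__all__ = [
    "AncestralReconstruction",
    "marginal_asr",
    "family_root_presence",
    "reconstructability_summary",
    "category_normalized_reconstruction",
    "pairwise_family_overlap",
    "proto_child_distance",
]

#: The five probability bands partitioning [0, 1] for reconstructability:
#: confidently present, weakly present, uncertain, weakly absent,
#: confidently absent.
BANDS = ("p95", "p75", "uncertain", "a75", "a95")


@dataclass(frozen=True)
class AncestralReconstruction:
    """Per-node marginal hidden-state probabilities for one trait on one tree."""

    tree: IndexedTree
    node_probs: np.ndarray  # (n_nodes, 4), rows sum to 1
    log_likelihood: float
    node_loglik: np.ndarray | None = None  # per-node likelihood reconstruction
    feature: str | None = None

    @property
    def p_present(self) -> np.ndarray:
        return self.node_probs[:, 2] + self.node_probs[:, 3]

    def node_of(self, tip_labels: Sequence[str]) -> int:
        """Node index of the MRCA of a set of tips."""
        tips = {self.tree.tip_index(l) for l in tip_labels}
        return self.tree.mrca(tips)


def marginal_asr(
    tree,
    trait: Mapping[str, object],
    Q: "RateMatrix | np.ndarray",
) -> AncestralReconstruction:
    """Marginal reconstruction at every node, by a down pass and an up pass.

    At each node, marginal ∝ down-partial × up-partial, where the up partial
    of a child combines the parent's up partial with the sibling's propagated
    down partial through the child's branch.  Tips with an observed value keep
    probability 1 on the matching pair of hidden states.
    """
    idx = as_indexed(tree)
    states = _coerce_states(trait)
    G = Q.generator() if isinstance(Q, RateMatrix) else np.asarray(Q, dtype=float)
    down, logscale, prop = _down_pass(idx, states, G)
    prior, combined = root_weighting(down[idx.root])
    loglik = float(np.log(combined) + logscale[idx.root])

    up = np.empty_like(down)
    up_ls = np.zeros(idx.n_nodes)
    up[idx.root] = prior
    for i in idx.preorder:
        if i < idx.n_tips:
            continue
        c1, c2 = idx.children[i]
        s1 = prop.P[c1] @ down[c1]
        s2 = prop.P[c2] @ down[c2]
        raw1 = prop.P[c1].T @ (up[i] * s2)
        raw2 = prop.P[c2].T @ (up[i] * s1)
        m1 = max(raw1.max(), np.finfo(float).tiny)
        m2 = max(raw2.max(), np.finfo(float).tiny)
        up[c1] = raw1 / m1
        up[c2] = raw2 / m2
        up_ls[c1] = up_ls[i] + logscale[c2] + np.log(m1)
        up_ls[c2] = up_ls[i] + logscale[c1] + np.log(m2)

    probs = down * up
    total = probs.sum(axis=1, keepdims=True)
    if (total <= 0).any():
        raise ValueError("zero marginal mass at a node")
    # per-node reconstruction of the full-tree likelihood (marginal identity)
    node_loglik = np.log(total[:, 0]) + logscale + up_ls
    probs = probs / total
    return AncestralReconstruction(idx, probs, loglik, node_loglik=node_loglik)


def family_root_presence(
    asr: AncestralReconstruction,
    family: str,
    families: Mapping[str, str],
) -> float:
    """p_present at the MRCA of a family's tips in the reconstructed tree."""
    tips = [t for t in asr.tree.tip_labels if families.get(t) == family]
    if len(tips) < 2:
        raise ValueError(
            f"family {family!r} has {len(tips)} tip(s) in the tree; need >= 2"
        )
    node = asr.node_of(tips)
    return float(asr.p_present[node])


def _band(p: float, hi: float, lo_hi: float) -> str:
    # partition: [hi,1] / [lo_hi,hi) / (1-lo_hi,lo_hi)... expressed via both tails
    if p >= hi:
        return "p95"
    if p >= lo_hi:
        return "p75"
    if p <= 1.0 - hi:
        return "a95"
    if p <= 1.0 - lo_hi:
        return "a75"
    return "uncertain"


def reconstructability_summary(
    family_probs: pd.DataFrame,
    thresholds: tuple[float, float] = (0.95, 0.75),
) -> dict[str, pd.DataFrame]:
    """Reconstructability proportions per family.

    ``family_probs``: features (rows) x families (columns), each cell the
    family-root probability of "present".  Returns per-family counts and
    proportions for the five exclusive bands (confident/weak present,
    uncertain, weak/confident absent) and for the four cumulative tails
    (p >= 0.95, p >= 0.75, p <= 0.05, p <= 0.25).
    """
    hi, mid = thresholds
    if not (0.5 < mid < hi < 1.0):
        raise ValueError("thresholds must satisfy 0.5 < t2 < t1 < 1")
    bad = family_probs.to_numpy(dtype=float)
    if np.nanmin(bad) < 0 or np.nanmax(bad) > 1:
        raise ValueError("probabilities must lie in [0, 1]")

    bands = pd.DataFrame(
        {
            fam: family_probs[fam].dropna().map(lambda p: _band(p, hi, mid)).value_counts()
            for fam in family_probs.columns
        }
    ).reindex(list(BANDS)).fillna(0).astype(int)
    n = family_probs.notna().sum(axis=0)
    cumulative = pd.DataFrame(
        {
            f"p>={hi}": (family_probs >= hi).sum(axis=0),
            f"p>={mid}": (family_probs >= mid).sum(axis=0),
            f"p<={round(1-hi, 6)}": (family_probs <= 1 - hi).sum(axis=0),
            f"p<={round(1-mid, 6)}": (family_probs <= 1 - mid).sum(axis=0),
        }
    ).T
    return {
        "band_counts": bands,
        "band_proportions": bands / n,
        "cumulative_counts": cumulative.astype(int),
        "cumulative_proportions": cumulative / n,
        "n_features": n.to_frame().T,
    }


def category_normalized_reconstruction(
    family_probs: pd.DataFrame,
    catalog: FeatureCatalog,
    axis: str = "functional_category",
    threshold: float = 0.95,
) -> pd.DataFrame:
    """Per (family, category): reconstructable-feature count divided by
    category size, removing the effect of unequal category sizes."""
    catalog.check_features(list(family_probs.index))
    cats = catalog.table.loc[family_probs.index, axis]
    out = {}
    for cat, feats in family_probs.groupby(cats):
        size = len(feats)
        out[cat] = (feats >= threshold).sum(axis=0) / size
    df = pd.DataFrame(out).T
    df.index.name = axis
    return df


def pairwise_family_overlap(
    family_probs: pd.DataFrame,
    threshold: float = 0.95,
) -> pd.DataFrame:
    """Percentage of features confidently present at both families' roots.

    Cell (A, B) = 100 * |{features reconstructed present (>= threshold) at
    both A and B}| / total features.  Symmetric; the diagonal holds each
    family's own percentage.
    """
    fams = list(family_probs.columns)
    if len(fams) < 2:
        raise ValueError("need at least 2 families")
    hits = (family_probs >= threshold).to_numpy()
    n = family_probs.shape[0]
    mat = 100.0 * (hits.T.astype(float) @ hits.astype(float)) / n
    return pd.DataFrame(mat, index=fams, columns=fams)


def proto_child_distance(
    family_probs: pd.Series,
    matrix: FeatureMatrix,
    family: str,
    threshold: float = 0.95,
) -> pd.DataFrame:
    """Trait distance between a reconstructed proto-language and its children.

    Restricts to features confidently present at the family root
    (``family_probs`` indexed by feature, values = p_present at that root),
    then counts, per family member, the features observed absent (the
    distance) and the features missing (reported separately, not counted).
    """
    feats = [f for f, p in family_probs.items() if p >= threshold]
    tips = [t for t in matrix.taxa if matrix.families[t] == family]
    rows = []
    for t in tips:
        n_diff = n_missing = 0
        for f in feats:
            s = matrix.state(t, f)
            if s == ABSENT:
                n_diff += 1
            elif s == MISSING:
                n_missing += 1
        rows.append({"taxon": t, "n_differing": n_diff, "n_missing": n_missing,
                     "n_reconstructed": len(feats)})
    return pd.DataFrame(rows).set_index("taxon")
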