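"""Synthetic taxonomies, trees and trait matrices.

The generator emulates the statistical shape of a typological presence/
absence survey over a small set of language families: a five-family,
~60-tip constraint taxonomy with unresolved groupings, and a feature matrix
whose columns follow known generating regimes —

* ``ctmc``      — gain/loss evolution under a known 2- or 4-state generator
                  (exact event-time simulation, true node states retained);
* ``clumped``   — a single gain on one internal branch (all descendants
                  present), the strongest possible phylogenetic clumping;
* ``shuffled``  — a random tip subset of random size, no phylogenetic
                  structure at all;
* ``brownian_threshold`` — a thresholded Brownian character, the graded
                  clumping the D statistic is calibrated against —

with missing values injected at a configurable rate, either completely at
random or family-blocked (whole families uncodable for a feature, mimicking
per-language documentation gaps).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._treeindex import IndexedTree, as_indexed
from .hmm import RATE_MAX, RATE_MIN, RateMatrix
from .matrix import (
    DOMAINS,
    FUNCTIONAL_CATEGORIES,
    PARTS_OF_SPEECH,
    FeatureCatalog,
    FeatureMatrix,
)
from .trees import Taxonomy, TreePosterior, taxonomy_from_string

__all__ = [
    "Regime",
    "SimulationConfig",
    "make_taxonomy",
    "make_catalog",
    "clumped_trait",
    "simulate_trait",
    "simulate_matrix",
    "two_state_generator",
]

REGIME_KINDS = ("ctmc", "clumped", "shuffled", "brownian_threshold")


def two_state_generator(gain: float, loss: float) -> np.ndarray:
    """Plain 2-state generator over (absent, present)."""
    for r in (gain, loss):
        if not (RATE_MIN <= r <= RATE_MAX):
            raise ValueError(f"rate {r!r} outside [{RATE_MIN}, {RATE_MAX}]")
    return np.array([[-gain, gain], [loss, -loss]])


@dataclass(frozen=True)
class Regime:
    """Generating regime for one feature."""

    kind: str
    gain: float | None = None
    loss: float | None = None
    rates: RateMatrix | None = None  # full 4-state generator for kind="ctmc"

    def __post_init__(self) -> None:
        if self.kind not in REGIME_KINDS:
            raise ValueError(f"unknown regime kind {self.kind!r}")
        if self.kind == "ctmc" and self.rates is None:
            if self.gain is None or self.loss is None:
                raise ValueError("ctmc regime needs gain/loss or a RateMatrix")
            two_state_generator(self.gain, self.loss)  # bound check


#: Default regime mix: one quarter each of CTMC gain/loss dynamics at the
#: reference rates, single-origin clumping, pure noise, and graded
#: (Brownian) clumping.
_DEFAULT_CYCLE = (
    Regime("ctmc", gain=0.5, loss=1.0),
    Regime("clumped"),
    Regime("shuffled"),
    Regime("brownian_threshold"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped defaults: 5 families of sizes 12/2/14/11/21 (60 tips),
    ~1/10 of cells missing, polytomies on half the within-family nodes."""

    n_families: int = 5
    tips_per_family: tuple[int, ...] = (12, 2, 14, 11, 21)
    polytomy_fraction: float = 0.5
    n_features: int = 120
    regimes: tuple[Regime, ...] | None = None
    missing_rate: float = 0.1
    missing_mode: str = "mcar"  # or "family_block"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.tips_per_family) != self.n_families:
            raise ValueError("tips_per_family must list one size per family")
        if any(k < 2 for k in self.tips_per_family):
            raise ValueError("every family needs at least 2 tips")
        for p in (self.polytomy_fraction, self.missing_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.missing_mode not in ("mcar", "family_block"):
            raise ValueError(f"unknown missing mode {self.missing_mode!r}")
        if self.regimes is not None and len(self.regimes) != self.n_features:
            raise ValueError("regimes must list one regime per feature")

    def effective_regimes(self) -> tuple[Regime, ...]:
        if self.regimes is not None:
            return self.regimes
        return tuple(_DEFAULT_CYCLE[i % len(_DEFAULT_CYCLE)] for i in range(self.n_features))

    @property
    def family_names(self) -> tuple[str, ...]:
        return tuple(f"Fam{i + 1}" for i in range(self.n_families))

    def family_of(self, tip: str) -> str:
        return tip.rsplit("_", 1)[0]

    def families_map(self) -> dict[str, str]:
        out = {}
        for fam, k in zip(self.family_names, self.tips_per_family):
            for j in range(k):
                out[f"{fam}_t{j + 1:02d}"] = fam
        return out


def _family_newick(tips: list[str], rng: np.random.Generator, polytomy_fraction: float) -> str:
    """Random nested subgrouping of a family with the requested share of
    unresolved (collapsed) internal nodes."""
    if len(tips) == 1:
        return tips[0]
    # random binary join sequence, then collapse internal edges
    nodes: list[list] = [[t] for t in tips]  # nested-list tree encoding
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        merged = [nodes[i], nodes[j]]
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(merged)
    root = nodes[0]

    def collapse(node) -> list:
        """Splice a binary node into its parent with prob. polytomy_fraction."""
        if not (isinstance(node, list) and len(node) == 2):
            return [node]
        if rng.uniform() < polytomy_fraction:
            out = []
            for child in node:
                out.extend(collapse(child))
            return out
        return [node]

    def render(node) -> str:
        if isinstance(node, list) and len(node) == 1 and not isinstance(node[0], list):
            return str(node[0])
        parts = []
        for child in node:
            for piece in collapse(child):
                parts.append(render(piece))
        return "(" + ",".join(parts) + ")"

    return render(root)


def make_taxonomy(config: SimulationConfig) -> Taxonomy:
    """Constraint taxonomy: each family a (constrained) clade with nested,
    partly unresolved subgroups; families meet at an unresolved root."""
    rng = np.random.default_rng(config.seed)
    fams = []
    for fam, k in zip(config.family_names, config.tips_per_family):
        tips = [f"{fam}_t{j + 1:02d}" for j in range(k)]
        fams.append(_family_newick(tips, rng, config.polytomy_fraction))
    return taxonomy_from_string("(" + ",".join(fams) + ");")


def make_catalog(features: Sequence[str], seed: int = 0) -> FeatureCatalog:
    """Random catalogue over the closed vocabularies (synthetic stand-in for
    a hand-curated feature classification)."""
    rng = np.random.default_rng(seed)
    func = sorted(FUNCTIONAL_CATEGORIES)
    dom = sorted(DOMAINS)
    pos = sorted(PARTS_OF_SPEECH)
    table = pd.DataFrame(
        {
            "functional_category": rng.choice(func, size=len(features)),
            "domain": rng.choice(dom, size=len(features)),
            "part_of_speech": rng.choice(pos, size=len(features)),
        },
        index=list(features),
    )
    return FeatureCatalog(table)


def _simulate_branch(
    state: int, t: float, Q: np.ndarray, rng: np.random.Generator
) -> int:
    """Exact CTMC endpoint by exponential waiting times along one branch."""
    remaining = t
    k = Q.shape[0]
    while True:
        out_rate = -Q[state, state]
        if out_rate <= 0:
            return state
        wait = rng.exponential(1.0 / out_rate)
        if wait >= remaining:
            return state
        remaining -= wait
        probs = Q[state].clip(min=0.0)
        probs[state] = 0.0
        probs = probs / probs.sum()
        state = int(rng.choice(k, p=probs))


def simulate_trait(
    tree,
    Q: "RateMatrix | np.ndarray",
    root: "int | np.ndarray | None" = None,
    seed: int = 0,
) -> tuple[dict[str, int], np.ndarray]:
    """Evolve a character down the tree by exact event simulation.

    ``Q`` is either a full 4-state :class:`RateMatrix` or a plain k-state
    generator; ``root`` an initial state index or a prior to draw from
    (default: stationary distribution of ``Q``).  Returns the observed tip
    values (0/1; hidden states projected) and the true state of every node.
    """
    idx = as_indexed(tree)
    G = Q.generator() if isinstance(Q, RateMatrix) else np.asarray(Q, dtype=float)
    k = G.shape[0]
    rng = np.random.default_rng(seed)
    if root is None:
        # stationary distribution: left null vector of the generator
        w, V = np.linalg.eig(G.T)
        j = int(np.argmin(np.abs(w)))
        pi = np.real(V[:, j])
        pi = np.abs(pi) / np.abs(pi).sum()
        root_state = int(rng.choice(k, p=pi))
    elif np.ndim(root) == 0:
        root_state = int(root)
    else:
        prior = np.asarray(root, dtype=float)
        root_state = int(rng.choice(k, p=prior / prior.sum()))

    states = np.empty(idx.n_nodes, dtype=np.int64)
    states[idx.root] = root_state
    for i in idx.preorder:
        p = idx.parent[i]
        if p >= 0:
            states[i] = _simulate_branch(int(states[p]), float(idx.blen[i]), G, rng)
    present_from = k // 2  # 2-state: state 1; 4-state: {1S,1F} = indices 2,3
    tips = {
        label: int(states[i] >= present_from) for i, label in enumerate(idx.tip_labels)
    }
    return tips, states


def clumped_trait(tree, seed: int = 0) -> dict[str, int]:
    """Single-origin trait: one gain on a random internal branch."""
    return _clumped_trait(as_indexed(tree), np.random.default_rng(seed))


def _clumped_trait(idx: IndexedTree, rng: np.random.Generator) -> dict[str, int]:
    """One gain event on a random internal branch; descendants present."""
    below = idx.tipset_below()
    n = idx.n_tips
    candidates = [
        i for i in range(idx.n_tips, idx.n_nodes)
        if i != idx.root and 2 <= len(below[i]) <= n - 2
    ]
    if not candidates:  # tiny trees: fall back to a cherry-sized random pick
        candidates = [i for i in range(idx.n_tips, idx.n_nodes) if i != idx.root]
    node = int(rng.choice(candidates))
    chosen = below[node]
    return {label: int(i in chosen) for i, label in enumerate(idx.tip_labels)}


def _shuffled_trait(idx: IndexedTree, rng: np.random.Generator) -> dict[str, int]:
    n = idx.n_tips
    k = int(rng.integers(2, n - 1))
    chosen = set(rng.choice(n, size=k, replace=False).tolist())
    return {label: int(i in chosen) for i, label in enumerate(idx.tip_labels)}


def _brownian_trait(idx: IndexedTree, rng: np.random.Generator) -> dict[str, int]:
    x = np.zeros(idx.n_nodes)
    sd = np.sqrt(np.maximum(idx.blen, 0.0))
    for i in idx.preorder:
        p = idx.parent[i]
        if p >= 0:
            x[i] = x[p] + sd[i] * rng.standard_normal()
    tips = x[: idx.n_tips]
    n = idx.n_tips
    k = int(rng.integers(2, n - 1))
    order = np.argsort(tips)
    chosen = set(order[n - k :].tolist())
    return {label: int(i in chosen) for i, label in enumerate(idx.tip_labels)}


def simulate_matrix(
    config: SimulationConfig,
    posterior: TreePosterior,
    generating_tree: int = 0,
) -> tuple[FeatureMatrix, dict]:
    """Simulate a full feature matrix on one tree of the posterior.

    Returns the matrix (with missing values injected) and a ground-truth
    record: the regime and, where applicable, the generator and true node
    states of every feature.
    """
    tree = posterior[generating_tree]
    idx = as_indexed(tree)
    regimes = config.effective_regimes()
    families = config.families_map()
    for label in idx.tip_labels:
        if label not in families:
            raise ValueError(f"tree tip {label!r} not covered by the config")

    rng = np.random.default_rng(config.seed)
    features = [f"S{j + 1:03d}" for j in range(config.n_features)]
    data = np.empty((idx.n_tips, config.n_features))
    truth: dict = {"generating_tree": generating_tree, "features": {}}
    for j, (feat, regime) in enumerate(zip(features, regimes)):
        fseed = int(rng.integers(0, 2**31 - 1))
        rec: dict = {"regime": regime.kind, "seed": fseed}
        frng = np.random.default_rng(fseed)
        if regime.kind == "ctmc":
            Q = regime.rates if regime.rates is not None else two_state_generator(
                regime.gain, regime.loss
            )
            tips, states = simulate_trait(idx, Q, seed=fseed)
            rec["node_states"] = states.tolist()
            if regime.rates is not None:
                rec["rates"] = {n: getattr(regime.rates, n) for n in
                                ("gain_S", "loss_S", "gain_F", "loss_F")}
            else:
                rec["gain"], rec["loss"] = regime.gain, regime.loss
        elif regime.kind == "clumped":
            tips = _clumped_trait(idx, frng)
        elif regime.kind == "shuffled":
            tips = _shuffled_trait(idx, frng)
        else:
            tips = _brownian_trait(idx, frng)
        col = np.array([float(tips[l]) for l in idx.tip_labels])
        rec["tip_values"] = {l: tips[l] for l in idx.tip_labels}
        data[:, j] = col
        truth["features"][feat] = rec

    # missing-value injection
    mrng = np.random.default_rng(config.seed + 1)
    if config.missing_rate > 0:
        if config.missing_mode == "mcar":
            mask = mrng.uniform(size=data.shape) < config.missing_rate
        else:
            fam_labels = np.array([families[l] for l in idx.tip_labels])
            mask = np.zeros(data.shape, dtype=bool)
            for fam in config.family_names:
                rows = fam_labels == fam
                drop = mrng.uniform(size=config.n_features) < config.missing_rate
                mask[np.ix_(rows, drop)] = True
        data[mask] = np.nan

    values = pd.DataFrame(data, index=list(idx.tip_labels), columns=features)
    fam_series = pd.Series({l: families[l] for l in idx.tip_labels})
    return FeatureMatrix(values, fam_series), truth
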