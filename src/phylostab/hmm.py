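"""Hidden-rates gain/loss model for a binary trait on a tree.

The observed character (absent/present, 0/1) is expanded with an unobserved
rate class, slow (S) or fast (F), giving a 4-state continuous-time Markov
chain over {0S, 0F, 1S, 1F}.  Eight transition rates are free: gain and loss
within each class, and class switching within each observed value.
Transitions changing value and class at once are structurally zero.

The likelihood of tip data is computed by postorder pruning; the root is
treated with conditional-likelihood weighting (the root prior is proportional
to the root partials themselves), so a tree with no data has likelihood 1.
Fitting maximises the log-likelihood over the 8 rates in log space with bound
constraints and random multi-starts.

Per-feature scalar gain/loss rates are occupancy-weighted averages of the
slow- and fast-class rates, where occupancy is the mean marginal probability
of the fast class over all tips and internal nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from ._treeindex import IndexedTree, as_indexed
from .matrix import ABSENT, MISSING, PRESENT

__all__ = [
    "STATES",
    "RATE_MIN",
    "RATE_MAX",
    "RateMatrix",
    "HiddenRateFit",
    "transition_matrix",
    "pruning_loglik",
    "root_weighting",
    "fit",
    "fit_two_state",
    "summarize_rates",
    "log10_rate",
]

#: Hidden state order used for all 4-vectors and 4x4 matrices.
STATES = ("0S", "0F", "1S", "1F")
_I0S, _I0F, _I1S, _I1F = 0, 1, 2, 3

RATE_MIN = 1e-10
RATE_MAX = 100.0

RATE_NAMES = (
    "gain_S",
    "loss_S",
    "gain_F",
    "loss_F",
    "class_up_0",
    "class_down_0",
    "class_up_1",
    "class_down_1",
)


@dataclass(frozen=True)
class RateMatrix:
    """The eight free rates of the 4-state hidden-rates generator.

    gain/loss act within a rate class (0S<->1S slow, 0F<->1F fast);
    class_up/class_down switch S<->F within an observed value.  Rates are per
    unit branch length (root height 1 under the default tree calibration).
    """

    gain_S: float
    loss_S: float
    gain_F: float
    loss_F: float
    class_up_0: float
    class_down_0: float
    class_up_1: float
    class_down_1: float

    def __post_init__(self) -> None:
        for name in RATE_NAMES:
            v = getattr(self, name)
            if not (RATE_MIN <= v <= RATE_MAX):
                raise ValueError(
                    f"rate {name}={v!r} outside bounds [{RATE_MIN}, {RATE_MAX}]"
                )

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in RATE_NAMES])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "RateMatrix":
        return cls(**dict(zip(RATE_NAMES, map(float, v))))

    def generator(self) -> np.ndarray:
        """The 4x4 generator: dual (value+class) transitions are zero and the
        diagonal makes every row sum to zero."""
        Q = np.zeros((4, 4))
        Q[_I0S, _I1S] = self.gain_S
        Q[_I1S, _I0S] = self.loss_S
        Q[_I0F, _I1F] = self.gain_F
        Q[_I1F, _I0F] = self.loss_F
        Q[_I0S, _I0F] = self.class_up_0
        Q[_I0F, _I0S] = self.class_down_0
        Q[_I1S, _I1F] = self.class_up_1
        Q[_I1F, _I1S] = self.class_down_1
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q


@dataclass(frozen=True)
class HiddenRateFit:
    rates: RateMatrix
    log_likelihood: float
    n_starts: int
    converged: bool
    summary_gain: float
    summary_loss: float
    class_occupancy: float


def transition_matrix(Q: "RateMatrix | np.ndarray", t: float) -> np.ndarray:
    """P(t) = exp(Q t): probability of ending in column state after time t."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    G = Q.generator() if isinstance(Q, RateMatrix) else np.asarray(Q, dtype=float)
    P = expm(G * t)
    return np.clip(P, 0.0, 1.0)


class _Propagator:
    """All branch transition matrices for one generator, via eigendecomposition.

    The generator is shared by every branch, so one eigendecomposition gives
    P(t) = V diag(e^{wt}) V^{-1} for all branch lengths at once.  Falls back
    to scipy's expm when the eigenbasis is ill-conditioned.
    """

    def __init__(self, Q: np.ndarray, blens: np.ndarray):
        self.P = self._batch(Q, np.asarray(blens, dtype=float))

    @staticmethod
    def _batch(Q: np.ndarray, t: np.ndarray) -> np.ndarray:
        try:
            w, V = np.linalg.eig(Q)
            Vinv = np.linalg.inv(V)
            E = np.exp(np.multiply.outer(t, w))  # (n, 4)
            P = np.einsum("ij,nj,jk->nik", V, E, Vinv)
            P = np.real(P)
            err = np.abs(P.sum(axis=2) - 1.0).max()
            if not np.isfinite(P).all() or err > 1e-8 or P.min() < -1e-8:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            P = np.stack([expm(Q * ti) for ti in t])
        return np.clip(P, 0.0, 1.0)


def _tip_partial(state: str) -> np.ndarray:
    if state == PRESENT:
        return np.array([0.0, 0.0, 1.0, 1.0])
    if state == ABSENT:
        return np.array([1.0, 1.0, 0.0, 0.0])
    if state == MISSING:
        return np.ones(4)
    raise ValueError(f"invalid trait state {state!r}")


def _coerce_states(trait: Mapping[str, object]) -> dict[str, str]:
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


def _down_pass(
    idx: IndexedTree, trait: Mapping[str, str], Q: np.ndarray
) -> tuple[np.ndarray, np.ndarray, _Propagator]:
    """Scaled postorder partials.

    Returns (partials, logscale, propagator) where the true conditional
    likelihood of the data below node i given its state is
    partials[i] * exp(logscale[i]).
    """
    if not np.isfinite(idx.blen).all():
        raise ValueError("non-finite branch length")
    prop = _Propagator(Q, idx.blen)
    partials = np.empty((idx.n_nodes, 4))
    logscale = np.zeros(idx.n_nodes)
    for i, label in enumerate(idx.tip_labels):
        if label not in trait:
            raise ValueError(f"tip {label!r} has no trait value")
        partials[i] = _tip_partial(trait[label])
    for i in idx.internal_postorder:
        c1, c2 = idx.children[i]
        raw = (prop.P[c1] @ partials[c1]) * (prop.P[c2] @ partials[c2])
        m = raw.max()
        if m <= 0.0:
            raise ValueError("zero likelihood at an internal node")
        partials[i] = raw / m
        logscale[i] = np.log(m) + logscale[c1] + logscale[c2]
    return partials, logscale, prop


def root_weighting(root_partials: np.ndarray) -> tuple[np.ndarray, float]:
    """Conditional-likelihood root treatment.

    The root prior is the normalized root partial vector itself; the combined
    likelihood is the prior-weighted sum of the partials.
    """
    L = np.asarray(root_partials, dtype=float)
    if (L < 0).any():
        raise ValueError("negative root partials")
    s = L.sum()
    if s <= 0.0:
        raise ValueError("all-zero root partials")
    prior = L / s
    return prior, float(prior @ L)


def pruning_loglik(
    tree: "IndexedTree",
    trait: Mapping[str, object],
    Q: "RateMatrix | np.ndarray",
) -> float:
    """Log-likelihood of the tip data by postorder pruning.

    ``present``/``absent`` tips restrict the state to the matching pair of
    hidden states; ``missing`` tips are fully ambiguous (all four states).
    """
    idx = as_indexed(tree)
    states = _coerce_states(trait)
    G = Q.generator() if isinstance(Q, RateMatrix) else np.asarray(Q, dtype=float)
    partials, logscale, _ = _down_pass(idx, states, G)
    _, combined = root_weighting(partials[idx.root])
    return float(np.log(combined) + logscale[idx.root])


def _fit_occupancy(idx: IndexedTree, states: Mapping[str, str], rates: RateMatrix) -> float:
    # late import: asr builds on this module
    from .asr import marginal_asr

    rec = marginal_asr(idx, states, rates)
    return float(rec.node_probs[:, [_I0F, _I1F]].sum(axis=1).mean())


def summarize_rates(rates: RateMatrix, occupancy: float) -> tuple[float, float]:
    """Collapse the class-specific rates to one gain and one loss rate by
    occupancy weighting (occupancy = probability mass of the fast class)."""
    if not (0.0 <= occupancy <= 1.0):
        raise ValueError("occupancy must lie in [0, 1]")
    gain = (1.0 - occupancy) * rates.gain_S + occupancy * rates.gain_F
    loss = (1.0 - occupancy) * rates.loss_S + occupancy * rates.loss_F
    return float(gain), float(loss)


def log10_rate(rate: float) -> float:
    """log10 transform with the optimizer's lower bound as floor (0 -> -10)."""
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    return float(np.log10(max(rate, RATE_MIN)))


def _two_state_loglik(idx: IndexedTree, tipcol: np.ndarray, gain: float, loss: float) -> float:
    """Pruning log-likelihood of the collapsed 2-state ARD model.

    ``tipcol`` is (n_tips, 2): per-tip partials over (absent, present).
    """
    Q = np.array([[-gain, gain], [loss, -loss]])
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        P = np.real(np.einsum("ij,nj,jk->nik", V, np.exp(np.outer(idx.blen, w)), Vinv))
        if not np.isfinite(P).all() or np.abs(P.sum(axis=2) - 1.0).max() > 1e-8:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        P = np.stack([expm(Q * t) for t in idx.blen])
    P = np.clip(P, 0.0, 1.0)
    part = np.zeros((idx.n_nodes, 2))
    part[: idx.n_tips] = tipcol
    ls = 0.0
    for i in idx.internal_postorder:
        c1, c2 = idx.children[i]
        raw = (P[c1] @ part[c1]) * (P[c2] @ part[c2])
        m = raw.max()
        if m <= 0.0:
            return -np.inf
        part[i] = raw / m
        ls += np.log(m)
    prior, combined = root_weighting(part[idx.root])
    return float(np.log(combined) + ls)


def fit_two_state(tree, trait: Mapping[str, object]) -> tuple[float, float, float]:
    """ML fit of the collapsed 2-state ARD model: (gain, loss, log-likelihood).

    Deterministic: a small fixed grid of starting points, L-BFGS-B in log
    space with the same rate bounds as the hidden-rates model.
    """
    idx = as_indexed(tree)
    states = _coerce_states(trait)
    tipcol = np.zeros((idx.n_tips, 2))
    for i, label in enumerate(idx.tip_labels):
        s = states.get(label)
        if s is None:
            raise ValueError(f"tip {label!r} has no trait value")
        tipcol[i] = {PRESENT: (0.0, 1.0), ABSENT: (1.0, 0.0), MISSING: (1.0, 1.0)}[s]
    lo, hi = np.log(RATE_MIN), np.log(RATE_MAX)

    def nll(logv: np.ndarray) -> float:
        g, l = np.clip(np.exp(logv), RATE_MIN, RATE_MAX)
        v = _two_state_loglik(idx, tipcol, g, l)
        return 1e12 if not np.isfinite(v) else -v

    best = None
    for x0 in ([0.0, 0.0], [np.log(0.1)] * 2, [np.log(3.0)] * 2, [np.log(0.1), 0.0], [0.0, np.log(0.1)]):
        res = minimize(nll, x0, method="L-BFGS-B", bounds=[(lo, hi)] * 2)
        if best is None or res.fun < best.fun:
            best = res
    x = _snap_to_floor(nll, np.asarray(best.x, dtype=float), lo)
    g, l = np.clip(np.exp(x), RATE_MIN, RATE_MAX)
    return float(g), float(l), float(-nll(x))


#: Likelihood tolerance below which a rate is indistinguishable from zero.
_FLOOR_TOL = 1e-6


def _snap_to_floor(nll, x: np.ndarray, lo: float) -> np.ndarray:
    """Report statistically-zero rates at the lower bound.

    The likelihood is flat in a rate whose true value is zero: the optimizer
    stops at an arbitrary small value.  Any coordinate that can be moved to
    the bound at a likelihood cost below ``_FLOOR_TOL`` is pinned there, so
    zero rates are reported as zero (-10 on the log10 scale) rather than as
    optimizer noise.
    """
    base = nll(x)
    for j in range(len(x)):
        if x[j] <= lo:
            continue
        trial = x.copy()
        trial[j] = lo
        cost = nll(trial) - base
        if cost < _FLOOR_TOL:
            x = trial
            base = nll(x)
    return x


#: AIC margin for accepting the 8-rate model over the collapsed 2-rate one
#: (6 extra free parameters).
_AIC_MARGIN = 6.0

#: Class-switch rate used when embedding a tied-classes solution in the
#: 4-state space (the likelihood does not depend on it when classes are tied).
_TIED_SWITCH = 1.0


def fit(
    tree,
    trait: Mapping[str, object],
    seed: int = 0,
    n_starts: int = 5,
    select: str = "aic",
) -> HiddenRateFit:
    """Fit the hidden-rates model to one binary trait.

    Optimizes the 8-rate log-likelihood in log-rate space (L-BFGS-B, bounds
    [1e-10, 100]) from ``n_starts`` log-uniform random starting points (seeds
    derived from ``seed``) plus one start at the collapsed 2-state ML solution.

    A single binary character rarely identifies all 8 rates: the likelihood
    surface has a near-flat ridge along which the class-specific rates drift
    to extreme values at negligible likelihood gain.  With ``select="aic"``
    (default) the 8-rate solution is therefore returned only when it beats
    the collapsed 2-state ARD fit by the AIC margin for its 6 extra
    parameters; otherwise the tied-classes embedding of the 2-state ML is
    returned.  ``select="ml"`` always returns the best 8-rate solution.

    The summary gain/loss rates collapse the classes by fast-class occupancy
    (mean marginal probability of F over all nodes) per ``summarize_rates``.
    """
    if select not in ("aic", "ml"):
        raise ValueError(f"unknown selection rule {select!r}")
    idx = as_indexed(tree)
    states = _coerce_states(trait)
    n_informative = sum(1 for v in states.values() if v != MISSING)
    if n_informative < 1:
        raise ValueError("trait must have at least one non-missing tip")

    lo, hi = np.log(RATE_MIN), np.log(RATE_MAX)

    def _rates_from(logv: np.ndarray) -> RateMatrix:
        # clip in rate space too: exp(log(bound)) can land just outside
        return RateMatrix.from_vector(np.clip(np.exp(logv), RATE_MIN, RATE_MAX))

    def negloglik(logv: np.ndarray) -> float:
        Q = _rates_from(logv)
        try:
            return -pruning_loglik(idx, states, Q)
        except (ValueError, np.linalg.LinAlgError):
            return 1e12

    g2, l2, ll2 = fit_two_state(idx, states)
    tied = np.log(np.clip(
        [g2, l2, g2, l2, _TIED_SWITCH, _TIED_SWITCH, _TIED_SWITCH, _TIED_SWITCH],
        RATE_MIN, RATE_MAX,
    ))

    rng = np.random.default_rng(seed)
    starts = [tied] + [
        rng.uniform(np.log(1e-3), np.log(10.0), size=8) for _ in range(max(1, n_starts))
    ]
    best = None
    any_converged = False
    for x0 in starts:
        res = minimize(
            negloglik,
            x0,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * 8,
            options={"maxiter": 500},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    use_full = select == "ml" or (-best.fun) - ll2 > _AIC_MARGIN
    if use_full:
        x = _snap_to_floor(negloglik, np.asarray(best.x, dtype=float), lo)
        rates = _rates_from(x)
        loglik = float(-negloglik(x))
    else:
        rates = RateMatrix(
            gain_S=max(g2, RATE_MIN), loss_S=max(l2, RATE_MIN),
            gain_F=max(g2, RATE_MIN), loss_F=max(l2, RATE_MIN),
            class_up_0=_TIED_SWITCH, class_down_0=_TIED_SWITCH,
            class_up_1=_TIED_SWITCH, class_down_1=_TIED_SWITCH,
        )
        loglik = float(ll2)
    occupancy = _fit_occupancy(idx, states, rates)
    gain, loss = summarize_rates(rates, occupancy)
    return HiddenRateFit(
        rates=rates,
        log_likelihood=loglik,
        n_starts=max(1, n_starts),
        converged=any_converged,
        summary_gain=gain,
        summary_loss=loss,
        class_occupancy=occupancy,
    )
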