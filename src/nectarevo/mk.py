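"""Mk models, ancestral states, and stochastic character mapping.

Discrete-trait evolution on a rooted time tree follows a continuous-time
Markov chain with generator Q (off-diagonal rates q_ij >= 0, rows sum to
zero).  This module provides:

* the pruning (Felsenstein) log-likelihood, underflow-rescaled so trees
  of 10^4 tips are safe;
* maximum-likelihood fitting of ER / SYM / ARD rate constraints with
  bounded, log-parameterized, multi-start optimization;
* marginal ancestral state probabilities (above/below partials);
* stochastic character maps: joint node-state sampling followed by
  endpoint-conditioned branch histories via uniformization (exact; no
  rejection pathologies on long branches);
* ensemble summaries — transition counts and per-branch posterior state
  densities on a time grid.

States are integers 0..k-1 throughout; binary traits use 0 = absent,
1 = present, so a "gain" is a 0->1 transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.linalg import expm
from scipy.optimize import minimize

from .treeio import PhyloTree, node_ages

__all__ = [
    "MkFit",
    "SimmapRealization",
    "SimmapEnsemble",
    "TransitionCounts",
    "build_q",
    "stationary_distribution",
    "mk_loglik",
    "mk_fit",
    "select_model",
    "marginal_states",
    "sample_simmaps",
    "count_transitions",
    "posterior_density",
]

RATE_LO, RATE_HI = 1e-9, 1e3


# -- model construction --------------------------------------------------


def build_q(rates: np.ndarray, k: int, model: str = "ER") -> np.ndarray:
    """Generator matrix from a free-rate vector under a constraint class.

    ER: one rate for every transition.  SYM: one rate per unordered pair.
    ARD: one rate per ordered pair (row-major order of off-diagonals).
    """
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    Q = np.zeros((k, k))
    if model == "ER":
        Q[:] = rates[0]
    elif model == "SYM":
        idx = 0
        for i in range(k):
            for j in range(i + 1, k):
                Q[i, j] = Q[j, i] = rates[idx]
                idx += 1
    elif model == "ARD":
        idx = 0
        for i in range(k):
            for j in range(k):
                if i != j:
                    Q[i, j] = rates[idx]
                    idx += 1
    else:
        raise ValueError(f"unknown model {model!r}")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def n_free_rates(k: int, model: str) -> int:
    return {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[model]


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution pi with pi Q = 0; uniform if Q is ~zero."""
    k = Q.shape[0]
    if np.abs(Q).max() < 1e-300:
        return np.full(k, 1.0 / k)
    A = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()


def _resolve_root_prior(root_prior, Q, fitzjohn_weights=None) -> np.ndarray:
    k = Q.shape[0]
    if isinstance(root_prior, str):
        if root_prior == "stationary":
            return stationary_distribution(Q)
        if root_prior == "flat":
            return np.full(k, 1.0 / k)
        if root_prior == "fitzjohn":
            if fitzjohn_weights is None:
                raise ValueError("fitzjohn prior needs root partials")
            w = np.asarray(fitzjohn_weights, dtype=float)
            s = w.sum()
            return w / s if s > 0 else np.full(k, 1.0 / k)
        raise ValueError(f"unknown root prior {root_prior!r}")
    pi = np.asarray(root_prior, dtype=float)
    return pi / pi.sum()


# -- pruning likelihood --------------------------------------------------


def tip_partials(tree: PhyloTree, tip_states, k: int) -> np.ndarray:
    """(n_tips, k) likelihood array from a species->state mapping.

    ``tip_states`` may be a dict keyed by tip label, or an array in tip
    order.  A state of -1 (or missing key) is treated as ambiguous.
    """
    L = np.zeros((tree.n_tips, k))
    if isinstance(tip_states, dict):
        for i, lab in enumerate(tree.tip_labels):
            if lab not in tip_states:
                raise ValueError(f"tip {lab!r} has no state")
            s = tip_states[lab]
            if s == -1:
                L[i, :] = 1.0
            else:
                L[i, int(s)] = 1.0
    else:
        arr = np.asarray(tip_states)
        if arr.ndim == 2:  # already a partial-likelihood matrix
            if arr.shape != (tree.n_tips, k):
                raise ValueError("partial matrix has wrong shape")
            return arr.astype(float)
        if len(arr) != tree.n_tips:
            raise ValueError("tip state vector length mismatch")
        for i, s in enumerate(arr):
            if s == -1:
                L[i, :] = 1.0
            else:
                L[i, int(s)] = 1.0
    return L


def _branch_pmats(tree: PhyloTree, Q: np.ndarray) -> np.ndarray:
    """P(t_v) = expm(Q t_v) for the branch above every node (root: I).

    Computed in one shot through the eigendecomposition of Q (validated
    against expm on the longest branch; falls back to per-branch expm
    for defective or ill-conditioned generators).
    """
    k = Q.shape[0]
    ts = np.where(tree.parent >= 0, tree.lengths, 0.0)
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        P = np.real(np.einsum("ij,nj,jk->nik", V, np.exp(np.outer(ts, w)), Vinv))
        vmax = int(np.argmax(ts))
        if ts[vmax] > 0 and np.max(np.abs(P[vmax] - expm(Q * ts[vmax]))) > 1e-10:
            raise np.linalg.LinAlgError("eigendecomposition inaccurate")
        if P.min() < -1e-10:
            raise np.linalg.LinAlgError("negative transition probability")
        return np.clip(P, 0.0, None)
    except np.linalg.LinAlgError:
        P = np.empty((tree.n_nodes, k, k))
        cache: dict[float, np.ndarray] = {}
        for v in range(tree.n_nodes):
            t = float(ts[v])
            if t not in cache:
                cache[t] = np.eye(k) if t == 0.0 else expm(Q * t)
            P[v] = cache[t]
        return P


@njit(cache=True)
def _prune_kernel(post, child_ptr, child_idx, P, partials):
    """Post-order conditional likelihoods with per-node max rescaling.

    Returns (F, total_log_scale); total is -inf on a zero likelihood.
    """
    n_nodes = post.shape[0]
    k = partials.shape[1]
    F = np.zeros((n_nodes, k))
    total = 0.0
    for ii in range(n_nodes):
        v = post[ii]
        lo, hi = child_ptr[v], child_ptr[v + 1]
        if lo == hi:  # tip
            for s in range(k):
                F[v, s] = partials[v, s]
            continue
        acc = np.ones(k)
        for ci in range(lo, hi):
            c = child_idx[ci]
            for i in range(k):
                s = 0.0
                for j in range(k):
                    s += P[c, i, j] * F[c, j]
                acc[i] *= s
        m = 0.0
        for i in range(k):
            if acc[i] > m:
                m = acc[i]
        if m <= 0.0:
            return F, -np.inf
        for i in range(k):
            F[v, i] = acc[i] / m
        total += np.log(m)
    return F, total


def _children_csr(tree: PhyloTree):
    cached = getattr(tree, "_ctmc_csr", None)
    if cached is not None:
        return cached
    ch = tree.children_map()
    ptr = np.zeros(tree.n_nodes + 1, dtype=np.int64)
    for v in range(tree.n_nodes):
        ptr[v + 1] = ptr[v] + len(ch[v])
    idx = np.empty(ptr[-1], dtype=np.int64)
    for v in range(tree.n_nodes):
        idx[ptr[v]:ptr[v + 1]] = ch[v]
    tree._ctmc_csr = (ptr, idx)
    return ptr, idx


def _down_partials(tree: PhyloTree, partials: np.ndarray, P: np.ndarray):
    """Conditional likelihoods of data below each node, plus the summed
    log-scalers (a scalar; every node's rescaling reaches the root)."""
    ptr, idx = _children_csr(tree)
    F, total = _prune_kernel(tree.postorder(), ptr, idx,
                             np.ascontiguousarray(P), np.ascontiguousarray(partials))
    if not np.isfinite(total):
        raise FloatingPointError("zero likelihood at an internal node")
    return F, total


def mk_loglik(tree: PhyloTree, tip_states, Q: np.ndarray, root_prior="stationary") -> float:
    """Pruning log-likelihood of discrete tip data under generator Q."""
    k = Q.shape[0]
    partials = tip_partials(tree, tip_states, k)
    P = _branch_pmats(tree, Q)
    F, logscale = _down_partials(tree, partials, P)
    r = tree.root
    pi = _resolve_root_prior(root_prior, Q, fitzjohn_weights=F[r])
    lik = float(pi @ F[r])
    if lik <= 0:
        return -np.inf
    return np.log(lik) + logscale


# -- fitting -------------------------------------------------------------


@dataclass
class MkFit:
    model: str
    Q: np.ndarray
    rates: np.ndarray
    lnL: float
    k_params: int
    root_prior: str = "stationary"

    @property
    def AIC(self) -> float:
        return 2 * self.k_params - 2 * self.lnL


def mk_fit(
    tree: PhyloTree,
    tip_states,
    model_class: str = "ER",
    k: int = 2,
    root_prior: str = "stationary",
    n_starts: int = 3,
    seed: int = 0,
) -> MkFit:
    """Maximum-likelihood Mk rates, bounded in [1e-9, 1e3] per My.

    Optimization is over log-rates with multiple perturbed starts; the
    starting scale is (state changes needed / total branch length)-ish,
    i.e. 1 / tree height.
    """
    if tree.n_tips < 2:
        raise ValueError("need at least 2 tips")
    npar = n_free_rates(k, model_class)
    partials = tip_partials(tree, tip_states, k)
    rng = np.random.default_rng(seed)

    def nll(logr):
        Q = build_q(np.exp(logr), k, model_class)
        try:
            ll = mk_loglik(tree, partials, Q, root_prior)
        except FloatingPointError:
            return 1e10
        return 1e10 if not np.isfinite(ll) else -ll

    h = max(tree.height, 1e-6)
    base = np.log(1.0 / h)
    best = None
    bounds = [(np.log(RATE_LO), np.log(RATE_HI))] * npar
    for s in range(n_starts):
        x0 = np.full(npar, base) + (rng.normal(0, 1.0, npar) if s else 0.0)
        x0 = np.clip(x0, bounds[0][0], bounds[0][1])
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("Mk optimization failed to converge")
    rates = np.exp(best.x)
    return MkFit(
        model=model_class,
        Q=build_q(rates, k, model_class),
        rates=rates,
        lnL=-best.fun,
        k_params=npar,
        root_prior=root_prior,
    )


def select_model(fits: list[MkFit]) -> MkFit:
    """Minimum-AIC fit; AIC ties broken toward fewer parameters."""
    if not fits:
        raise ValueError("no fits to select from")
    return min(fits, key=lambda f: (round(f.AIC, 10), f.k_params))


# -- marginal ancestral states ------------------------------------------


def marginal_states(tree: PhyloTree, tip_states, Q: np.ndarray, root_prior="stationary") -> np.ndarray:
    """(n_nodes, k) marginal posterior state probabilities.

    Combines below-partials F with above-partials G (likelihood of the
    rest of the tree given the state at the node); rows sum to 1.
    """
    k = Q.shape[0]
    partials = tip_partials(tree, tip_states, k)
    P = _branch_pmats(tree, Q)
    F, _ = _down_partials(tree, partials, P)
    r = tree.root
    pi = _resolve_root_prior(root_prior, Q, fitzjohn_weights=F[r])
    G = np.zeros((tree.n_nodes, k))
    G[r] = pi
    ch = tree.children_map()
    for v in tree.preorder():
        kids = ch[v]
        down = {c: P[c] @ F[c] for c in kids}
        for c in kids:
            sib = np.ones(k)
            for s in kids:
                if s != c:
                    sib = sib * down[s]
            g = (G[v] * sib) @ P[c]
            m = g.max()
            G[c] = g / m if m > 0 else g
    M = G * F
    M /= M.sum(axis=1, keepdims=True)
    return M


# -- stochastic character maps ------------------------------------------


@dataclass
class SimmapRealization:
    """One sampled character history.

    ``node_states[v]`` is the state at node v; ``segments[v]`` paints the
    branch above v as ordered (state, duration) pairs from the parent end
    to the node end (empty list at the root).  Durations on a branch sum
    to its length and adjacent segments differ in state.
    """

    node_states: np.ndarray
    segments: list[list[tuple[int, float]]]


@dataclass
class SimmapEnsemble:
    tree: PhyloTree
    realizations: list[SimmapRealization]
    states: int
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.realizations)


def _pick(rng, w) -> int:
    """Draw an index from unnormalized weights (cumsum inversion)."""
    c = np.cumsum(w)
    return int(np.searchsorted(c, rng.random() * c[-1], side="right"))


def _sample_branch_history(rng, Q, R, omega, Pt, t, a, b, max_jumps=100000):
    """Endpoint-conditioned CTMC path on one branch via uniformization."""
    if t <= 0.0 or omega <= 0.0:
        if a != b:
            raise ValueError("impossible history: discordant endpoints with no rate")
        return [(int(b), float(t))]
    p_ab = Pt[a, b]
    if p_ab <= 0:
        raise ValueError("impossible history: zero transition probability")
    if omega * t > 2e4:
        raise ValueError(
            f"rate saturation (omega*t = {omega * t:.0f}): history sampling "
            "would need too many uniformized jumps; refit with bounded rates")
    # number of uniformized jumps n ~ Poisson(omega t) weighted by R^n[a,b]
    u = rng.random()
    log_pois = -omega * t
    Rpow = [np.eye(Q.shape[0])]
    cum = np.exp(log_pois) * Rpow[0][a, b] / p_ab
    n = 0
    while cum < u and n < max_jumps:
        n += 1
        log_pois += np.log(omega * t) - np.log(n)
        Rpow.append(Rpow[-1] @ R)
        cum += np.exp(log_pois) * Rpow[n][a, b] / p_ab
    if n == 0:
        return [(int(b), float(t))]
    # jump chain states conditioned on endpoints
    states = [a]
    cur = a
    for m in range(1, n):
        w = R[cur, :] * Rpow[n - m][:, b]
        cur = _pick(rng, w)
        states.append(cur)
    states.append(b)
    times = np.sort(rng.random(n)) * t
    # collapse virtual (self) jumps into segments
    segs: list[tuple[int, float]] = []
    prev_t = 0.0
    for m in range(1, n + 1):
        if states[m] != states[m - 1]:
            segs.append((int(states[m - 1]), float(times[m - 1] - prev_t)))
            prev_t = float(times[m - 1])
    segs.append((int(states[-1]), float(t - prev_t)))
    return segs


def sample_simmaps(
    tree: PhyloTree,
    tip_states,
    Q: np.ndarray,
    n: int = 100,
    root_prior="stationary",
    seed: int = 0,
) -> SimmapEnsemble:
    """Draw n stochastic character maps in proportion to their posterior.

    Node states are sampled jointly (root from pi*F, then pre-order
    child-given-parent); branch interiors are endpoint-conditioned via
    uniformization.  Tip ambiguity (state -1) is resolved by sampling.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    k = Q.shape[0]
    partials = tip_partials(tree, tip_states, k)
    P = _branch_pmats(tree, Q)
    F, _ = _down_partials(tree, partials, P)
    r = tree.root
    pi = _resolve_root_prior(root_prior, Q, fitzjohn_weights=F[r])
    rng = np.random.default_rng(seed)
    omega = float(np.max(-np.diag(Q)))
    R = np.eye(k) + Q / omega if omega > 0 else np.eye(k)
    pre = tree.preorder()
    reals: list[SimmapRealization] = []
    root_w = pi * F[r]
    if root_w.sum() <= 0:
        raise ValueError("data have zero likelihood under this model")
    root_w = root_w / root_w.sum()
    for _ in range(n):
        node_states = np.zeros(tree.n_nodes, dtype=np.int64)
        node_states[r] = _pick(rng, root_w)
        segments: list[list[tuple[int, float]]] = [[] for _ in range(tree.n_nodes)]
        for v in pre:
            if v == r:
                continue
            p = tree.parent[v]
            w = P[v][node_states[p], :] * F[v]
            node_states[v] = _pick(rng, w)
            segments[v] = _sample_branch_history(
                rng, Q, R, omega, P[v], float(tree.lengths[v]),
                int(node_states[p]), int(node_states[v]),
            )
        reals.append(SimmapRealization(node_states, segments))
    return SimmapEnsemble(tree=tree, realizations=reals, states=k, seed=seed)


# -- ensemble summaries --------------------------------------------------


@dataclass
class TransitionCounts:
    """Per-realization ordered transition counts and ensemble means."""

    per_realization: np.ndarray  # (n, k, k) integer counts
    mean_matrix: np.ndarray = field(init=False)

    def __post_init__(self):
        self.mean_matrix = self.per_realization.mean(axis=0)

    @property
    def gains(self) -> np.ndarray:
        return self.per_realization[:, 0, 1]

    @property
    def losses(self) -> np.ndarray:
        return self.per_realization[:, 1, 0]

    @property
    def mean_gains(self) -> float:
        return float(self.gains.mean())

    @property
    def mean_losses(self) -> float:
        return float(self.losses.mean())

    def percent_of_changes(self) -> tuple[float, float]:
        """Mean gains and losses as percent of total state changes."""
        tot = self.mean_gains + self.mean_losses
        if tot == 0:
            return 0.0, 0.0
        return 100 * self.mean_gains / tot, 100 * self.mean_losses / tot


def count_transitions(ensemble: SimmapEnsemble) -> TransitionCounts:
    """Tally ordered state changes (segment boundaries) per realization."""
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    k = ensemble.states
    counts = np.zeros((len(ensemble), k, k), dtype=np.int64)
    for idx, real in enumerate(ensemble.realizations):
        for segs in real.segments:
            for (s1, _), (s2, _) in zip(segs, segs[1:]):
                counts[idx, s1, s2] += 1
    return TransitionCounts(counts)


def state_at_age(real: SimmapRealization, tree: PhyloTree, ages: np.ndarray, node: int, age: float) -> int:
    """State painted on the branch above ``node`` at a given age."""
    p = tree.parent[node]
    if p < 0:
        return int(real.node_states[node])
    top, bot = ages[p], ages[node]
    if not (bot - 1e-9 <= age <= top + 1e-9):
        raise ValueError("age outside branch span")
    elapsed = top - age
    acc = 0.0
    for s, d in real.segments[node]:
        acc += d
        if elapsed <= acc + 1e-12:
            return int(s)
    return int(real.segments[node][-1][0])


def posterior_density(ensemble: SimmapEnsemble, n_grid: int = 64) -> dict[int, pd.DataFrame]:
    """Per-branch state frequencies across the ensemble on an age grid.

    Returns {node: DataFrame(age, p_state0 .. p_state{k-1})} for every
    non-root node; each row's probabilities sum to 1.
    """
    tree = ensemble.tree
    ages = node_ages(tree)
    k = ensemble.states
    out: dict[int, pd.DataFrame] = {}
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0:
            continue
        top, bot = ages[p], ages[v]
        if top - bot <= 0:
            grid = np.array([bot])
        else:
            grid = np.linspace(bot, top, n_grid)
        freq = np.zeros((len(grid), k))
        for real in ensemble.realizations:
            for gi, age in enumerate(grid):
                freq[gi, state_at_age(real, tree, ages, v, age)] += 1
        freq /= len(ensemble)
        df = pd.DataFrame(freq, columns=[f"p_state{s}" for s in range(k)])
        df.insert(0, "age", grid)
        out[v] = df
    return out


# -- serialization -------------------------------------------------------


def ensemble_to_frame(ensemble: SimmapEnsemble) -> pd.DataFrame:
    """Long-format table: realization, branch (child node), segment, state, duration."""
    rows = []
    for ri, real in enumerate(ensemble.realizations):
        for v, segs in enumerate(real.segments):
            for si, (s, d) in enumerate(segs):
                rows.append((ri, v, si, s, d))
    return pd.DataFrame(rows, columns=["realization", "branch", "segment", "state", "duration"])


def simmap_newick(real: SimmapRealization, tree: PhyloTree) -> str:
    """phytools-style simmap newick; segments listed root-to-tip."""

    def paint(v: int) -> str:
        segs = real.segments[v]
        body = ":".join(f"{s},{d:.8g}" for s, d in segs)
        return "{" + body + "}"

    def rec(v: int) -> str:
        ch = tree.children(v)
        if not ch:
            base = tree.tip_labels[v]
        else:
            base = "(" + ",".join(rec(c) for c in ch) + ")"
        if tree.parent[v] >= 0:
            base += ":" + paint(v)
        return base

    return rec(tree.root) + ";"
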