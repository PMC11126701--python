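"""Stepwise-AICc diversification rate shifts, gain proximity, shift windows.

The shift detector follows the MEDUSA recipe: fit a single birth-death
process to the whole time tree, then greedily add rate shifts at nodes,
refitting the affected partitions, while the AICc improves by more than
a stopping threshold.  Per-partition likelihood is branch-decomposable:

* every split contributes log(lambda);
* every internal branch from age t_top to t_bot contributes
  log Psi(t_top) - log Psi(t_bot), where
  log Psi(t) = -r t + 2 log(1 - eps) - 2 log(1 - eps e^(-r t))
  is the probability a lineage at age t leaves exactly one reconstructed
  descendant (r = lambda - mu, eps = mu / lambda);
* a terminal branch carrying an unresolved clade of described richness n
  (stem age t) contributes log P(N = n | t), the geometric-tailed
  birth-death count distribution — with n = 1 this is the ordinary
  fully-sampled contribution, so a richness table of all ones changes
  nothing.

A partition whose extinction fraction collapses (eps < 1e-4) is reported
as Yule with one parameter.  Shift ages feed a four-node gain-proximity
match (a diversification shift "follows" a trait gain if it sits within
four parent-to-child steps below the gain node) and a sliding-window
bootstrap of shift times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .treeio import PhyloTree, node_ages

__all__ = [
    "MedusaFit",
    "ShiftRecord",
    "medusa_fit",
    "four_node_match",
    "sliding_window_bootstrap",
    "partition_loglik",
]

EPS_YULE = 1e-4


def _log_psi(t, r, eps):
    """log prob. of exactly one reconstructed descendant after time t."""
    t = np.asarray(t, dtype=float)
    return -r * t + 2 * np.log1p(-eps) - 2 * np.log1p(-eps * np.exp(-r * t))


def _log_richness(n, t, r, eps):
    """log P(N = n | stem age t) under birth-death (geometric tail)."""
    if t <= 0:
        return 0.0 if n == 1 else -np.inf
    lam = r / (1.0 - eps)
    lnD = np.log(lam) + r * t + np.log1p(-eps * np.exp(-r * t))
    ln1ma = r * t + np.log(lam) + np.log1p(-eps) - lnD
    ln1mb = np.log(lam) + np.log1p(-eps) - lnD
    out = ln1ma + ln1mb
    if n > 1:
        lnb = np.log(lam) + r * t + np.log1p(-np.exp(-r * t)) - lnD
        out += (n - 1) * lnb
    return out


@dataclass
class _Pieces:
    """Likelihood pieces of one partition."""

    split_ages: np.ndarray          # ages of splits (internal nodes)
    internal_spans: np.ndarray      # (m, 2) [t_top, t_bot] internal branches
    tip_stems: np.ndarray           # stem ages of terminal branches
    tip_richness: np.ndarray        # described richness per terminal branch

    @property
    def n_obs(self) -> int:
        return len(self.split_ages) + len(self.tip_stems)


def partition_loglik(pieces: _Pieces, r: float, eps: float) -> float:
    if r <= 0 or not 0 <= eps < 1:
        return -np.inf
    lam = r / (1.0 - eps)
    ll = len(pieces.split_ages) * np.log(lam)
    if len(pieces.internal_spans):
        tt, tb = pieces.internal_spans[:, 0], pieces.internal_spans[:, 1]
        ll += float(np.sum(_log_psi(tt, r, eps) - _log_psi(tb, r, eps)))
    t = pieces.tip_stems
    n = pieces.tip_richness
    if len(t):
        pos = t > 0
        if np.any(~pos & (n > 1)):
            return -np.inf
        tp, npos = t[pos], n[pos]
        with np.errstate(divide="ignore"):
            lnD = np.log(lam) + r * tp + np.log1p(-eps * np.exp(-r * tp))
            ln1ma = r * tp + np.log(lam) + np.log1p(-eps) - lnD
            ln1mb = np.log(lam) + np.log1p(-eps) - lnD
            contrib = ln1ma + ln1mb
            many = npos > 1
            if np.any(many):
                lnb = np.log(lam) + r * tp[many] + np.log1p(-np.exp(-r * tp[many])) - lnD[many]
                contrib[many] += (npos[many] - 1) * lnb
        ll += float(contrib.sum())
    return float(ll)


def _fit_partition(pieces: _Pieces):
    """MLE (r, eps); returns (r, eps, lnL, k) with Yule fallback."""
    total_time = pieces.internal_spans[:, 0].sum() - pieces.internal_spans[:, 1].sum() \
        if len(pieces.internal_spans) else 0.0
    total_time += pieces.tip_stems.sum()
    n_split = max(len(pieces.split_ages), 1)
    r0 = max(n_split / max(total_time, 1e-9), 1e-6)

    def nll(x):
        r = np.exp(x[0])
        eps = 1.0 / (1.0 + np.exp(-x[1]))
        ll = partition_loglik(pieces, r, eps * 0.999)
        return 1e10 if not np.isfinite(ll) else -ll

    best = None
    for e0 in (-4.0, 0.0):
        res = minimize(nll, np.array([np.log(r0), e0]), method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 800})
        if best is None or res.fun < best.fun:
            best = res
    r = float(np.exp(best.x[0]))
    eps = float(0.999 / (1.0 + np.exp(-best.x[1])))
    lnl = -best.fun
    if eps < EPS_YULE:
        # Yule: 1-D refit with eps pinned to 0
        res = minimize(lambda x: -partition_loglik(pieces, np.exp(x[0]), 0.0)
                       if np.isfinite(partition_loglik(pieces, np.exp(x[0]), 0.0)) else 1e10,
                       np.array([np.log(r0)]), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        return float(np.exp(res.x[0])), 0.0, float(-res.fun), 1
    return r, eps, float(lnl), 2


@dataclass
class ShiftRecord:
    node: int
    age: float
    r: float
    eps: float
    dAICc: float


@dataclass
class MedusaFit:
    shifts: list[ShiftRecord]
    background: dict[str, float]
    aicc_path: list[float]
    threshold: float
    partition_of: np.ndarray  # node -> partition id (0 = background)

    @property
    def shift_ages(self) -> np.ndarray:
        return np.array([s.age for s in self.shifts])


def _aicc(lnl: float, k: int, n: int) -> float:
    aic = 2 * k - 2 * lnl
    if n - k - 1 <= 0:
        return np.inf
    return aic + 2 * k * (k + 1) / (n - k - 1)


def _pieces_for(tree, ages, richness_arr, nodes: set[int]) -> _Pieces:
    splits, spans, stems, rich = [], [], [], []
    for v in nodes:
        if not tree.is_tip(v):
            splits.append(ages[v])
        p = tree.parent[v]
        if p >= 0:
            if tree.is_tip(v):
                stems.append(ages[p])
                rich.append(richness_arr[v])
            else:
                spans.append((ages[p], ages[v]))
    return _Pieces(np.array(splits), np.array(spans).reshape(-1, 2),
                   np.array(stems), np.array(rich))


def medusa_fit(
    tree: PhyloTree,
    richness: dict[str, int] | None = None,
    max_shifts: int = 5,
    threshold: float = 4.0,
) -> MedusaFit:
    """Greedy stepwise AICc placement of diversification rate shifts.

    ``richness`` maps tip labels to described species richness of the
    clade each tip stands for (default 1 = fully sampled).  Candidate
    shift nodes are internal nodes plus tips with richness > 1; a shift
    claims the candidate's branch and everything below it that is not
    already inside a nested shift.  Ties on AICc go to the older node.
    """
    if tree.n_tips < 3:
        raise ValueError("need at least 3 tips")
    ages = node_ages(tree)
    richness_arr = np.ones(tree.n_tips, dtype=np.int64)
    if richness:
        for lab, n in richness.items():
            if n < 1:
                raise ValueError(f"richness < 1 for {lab!r}")
            richness_arr[tree.tip_index()[lab]] = int(n)

    part_of = np.zeros(tree.n_nodes, dtype=np.int64)
    n_obs = (tree.n_nodes - tree.n_tips) + tree.n_tips  # splits + richness entries

    def subtree_nodes(v):
        out, stack = [], [v]
        ch = tree.children_map()
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(ch[u])
        return out

    # initial single-partition fit
    part_fit: dict[int, tuple[float, float, float, int]] = {}
    part_fit[0] = _fit_partition(_pieces_for(tree, ages, richness_arr, set(range(tree.n_nodes))))

    def total_aicc(fits, n_shifts):
        lnl = sum(f[2] for f in fits.values())
        k = sum(f[3] for f in fits.values()) + n_shifts
        return _aicc(lnl, k, n_obs)

    shifts: list[ShiftRecord] = []
    aicc_path = [total_aicc(part_fit, 0)]
    candidates = [v for v in range(tree.n_nodes)
                  if (not tree.is_tip(v) and v != tree.root) or
                     (tree.is_tip(v) and richness_arr[v] > 1)]

    while len(shifts) < max_shifts:
        current = aicc_path[-1]
        best = None  # (aicc, -age, node, new_fits, members)
        for v in candidates:
            if any(s.node == v for s in shifts):
                continue
            src = part_of[v]
            members = [u for u in subtree_nodes(v) if part_of[u] == src]
            if len(members) < 3:
                continue
            member_set = set(members)
            remaining = [u for u in np.flatnonzero(part_of == src) if u not in member_set]
            if sum(1 for u in remaining if not tree.is_tip(u)) < 1:
                continue
            fit_new = _fit_partition(_pieces_for(tree, ages, richness_arr, set(members)))
            fit_rem = _fit_partition(_pieces_for(tree, ages, richness_arr, set(remaining)))
            trial = dict(part_fit)
            new_id = len(shifts) + 1
            trial[new_id] = fit_new
            trial[src] = fit_rem
            a = total_aicc(trial, len(shifts) + 1)
            key = (a, -ages[v])
            if best is None or key < best[0]:
                best = (key, v, trial, members, new_id, fit_new)
        if best is None:
            break
        (a, _), v, trial, members, new_id, fit_new = best
        if current - a < threshold:
            break
        part_fit = trial
        part_of[members] = new_id
        shifts.append(ShiftRecord(v, float(ages[v] if not tree.is_tip(v) else ages[tree.parent[v]]),
                                  fit_new[0], fit_new[1], float(current - a)))
        aicc_path.append(a)

    bg = part_fit[0]
    return MedusaFit(shifts, {"r": bg[0], "eps": bg[1], "lnL": bg[2], "k": bg[3]},
                     aicc_path, threshold, part_of)


# -- gain proximity ------------------------------------------------------


def four_node_match(gain_nodes, shift_nodes, tree: PhyloTree, max_steps: int = 4):
    """Match diversification shifts to trait gains within N descent steps.

    Returns ({gain_node: sorted matched shift nodes}, unmatched shifts).
    The gain node itself counts as step 0.
    """
    gain_nodes = set(int(v) for v in gain_nodes)
    shift_nodes = set(int(v) for v in shift_nodes)
    for v in gain_nodes | shift_nodes:
        if not 0 <= v < tree.n_nodes:
            raise ValueError(f"node {v} not in tree")
    ch = tree.children_map()
    matches: dict[int, list[int]] = {}
    matched_shifts: set[int] = set()
    for g in sorted(gain_nodes):
        frontier = {g}
        within = {g}
        for _ in range(max_steps):
            frontier = {c for v in frontier for c in ch[v]}
            within |= frontier
        hits = sorted(within & shift_nodes)
        matches[g] = hits
        matched_shifts.update(hits)
    return matches, sorted(shift_nodes - matched_shifts)


# -- sliding-window bootstrap -------------------------------------------


def sliding_window_bootstrap(
    times,
    window_sizes=(10, 20, 30, 40, 50, 60, 70, 80, 90, 100),
    step_sizes=(5, 10, 15, 20, 25, 30, 35, 40, 45, 50),
    n_boot: int = 1000,
    seed: int = 0,
    t_max: float | None = None,
    pair_elementwise: bool = True,
) -> pd.DataFrame:
    """Bin shift ages in half-open sliding windows with a bootstrap band.

    Window and step lists are paired element-wise by default (10<->5,
    20<->10, ... giving 50% overlap); ``pair_elementwise=False`` takes
    the full cross-product.  Bins are [start, start + w) in My BP,
    descending from ``t_max`` (default: oldest shift age) toward 0.
    Each bootstrap replicate resamples the shifts with replacement.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("no shift times supplied")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if t_max is None:
        t_max = float(times.max())
    if pair_elementwise:
        if len(window_sizes) != len(step_sizes):
            raise ValueError("paired window/step lists must have equal length")
        pairs = list(zip(window_sizes, step_sizes))
    else:
        pairs = [(w, s) for w in window_sizes for s in step_sizes]

    rng = np.random.default_rng(seed)
    boot = rng.choice(times, size=(n_boot, times.size), replace=True)
    rows = []
    for w, s in pairs:
        starts = np.arange(0.0, max(t_max - w, 0.0) + s / 2, s)
        if starts.size == 0 or starts[-1] + w < t_max:
            starts = np.append(starts, max(t_max - w, 0.0))
        starts = np.unique(starts)
        for lo in starts:
            hi = lo + w
            obs = int(np.sum((times >= lo) & (times < hi)))
            bc = np.sum((boot >= lo) & (boot < hi), axis=1)
            rows.append({
                "window": w, "step": s, "start": lo, "end": hi,
                "observed": obs,
                "boot_mean": float(bc.mean()),
                "boot_lo": float(np.percentile(bc, 2.5)),
                "boot_hi": float(np.percentile(bc, 97.5)),
            })
    return pd.DataFrame(rows)
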