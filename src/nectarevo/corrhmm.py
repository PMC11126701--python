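"""Correlated evolution of two binary traits with hidden rate classes.

The observed chain lives on dual states {00, 01, 10, 11} (trait1 =
nectary presence, trait2 = habit, coded d = 2*t1 + t2); hidden rate
classes multiply the state space to 4R states (global index 4*c + d for
class c).  Transitions change exactly one thing at a time: one trait, or
the hidden class (dual simultaneous changes are disallowed, the standard
Pagel/corHMM structure).

Four models form the correlation test:

* dependent,   R=1 — classic Pagel correlated model (8 rates);
* independent, R=1 — each trait evolves blind to the other (4 rates);
* independent, R=2 — hidden rate heterogeneity, no correlation (9);
* dependent,   R=2 — correlation plus hidden rate heterogeneity (17).

Models are ranked by AICc (n = number of tips).  The fitted chain feeds
the same stochastic-mapping machinery as plain Mk models, with
marginalized views by trait or by rate class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .mk import (
    SimmapEnsemble,
    SimmapRealization,
    mk_loglik,
    sample_simmaps,
    count_transitions,
)
from .treeio import PhyloTree

__all__ = [
    "HiddenRateModel",
    "HiddenRateFit",
    "CorrelationTestResult",
    "build_model",
    "dual_states",
    "fit_hidden_model",
    "correlation_test",
    "simmap_hidden",
    "project_ensemble",
    "count_dual_transitions",
    "aicc",
]

DUAL_LABELS = ("00", "01", "10", "11")


def aicc(lnL: float, k: int, n: int) -> float:
    """Corrected AIC; infinite when n <= k + 1."""
    aic = 2 * k - 2 * lnL
    if n - k - 1 <= 0:
        return np.inf
    return aic + 2 * k * (k + 1) / (n - k - 1)


def dual_states(trait1: dict[str, int], trait2: dict[str, int]) -> dict[str, int]:
    """Combine two binary trait maps into dual-state codes 2*t1 + t2."""
    if set(trait1) != set(trait2):
        raise ValueError("trait maps cover different species")
    return {sp: 2 * int(trait1[sp]) + int(trait2[sp]) for sp in trait1}


@dataclass
class HiddenRateModel:
    """Parameter-tying map for a (possibly hidden-rate) dual-trait chain."""

    structure: str            # "independent" | "dependent"
    rate_classes: int         # R in {1, 2}
    share_class_switch: bool = True

    def __post_init__(self):
        if self.structure not in ("independent", "dependent"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.rate_classes not in (1, 2):
            raise ValueError("rate_classes must be 1 or 2")

    @property
    def n_states(self) -> int:
        return 4 * self.rate_classes

    @property
    def per_class_rates(self) -> int:
        return 8 if self.structure == "dependent" else 4

    @property
    def n_params(self) -> int:
        n = self.per_class_rates * self.rate_classes
        if self.rate_classes == 2:
            n += 1 if self.share_class_switch else 2
        return n

    def param_names(self) -> list[str]:
        names = []
        for c in range(self.rate_classes):
            suf = f"_c{c}" if self.rate_classes > 1 else ""
            if self.structure == "dependent":
                names += [f"q_t1gain_bg0{suf}", f"q_t1gain_bg1{suf}",
                          f"q_t1loss_bg0{suf}", f"q_t1loss_bg1{suf}",
                          f"q_t2gain_bg0{suf}", f"q_t2gain_bg1{suf}",
                          f"q_t2loss_bg0{suf}", f"q_t2loss_bg1{suf}"]
            else:
                names += [f"q_t1gain{suf}", f"q_t1loss{suf}",
                          f"q_t2gain{suf}", f"q_t2loss{suf}"]
        if self.rate_classes == 2:
            names += ["q_class"] if self.share_class_switch else ["q_class_01", "q_class_10"]
        return names

    def build_q(self, params: np.ndarray) -> np.ndarray:
        """Generator over the 4R global states from the free-rate vector."""
        params = np.asarray(params, dtype=float)
        if len(params) != self.n_params:
            raise ValueError("wrong parameter count")
        R = self.rate_classes
        k = self.n_states
        Q = np.zeros((k, k))
        p = self.per_class_rates
        for c in range(R):
            block = params[c * p:(c + 1) * p]
            for t1 in (0, 1):
                for t2 in (0, 1):
                    d = 2 * t1 + t2
                    i = 4 * c + d
                    # trait1 change (background = t2)
                    j = 4 * c + 2 * (1 - t1) + t2
                    if self.structure == "dependent":
                        rate = block[t2] if t1 == 0 else block[2 + t2]
                    else:
                        rate = block[0] if t1 == 0 else block[1]
                    Q[i, j] = rate
                    # trait2 change (background = t1)
                    j = 4 * c + 2 * t1 + (1 - t2)
                    if self.structure == "dependent":
                        rate = block[4 + t1] if t2 == 0 else block[6 + t1]
                    else:
                        rate = block[2] if t2 == 0 else block[3]
                    Q[i, j] = rate
        if R == 2:
            sw = params[-1:] if self.share_class_switch else params[-2:]
            for d in range(4):
                Q[d, 4 + d] = sw[0]
                Q[4 + d, d] = sw[0] if self.share_class_switch else sw[1]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def tip_partials(self, tree: PhyloTree, dual: dict[str, int]) -> np.ndarray:
        """Observed dual state, hidden class unobserved (partial = 1 per class)."""
        L = np.zeros((tree.n_tips, self.n_states))
        for i, lab in enumerate(tree.tip_labels):
            if lab not in dual:
                raise ValueError(f"tip {lab!r} has no dual state")
            d = int(dual[lab])
            for c in range(self.rate_classes):
                L[i, 4 * c + d] = 1.0
        return L


def build_model(structure: str, rate_classes: int, share_class_switch: bool = True) -> HiddenRateModel:
    return HiddenRateModel(structure, rate_classes, share_class_switch)


@dataclass
class HiddenRateFit:
    model: HiddenRateModel
    rates: np.ndarray
    Q: np.ndarray
    lnL: float
    k_params: int
    n_tips: int

    @property
    def AICc(self) -> float:
        return aicc(self.lnL, self.k_params, self.n_tips)


def fit_hidden_model(
    tree: PhyloTree,
    dual: dict[str, int],
    model: HiddenRateModel,
    n_starts: int = 3,
    seed: int = 0,
    root_prior: str = "stationary",
    extra_starts: list[np.ndarray] | None = None,
) -> HiddenRateFit:
    """MLE of tied rates by bounded log-scale multi-start optimization.

    ``extra_starts`` (natural-scale rate vectors) lets a richer model
    start from the embedded optimum of a nested one, which keeps fitted
    log-likelihoods monotone along the nesting chain.
    """
    partials = model.tip_partials(tree, dual)
    rng = np.random.default_rng(seed)
    lo, hi = np.log(1e-9), np.log(1e3)

    def nll(logr):
        Q = model.build_q(np.exp(logr))
        try:
            ll = mk_loglik(tree, partials, Q, root_prior)
        except FloatingPointError:
            return 1e10
        return 1e10 if not np.isfinite(ll) else -ll

    base = np.log(1.0 / max(tree.height, 1e-6))
    starts = [np.full(model.n_params, base)]
    starts += [np.log(np.clip(np.asarray(v, dtype=float), 1e-9, 1e3))
               for v in (extra_starts or [])]
    starts += [np.full(model.n_params, base) + rng.normal(0, 1.0, model.n_params)
               for _ in range(max(n_starts - len(starts), 0))]
    best = None
    for x0 in starts:
        res = minimize(nll, np.clip(x0, lo, hi), method="L-BFGS-B",
                       bounds=[(lo, hi)] * model.n_params,
                       options={"maxiter": 300, "maxfun": 4000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e10:
        raise RuntimeError("hidden-rate model optimization failed")
    rates = np.exp(best.x)
    return HiddenRateFit(model, rates, model.build_q(rates), -best.fun,
                         model.n_params, tree.n_tips)


@dataclass
class CorrelationTestResult:
    fits: dict[str, HiddenRateFit]
    best_name: str

    @property
    def best(self) -> HiddenRateFit:
        return self.fits[self.best_name]

    def table(self):
        import pandas as pd

        rows = [{"model": name, "lnL": f.lnL, "k": f.k_params, "AICc": f.AICc}
                for name, f in self.fits.items()]
        df = pd.DataFrame(rows).sort_values(["AICc", "k"]).reset_index(drop=True)
        df["dAICc"] = df["AICc"] - df["AICc"].min()
        return df


FOUR_MODELS = {
    "dependent_R1": ("dependent", 1),
    "independent_R1": ("independent", 1),
    "independent_R2": ("independent", 2),
    "dependent_R2": ("dependent", 2),
}


def correlation_test(
    tree: PhyloTree,
    trait1: dict[str, int],
    trait2: dict[str, int],
    n_starts: int = 3,
    seed: int = 0,
) -> CorrelationTestResult:
    """Fit the four-model set and rank by AICc (ties -> fewer parameters)."""
    for name, tr in (("trait1", trait1), ("trait2", trait2)):
        vals = {tr[l] for l in tree.tip_labels}
        if len(vals) < 2:
            raise ValueError(f"{name} is constant across tips (uninformative)")
    dual = dual_states(trait1, trait2)
    fits: dict[str, HiddenRateFit] = {}

    def indep_to_dep(v):
        g1, l1, g2, l2 = v
        return np.array([g1, g1, l1, l1, g2, g2, l2, l2])

    fits["independent_R1"] = fit_hidden_model(
        tree, dual, build_model("independent", 1), n_starts=n_starts, seed=seed)
    fits["dependent_R1"] = fit_hidden_model(
        tree, dual, build_model("dependent", 1), n_starts=n_starts, seed=seed,
        extra_starts=[indep_to_dep(fits["independent_R1"].rates)])
    fits["independent_R2"] = fit_hidden_model(
        tree, dual, build_model("independent", 2), n_starts=n_starts, seed=seed,
        extra_starts=[np.concatenate([fits["independent_R1"].rates,
                                      fits["independent_R1"].rates, [1e-8]])])
    fits["dependent_R2"] = fit_hidden_model(
        tree, dual, build_model("dependent", 2), n_starts=n_starts, seed=seed,
        extra_starts=[np.concatenate([fits["dependent_R1"].rates,
                                      fits["dependent_R1"].rates, [1e-8]])])
    best = min(fits, key=lambda nm: (round(fits[nm].AICc, 9), fits[nm].k_params))
    return CorrelationTestResult(fits, best)


def simmap_hidden(tree: PhyloTree, fit: HiddenRateFit, n: int = 100, seed: int = 0,
                  dual: dict[str, int] | None = None) -> SimmapEnsemble:
    """Stochastic maps on the expanded (dual x class) state space."""
    if dual is None:
        raise ValueError("tip dual states are required")
    partials = fit.model.tip_partials(tree, dual)
    return sample_simmaps(tree, partials, fit.Q, n=n, seed=seed)


def project_ensemble(ensemble: SimmapEnsemble, mapping: np.ndarray) -> SimmapEnsemble:
    """Relabel states through ``mapping`` and merge equal adjacent segments.

    ``mapping[s]`` is the projected state of global state s; use
    ``s % 4`` to marginalize out the hidden class, ``s // 4`` to view
    rate classes only.
    """
    mapping = np.asarray(mapping, dtype=np.int64)
    k_new = int(mapping.max()) + 1
    reals = []
    for real in ensemble.realizations:
        segments = []
        for segs in real.segments:
            merged: list[tuple[int, float]] = []
            for s, d in segs:
                ns = int(mapping[s])
                if merged and merged[-1][0] == ns:
                    merged[-1] = (ns, merged[-1][1] + d)
                else:
                    merged.append((ns, d))
            segments.append(merged)
        reals.append(SimmapRealization(mapping[real.node_states], segments))
    return SimmapEnsemble(tree=ensemble.tree, realizations=reals, states=k_new,
                          seed=ensemble.seed)


def dual_view(ensemble: SimmapEnsemble) -> SimmapEnsemble:
    k = ensemble.states
    return project_ensemble(ensemble, np.arange(k) % 4)


def class_view(ensemble: SimmapEnsemble) -> SimmapEnsemble:
    k = ensemble.states
    return project_ensemble(ensemble, np.arange(k) // 4)


@dataclass
class FourStateModel:
    """Binary focal trait x four-state habit, no hidden classes.

    States are indexed 4*t1 + h for habit h in {0: terrestrial,
    1: epiphyte, 2: climber, 3: tree}.  Habit moves among its four
    states at one shared (ER) rate; the focal trait gains and loses at
    rates that are shared across habits (independent, 3 free rates) or
    habit-specific (dependent, 9 free rates).  Dual simultaneous
    changes are disallowed.
    """

    structure: str

    @property
    def n_states(self) -> int:
        return 8

    @property
    def n_params(self) -> int:
        return 3 if self.structure == "independent" else 9

    def param_names(self) -> list[str]:
        if self.structure == "independent":
            return ["q_t1gain", "q_t1loss", "q_habit"]
        habs = ["terr", "epi", "climb", "tree"]
        return [f"q_t1gain_{h}" for h in habs] + [f"q_t1loss_{h}" for h in habs] + ["q_habit"]

    def build_q(self, params: np.ndarray) -> np.ndarray:
        params = np.asarray(params, dtype=float)
        Q = np.zeros((8, 8))
        q_hab = params[-1]
        for t1 in (0, 1):
            for h in range(4):
                i = 4 * t1 + h
                for h2 in range(4):
                    if h2 != h:
                        Q[i, 4 * t1 + h2] = q_hab
                j = 4 * (1 - t1) + h
                if self.structure == "independent":
                    Q[i, j] = params[0] if t1 == 0 else params[1]
                else:
                    Q[i, j] = params[h] if t1 == 0 else params[4 + h]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def tip_partials(self, tree: PhyloTree, states: dict[str, int]) -> np.ndarray:
        L = np.zeros((tree.n_tips, 8))
        for i, lab in enumerate(tree.tip_labels):
            L[i, int(states[lab])] = 1.0
        return L


def correlation_test_four_state(
    tree: PhyloTree,
    trait1: dict[str, int],
    habit4: dict[str, int],
    n_starts: int = 2,
    seed: int = 0,
) -> CorrelationTestResult:
    """Independent-vs-dependent comparison under the four-state habit coding.

    ``habit4`` maps species to {0: terrestrial, 1: epiphyte, 2: climber,
    3: tree}.  Only these two models are compared (no hidden classes).
    """
    if len({trait1[l] for l in tree.tip_labels}) < 2:
        raise ValueError("focal trait is constant across tips (uninformative)")
    states = {sp: 4 * int(trait1[sp]) + int(habit4[sp]) for sp in trait1}
    fits: dict[str, HiddenRateFit] = {}
    for name in ("independent", "dependent"):
        model = FourStateModel(name)
        partials = model.tip_partials(tree, states)
        rng = np.random.default_rng(seed)
        lo, hi = np.log(1e-9), np.log(1e3)

        def nll(logr, model=model):
            Q = model.build_q(np.exp(logr))
            try:
                ll = mk_loglik(tree, partials, Q, "stationary")
            except FloatingPointError:
                return 1e10
            return 1e10 if not np.isfinite(ll) else -ll

        base = np.log(1.0 / max(tree.height, 1e-6))
        starts = [np.full(model.n_params, base)]
        if name == "dependent" and "independent" in fits:
            g, l, h = fits["independent"].rates
            starts.append(np.log(np.array([g] * 4 + [l] * 4 + [h])))
        starts += [np.full(model.n_params, base) + rng.normal(0, 1.0, model.n_params)
                   for _ in range(max(n_starts - len(starts), 0))]
        best = None
        for x0 in starts:
            res = minimize(nll, np.clip(x0, lo, hi), method="L-BFGS-B",
                           bounds=[(lo, hi)] * model.n_params,
                           options={"maxiter": 300, "maxfun": 4000})
            if best is None or res.fun < best.fun:
                best = res
        rates = np.exp(best.x)
        fits[name] = HiddenRateFit(model, rates, model.build_q(rates), -best.fun,
                                   model.n_params, tree.n_tips)
    best_name = min(fits, key=lambda nm: (round(fits[nm].AICc, 9), fits[nm].k_params))
    return CorrelationTestResult(fits, best_name)


def count_dual_transitions(ensemble: SimmapEnsemble) -> np.ndarray:
    """Mean 4x4 count matrix of observed dual-state changes.

    Hidden-class switches leave the dual state unchanged and are merged
    away; dual-simultaneous entries are structurally zero.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    proj = dual_view(ensemble) if ensemble.states > 4 else ensemble
    return count_transitions(proj).mean_matrix
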