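"""Synthetic data with known ground truth for every analysis stage.

One Gillespie engine drives all generators: forward birth-death trees
(extinct lineages pruned, ultrametric survivors), forward Mk trait
histories (returning the true branch painting, so planted gain ages are
exact), hidden-rate dual-trait chains, and joint BiSSE simulation of
cladogenesis + extinction + state change.

``make_fixture`` assembles clade-like test inputs emulating the
statistical structure of the empirical datasets this pipeline targets —
a rare (1-5% prevalence), phylogenetically clustered binary trait on an
ultrametric tree with genus/family/order labels and a correlated growth
habit — with a ground-truth ledger (true gain ages, rates, prevalence).
``make_survey_table`` builds a synthetic species-survey table whose
marginal counts follow the published fern and angiosperm surveys
(149 nectary ferns in 12 genera / 5 families / 3 orders with a
75/64/6/4 tree/epiphyte/climber/terrestrial habit split; 3913 EFN
angiosperms in 796 genera / 119 families / 42 orders); the species
lists themselves are synthetic stand-ins, not the curated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mk import SimmapRealization
from .treeio import PhyloTree, drop_tips, node_ages

__all__ = [
    "sim_bd_tree",
    "sim_mk_traits",
    "sim_hidden_dual",
    "sim_bisse",
    "plant_gain_history",
    "make_fixture",
    "make_survey_table",
]


def _collapse_unary_root(tree: PhyloTree) -> PhyloTree:
    """Re-root at the first multifurcation (drop a stem left by pruning)."""
    ch = tree.children_map()
    root = tree.root
    while len(ch[root]) == 1:
        root = ch[root][0]
    if root == tree.root:
        return tree
    keep = set()
    stack = [root]
    while stack:
        v = stack.pop()
        keep.add(v)
        stack.extend(ch[v])
    order = sorted([v for v in keep if tree.is_tip(v)]) + \
        sorted([v for v in keep if not tree.is_tip(v)])
    idx = {v: i for i, v in enumerate(order)}
    parent = np.full(len(order), -1, dtype=np.int64)
    lengths = np.zeros(len(order))
    for v in order:
        if v != root:
            parent[idx[v]] = idx[tree.parent[v]]
            lengths[idx[v]] = tree.lengths[v]
    labels = [tree.tip_labels[v] for v in order if tree.is_tip(v)]
    return PhyloTree(parent, lengths, labels)


def sim_bd_tree(lam: float, mu: float, stop_n: int | None = None, stop_t: float | None = None,
                seed: int = 0, max_attempts: int = 1000) -> PhyloTree:
    """Forward (Gillespie) birth-death tree of the surviving lineages.

    Starts from a single lineage; stops at ``stop_n`` extant lineages or
    at time ``stop_t``.  Extinct subtrees are pruned and the stem below
    the survivors' crown is collapsed, so the result is an ultrametric
    crown tree.  Conditioned on >= 2 survivors by resimulation.
    """
    if lam <= 0 or mu < 0:
        raise ValueError("need lam > 0 and mu >= 0")
    if (stop_n is None) == (stop_t is None):
        raise ValueError("specify exactly one of stop_n, stop_t")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        # node records: (parent, birth_time); tips resolved at the end
        parent_rec: list[int] = [-1]
        birth: list[float] = [0.0]
        active: list[int] = [0]
        death: dict[int, float] = {}
        t = 0.0
        ok = True
        while True:
            n = len(active)
            if n == 0:
                ok = False
                break
            if stop_n is not None and n >= stop_n:
                end = t
                break
            rate = n * (lam + mu)
            dt = rng.exponential(1.0 / rate)
            if stop_t is not None and t + dt >= stop_t:
                end = stop_t
                break
            t += dt
            li = int(rng.integers(n))
            lineage = active[li]
            if rng.random() < lam / (lam + mu):
                for _ in range(2):
                    parent_rec.append(lineage)
                    birth.append(t)
                    active.append(len(parent_rec) - 1)
                active.remove(lineage)
            else:
                death[lineage] = t
                active.remove(lineage)
        if not ok or len(active) < 2:
            continue
        # build full tree: active lineages end at `end`, dead at death time
        n_rec = len(parent_rec)
        is_leaf = np.ones(n_rec, dtype=bool)
        for p in parent_rec[1:]:
            if p >= 0:
                is_leaf[p] = False
        leaves = [i for i in range(n_rec) if is_leaf[i]]
        internals = [i for i in range(n_rec) if not is_leaf[i]]
        idx = {}
        labels = []
        alive_labels = []
        for k, i in enumerate(leaves):
            idx[i] = k
            if i in death:
                labels.append(f"x{k}")
            else:
                labels.append(f"t{k}")
                alive_labels.append(f"t{k}")
        for k, i in enumerate(internals):
            idx[i] = len(leaves) + k
        parent = np.full(n_rec, -1, dtype=np.int64)
        lengths = np.zeros(n_rec)
        for i in range(n_rec):
            p = parent_rec[i]
            t_end = death.get(i, end) if is_leaf[i] else birth[
                next(j for j in range(n_rec) if parent_rec[j] == i)]
            if p >= 0:
                parent[idx[i]] = idx[p]
                lengths[idx[i]] = t_end - birth[i]
        full = PhyloTree(parent, lengths, labels)
        dead_labels = [l for l in labels if l.startswith("x")]
        pruned = drop_tips(full, dead_labels) if dead_labels else full
        return _collapse_unary_root(pruned)
    raise RuntimeError(f"no surviving tree in {max_attempts} attempts")


def scale_tree_height(tree: PhyloTree, height: float) -> PhyloTree:
    out = tree.copy()
    out.lengths = out.lengths * (height / tree.height)
    return out


def _sim_branch_path(rng, Q, state: int, t: float):
    """Forward CTMC path: (segments, end_state)."""
    segs: list[tuple[int, float]] = []
    k = Q.shape[0]
    s = state
    remaining = t
    start = 0.0
    while True:
        rate = -Q[s, s]
        wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        if wait >= remaining:
            segs.append((int(s), float(remaining)))
            return segs, int(s)
        segs.append((int(s), float(wait)))
        remaining -= wait
        w = Q[s].copy()
        w[s] = 0.0
        w = w / w.sum()
        s = int(rng.choice(k, p=w))
        start += wait


def sim_mk_traits(tree: PhyloTree, Q: np.ndarray, root_state: int = 0, seed: int = 0):
    """Forward-simulate a discrete trait; returns (tip_states, true history)."""
    rng = np.random.default_rng(seed)
    k = Q.shape[0]
    node_states = np.zeros(tree.n_nodes, dtype=np.int64)
    node_states[tree.root] = root_state
    segments: list[list[tuple[int, float]]] = [[] for _ in range(tree.n_nodes)]
    for v in tree.preorder():
        p = tree.parent[v]
        if p < 0:
            continue
        segs, end = _sim_branch_path(rng, Q, int(node_states[p]), float(tree.lengths[v]))
        segments[v] = segs
        node_states[v] = end
    tip_states = {tree.tip_labels[i]: int(node_states[i]) for i in range(tree.n_tips)}
    return tip_states, SimmapRealization(node_states, segments)


def sim_hidden_dual(tree: PhyloTree, Q: np.ndarray, seed: int = 0, root_state: int = 0):
    """Forward-simulate a hidden-rate dual chain (4R states).

    Returns (observed dual tip states, full-chain history, observed-dual
    history); the hidden path is retained in the full history.
    """
    from .corrhmm import dual_view
    from .mk import SimmapEnsemble

    tips_full, hist = sim_mk_traits(tree, Q, root_state=root_state, seed=seed)
    obs = {sp: s % 4 for sp, s in tips_full.items()}
    ens = SimmapEnsemble(tree=tree, realizations=[hist], states=Q.shape[0], seed=seed)
    obs_hist = dual_view(ens).realizations[0]
    return obs, hist, obs_hist


@dataclass
class MultiStateParams:
    """k-state diversification parameters for the Gillespie simulator.

    ``obs_of_state`` maps each model state to the observed (reported)
    state — use it to simulate hidden-class (HiSSE/CID-style) processes.
    """

    lam: np.ndarray
    mu: np.ndarray
    Q: np.ndarray
    obs_of_state: np.ndarray | None = None

    def arrays(self):
        return np.asarray(self.lam, float), np.asarray(self.mu, float), np.asarray(self.Q, float)


def sim_bisse(params, stop_n: int | None = None, stop_t: float | None = None,
              seed: int = 0, root_state: int = 0, max_attempts: int = 1000):
    """Joint Gillespie simulation of cladogenesis, extinction, state change.

    ``params`` is a BisseParams or MultiStateParams (anything with
    ``arrays()``); returns (ultrametric surviving tree, tip state dict)
    where states are projected through ``obs_of_state`` when present.
    """
    lam, mu, Q = params.arrays()
    obs_map = getattr(params, "obs_of_state", None)
    k = len(lam)
    if (stop_n is None) == (stop_t is None):
        raise ValueError("specify exactly one of stop_n, stop_t")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        parent_rec = [-1]
        birth = [0.0]
        state_rec = [root_state]  # state at lineage birth; mutated in place
        active = [0]
        death: dict[int, float] = {}
        t = 0.0
        while True:
            n = len(active)
            if n == 0:
                break
            if stop_n is not None and n >= stop_n:
                end = t
                break
            rates = np.array([lam[state_rec[i]] + mu[state_rec[i]] - Q[state_rec[i], state_rec[i]]
                              for i in active])
            tot = rates.sum()
            dt = rng.exponential(1.0 / tot)
            if stop_t is not None and t + dt >= stop_t:
                end = stop_t
                break
            t += dt
            li = int(rng.choice(n, p=rates / tot))
            lineage = active[li]
            s = state_rec[lineage]
            u = rng.random() * rates[li]
            if u < lam[s]:
                for _ in range(2):
                    parent_rec.append(lineage)
                    birth.append(t)
                    state_rec.append(s)
                    active.append(len(parent_rec) - 1)
                active.remove(lineage)
            elif u < lam[s] + mu[s]:
                death[lineage] = t
                active.remove(lineage)
            else:
                w = Q[s].copy()
                w[s] = 0.0
                state_rec[lineage] = int(rng.choice(k, p=w / w.sum()))
        if len(active) < 2:
            continue
        n_rec = len(parent_rec)
        is_leaf = np.ones(n_rec, dtype=bool)
        for p in parent_rec[1:]:
            if p >= 0:
                is_leaf[p] = False
        leaves = [i for i in range(n_rec) if is_leaf[i]]
        internals = [i for i in range(n_rec) if not is_leaf[i]]
        idx = {i: j for j, i in enumerate(leaves)}
        idx.update({i: len(leaves) + j for j, i in enumerate(internals)})
        labels, states, dead_labels = [], {}, []
        for j, i in enumerate(leaves):
            if i in death:
                labels.append(f"x{j}")
                dead_labels.append(f"x{j}")
            else:
                labels.append(f"t{j}")
                s_obs = int(state_rec[i]) if obs_map is None else int(obs_map[state_rec[i]])
                states[f"t{j}"] = s_obs
        parent = np.full(n_rec, -1, dtype=np.int64)
        lengths = np.zeros(n_rec)
        for i in range(n_rec):
            p = parent_rec[i]
            t_end = death.get(i, end) if is_leaf[i] else birth[
                next(j for j in range(n_rec) if parent_rec[j] == i)]
            if p >= 0:
                parent[idx[i]] = idx[p]
                lengths[idx[i]] = t_end - birth[i]
        full = PhyloTree(parent, lengths, labels)
        pruned = drop_tips(full, dead_labels) if dead_labels else full
        tree = _collapse_unary_root(pruned)
        return tree, {l: states[l] for l in tree.tip_labels}
    raise RuntimeError(f"no surviving tree in {max_attempts} attempts")


def plant_gain_history(tree: PhyloTree, gain_age: float, seed: int = 0,
                       min_subtree_tips: int = 3,
                       max_branch_span: float | None = None):
    """Paint a single 0->1 gain at an exact age on a randomly chosen branch.

    All tips below the gain branch are state 1, everything else 0; used
    as ground truth for origin-timing recovery.  The data can only
    localize the gain to the carrying branch, so candidate branches must
    subtend at least ``min_subtree_tips`` tips (a pendant-branch gain is
    wholly unidentifiable) and, when ``max_branch_span`` is set, span at
    most that many My — planting on longer branches caps how well any
    estimator can rank the true ages.
    """
    ages = node_ages(tree)
    rng = np.random.default_rng(seed)
    cands = [v for v in range(tree.n_nodes)
             if tree.parent[v] >= 0 and ages[tree.parent[v]] > gain_age >= ages[v]
             and len(tree.subtree_tips(v)) >= min_subtree_tips
             and (max_branch_span is None
                  or ages[tree.parent[v]] - ages[v] <= max_branch_span)]
    if not cands:
        raise ValueError(f"no eligible branch crosses age {gain_age}")
    v = int(cands[rng.integers(len(cands))])
    below = set(tree.subtree_tips(v))
    in_sub = np.zeros(tree.n_nodes, dtype=bool)
    stack = [v]
    ch = tree.children_map()
    while stack:
        u = stack.pop()
        in_sub[u] = True
        stack.extend(ch[u])
    node_states = in_sub.astype(np.int64)
    node_states[tree.parent[v]] = 0
    segments: list[list[tuple[int, float]]] = [[] for _ in range(tree.n_nodes)]
    for u in range(tree.n_nodes):
        p = tree.parent[u]
        if p < 0:
            continue
        t = float(tree.lengths[u])
        if u == v:
            d0 = float(ages[p] - gain_age)
            if d0 <= 0:
                segments[u] = [(1, t)]
                node_states[u] = 1
            else:
                segments[u] = [(0, d0), (1, t - d0)]
        elif in_sub[u]:
            segments[u] = [(1, t)]
        else:
            segments[u] = [(0, t)]
    tip_states = {tree.tip_labels[i]: (1 if i in below else 0) for i in range(tree.n_tips)}
    return tip_states, SimmapRealization(node_states, segments)


# -- clade-like fixtures -------------------------------------------------


@dataclass
class Fixture:
    tree: PhyloTree
    table: pd.DataFrame
    truth: dict = field(default_factory=dict)


_FIXTURE_CONF = {
    # height in My, target tips, dual-chain rate multipliers (x 1/height),
    # prevalence window (nectaries rare 1-5%; ant plant associations common)
    "fern": {"height": 350.0, "n_tips": 300, "prevalence": (0.01, 0.05),
             "gain_under_x": 0.04, "gain_canopy_x": 0.5, "loss_x": 1.2,
             "habit_x": 0.6},
    "angiosperm": {"height": 250.0, "n_tips": 400, "prevalence": (0.01, 0.05),
                   "gain_under_x": 0.04, "gain_canopy_x": 0.45, "loss_x": 1.2,
                   "habit_x": 0.6},
    "ant": {"height": 150.0, "n_tips": 250, "prevalence": (0.2, 0.6),
            "gain_under_x": 0.5, "gain_canopy_x": 1.5, "loss_x": 0.6,
            "habit_x": 0.6},
}


def _clade_partition(tree: PhyloTree, ages: np.ndarray, cutoff: float) -> dict[int, int]:
    """Assign each tip the oldest ancestor with age <= cutoff (clade id)."""
    assign: dict[int, int] = {}
    ch = tree.children_map()

    def walk(v, current):
        if current is None and ages[v] <= cutoff:
            current = v
        if tree.is_tip(v):
            assign[v] = current if current is not None else v
            return
        for c in ch[v]:
            walk(c, current)

    walk(tree.root, None)
    return assign


def make_fixture(clade: str = "fern", seed: int = 0) -> Fixture:
    """A clade-like synthetic dataset: tree, trait table, truth ledger.

    The focal trait (nectary presence / plant association) and a binary
    habitat trait (canopy vs understory) co-evolve under a dependent
    dual-trait chain in which trait gains are concentrated in canopy
    lineages; the pair is resampled until trait prevalence lands in the
    clade's window, so the trait is rare (for plants) and clustered.
    Genus, family and order labels come from age-threshold clade
    partitions; canopy tips get a per-genus subtype (tree / epiphyte /
    climber).  The truth ledger records the true gain ages (the oldest
    is the planted origin), the generating rates and the prevalence.
    """
    from .corrhmm import build_model

    if clade not in _FIXTURE_CONF:
        raise ValueError(f"unknown clade {clade!r}")
    conf = _FIXTURE_CONF[clade]
    rng = np.random.default_rng(seed)
    tree = sim_bd_tree(lam=0.05, mu=0.018, stop_n=conf["n_tips"], seed=seed)
    tree = scale_tree_height(tree, conf["height"])

    base = 1.0 / conf["height"]
    dual_rates = np.array([
        conf["gain_under_x"] * base, conf["gain_canopy_x"] * base,
        conf["loss_x"] * base, conf["loss_x"] * base,
        conf["habit_x"] * base, conf["habit_x"] * base,
        conf["habit_x"] * base, conf["habit_x"] * base,
    ])
    Qd = build_model("dependent", 1).build_q(dual_rates)

    lo, hi = conf["prevalence"]
    for sub in range(200):
        dual, hist, obs_hist = sim_hidden_dual(tree, Qd, seed=seed * 1000 + sub)
        tip_states = {sp: d // 2 for sp, d in dual.items()}
        canopy_states = {sp: d % 2 for sp, d in dual.items()}
        prev = sum(tip_states.values()) / tree.n_tips
        canopy_share = sum(canopy_states.values()) / tree.n_tips
        if lo <= prev <= hi and 0.1 <= canopy_share <= 0.9:
            break
    else:
        raise RuntimeError("could not reach target prevalence")

    ages = node_ages(tree)
    genus_of = _clade_partition(tree, ages, 0.12 * conf["height"])
    family_of = _clade_partition(tree, ages, 0.45 * conf["height"])
    order_of = _clade_partition(tree, ages, 0.80 * conf["height"])

    def names(assign, prefix):
        ids = {}
        out = {}
        for tip, node in assign.items():
            if node not in ids:
                ids[node] = f"{prefix}{len(ids) + 1:03d}"
            out[tip] = ids[node]
        return out

    gname = names(genus_of, "Gen")
    fname = names(family_of, "Fam")
    oname = names(order_of, "Ord")

    subtype_of_genus = {g: rng.choice(["tree", "epiphyte", "climber"], p=[0.4, 0.5, 0.1])
                        for g in sorted(set(gname.values()))}
    rows = []
    for i, lab in enumerate(tree.tip_labels):
        habit = subtype_of_genus[gname[i]] if canopy_states[lab] else "terrestrial"
        rows.append({"species": f"{gname[i]}_{lab}", "trait": tip_states[lab],
                     "genus": gname[i], "family": fname[i], "order": oname[i],
                     "habit": habit})
    table = pd.DataFrame(rows)
    relabeled = tree.copy()
    relabeled.tip_labels = list(table["species"])

    # true focal-trait gain events: dual-state boundaries where t1 flips
    # 0 -> 1, recorded as (age, branch node carrying the gain)
    gain_events = []
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0:
            continue
        acc = 0.0
        segs = obs_hist.segments[v]
        for (s1, d1), (s2, _) in zip(segs, segs[1:]):
            acc += d1
            if s1 // 2 == 0 and s2 // 2 == 1:
                gain_events.append((float(ages[p] - acc), int(v)))
    gain_events.sort(reverse=True)
    gains = [a for a, _ in gain_events]
    truth = {
        "clade": clade,
        "prevalence": prev,
        "dual_rates_per_my": [float(x) for x in dual_rates],
        "gain_ages": gains,
        "gain_nodes": [v for _, v in gain_events],
        "first_gain_age": gains[0] if gains else None,
        "n_tips": tree.n_tips,
        "height": conf["height"],
        "seed": seed,
        "trait_sim_subseed": sub,
    }
    return Fixture(relabeled, table, truth)


# -- synthetic survey tables --------------------------------------------

_FERN_SURVEY = [
    # genus, family, order, habit, n trait-positive species
    ("Pleopeltis", "Polypodiaceae", "Polypodiales", "epiphyte", 12),
    ("Campyloneurum", "Polypodiaceae", "Polypodiales", "epiphyte", 11),
    ("Niphidium", "Polypodiaceae", "Polypodiales", "epiphyte", 8),
    ("Drynaria", "Polypodiaceae", "Polypodiales", "epiphyte", 12),
    ("Platycerium", "Polypodiaceae", "Polypodiales", "epiphyte", 9),
    ("Selliguea", "Polypodiaceae", "Polypodiales", "epiphyte", 7),
    ("Serpocaulon", "Polypodiaceae", "Polypodiales", "epiphyte", 5),
    ("Lygodium", "Lygodiaceae", "Schizaeales", "climber", 6),
    ("Cyathea", "Cyatheaceae", "Cyatheales", "tree", 40),
    ("Alsophila", "Cyatheaceae", "Cyatheales", "tree", 25),
    ("Dicksonia", "Dicksoniaceae", "Cyatheales", "tree", 10),
    ("Pteridium", "Dennstaedtiaceae", "Polypodiales", "terrestrial", 4),
]


def make_survey_table(clade: str = "fern", seed: int = 0, n_negative: int = 0) -> pd.DataFrame:
    """Synthetic species-survey table matching the published marginal counts.

    The species names are synthetic placeholders; only the marginal
    structure (counts of trait-positive species per genus/family/order
    and the growth-habit split) follows the real surveys.  Optional
    trait-negative filler rows give realistic prevalence.
    """
    rng = np.random.default_rng(seed)
    rows = []
    if clade == "fern":
        for genus, fam, order, habit, n in _FERN_SURVEY:
            for i in range(n):
                rows.append({"species": f"{genus}_sp{i + 1:03d}", "trait": 1,
                             "genus": genus, "family": fam, "order": order, "habit": habit})
    elif clade == "angiosperm":
        n_pos, n_gen, n_fam, n_ord = 3913, 796, 119, 42
        fam_of_gen = [g % n_fam for g in range(n_gen)]
        ord_of_fam = [f % n_ord for f in range(n_fam)]
        for i in range(n_pos):
            g = i % n_gen
            f = fam_of_gen[g]
            rows.append({"species": f"Agen{g + 1:03d}_sp{i + 1:04d}", "trait": 1,
                         "genus": f"Agen{g + 1:03d}", "family": f"Afam{f + 1:03d}",
                         "order": f"Aord{ord_of_fam[f] + 1:02d}", "habit": None})
    elif clade == "ant":
        n_tot = 1341
        from .traits import code_ant_association

        for i in range(n_tot):
            diet = int(rng.random() < 0.30)
            forage = int(rng.random() < 0.25)
            nest = int(rng.random() < 0.20)
            rows.append({"species": f"Ant_sp{i + 1:04d}",
                         "trait": code_ant_association(diet, forage, nest),
                         "genus": f"AntGen{(i % 120) + 1:03d}",
                         "family": "Formicidae", "order": "Hymenoptera", "habit": None})
    else:
        raise ValueError(f"unknown clade {clade!r}")
    for j in range(n_negative):
        g = j % 300
        rows.append({"species": f"NegGen{g + 1:03d}_sp{j + 1:05d}", "trait": 0,
                     "genus": f"NegGen{g + 1:03d}", "family": f"NegFam{(g % 40) + 1:02d}",
                     "order": f"NegOrd{(g % 7) + 1}",
                     "habit": ["terrestrial", "epiphyte", "tree", "climber"][j % 4]})
    return pd.DataFrame(rows)
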