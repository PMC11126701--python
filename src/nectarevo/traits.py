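"""Trait tables: coding schemes, taxonomy/habit summaries, dataset reduction.

A trait table is a pandas DataFrame with columns ``species`` (unique),
``trait`` (0/1), optional taxonomy columns ``genus``/``family``/``order``
and a ``habit`` column from the closed vocabulary
{terrestrial, epiphyte, climber, tree}.  Habit is recoded either binary
(understory vs canopy-dwelling: epiphytes, climbers and tree ferns all
elevate their leaves off the forest floor) or kept as four states.

Reduction rules mirror the survey-to-tree workflow: collapse to one tip
per genus (a genus carries the trait if any member does), or keep all
trait-positive species while thinning absences (one tip per all-negative
genus, then a random fraction of the remaining negatives).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .treeio import PhyloTree, drop_tips

logger = logging.getLogger(__name__)

HABIT_VOCAB = ("terrestrial", "epiphyte", "climber", "tree")
CANOPY_HABITS = ("epiphyte", "climber", "tree")

REQUIRED_COLUMNS = ("species", "trait")


class TraitTableError(ValueError):
    pass


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise TraitTableError(f"missing required column {col!r}")
    if table["species"].duplicated().any():
        dups = table.loc[table["species"].duplicated(), "species"].tolist()
        raise TraitTableError(f"duplicate species: {dups[:5]}")
    if not set(table["trait"].unique()) <= {0, 1}:
        raise TraitTableError("trait must be binary 0/1")
    if "habit" in table.columns:
        bad = set(table["habit"].dropna().unique()) - set(HABIT_VOCAB)
        if bad:
            raise TraitTableError(f"unknown habit categories: {sorted(bad)}")
    return table


def read_trait_table(path: str) -> pd.DataFrame:
    return validate_table(pd.read_csv(path, sep="\t"))


def write_trait_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)


# -- coding --------------------------------------------------------------


def code_ant_association(diet_has_plants, forages_canopy, nests_canopy):
    """Plant-associated iff the ant eats plants, forages or nests in canopy.

    Any missing flag excludes the record (returns None with a warning).
    """
    flags = (diet_has_plants, forages_canopy, nests_canopy)
    if any(f is None or (isinstance(f, float) and np.isnan(f)) for f in flags):
        logger.warning("ant record with missing association flags excluded")
        return None
    return int(bool(diet_has_plants) or bool(forages_canopy) or bool(nests_canopy))


def code_habit(habit: str, scheme: str = "binary") -> str:
    """Recode growth habit.

    binary: terrestrial -> understory, {epiphyte, climber, tree} -> canopy.
    four_state: identity.
    """
    if habit not in HABIT_VOCAB:
        raise TraitTableError(f"unknown habit {habit!r}")
    if scheme == "binary":
        return "canopy" if habit in CANOPY_HABITS else "understory"
    if scheme == "four_state":
        return habit
    raise TraitTableError(f"unknown scheme {scheme!r}")


# -- summaries -----------------------------------------------------------


def taxonomy_summary(table: pd.DataFrame, totals: dict[str, int] | None = None) -> pd.DataFrame:
    """Counts of taxa at each level containing >=1 trait-positive species.

    ``totals`` supplies reference diversity denominators per level
    (species/genus/family/order); percents are reported against them,
    both unrounded and at whole-percent printing precision.
    """
    validate_table(table)
    totals = totals or {}
    pos = table[table["trait"] == 1]
    rows = []
    for level, col in (("species", "species"), ("genus", "genus"),
                       ("family", "family"), ("order", "order")):
        if col != "species" and col not in table.columns:
            continue
        if col != "species" and table[col].isna().any():
            bad = table.loc[table[col].isna(), "species"].tolist()
            raise TraitTableError(f"missing {col} for rows: {bad[:5]}")
        count = pos[col].nunique() if len(pos) else 0
        total = totals.get(level)
        if total is not None and total < table[col].nunique():
            raise TraitTableError(f"supplied {level} total below observed diversity")
        pct = 100.0 * count / total if total else np.nan
        rows.append({"level": level, "count": count, "total": total,
                     "percent": pct,
                     "percent_printed": round(pct) if total else np.nan})
    return pd.DataFrame(rows)


def habit_summary(table: pd.DataFrame, habit_totals: dict[str, int] | None = None) -> pd.DataFrame:
    """Growth-habit breakdown of trait-bearing species.

    Reports, per habit, the share of all trait-bearers (sums to 100) and
    — when per-habit totals are supplied — the share of that habit's
    total diversity bearing the trait.  Percentages rounded to 1 decimal
    for printing, unrounded values kept alongside.
    """
    validate_table(table)
    pos = table[table["trait"] == 1]
    if "habit" not in table.columns or pos["habit"].isna().any():
        raise TraitTableError("habit missing on trait-positive rows")
    n_pos = len(pos)
    if n_pos == 0:
        raise TraitTableError("no trait-positive rows")
    habit_totals = habit_totals or {}
    rows = []
    for habit in HABIT_VOCAB:
        n = int((pos["habit"] == habit).sum())
        share = 100.0 * n / n_pos
        tot = habit_totals.get(habit)
        of_total = 100.0 * n / tot if tot else np.nan
        rows.append({
            "habit": habit, "n": n,
            "percent_of_trait_bearing": share,
            "percent_of_trait_bearing_printed": round(share, 1),
            "percent_of_habit_total": of_total,
            "percent_of_habit_total_printed": round(of_total, 2) if tot else np.nan,
        })
    return pd.DataFrame(rows)


# -- reduction -----------------------------------------------------------


def _genus_of(table: pd.DataFrame) -> pd.Series:
    """Genus per row: explicit column if present, else label prefix."""
    if "genus" in table.columns and table["genus"].notna().all():
        return table["genus"].astype(str)
    gen = table["species"].astype(str).str.replace(" ", "_").str.split("_").str[0]
    if (gen == "").any():
        bad = table.loc[gen == "", "species"].tolist()
        raise TraitTableError(f"cannot resolve genus for: {bad[:5]}")
    return gen


def genus_collapse(tree: PhyloTree, table: pd.DataFrame) -> tuple[PhyloTree, pd.DataFrame]:
    """One tip per genus; a genus is trait-positive if any member is.

    The surviving tip for each genus is the first in tip-label order; the
    returned table carries the genus-level trait.
    """
    validate_table(table)
    tab = table.set_index("species")
    genus = _genus_of(table)
    genus_by_species = dict(zip(table["species"], genus))
    missing = [l for l in tree.tip_labels if l not in genus_by_species]
    if missing:
        raise TraitTableError(f"tips absent from table: {missing[:5]}")
    keep: dict[str, str] = {}
    for lab in tree.tip_labels:
        g = genus_by_species[lab]
        keep.setdefault(g, lab)
    drop = [l for l in tree.tip_labels if keep[genus_by_species[l]] != l]
    pruned = drop_tips(tree, drop) if drop else tree.copy()
    logger.info("genus_collapse: dropped %d of %d tips", len(drop), tree.n_tips)
    rows = []
    for g, lab in keep.items():
        members = [s for s, gg in genus_by_species.items() if gg == g and s in set(tree.tip_labels)]
        rows.append({"species": lab, "genus": g,
                     "trait": int(tab.loc[members, "trait"].max())})
    out = pd.DataFrame(rows)
    return pruned, out


def downsample_absences(
    tree: PhyloTree,
    table: pd.DataFrame,
    keep_all_positive_genera: bool = True,
    absence_fraction_dropped: float = 0.0,
    seed: int = 0,
) -> tuple[PhyloTree, pd.DataFrame]:
    """Thin trait-negative tips while keeping every trait-positive one.

    Genera with >=1 positive species keep all their tips (when
    ``keep_all_positive_genera``); all-negative genera are reduced to one
    random tip; then ``floor(fraction * n_remaining_negatives)`` further
    negatives are dropped at random.  Seeded and deterministic.
    """
    if not 0.0 <= absence_fraction_dropped < 1.0:
        raise TraitTableError("absence_fraction_dropped must be in [0, 1)")
    validate_table(table)
    rng = np.random.default_rng(seed)
    trait = dict(zip(table["species"], table["trait"]))
    genus = dict(zip(table["species"], _genus_of(table)))
    tips = [l for l in tree.tip_labels]
    missing = [l for l in tips if l not in trait]
    if missing:
        raise TraitTableError(f"tips absent from table: {missing[:5]}")

    by_genus: dict[str, list[str]] = {}
    for l in tips:
        by_genus.setdefault(genus[l], []).append(l)

    drop: set[str] = set()
    for g, members in sorted(by_genus.items()):
        if keep_all_positive_genera and any(trait[m] == 1 for m in members):
            continue
        negs = sorted(m for m in members if trait[m] == 0)
        if len(negs) > 1:
            keep_one = negs[rng.integers(len(negs))]
            drop.update(m for m in negs if m != keep_one)
    remaining_neg = sorted(l for l in tips if trait[l] == 0 and l not in drop)
    n_extra = int(np.floor(absence_fraction_dropped * len(remaining_neg)))
    if n_extra:
        extra = rng.choice(len(remaining_neg), size=n_extra, replace=False)
        drop.update(remaining_neg[i] for i in extra)
    survivors = [l for l in tips if l not in drop]
    if len(survivors) < 2:
        raise TraitTableError("downsampling would leave fewer than 2 tips")
    logger.info(
        "downsample_absences: dropped %d tips (%d genus-level, %d random)",
        len(drop), len(drop) - n_extra, n_extra,
    )
    pruned = drop_tips(tree, sorted(drop)) if drop else tree.copy()
    out = table[table["species"].isin(survivors)].reset_index(drop=True)
    return pruned, out
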