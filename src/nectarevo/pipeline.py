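"""Config-driven pipeline reproducing the analysis stage order.

Stages (dependency order): prep -> simmap -> {ltt, timing, corrtest,
sse} and medusa -> windows.  Every stage writes deterministic TSV/JSON
outputs into the run directory and appends to a run log recording seeds,
model choices, AIC tables and filter counts.  A stage list that skips a
dependency is rejected before anything executes.

Config is a plain dict (or a ``key = value`` text file) — e.g.::

    fixture = fern
    seed = 7
    stages = prep,simmap,ltt,timing,corrtest,sse,medusa,windows
    n_simmaps = 100

The console script exposes one subcommand per stage plus ``all``; a
stage subcommand runs the dependency-closed prefix ending at that stage.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import click
import pandas as pd

from . import corrhmm, mk, rateshift, sse, synth, timing, traits, treeio

logger = logging.getLogger(__name__)

STAGES = ("prep", "simmap", "ltt", "timing", "corrtest", "sse", "medusa", "windows")
DEPENDS = {
    "prep": (),
    "simmap": ("prep",),
    "ltt": ("simmap",),
    "timing": ("simmap",),
    "corrtest": ("prep",),
    "sse": ("prep",),
    "medusa": ("prep",),
    "windows": ("medusa",),
}


class ConfigError(ValueError):
    pass


def parse_config_file(path: str) -> dict:
    conf: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"bad config line: {line!r}")
        key, val = line.split("=", 1)
        conf[key.strip()] = val.strip()
    return conf


def _validate_stages(stages) -> list[str]:
    stages = list(stages)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stages: {unknown}")
    seen = set()
    for s in STAGES:
        if s in stages:
            missing = [d for d in DEPENDS[s] if d not in seen]
            if missing:
                raise ConfigError(f"stage {s!r} requires {missing} to run first")
            seen.add(s)
    return [s for s in STAGES if s in stages]


def run_pipeline(config: dict, out_dir: str) -> Path:
    """Run the configured stages; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    raw_stages = config.get("stages", "all")
    if isinstance(raw_stages, str):
        stages = list(STAGES) if raw_stages == "all" else [s.strip() for s in raw_stages.split(",")]
    else:
        stages = list(raw_stages)
    stages = _validate_stages(stages)

    log_lines: list[str] = []

    def log(msg: str):
        logger.info(msg)
        log_lines.append(msg)

    (out / "config_resolved.txt").write_text(
        "".join(f"{k} = {v}\n" for k, v in sorted(config.items())) + f"out = {out}\n"
    )

    state: dict = {}
    n_simmaps = int(config.get("n_simmaps", 100))

    for stage in stages:
        log(f"stage {stage} (seed {seed})")
        if stage == "prep":
            if "tree" in config:
                tree = treeio.read_newick_file(str(config["tree"]))
                table = traits.read_trait_table(str(config["traits"]))
                truth = {}
            else:
                clade = str(config.get("fixture", "fern"))
                fx = synth.make_fixture(clade, seed=seed)
                tree, table, truth = fx.tree, fx.table, fx.truth
            tree = treeio.force_ultrametric(treeio.resolve_polytomies(tree, seed=seed))
            log(f"tree: {tree.n_tips} tips, height {tree.height:.2f} My")
            state.update(tree=tree, table=table, truth=truth)
            treeio.write_newick_file(tree, out / "prep_tree.nwk")
            traits.write_trait_table(table, out / "prep_traits.tsv")
            if truth:
                (out / "prep_truth.json").write_text(json.dumps(truth, indent=1))
        elif stage == "simmap":
            tree, table = state["tree"], state["table"]
            tip_states = dict(zip(table["species"], table["trait"]))
            fits = [mk.mk_fit(tree, tip_states, m, seed=seed) for m in ("ER", "ARD")]
            best = mk.select_model(fits)
            log("Mk AIC: " + ", ".join(f"{f.model}={f.AIC:.2f}" for f in fits)
                + f"; selected {best.model}")
            ens = mk.sample_simmaps(tree, tip_states, best.Q, n=n_simmaps, seed=seed)
            counts = mk.count_transitions(ens)
            gp, lp = counts.percent_of_changes()
            log(f"transitions: mean gains {counts.mean_gains:.2f} ({gp:.0f}%), "
                f"mean losses {counts.mean_losses:.2f} ({lp:.0f}%)")
            state.update(ensemble=ens, mk_best=best, counts=counts)
            mk.ensemble_to_frame(ens).to_csv(out / "simmap_ensemble.tsv", sep="\t", index=False)
            pd.DataFrame({"gains": counts.gains, "losses": counts.losses}).to_csv(
                out / "simmap_transitions.tsv", sep="\t", index=False)
        elif stage == "ltt":
            ltt = timing.trait_ltt(state["ensemble"], focal_state=1)
            pd.DataFrame({"age": ltt.grid, "mean_lineages": ltt.mean_curve}).to_csv(
                out / "ltt_mean_curve.tsv", sep="\t", index=False)
            state["ltt"] = ltt
        elif stage == "timing":
            ens = state["ensemble"]
            curves = [timing.gain_curve(r, ens.tree) for r in ens.realizations]
            summary = timing.origin_timing(curves)
            log(f"origin timing: median {summary.median:.1f}, mean {summary.mean:.1f}, "
                f"min {summary.min:.1f}, max {summary.max:.1f}, sd {summary.sd:.1f} My BP "
                f"({summary.n_dropped} gain-free realizations dropped)")
            pd.DataFrame([{"min": summary.min, "max": summary.max, "median": summary.median,
                           "mean": summary.mean, "sd": summary.sd,
                           "n_curves": len(summary.per_curve_medians),
                           "n_dropped": summary.n_dropped}]).to_csv(
                out / "timing_summary.tsv", sep="\t", index=False)
            pd.DataFrame({"median_gain_age": summary.per_curve_medians}).to_csv(
                out / "timing_per_realization.tsv", sep="\t", index=False)
            state["timing"] = summary
        elif stage == "corrtest":
            tree, table = state["tree"], state["table"]
            trait1 = dict(zip(table["species"], table["trait"]))
            trait2 = {sp: int(traits.code_habit(h) == "canopy")
                      for sp, h in zip(table["species"], table["habit"])}
            res = corrhmm.correlation_test(tree, trait1, trait2, n_starts=2, seed=seed)
            tab = res.table()
            log("correlation test AICc:\n" + tab.to_string(index=False))
            payload = {
                "best_model": res.best_name,
                "models": {nm: {"lnL": f.lnL, "k": f.k_params, "AICc": f.AICc}
                           for nm, f in res.fits.items()},
                "best_rates": dict(zip(res.best.model.param_names(),
                                       map(float, res.best.rates))),
            }
            (out / "corrtest.json").write_text(json.dumps(payload, indent=1))
            state["corrtest"] = res
        elif stage == "sse":
            tree, table = state["tree"], state["table"]
            tip_states = dict(zip(table["species"], table["trait"]))
            fits = sse.hisse_fit_set(tree, tip_states, n_starts=1, seed=seed)
            tab = sse.aicc_table(fits)
            log("SSE model comparison:\n" + tab.to_string(index=False))
            tab.to_csv(out / "sse_aicc.tsv", sep="\t", index=False)
            (out / "sse_fits.json").write_text(json.dumps(
                {f.model: {"lnL": f.lnL, "k": f.k_params, "AICc": f.AICc,
                           "params": {k: float(v) for k, v in f.params.items()}}
                 for f in fits}, indent=1))
            state["sse"] = fits
        elif stage == "medusa":
            tree = state["tree"]
            fit = rateshift.medusa_fit(tree, max_shifts=int(config.get("max_shifts", 4)))
            log(f"medusa: {len(fit.shifts)} shifts; background r={fit.background['r']:.4f} "
                f"eps={fit.background['eps']:.3f}")
            pd.DataFrame([{"node": s.node, "age": s.age, "r": s.r, "eps": s.eps,
                           "dAICc": s.dAICc} for s in fit.shifts]).to_csv(
                out / "medusa_shifts.tsv", sep="\t", index=False)
            state["medusa"] = fit
        elif stage == "windows":
            fit = state["medusa"]
            ages = fit.shift_ages
            if len(ages) == 0:  # no shifts: report an empty table, not an error
                pd.DataFrame(columns=["window", "step", "start", "end", "observed",
                                      "boot_mean", "boot_lo", "boot_hi"]).to_csv(
                    out / "window_counts.tsv", sep="\t", index=False)
                log("windows: no shifts to bin")
            else:
                wdf = rateshift.sliding_window_bootstrap(
                    ages, n_boot=int(config.get("n_boot", 500)), seed=seed,
                    t_max=state["tree"].height)
                wdf.to_csv(out / "window_counts.tsv", sep="\t", index=False)
                state["windows"] = wdf

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out


# -- CLI -----------------------------------------------------------------


@click.group()
def main():
    """Cross-kingdom nectary-evolution analysis pipeline."""
    logging.basicConfig(level=logging.INFO, stream=sys.stderr,
                        format="%(levelname)s %(name)s: %(message)s")


def _make_stage_command(stage: str):
    @click.command(name=stage, help=f"Run stages up to and including {stage!r}.")
    @click.option("--config", "config_path", type=click.Path(exists=True), default=None)
    @click.option("--seed", type=int, default=0)
    @click.option("--out", "out_dir", type=click.Path(), required=True)
    def cmd(config_path, seed, out_dir):
        conf = parse_config_file(config_path) if config_path else {}
        conf.setdefault("seed", seed)
        if stage == "all":
            conf["stages"] = "all"
        else:
            closure: set = set()

            def close(s):
                closure.add(s)
                for d in DEPENDS[s]:
                    close(d)

            close(stage)
            conf["stages"] = ",".join(s for s in STAGES if s in closure)
        run_pipeline(conf, out_dir)

    return cmd


for _stage in STAGES + ("all",):
    main.add_command(_make_stage_command(_stage))
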