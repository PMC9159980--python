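"""End-to-end orchestration of the two analyses from a flat config.

A run config (YAML/JSON-compatible mapping) names the input files, the index
to model, model/simmap options, an output directory and a global seed.  The
global seed deterministically spawns per-stage substreams, so a run is fully
reproducible from (config, seed).  Every output table carries the seed and a
hash of the config in a header comment line.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import morphodata, phyloreg, treeio
from .mk_simmap import summarize_node_pp
from .treeio import extract_subtree, phylo_correlation, to_unit_height

__all__ = ["RunConfig", "run_regression_pipeline", "run_asr_pipeline", "StageError"]


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    measurements: Optional[str] = None
    tip_states: Optional[str] = None
    consensus_tree: Optional[str] = None
    tree_sample: Optional[str] = None
    index: str = "IFA"
    out_dir: str = "results"
    seed: int = 0
    make_plot: bool = False
    chains: int = 4
    iterations: int = 5000
    warmup_frac: float = 0.5
    simmap_model: str = "ER"
    n_maps_per_tree: int = 1
    interval: float = 0.89

    @classmethod
    def from_mapping(cls, m: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(m) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**m)
        if cfg.index not in morphodata.INDEX_NAMES:
            raise ValueError(f"index must be one of {morphodata.INDEX_NAMES}")
        return cfg

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# seed={cfg.seed} config_sha={cfg.digest()}\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapped
    return deco


# ------------------------------------------------------------- regression
def run_regression_pipeline(cfg: RunConfig) -> dict:
    """Dataset build → BM and no-BM fits → WAIC comparison → report tables.

    Returns a dict with the fitted objects and written file paths.  Species
    whose index value is missing on every row (structure absent) are excluded
    by the dataset builder; the exclusion is recorded in the run summary.
    """
    out = Path(cfg.out_dir)
    seeds = np.random.SeedSequence(cfg.seed).spawn(2)

    @_stage("read-inputs")
    def read_inputs():
        records = pd.read_csv(cfg.measurements, comment="#")
        tree = treeio.parse_newick(Path(cfg.consensus_tree).read_text())
        return records, tree

    records, tree = read_inputs()

    @_stage("build-dataset")
    def build():
        rows = records[records["index"] == cfg.index]
        all_species = sorted(set(rows["species"]))
        with_data = sorted(set(rows.loc[np.isfinite(rows["value"].astype(float)), "species"]))
        sub = tree if set(with_data) == set(tree.tip_labels) else extract_subtree(tree, with_data)
        ds = morphodata.build_dataset(records, cfg.index, sub)
        excluded = sorted(set(all_species) - set(ds.species))
        R = phylo_correlation(to_unit_height(sub), ds.species)
        return ds, R, excluded

    ds, R, excluded = build()

    @_stage("fit-models")
    def fit():
        full = phyloreg.fit_varying_effects(
            ds,
            phyloreg.ModelSpec(R=R, include_bm=True, chains=cfg.chains,
                               iterations=cfg.iterations, warmup_frac=cfg.warmup_frac,
                               seed=int(seeds[0].generate_state(1)[0] % (2**31))),
        )
        reduced = phyloreg.fit_varying_effects(
            ds,
            phyloreg.ModelSpec(R=R, include_bm=False, chains=cfg.chains,
                               iterations=cfg.iterations, warmup_frac=cfg.warmup_frac,
                               seed=int(seeds[1].generate_state(1)[0] % (2**31))),
        )
        return full, reduced

    full, reduced = fit()

    @_stage("waic-compare")
    def compare():
        w_full = phyloreg.compute_waic(full)
        w_red = phyloreg.compute_waic(reduced)
        return w_full, w_red, phyloreg.compare_models(w_full, w_red)

    w_full, w_red, comparison = compare()

    @_stage("report")
    def report():
        paths = {}
        summ_full = phyloreg.posterior_summary(full, cfg.interval)
        summ_red = phyloreg.posterior_summary(reduced, cfg.interval)
        shares = phyloreg.variance_shares(full, cfg.interval)
        comp_df = pd.DataFrame([{
            "index": cfg.index,
            "waic_with_bm": w_full.waic,
            "waic_without_bm": w_red.waic,
            "delta_waic": comparison.delta_waic,
            "delta_se": comparison.delta_se,
            "preferred": "with_bm" if comparison.preferred == "full" else "without_bm",
            "n_obs": w_full.n,
        }])
        for name, df in (
            (f"{cfg.index}_summary_with_bm", summ_full),
            (f"{cfg.index}_summary_without_bm", summ_red),
            (f"{cfg.index}_variance_shares", shares),
            (f"{cfg.index}_waic_comparison", comp_df),
        ):
            p = out / f"{name}.csv"
            _write_table(df, p, cfg)
            paths[name] = p
        bad = summ_full[~summ_full["converged"]]
        lines = [
            f"index: {cfg.index}",
            f"n_obs: {ds.n}",
            f"n_species: {ds.n_species}",
            f"excluded_species (structure absent): {excluded or 'none'}",
            f"delta_waic: {comparison.delta_waic:.6g}",
            f"delta_se: {comparison.delta_se:.6g}",
            f"preferred: {'with_bm' if comparison.preferred == 'full' else 'without_bm'}",
            f"convergence_flags (rhat > 1.05): {list(bad['parameter']) or 'none'}",
        ]
        p = out / f"{cfg.index}_run_summary.txt"
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(f"# seed={cfg.seed} config_sha={cfg.digest()}\n" + "\n".join(lines) + "\n")
        paths["run_summary"] = p
        return paths

    paths = report()
    if cfg.make_plot:
        p = out / f"{cfg.index}_scaling.png"
        plot_scaling(ds, full, p, interval=cfg.interval)
        paths["scaling_plot"] = p
    return {
        "dataset": ds,
        "posterior_with_bm": full,
        "posterior_without_bm": reduced,
        "comparison": comparison,
        "excluded_species": excluded,
        "paths": paths,
    }


def plot_scaling(ds, post, path, interval: float = 0.89) -> None:
    """Log-log scatter of index vs body mass with the population-level line
    and its central compatibility band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    abar = post.flat("abar")
    bbar = post.flat("bbar") if post.include_bm else np.zeros_like(abar)
    grid = np.linspace(ds.x.min(), ds.x.max(), 100)
    lines = abar[:, None] + bbar[:, None] * grid[None, :]
    lo_q = (1 - interval) / 2
    lo, hi = np.quantile(lines, [lo_q, 1 - lo_q], axis=0)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ds.x, ds.y, s=12, alpha=0.5, c=ds.species_idx, cmap="viridis")
    ax.plot(grid, lines.mean(axis=0), color="black")
    ax.fill_between(grid, lo, hi, alpha=0.25, color="grey",
                    label=f"{int(100 * interval)}% CI")
    ax.set_xlabel("centered log body mass")
    ax.set_ylabel(f"log {ds.index}")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# -------------------------------------------------------------------- ASR
def run_asr_pipeline(cfg: RunConfig) -> dict:
    """Per-character stochastic mapping over a tree sample.

    Constant characters (a single observed state) carry no mappable signal
    and are skipped with a notice.  Returns per-character node-posterior
    tables keyed by clade.
    """
    out = Path(cfg.out_dir)

    @_stage("read-inputs")
    def read_inputs():
        states = pd.read_csv(cfg.tip_states, comment="#")
        need = {"taxon", "character", "state"}
        if not need <= set(states.columns):
            raise ValueError(f"tip-state CSV must have columns {sorted(need)}")
        sample = treeio.read_tree_sample(cfg.tree_sample)
        # per-tree unit-height scaling keeps ML rates on a common scale
        sample = treeio.TreeSample(
            [to_unit_height(t) for t in sample.trees], sample.taxa)
        return states, sample

    states, sample = read_inputs()
    seeds = np.random.SeedSequence(cfg.seed).spawn(len(set(states["character"])))

    results, skipped, paths = {}, [], {}
    for (char, sub), cs in zip(states.groupby("character", sort=True), seeds):
        tips = dict(zip(sub["taxon"], sub["state"].astype(int)))

        @_stage(f"asr:{char}")
        def one():
            missing = sample.taxa - set(tips)
            if missing:
                raise ValueError(f"character {char}: no state for taxa {sorted(missing)}")
            if len(set(tips.values())) < 2:
                return None
            return summarize_node_pp(
                sample, tips, model=cfg.simmap_model,
                n_maps_per_tree=cfg.n_maps_per_tree,
                seed=int(cs.generate_state(1)[0] % (2**31)),
            )

        table = one()
        if table is None:
            skipped.append(char)
            continue
        results[char] = table
        p = out / f"asr_{char}_node_pp.csv"
        _write_table(table.to_frame(), p, cfg)
        paths[char] = p

    p = out / "asr_summary.txt"
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(
        f"# seed={cfg.seed} config_sha={cfg.digest()}\n"
        f"n_trees: {len(sample)}\n"
        f"maps_per_tree: {cfg.n_maps_per_tree}\n"
        f"characters_mapped: {sorted(results)}\n"
        f"characters_skipped_constant: {skipped or 'none'}\n"
    )
    paths["summary"] = p
    return {"tables": results, "skipped": skipped, "paths": paths}
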