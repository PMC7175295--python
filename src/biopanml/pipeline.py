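"""End-to-end workflow: simulate/ingest -> preprocess -> collate -> ELISA
calls -> TR dataset -> train -> introspect -> predict -> panels.

Every stage reads and writes plain-text artifacts in one run directory
and is recorded in ``manifest.json`` (stage name, outputs, key numbers,
seeds), so a run is fully reproducible from its config: identical config
and seed give byte-identical outputs. A stage failure aborts the run
with the stage name and offending record context.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import clonotypes as ct
from . import dataset as dsmod
from . import elisa as elisamod
from . import introspect as intro
from . import model as modelmod
from . import panel as panelmod
from . import preprocess as pp
from . import simulate as sim

__all__ = ["RunConfig", "PipelineError", "run_pipeline",
           "load_config", "save_config"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and context."""


@dataclass
class RunConfig:
    """Flat configuration for one pipeline run."""

    outdir: str = "run"
    seed: int = 0
    chains: tuple[str, ...] = ("H", "L")

    # input mode: simulate a campaign, or read existing per-round FASTQs
    simulate: bool = True
    fastq_h: tuple[str, ...] = ()
    fastq_l: tuple[str, ...] = ()

    # simulation conditions
    n_clonotypes: int = 2000
    binder_fraction: float = 0.23
    wash_stringency: tuple[float, ...] = (0.0, 0.1, 0.3, 0.3, 0.5)
    read_depth: tuple[int, ...] = (20000, 20000, 20000, 20000, 20000)
    read_error_rate: float = 0.001
    n_retrieved_clones: int = 384
    elisa_noise_sd: float = 0.1

    # preprocessing
    min_mean_phred: float = 20.0
    max_primer_mismatches: int = 1

    # modeling
    train_fraction: float = 0.75
    mtry: int = 4
    ntree: int = 200
    do_benchmark: bool = False
    benchmark_repeats: int = 5
    benchmark_folds: int = 10

    # panel selection
    panel_n_ar: int = 40
    panel_n_nr: int = 10
    min_confidence: float = 0.9
    make_plots: bool = False


def _simulation_config(cfg: RunConfig) -> sim.SimulationConfig:
    return sim.SimulationConfig(
        n_clonotypes=cfg.n_clonotypes,
        binder_fraction=cfg.binder_fraction,
        wash_stringency=tuple(cfg.wash_stringency),
        read_depth=tuple(cfg.read_depth),
        read_error_rate=cfg.read_error_rate,
        seed=cfg.seed,
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow and return the machine-readable manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "config": _config_to_flat(cfg),
                      "stages": []}

    def stage(name: str):
        def wrap(fn):
            logger.info("stage %s", name)
            try:
                info = fn() or {}
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"].append({"name": name, **info})
            return info
        return wrap

    # ------------------------------------------------------------------ input
    per_chain_reads: dict[str, dict[int, list[pp.ReadRecord]]] = {}
    truth_by_chain: dict[str, sim.SimulationTruth] = {}
    counts_by_chain: dict[str, pd.DataFrame] = {}

    if cfg.simulate:
        sim_cfg = _simulation_config(cfg)

        @stage("simulate")
        def _simulate():
            truth_h, truth_l = sim.simulate_paired_repertoire(sim_cfg)
            truth_by_chain["H"], truth_by_chain["L"] = truth_h, truth_l
            outputs = []
            for chain in cfg.chains:
                truth = truth_by_chain[chain]
                counts = sim.simulate_panning(truth, sim_cfg, chain=chain)
                counts_by_chain[chain] = counts
                reads = sim.simulate_reads(truth, counts, sim_cfg, chain=chain)
                paths = sim.write_reads_fastq(reads, outdir,
                                              prefix=f"{chain.lower()}_round")
                per_chain_reads[chain] = reads
                tpath = outdir / f"truth_{chain}.tsv"
                sim.write_truth_tsv(truth, tpath)
                outputs += [str(p) for p in paths.values()] + [str(tpath)]
            return {"outputs": outputs,
                    "n_clonotypes": cfg.n_clonotypes}
    else:
        @stage("load_fastq")
        def _load():
            paths = {"H": cfg.fastq_h, "L": cfg.fastq_l}
            outputs = []
            for chain in cfg.chains:
                chain_paths = paths[chain]
                if not chain_paths:
                    raise PipelineError(
                        f"stage 'load_fastq': no FASTQ paths configured for "
                        f"chain {chain}")
                rounds = {}
                for r, path in enumerate(chain_paths):
                    if not Path(path).exists():
                        raise PipelineError(
                            f"stage 'load_fastq': missing FASTQ file {path}")
                    rounds[r] = list(pp.read_fastq(path))
                    outputs.append(str(path))
                per_chain_reads[chain] = rounds
            return {"outputs": outputs}

    # ------------------------------------------------------------ preprocess
    cdr3s_by_chain: dict[str, list[list[str]]] = {}

    @stage("preprocess")
    def _preprocess():
        outputs, info = [], {}
        for chain in cfg.chains:
            fcfg = pp.default_filter_config(
                chain, min_mean_phred=cfg.min_mean_phred,
                max_primer_mismatches=cfg.max_primer_mismatches)
            per_round = []
            for r in sorted(per_chain_reads[chain]):
                cdr3s, stats = pp.filter_and_extract(
                    per_chain_reads[chain][r], fcfg)
                per_round.append(cdr3s)
                spath = outdir / f"rejection_{chain}_r{r}.json"
                stats.to_json(spath)
                outputs.append(str(spath))
                info[f"{chain}_r{r}_passed"] = stats.passed
            cdr3s_by_chain[chain] = per_round
        return {"outputs": outputs, **info}

    # --------------------------------------------------------------- collate
    tables: dict[str, pd.DataFrame] = {}

    @stage("collate")
    def _collate():
        outputs, info = [], {}
        for chain in cfg.chains:
            table = ct.collate_clonotypes(cdr3s_by_chain[chain], chain=chain)
            if len(table) == 0:
                raise PipelineError(
                    f"stage 'collate': no valid clonotypes for chain {chain}")
            tables[chain] = table
            tpath = outdir / f"clonotypes_{chain}.tsv"
            ct.write_clonotype_tsv(table, tpath)
            profile = ct.entropy_profile(table)
            epath = outdir / f"entropy_{chain}.tsv"
            profile.to_csv(epath, sep="\t", header=True)
            outputs += [str(tpath), str(epath)]
            info[f"{chain}_clonotypes"] = len(table)
        return {"outputs": outputs, **info}

    # ----------------------------------------------------------------- elisa
    calls_holder: dict[str, list] = {}

    @stage("elisa")
    def _elisa():
        if not cfg.simulate:
            raise PipelineError(
                "stage 'elisa': real-data mode requires a pre-computed ELISA "
                "table; run the elisa-call subcommand instead")
        truth_h = truth_by_chain["H"]
        counts_h = counts_by_chain["H"]
        last = f"r{len(cfg.read_depth) - 1}"
        weights = counts_h[last].to_numpy(dtype=float)
        if weights.sum() <= 0:
            raise PipelineError("stage 'elisa': final round has no reads")
        rng = np.random.default_rng([cfg.seed, 41])
        idx = rng.choice(len(weights), size=cfg.n_retrieved_clones,
                         p=weights / weights.sum())
        h_cdr3 = truth_h.for_chain("H")["cdr3_aa"]
        l_cdr3 = truth_by_chain["L"].for_chain("L")["cdr3_aa"]
        clones = [(f"C{k:04d}", h_cdr3.iloc[i],
                   l_cdr3.iloc[i] if "L" in cfg.chains else None)
                  for k, i in enumerate(idx)]
        truth_all = sim.SimulationTruth(pd.concat(
            [truth_by_chain[c].table for c in cfg.chains], ignore_index=True))
        records = sim.simulate_elisa(clones, truth_all,
                                     noise_sd=cfg.elisa_noise_sd,
                                     seed=cfg.seed)
        epath = outdir / "elisa.tsv"
        sim.write_elisa_tsv(records, epath)
        calls = elisamod.call_reactive(records)
        cpath = outdir / "elisa_calls.tsv"
        elisamod.write_calls_tsv(calls, cpath)
        calls_holder["calls"] = calls
        n_ar = sum(c.label == "AR" for c in calls)
        return {"outputs": [str(epath), str(cpath)],
                "n_clones": len(calls), "n_ar": n_ar}

    # --------------------------------------------------------------- dataset
    datasets: dict[str, dsmod.TRDataset] = {}

    @stage("build_dataset")
    def _build():
        outputs, info = [], {}
        for chain in cfg.chains:
            ds = dsmod.build_tr_dataset(tables[chain], calls_holder["calls"],
                                        chain=chain)
            if len(ds) == 0 or len(np.unique(ds.y)) < 2:
                raise PipelineError(
                    f"stage 'build_dataset': chain {chain} dataset lacks both "
                    "classes; increase clone retrieval or read depth")
            datasets[chain] = ds
            dpath = outdir / f"tr_dataset_{chain}.tsv"
            dsmod.write_tr_tsv(ds, dpath)
            outputs.append(str(dpath))
            info[f"{chain}_rows"] = len(ds)
            info[f"{chain}_unmatched"] = len(ds.unmatched)
        return {"outputs": outputs, **info}

    # ------------------------------------------------------------- benchmark
    if cfg.do_benchmark:
        @stage("benchmark")
        def _benchmark():
            outputs = []
            for chain in cfg.chains:
                res = modelmod.benchmark_classifiers(
                    datasets[chain], repeats=cfg.benchmark_repeats,
                    folds=cfg.benchmark_folds, seed=cfg.seed)
                bpath = outdir / f"benchmark_{chain}.tsv"
                res.summary().to_csv(bpath, sep="\t", index=False)
                outputs.append(str(bpath))
            return {"outputs": outputs}

    # ------------------------------------------------- train/evaluate/inspect
    models: dict[str, modelmod.ForestModel] = {}

    @stage("train")
    def _train():
        outputs, info = [], {}
        for chain in cfg.chains:
            train, val = dsmod.split_dataset(datasets[chain],
                                             cfg.train_fraction, seed=cfg.seed)
            model = modelmod.train_rf(train, mtry=min(cfg.mtry,
                                                      len(train.feature_names)),
                                      ntree=cfg.ntree, seed=cfg.seed,
                                      sampling_ratio=cfg.train_fraction)
            models[chain] = model
            mpath = outdir / f"rf_model_{chain}.json"
            model.to_json(mpath)
            metrics = modelmod.evaluate(model, val)
            jpath = outdir / f"metrics_{chain}.json"
            jpath.write_text(json.dumps({
                "accuracy": metrics.accuracy,
                "sensitivity": metrics.sensitivity,
                "specificity": metrics.specificity,
                "confusion": metrics.confusion.tolist(),
            }, indent=2) + "\n")
            outputs += [str(mpath), str(jpath)]
            info[f"{chain}_accuracy"] = metrics.accuracy
        return {"outputs": outputs, **info}

    @stage("introspect")
    def _introspect():
        outputs = []
        for chain in cfg.chains:
            summary = intro.minimum_depths(models[chain])
            dpath = outdir / f"min_depth_{chain}.tsv"
            summary.table.to_csv(dpath, sep="\t")
            ipath = outdir / f"interactions_{chain}.tsv"
            intro.interaction_depths(models[chain]).to_csv(
                ipath, sep="\t", index=False)
            outputs += [str(dpath), str(ipath)]
            if cfg.make_plots:
                ppath = outdir / f"min_depth_{chain}.png"
                intro.plot_min_depth_distribution(summary, ppath)
                outputs.append(str(ppath))
        return {"outputs": outputs}

    @stage("predict_select")
    def _predict():
        outputs, info = [], {}
        for chain in cfg.chains:
            preds = modelmod.predict_confidence(models[chain], tables[chain])
            ppath = outdir / f"predictions_{chain}.tsv"
            preds.to_csv(ppath, sep="\t", index=False)
            ar = panelmod.select_panel(preds, "AR", cfg.panel_n_ar,
                                       min_confidence=cfg.min_confidence,
                                       chain=chain)
            nr = panelmod.select_panel(preds, "NR", cfg.panel_n_nr,
                                       min_confidence=cfg.min_confidence,
                                       chain=chain)
            apath = outdir / f"panel_{chain}_AR.tsv"
            npath = outdir / f"panel_{chain}_NR.tsv"
            ar.to_tsv(apath)
            nr.to_tsv(npath)
            outputs += [str(ppath), str(apath), str(npath)]
            info[f"{chain}_predicted_ar"] = int((preds["label"] == "AR").sum())
        return {"outputs": outputs, **info}

    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# flat key=value config files


def _config_to_flat(cfg: RunConfig) -> dict[str, str]:
    flat = {}
    for f in dataclasses.fields(cfg):
        value = getattr(cfg, f.name)
        if isinstance(value, (tuple, list)):
            flat[f.name] = ",".join(str(v) for v in value)
        else:
            flat[f.name] = str(value)
    return flat


def save_config(cfg: RunConfig, path: str | Path) -> None:
    lines = [f"{k} = {v}" for k, v in _config_to_flat(cfg).items()]
    Path(path).write_text("\n".join(lines) + "\n")


def _coerce(name: str, raw: str, annotation) -> object:
    raw = raw.strip()
    if annotation is bool:
        if raw.lower() in ("true", "1", "yes"):
            return True
        if raw.lower() in ("false", "0", "no"):
            return False
        raise ValueError(f"config key {name}: expected boolean, got {raw!r}")
    if annotation is int:
        return int(raw)
    if annotation is float:
        return float(raw)
    if annotation is str:
        return raw
    # tuple-typed fields: comma-separated, element type from the annotation
    origin = getattr(annotation, "__origin__", None)
    if origin is tuple:
        elem = annotation.__args__[0]
        if not raw:
            return ()
        return tuple(_coerce(name, item, elem) for item in raw.split(","))
    raise ValueError(f"config key {name}: unsupported type {annotation}")


def load_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` config file (# starts a comment)."""
    import typing

    hints = typing.get_type_hints(RunConfig)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    values = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, raw = (part.strip() for part in line.split("=", 1))
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        values[key] = _coerce(key, raw, hints[key])
    return RunConfig(**values)
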