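"""Run configuration, validation, and the end-to-end pipeline driver.

A run is described by a YAML-style text block validated into :class:`RunConfig`
(unknown keys rejected, defaults injected).  ``run_pipeline`` wires the
stages — simulate, call, qc, blup, cv, grid, crosspop, gwas, gain — into one
reproducible workflow on synthetic populations, writing tab-separated
artifacts plus a machine-readable manifest (config hash, derived seeds,
marker counts entering and leaving every filter) into the output directory.

One master seed drives everything; stage seeds are derived deterministically
by hashing the stage name, so adding a stage never perturbs the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import blup as blup_mod
from . import calling, evaluation, qc
from .assoc import kinship_matrix, manhattan_export, mixed_model_gwas
from .io import write_genotype_tsv, write_phenotype_tsv
from .simdata import (
    MISSING,
    GenotypeMatrix,
    PopulationSpec,
    derive_seed,
    make_tag_panel,
    mask_missing,
    simulate_tag_reads,
    simulate_two_populations,
)

log = logging.getLogger("polygs")

STAGES = ("simulate", "call", "qc", "blup", "cv", "grid", "crosspop", "gwas", "gain")
StageName = Literal[
    "simulate", "call", "qc", "blup", "cv", "grid", "crosspop", "gwas", "gain"
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PopulationConfig(_Strict):
    n_individuals: int = 124
    n_markers: int = 2000
    n_qtl: int = 50
    h2: float = 0.2
    ploidy_mode: Literal["diploid", "tetraploid-collapsed"] = "tetraploid-collapsed"
    n_blocks: int = 1


class TwoPopConfig(_Strict):
    n_individuals_b: int = 154
    shared_qtl_fraction: float = 1.0
    freq_divergence: float = 0.1


class CallingConfig(_Strict):
    mode: Literal["separate", "joint"] = "joint"
    min_tag_reads: int = 10
    min_depth: int = 3
    het_min_minor_reads: int = 2
    mean_depth: float = 60.0
    error_rate: float = 0.0
    cutsite_remnant: str = "CWGC"


class QcStageConfig(_Strict):
    thresholds: list[float] = Field(default_factory=lambda: list(qc.MISSING_THRESHOLDS))
    imputer: Literal["MNI", "SVDI", "RFI"] = "MNI"
    maf_min: float = 0.025
    joint: bool = False  # filter/impute the stacked two-cohort matrix, then split

    @field_validator("thresholds")
    @classmethod
    def _check_thresholds(cls, v):
        bad = [t for t in v if not 0.0 < t < 1.0]
        if bad:
            raise ValueError(f"thresholds outside (0,1): {bad}")
        return v

    @field_validator("maf_min")
    @classmethod
    def _check_maf(cls, v):
        if not 0.0 <= v <= 0.5:
            raise ValueError("maf_min must lie in [0, 0.5]")
        return v


class BlupConfig(_Strict):
    replications: int = 2
    s2_hs: float = 1.0
    s2_e: float = 2.0


class ChainConfig(_Strict):
    n_iter: int = 5000
    burn_in: int = 500
    thin: int = 5


class SvrConfig(_Strict):
    C: float = 1.0
    epsilon: float = 0.1


class RfrConfig(_Strict):
    n_trees: int = 500
    min_node: int = 5


class CvConfig(_Strict):
    train_frac: float = 0.9
    n_reps: int = 500

    @field_validator("train_frac")
    @classmethod
    def _check_frac(cls, v):
        if not 0.0 < v < 1.0:
            raise ValueError("train_frac must lie in (0, 1)")
        return v


class GridConfig(_Strict):
    strategies: list[Literal["separate", "joint"]] = Field(
        default_factory=lambda: ["separate", "joint"]
    )
    imputers: list[Literal["MNI", "SVDI", "RFI", "REF"]] = Field(
        default_factory=lambda: ["MNI", "SVDI", "RFI"]
    )
    n_reps: int = 20  # per-cell repetitions for the desk-scale grid


class GainConfig(_Strict):
    r_A: float | None = None  # default: mean CV accuracy of the first model
    h_N2: float = 0.21
    cycle_gs: float = 1.0
    cycle_conv: float = 5.0


class MaskConfig(_Strict):
    beta_a: float = 1.2
    beta_b: float = 3.0


class RunConfig(_Strict):
    """Validated, fully-defaulted description of one pipeline run."""

    seed: int = 0
    stages: list[StageName] = Field(default_factory=list)
    out_dir: str = "polygs_run"
    population: PopulationConfig = Field(default_factory=PopulationConfig)
    two_populations: TwoPopConfig = Field(default_factory=TwoPopConfig)
    masking: MaskConfig = Field(default_factory=MaskConfig)
    calling: CallingConfig = Field(default_factory=CallingConfig)
    qc: QcStageConfig = Field(default_factory=QcStageConfig)
    blup: BlupConfig = Field(default_factory=BlupConfig)
    models: list[str] = Field(default_factory=lambda: ["rrBLUP"])
    chain: ChainConfig = Field(default_factory=ChainConfig)
    svr: SvrConfig = Field(default_factory=SvrConfig)
    rfr: RfrConfig = Field(default_factory=RfrConfig)
    cv: CvConfig = Field(default_factory=CvConfig)
    grid: GridConfig = Field(default_factory=GridConfig)
    gain: GainConfig = Field(default_factory=GainConfig)

    @field_validator("models")
    @classmethod
    def _check_models(cls, v):
        from .models import MODEL_TAGS

        bad = [m for m in v if m not in MODEL_TAGS]
        if bad:
            raise ValueError(f"unknown model tags {bad}; choose from {sorted(MODEL_TAGS)}")
        return v

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:12]


def validate_config(raw_text: str) -> RunConfig:
    """Parse and validate a YAML-style config; defaults are injected and the
    resolved configuration is echoed to the log."""
    data = yaml.safe_load(raw_text) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    cfg = RunConfig(**data)
    log.info("resolved config: %s", json.dumps(cfg.model_dump(), sort_keys=True))
    return cfg


def _model_params(cfg: RunConfig, tag: str) -> dict:
    if tag in ("BayesA", "BayesB", "BayesLasso"):
        return cfg.chain.model_dump()
    if tag in ("SVR-lin", "SVR-gau"):
        return cfg.svr.model_dump()
    if tag == "RFR":
        return {"n_trees": cfg.rfr.n_trees, "min_node": cfg.rfr.min_node}
    return {}


def _strategy_matrices(
    masked: dict[str, GenotypeMatrix], strategy: str
) -> dict[str, GenotypeMatrix]:
    """Emulate the discovery difference between calling strategies on
    pre-simulated matrices (used when the read-level stage is not selected).

    Separate discovery only reports markers polymorphic within a cohort;
    joint discovery reports every marker polymorphic in the pooled cohorts,
    under shared names, for both cohorts.
    """
    pops = list(masked)
    if strategy == "separate":
        out = {}
        for p in pops:
            codes = np.ma.masked_equal(masked[p].codes, MISSING)
            poly = np.asarray(codes.std(axis=0) > 0).ravel()
            out[p] = masked[p].select_markers(np.nonzero(poly)[0])
        return out
    stacked = np.ma.masked_equal(
        np.vstack([masked[p].codes for p in pops]), MISSING
    )
    poly = np.asarray(stacked.std(axis=0) > 0).ravel()
    return {p: masked[p].select_markers(np.nonzero(poly)[0]) for p in pops}


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the selected stages and write artifacts + manifest.

    Returns the artifact directory.  With an empty stage list only the
    manifest is written.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "config": cfg.model_dump(),
        "stage_seeds": {s: derive_seed(cfg.seed, s) for s in cfg.stages},
        "stages": {},
    }
    state: dict = {}

    for stage in cfg.stages:
        seed = derive_seed(cfg.seed, stage)
        log.info("stage %s (seed %d)", stage, seed)
        record = _run_stage(stage, cfg, seed, state, out)
        manifest["stages"][stage] = record

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _require(state: dict, key: str, stage: str, needed_by: str):
    if key not in state:
        raise RuntimeError(
            f"stage {needed_by!r} needs the output of stage {stage!r}; "
            f"add it to the stage list"
        )
    return state[key]


def _run_stage(stage: str, cfg: RunConfig, seed: int, state: dict, out: Path) -> dict:
    if stage == "simulate":
        p = cfg.population
        spec_a = PopulationSpec(
            n_individuals=p.n_individuals, n_markers=p.n_markers, n_qtl=p.n_qtl,
            h2=p.h2, ploidy_mode=p.ploidy_mode, n_blocks=p.n_blocks, seed=seed,
        )
        spec_b = PopulationSpec(
            n_individuals=cfg.two_populations.n_individuals_b,
            n_markers=p.n_markers, n_qtl=p.n_qtl, h2=p.h2,
            ploidy_mode=p.ploidy_mode, n_blocks=p.n_blocks, seed=seed,
        )
        (Ga, ma, ya), (Gb, mb, yb) = simulate_two_populations(
            spec_a, spec_b,
            shared_qtl_fraction=cfg.two_populations.shared_qtl_fraction,
            freq_divergence=cfg.two_populations.freq_divergence,
            seed=seed,
        )
        masked = {
            "A": mask_missing(Ga, lambda rng, m: rng.beta(cfg.masking.beta_a, cfg.masking.beta_b, m),
                              seed=derive_seed(seed, "maskA")),
            "B": mask_missing(Gb, lambda rng, m: rng.beta(cfg.masking.beta_a, cfg.masking.beta_b, m),
                              seed=derive_seed(seed, "maskB")),
        }
        state.update(complete={"A": Ga, "B": Gb}, truth={"A": ma, "B": mb},
                     phenotypes={"A": ya, "B": yb}, masked=masked)
        for pop in ("A", "B"):
            write_genotype_tsv(masked[pop], out / f"genotypes_{pop}.tsv")
            write_phenotype_tsv(state["phenotypes"][pop],
                                masked[pop].sample_ids, out / f"phenotypes_{pop}.tsv")
        return {"n_individuals": {"A": Ga.n_individuals, "B": Gb.n_individuals},
                "n_markers": Ga.n_markers}

    if stage == "call":
        complete = _require(state, "complete", "simulate", "call")
        panel = make_tag_panel(
            complete["A"].n_markers, seed=derive_seed(seed, "panel"),
            cutsite_remnant="CAGC",
        )
        tables = {}
        for pop, G in complete.items():
            fq = out / f"reads_{pop}.fastq"
            key = out / f"key_{pop}.tsv"
            simulate_tag_reads(G, panel, fq, key,
                               mean_depth=cfg.calling.mean_depth,
                               error_rate=cfg.calling.error_rate,
                               seed=derive_seed(seed, f"reads{pop}"))
            tables[pop] = calling.demultiplex_trim(fq, key, cfg.calling.cutsite_remnant)
        pops = list(tables)
        called = calling.call_snps(
            [tables[p] for p in pops], mode=cfg.calling.mode,
            min_total_reads=cfg.calling.min_tag_reads,
            min_depth=cfg.calling.min_depth,
            het_min_minor_reads=cfg.calling.het_min_minor_reads,
        )
        state["called"] = dict(zip(pops, called))
        return {pop: {"n_markers": g.n_markers} for pop, g in state["called"].items()}

    if stage == "qc":
        source = state.get("called") or _require(state, "masked", "simulate", "qc")
        thr = cfg.qc.thresholds[0] if len(cfg.qc.thresholds) == 1 else 0.30
        cleaned, ledgers = {}, {}
        if cfg.qc.joint and len(source) == 2:
            pops = list(source)
            stacked = GenotypeMatrix(
                codes=np.vstack([source[p].codes for p in pops]),
                sample_ids=[s for p in pops for s in source[p].sample_ids],
                marker_names=source[pops[0]].marker_names,
            )
            G3, ledger = qc.qc_pipeline(stacked, thr, cfg.qc.imputer,
                                        cfg.qc.maf_min, seed=seed)
            offset = 0
            for p in pops:
                n = source[p].n_individuals
                cleaned[p] = G3.select_individuals(np.arange(offset, offset + n))
                ledgers[p] = ledger
                offset += n
        else:
            for pop, G in source.items():
                cleaned[pop], ledgers[pop] = qc.qc_pipeline(
                    G, thr, cfg.qc.imputer, cfg.qc.maf_min, seed=seed)
        state["clean"] = cleaned
        for pop, ledger in ledgers.items():
            ledger.to_csv(out / f"qc_ledger_{pop}.tsv", sep="\t", index=False)
        return {pop: ledgers[pop].set_index("stage")["n_markers"].to_dict()
                for pop in ledgers}

    if stage == "blup":
        phen = _require(state, "phenotypes", "simulate", "blup")
        adjusted = {}
        rec = {}
        for pop, y in phen.items():
            trial = blup_mod_simulate(y, cfg.blup, derive_seed(seed, pop))
            adj, vc, h2 = blup_mod.adjust_trial(trial)
            trial.to_csv(out / f"trial_{pop}.tsv", sep="\t", index=False)
            adj.rename("phenotype").to_frame().to_csv(out / f"blup_{pop}.tsv", sep="\t")
            adjusted[pop] = adj.to_numpy()
            rec[pop] = {"s2_hs": vc.s2_hs, "s2_e": vc.s2_e, "h_B2": h2}
        state["blup_phenotypes"] = adjusted
        return rec

    if stage == "cv":
        clean = _require(state, "clean", "qc", "cv")
        phen = _require(state, "phenotypes", "simulate", "cv")
        rows = []
        for pop, G in clean.items():
            for tag in cfg.models:
                rep = evaluation.cross_validate(
                    G.codes, phen[pop], model_spec=(tag, _model_params(cfg, tag)),
                    train_frac=cfg.cv.train_frac, n_reps=cfg.cv.n_reps,
                    seed=derive_seed(seed, f"{pop}|{tag}"),
                    config={"population": pop, "model": tag},
                )
                rows.append(rep.to_row())
        table = pd.DataFrame(rows)
        table.to_csv(out / "cv_accuracy.tsv", sep="\t", index=False)
        state["cv_table"] = table
        return table.to_dict(orient="records")

    if stage == "grid":
        masked = state.get("called") or _require(state, "masked", "simulate", "grid")
        phen = _require(state, "phenotypes", "simulate", "grid")
        datasets = {}
        for strat in cfg.grid.strategies:
            per_pop = _strategy_matrices(masked, strat)
            for pop, G in per_pop.items():
                for imp in cfg.grid.imputers:
                    for thr in cfg.qc.thresholds:
                        G3, _ = qc.qc_pipeline(G, thr, imp, cfg.qc.maf_min,
                                               seed=derive_seed(seed, f"{strat}{pop}{imp}{thr}"))
                        datasets[(pop, strat, imp, thr)] = G3
        table = evaluation.run_benchmark_grid(
            datasets, phen, strategies=cfg.grid.strategies,
            imputers=cfg.grid.imputers, thresholds=cfg.qc.thresholds,
            models=cfg.models, n_reps=cfg.grid.n_reps,
            train_frac=cfg.cv.train_frac, seed=seed,
        )
        table.to_csv(out / "grid_accuracy.tsv", sep="\t", index=False)
        state["grid_table"] = table
        return {"n_cells": len(table)}

    if stage == "crosspop":
        clean = _require(state, "clean", "qc", "crosspop")
        phen = _require(state, "phenotypes", "simulate", "crosspop")
        pops = list(clean)
        Ga, Gb = qc.build_common(clean[pops[0]], clean[pops[1]])
        rows = []
        for tag in cfg.models:
            r_ab = evaluation.cross_population_predict(
                Ga.codes, phen[pops[0]], Gb.codes, phen[pops[1]],
                model_spec=(tag, _model_params(cfg, tag)), seed=seed)
            r_ba = evaluation.cross_population_predict(
                Gb.codes, phen[pops[1]], Ga.codes, phen[pops[0]],
                model_spec=(tag, _model_params(cfg, tag)), seed=seed)
            rows.append({"model": tag, f"{pops[0]}->{pops[1]}": r_ab,
                         f"{pops[1]}->{pops[0]}": r_ba})
        table = pd.DataFrame(rows)
        table.to_csv(out / "crosspop_accuracy.tsv", sep="\t", index=False)
        return table.to_dict(orient="records")

    if stage == "gwas":
        clean = _require(state, "clean", "qc", "gwas")
        phen = _require(state, "phenotypes", "simulate", "gwas")
        rec = {}
        for pop, G in clean.items():
            K = kinship_matrix(G)
            res = mixed_model_gwas(G, phen[pop], K)
            table = manhattan_export(res)
            table.to_csv(out / f"gwas_{pop}.tsv", sep="\t", index=False)
            rec[pop] = {"n_markers": len(table),
                        "min_p": float(table["p_value"].min())}
        return rec

    if stage == "gain":
        r_A = cfg.gain.r_A
        if r_A is None:
            table = state.get("cv_table")
            if table is None:
                raise RuntimeError("gain stage needs either gain.r_A or the cv stage")
            r_A = float(table["mean_r"].iloc[0])
        g = evaluation.gain_ratio(r_A, cfg.gain.h_N2, cfg.gain.cycle_gs,
                                  cfg.gain.cycle_conv)
        rec = {"r_A": g.r_A, "h_N": g.h_N, "gain_gs": g.gain_gs,
               "gain_conv": g.gain_conv, "ratio": g.ratio}
        pd.DataFrame([rec]).to_csv(out / "gain_comparison.tsv", sep="\t", index=False)
        return rec

    raise ValueError(f"unknown stage {stage!r}")


def blup_mod_simulate(y, blup_cfg: BlupConfig, seed: int) -> pd.DataFrame:
    from .simdata import simulate_progeny_trial

    return simulate_progeny_trial(
        y, r=blup_cfg.replications, s2_hs=blup_cfg.s2_hs, s2_e=blup_cfg.s2_e,
        seed=seed,
    )
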