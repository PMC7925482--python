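"""End-to-end orchestration: config schema, seed fan-out and stage runner.

``run_pipeline`` executes the requested stages in dependency order —
simulate (or load) -> pheno -> qc -> gwas -> predict -> ibcf — writing each
stage's CSV outputs and a plain-text log into the output directory.  The
master seed fans out to per-stage child seeds by stable hashing of the
stage name, so toggling stages never changes another stage's stream.
A stage failure is logged and its dependent stages are skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import geno as geno_mod
from . import io as io_mod
from .gblup import run_cv
from .gwas import MixedGwas, significant_hits, variance_explained, STRIGA_TRAIT_THRESHOLD, GY_THRESHOLD
from .ibcf import cv2_evaluate
from .pheno import TrialMixedModel, ausnpc, entry_mean_heritability, remove_outliers, trait_correlations
from .simulate import make_fixture_dataset, simulate_genotypes, simulate_striga_counts, simulate_trial

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

logger = logging.getLogger("strigakit")

ALL_STAGES = ["simulate", "pheno", "qc", "gwas", "predict", "ibcf"]


def stage_seed(master: int, stage: str) -> int:
    """Stable per-stage child seed derived from the master seed."""
    digest = hashlib.blake2b(f"{master}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "little") % (2**31)


class SimulateConfig(BaseModel):
    n_lines: int = 380
    n_markers: int = 2000
    n_chrom: int = 10
    n_subpops: int = 3
    fst: float = 0.15
    ld_rho: float = 0.6
    het_rate: float = 0.005
    missing_rate: float = 0.01
    n_env: int = 3
    n_rep: int = 2
    block_size: int = 5
    sigma2_G: float = 1.0
    sigma2_GE: float = 0.25
    sigma2_e: float = 1.0
    striga_counts: bool = True


class QcConfig(BaseModel):
    maf_min: float = 0.05
    missing_max: float = 0.05
    het_max: float = 0.05
    n_pc: int = 3
    ld_max_dist_bp: int = 100_000


class GwasConfig(BaseModel):
    n_pcs: int = 3
    threshold_traits: float = STRIGA_TRAIT_THRESHOLD
    threshold_gy: float = GY_THRESHOLD
    use_ld_threshold: bool = False


class PredictConfig(BaseModel):
    schemes: list[str] = Field(default_factory=lambda: ["CV0", "CV1", "CV2"])
    models: list[str] = Field(default_factory=lambda: ["G", "G+GE"])
    k_folds: int = 5
    n_repetitions: int = 10
    augment_with_hits: str = "none"  # none | whole-panel


class IbcfConfig(BaseModel):
    denominator: str = "signed"
    restrict_to_other_envs: bool = False
    drop_negative: bool = False
    k_folds: int = 5
    n_repetitions: int = 10


class RunConfig(BaseModel):
    """Validated pipeline configuration (serialized into the output dir)."""

    out_dir: str
    genotypes: str | None = None
    phenotypes: str | None = None
    stages: list[str] = Field(default_factory=lambda: list(ALL_STAGES))
    seed: int = 0
    traits: list[str] | None = None
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    qc: QcConfig = Field(default_factory=QcConfig)
    gwas: GwasConfig = Field(default_factory=GwasConfig)
    predict: PredictConfig = Field(default_factory=PredictConfig)
    ibcf: IbcfConfig = Field(default_factory=IbcfConfig)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.model_validate(data)


def _load_genotypes(path: str):
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"genotype file not found: {p}")
    if p.suffix in (".vcf",) or p.name.endswith(".vcf.gz"):
        return io_mod.read_vcf(p)
    if p.suffix in (".tsv", ".hmp") or "hapmap" in p.name or p.name.endswith(".hmp.txt"):
        return io_mod.read_hapmap(p)
    return io_mod.read_csv_matrix(p)


def _derive_ausnpc(pheno: pd.DataFrame) -> pd.DataFrame:
    """Add an AUSNPC trait wherever the three count traits are present."""
    count_traits = [t for t in ("nstr_8wap", "nstr_10wap", "nstr_12wap")
                    if t in set(pheno["trait"])]
    if len(count_traits) != 3 or "ausnpc" in set(pheno["trait"]):
        return pheno
    wide = pheno[pheno["trait"].isin(count_traits)].pivot_table(
        index=["line", "env", "rep", "block"], columns="trait", values="value")
    wide = wide.dropna()
    rows = wide.reset_index()
    rows["trait"] = "ausnpc"
    rows["value"] = [ausnpc([r["nstr_8wap"], r["nstr_10wap"], r["nstr_12wap"]])
                     for _, r in wide.reset_index().iterrows()]
    return pd.concat([pheno, rows[["line", "env", "rep", "block", "trait", "value"]]],
                     ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns a report dict of written paths
    and key tables.  Raises only on configuration errors — stage failures
    are recorded in the report and dependent stages are skipped."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)
    (out / "config.yaml").write_text(yaml.safe_dump(config.model_dump()))

    report: dict = {"outputs": {}, "failures": {}, "skipped": []}
    state: dict = {}
    stages = [s for s in ALL_STAGES if s in config.stages]
    deps = {"pheno": [], "qc": [], "gwas": ["pheno", "qc"],
            "predict": ["pheno", "qc"], "ibcf": ["pheno", "qc"], "simulate": []}

    def _run(stage, fn):
        failed_deps = [d for d in deps[stage] if d in report["failures"] or
                       (d not in stages and d not in state)]
        if failed_deps:
            logger.warning("skipping %s (unmet dependencies: %s)", stage, failed_deps)
            report["skipped"].append(stage)
            return
        t0 = time.time()
        logger.info("stage %s: start (seed %d)", stage, stage_seed(config.seed, stage))
        try:
            fn()
            logger.info("stage %s: done in %.1fs", stage, time.time() - t0)
        except Exception as e:  # noqa: BLE001 - stage isolation is the point
            logger.error("stage %s failed: %s", stage, e)
            report["failures"][stage] = str(e)

    # ---- inputs ----------------------------------------------------------
    def do_inputs():
        sc = config.simulate
        seed = stage_seed(config.seed, "simulate")
        if config.genotypes:
            state["geno"] = _load_genotypes(config.genotypes)
        else:
            state["geno"] = simulate_genotypes(
                sc.n_lines, sc.n_markers, sc.n_chrom, sc.n_subpops, sc.fst,
                sc.ld_rho, sc.het_rate, sc.missing_rate, seed=seed)
            io_mod.write_vcf(state["geno"], out / "genotypes.vcf")
            report["outputs"]["genotypes"] = str(out / "genotypes.vcf")
        if config.phenotypes:
            p = Path(config.phenotypes)
            if not p.exists():
                raise FileNotFoundError(f"phenotype file not found: {p}")
            state["pheno"] = io_mod.read_phenotypes(p)
        else:
            pheno, truth = simulate_trial(
                state["geno"], n_env=sc.n_env, n_rep=sc.n_rep, block_size=sc.block_size,
                sigma2_G=sc.sigma2_G, sigma2_GE=sc.sigma2_GE, sigma2_e=sc.sigma2_e,
                trait="gy", seed=seed + 1)
            state["truth"] = truth
            if sc.striga_counts:
                counts = simulate_striga_counts(
                    -truth.genetic_main_values.to_numpy(),  # susceptible lines yield less
                    line_ids=state["geno"].line_ids, n_env=sc.n_env, n_rep=sc.n_rep,
                    seed=seed + 2)
                pheno = pd.concat([pheno, counts], ignore_index=True)
            state["pheno"] = pheno
            io_mod.write_phenotypes(pheno, out / "phenotypes.csv")
            report["outputs"]["phenotypes"] = str(out / "phenotypes.csv")
        logger.info("inputs: %d lines x %d markers; %d phenotype records",
                    state["geno"].n_lines, state["geno"].n_markers, len(state["pheno"]))

    _run("simulate", do_inputs)
    if "geno" not in state:
        raise RuntimeError("no input data: simulate stage failed or was not configured")

    # ---- pheno -----------------------------------------------------------
    def do_pheno():
        pheno = _derive_ausnpc(state["pheno"])
        vc_rows, blups, blues = [], {}, {}
        blups_env: dict = {}
        all_traits = [t for t in sorted(pheno["trait"].unique())
                      if config.traits is None or t in config.traits or t == "ausnpc"]
        for trait in all_traits:
            cleaned, n_rm = remove_outliers(pheno, trait)
            if n_rm:
                logger.info("pheno: removed %d outlier records for %s", n_rm, trait)
            fit = TrialMixedModel(cleaned, trait, scope="across", genotype_as="random").fit()
            h2 = entry_mean_heritability(fit.vc)
            vc_rows.append({
                "trait": trait, "sigma2_G": fit.vc.sigma2_G,
                "sigma2_GE": fit.vc.sigma2_GE, "sigma2_e": fit.vc.sigma2_e,
                "h2": h2, "converged": fit.converged,
            })
            blups[trait] = fit.line_values.set_index("line")["value"]
            blue = TrialMixedModel(cleaned, trait, scope="across", genotype_as="fixed").fit()
            blues[trait] = blue.line_values.set_index("line")["value"]
            for env in sorted(cleaned.loc[cleaned["trait"] == trait, "env"].unique()):
                f = TrialMixedModel(cleaned, trait, scope=env, genotype_as="random").fit()
                blups_env[(trait, env)] = f.line_values.set_index("line")["value"]
            (out / "fit_logs").mkdir(exist_ok=True)
            (out / "fit_logs" / f"{trait}.log").write_text(fit.log + "\n" + fit.summary())
        vc_table = pd.DataFrame(vc_rows)
        vc_table.to_csv(out / "variance_components.csv", index=False)
        blup_df = pd.DataFrame(blups)
        blue_df = pd.DataFrame(blues)
        blup_df.to_csv(out / "blups.csv")
        blue_df.to_csv(out / "blues.csv")
        env_df = pd.DataFrame(blups_env)
        env_df.columns = [f"{t}@{e}" for t, e in env_df.columns]
        env_df.to_csv(out / "blups_per_env.csv")
        corr, pvals = trait_correlations(blue_df)
        corr.to_csv(out / "trait_correlations.csv")
        pvals.to_csv(out / "trait_correlation_pvalues.csv")
        state.update(pheno_aug=pheno, vc_table=vc_table, blups=blup_df,
                     blues=blue_df, blups_env=blups_env)
        report["outputs"]["variance_components"] = str(out / "variance_components.csv")

    _run("pheno", do_pheno)

    # ---- qc --------------------------------------------------------------
    def do_qc():
        g, rep = geno_mod.filter_snps(state["geno"], config.qc.maf_min,
                                      config.qc.missing_max, config.qc.het_max)
        logger.info("qc: retained %d / %d markers (%s)", rep["n_retained"],
                    rep["n_input"], rep)
        g = geno_mod.impute_missing(g)
        grm = geno_mod.vanraden_grm(g)
        scores, explained = geno_mod.pca(g, n_pc=config.qc.n_pc)
        ld = geno_mod.ld_decay(g, max_dist_bp=config.qc.ld_max_dist_bp)
        io_mod.write_grm(grm, out / "grm.tsv")
        pd.DataFrame(scores, index=pd.Index(g.line_ids, name="line"),
                     columns=[f"PC{i+1}" for i in range(scores.shape[1])]
                     ).to_csv(out / "pcs.csv")
        ld.binned.to_csv(out / "ld_decay.csv", index=False)
        (out / "ld_summary.json").write_text(json.dumps({
            "d_r2_01_bp": ld.d_r2_01, "d_r2_02_bp": ld.d_r2_02,
            "genome_length_bp": ld.genome_length_bp,
            "n_effective_tests": ld.n_effective_tests,
            "significance_threshold": ld.significance_threshold,
        }, indent=2))
        state.update(geno_qc=g, grm=grm, pcs=scores, ld=ld)
        report["outputs"]["grm"] = str(out / "grm.tsv")

    _run("qc", do_qc)

    # ---- gwas ------------------------------------------------------------
    def do_gwas():
        gc = config.gwas
        hits_rows = []
        scan_tables = []
        for trait, blup in state["blups"].items():
            threshold = gc.threshold_gy if trait == "gy" else gc.threshold_traits
            if gc.use_ld_threshold:
                threshold = state["ld"].significance_threshold
            scan = MixedGwas(blup, state["geno_qc"], K=state["grm"],
                             covariates=state["pcs"][:, :gc.n_pcs]).fit()
            t = scan.table.assign(trait=trait)
            scan_tables.append(t)
            hits = significant_hits(scan, threshold)
            if len(hits):
                idx = [state["geno_qc"].marker_names.index(s) for s in hits["snp"]]
                dos = state["geno_qc"].values[:, idx].astype(float)
                h2 = float(state["vc_table"].set_index("trait").loc[trait, "h2"])
                r2_adj, p_g, flag = variance_explained(blup.to_numpy(), dos, h2)
            else:
                r2_adj, p_g, flag = 0.0, 0.0, False
            hits = hits.assign(trait=trait, r2_adj=r2_adj, p_G=p_g, p_G_flagged=flag)
            hits_rows.append(hits)
            logger.info("gwas %s: %d hits (threshold %.2e), lambda_gc %.3f",
                        trait, len(hits), threshold, scan.lambda_gc())
        pd.concat(scan_tables, ignore_index=True).to_csv(out / "gwas_scan.csv", index=False)
        hit_table = pd.concat(hits_rows, ignore_index=True)
        hit_table.to_csv(out / "gwas_hits.csv", index=False)
        state["hits"] = hit_table
        report["outputs"]["gwas_hits"] = str(out / "gwas_hits.csv")

    _run("gwas", do_gwas)

    # ---- predict ---------------------------------------------------------
    def do_predict():
        pc = config.predict
        seed = stage_seed(config.seed, "predict")
        results = []
        for trait in state["blups"].columns:
            long = pd.DataFrame([
                {"line": l, "env": e, "value": v}
                for (t, e), s in state["blups_env"].items() if t == trait
                for l, v in s.items()
            ])
            covs = None
            if pc.augment_with_hits == "whole-panel" and "hits" in state:
                snps = state["hits"].loc[state["hits"]["trait"] == trait, "snp"]
                if len(snps):
                    idx = [state["geno_qc"].marker_names.index(s) for s in snps]
                    covs = pd.DataFrame(state["geno_qc"].values[:, idx].astype(float),
                                        index=state["geno_qc"].line_ids)
            for scheme in pc.schemes:
                for model in pc.models:
                    cv = run_cv(long, state["grm"], scheme, model=model,
                                k_folds=pc.k_folds, n_repetitions=pc.n_repetitions,
                                seed=seed, snp_covariates=covs)
                    results.append(cv.table.assign(trait=trait))
            cv_across = run_cv(state["blues"][trait], state["grm"], "across",
                               model="G", k_folds=pc.k_folds,
                               n_repetitions=pc.n_repetitions, seed=seed,
                               snp_covariates=covs)
            results.append(cv_across.table.assign(trait=trait))
        cv_table = pd.concat(results, ignore_index=True)
        cv_table.to_csv(out / "cv_accuracy.csv", index=False)
        summary = (cv_table.groupby(["trait", "scheme", "model", "environment"])
                   ["correlation"].mean().reset_index())
        summary.to_csv(out / "cv_accuracy_summary.csv", index=False)
        state["cv_table"] = cv_table
        report["outputs"]["cv_accuracy"] = str(out / "cv_accuracy.csv")

    _run("predict", do_predict)

    # ---- ibcf ------------------------------------------------------------
    def do_ibcf():
        ic = config.ibcf
        wide = pd.DataFrame(state["blups_env"])
        wide.columns = pd.MultiIndex.from_tuples(wide.columns, names=["trait", "env"])
        envs = sorted({e for _, e in wide.columns})
        seed = stage_seed(config.seed, "ibcf")
        rows = []
        for env in envs:
            res = cv2_evaluate(wide, env, k_folds=ic.k_folds,
                               n_repetitions=ic.n_repetitions, seed=seed,
                               denominator=ic.denominator,
                               restrict_to_other_envs=ic.restrict_to_other_envs,
                               drop_negative=ic.drop_negative)
            res = (res.groupby(["trait", "env"])["correlation"].mean()
                   .reset_index())
            rows.append(res.assign(method="IBCF"))
        ibcf_table = pd.concat(rows, ignore_index=True)
        comparison = [ibcf_table]
        if "cv_table" in state:
            g = (state["cv_table"].query("scheme == 'CV2' and model == 'G+GE'")
                 .groupby(["trait", "environment"])["correlation"].mean()
                 .reset_index().rename(columns={"environment": "env"})
                 .assign(method="GBLUP"))
            comparison.append(g)
        comp = pd.concat(comparison, ignore_index=True)
        comp.to_csv(out / "ibcf_vs_gblup.csv", index=False)
        report["outputs"]["ibcf_vs_gblup"] = str(out / "ibcf_vs_gblup.csv")

    _run("ibcf", do_ibcf)

    logger.removeHandler(fh)
    fh.close()
    return report


def write_fixtures(out_dir, seed: int = 0) -> dict:
    """Emit the canonical small dataset used by the test suite."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geno, pheno, truth = make_fixture_dataset(seed)
    io_mod.write_vcf(geno, out / "fixture_genotypes.vcf")
    io_mod.write_hapmap(geno, out / "fixture_genotypes.hmp.tsv")
    io_mod.write_phenotypes(pheno, out / "fixture_phenotypes.csv")
    return {"genotypes": str(out / "fixture_genotypes.vcf"),
            "phenotypes": str(out / "fixture_phenotypes.csv")}
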