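"""End-to-end pipeline driver over the synthetic study.

Stages run in order: simulate -> depth matching -> per-assay NB DE ->
three-way classification -> SMA slopes and TE -> proteome conditional
independence -> miRNA DE and target enrichment -> eQTL scan and class
enrichment -> 3'UTR SNP density and motif impact -> pathway ORA.  Every
stage draws its seed from the master seed; the manifest records versions,
seeds, thresholds, per-class gene counts and a content hash, so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .containers import CLASS_BUFFERED, CLASS_FORWARDED, CLASS_REINFORCED, CountMatrix
from .cisreg import impact_table, ora_hypergeometric, pwm_class_test, snp_density_compare, toy_pwms
from .de import adjust_and_call, classify_genes, estimate_dispersion, fc_correlation, nb_wald_test
from .eqtl import class_eqtl_enrichment, eqtl_scan
from .mirna import NO_DE_MIRNAS, quantile_scale, quasipoisson_de, target_enrichment
from .prep import match_depth, size_factors
from .proteome import conditional_independence_suite, protein_class_shift, strain_log_means
from .regulation import sma_common_slope_test, sma_fit, translational_efficiency
from .sim import (
    SimConfig,
    simulate_counts,
    simulate_mirna,
    simulate_proteome,
    simulate_ri_panel,
    simulate_utr_variants,
)


@dataclass
class PipelineConfig:
    """Thresholds, stage toggles and sizes for a full run."""

    sim: SimConfig = field(default_factory=SimConfig)
    de_method: str = "bonferroni"
    de_threshold: float = 0.01
    mirna_fdr: float = 0.05
    min_fpkm: float = 1.0
    eqtl_n_perm: int = 500
    eqtl_fdr: float = 0.05
    eqtl_max_genes: int = 3000
    motif_max_snps: int = 300
    motif_n_shuffles: int = 200
    n_pwms: int = 5
    pwm_width: int = 8
    run_proteome: bool = True
    run_mirna: bool = True
    run_eqtl: bool = True
    run_cis: bool = True
    seed: int = 0

    def stage_seed(self, name: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _hash_frames(frames: dict) -> str:
    h = hashlib.sha256()
    for name in sorted(frames):
        h.update(name.encode())
        h.update(frames[name].to_csv().encode())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | None = None) -> dict:
    """Execute all stages; returns ``{"results": ..., "manifest": ...}``.

    A stage whose inputs are disabled is skipped with a notice in the
    manifest; a stage failure raises with the stage name attached.
    """
    results: dict = {}
    notices: list[str] = []
    timings: dict = {}
    hashed: dict[str, pd.DataFrame] = {}

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                fn()
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
            timings[name] = round(time.time() - t0, 2)

        return deco

    state: dict = {}

    @stage("simulate")
    def _sim():
        rna1, rna2, ribo, truth = simulate_counts(config.sim)
        state.update(rna1=rna1, rna2=rna2, ribo=ribo, truth=truth)

    @stage("prep")
    def _prep():
        rna1, rna2, ribo = match_depth(
            [state["rna1"], state["rna2"], state["ribo"]], seed=config.stage_seed("prep")
        )
        state.update(rna1=rna1, rna2=rna2, ribo=ribo)

    @stage("de")
    def _de():
        de_tabs = {}
        for name in ("rna1", "rna2", "ribo"):
            cm: CountMatrix = state[name]
            sf = size_factors(cm)
            groups = cm.strain_indicator()
            disp = estimate_dispersion(cm, groups, sf)
            tab = nb_wald_test(cm, sf, disp, groups)
            de_tabs[name] = adjust_and_call(tab, config.de_method, config.de_threshold)
        state["de"] = de_tabs
        hashed.update({f"de_{k}": v for k, v in de_tabs.items()})

    @stage("classify")
    def _classify():
        de = state["de"]
        classified = classify_genes(de["rna1"], de["rna2"], de["ribo"])
        state["classified"] = classified
        results["classified"] = classified
        results["class_counts"] = classified["class_label"].value_counts().to_dict()
        ok = classified["testable"]
        results["fc_correlation"] = fc_correlation(
            classified.loc[ok, "rna_fc"], classified.loc[ok, "ribo_fc"]
        )
        hashed["classified"] = classified

    @stage("slopes_te")
    def _slopes():
        cl = state["classified"]
        slopes = {}
        for label in (CLASS_FORWARDED, CLASS_BUFFERED, CLASS_REINFORCED):
            sub = cl[cl["class_label"] == label]
            if len(sub) >= 3 and sub["rna_fc"].var() > 0 and sub["ribo_fc"].var() > 0:
                slopes[label] = sma_fit(sub["rna_fc"], sub["ribo_fc"])
            else:
                notices.append(f"SMA skipped for {label}: too few genes")
        results["sma_slopes"] = slopes
        tests = {}
        for a, b in ((CLASS_FORWARDED, CLASS_REINFORCED), (CLASS_FORWARDED, CLASS_BUFFERED)):
            ga = cl[cl["class_label"] == a]
            gb = cl[cl["class_label"] == b]
            if len(ga) >= 3 and len(gb) >= 3:
                try:
                    tests[f"{a} vs {b}"] = sma_common_slope_test(
                        [
                            (ga["rna_fc"].to_numpy(), ga["ribo_fc"].to_numpy()),
                            (gb["rna_fc"].to_numpy(), gb["ribo_fc"].to_numpy()),
                        ]
                    )
                except ValueError as e:
                    notices.append(f"common-slope test {a} vs {b} skipped: {e}")
        results["sma_tests"] = tests
        lens = state["truth"].genes["cds_length"]
        te = translational_efficiency(
            state["ribo"], state["rna1"], state["rna2"], lens, min_fpkm=config.min_fpkm
        )
        state["te"] = te
        results["te"] = te
        med = {
            label: float(te.loc[(cl["class_label"] == label) & te["defined"], "te"].median())
            for label in (CLASS_FORWARDED, CLASS_BUFFERED, CLASS_REINFORCED)
        }
        results["te_class_medians"] = med
        hashed["te"] = te

    if config.run_proteome:

        @stage("proteome")
        def _prot():
            protein = simulate_proteome(
                state["truth"], state["ribo"], config.sim.protein_noise_sd,
                seed=config.stage_seed("proteome"),
            )
            rna_log = (strain_log_means(state["rna1"]) + strain_log_means(state["rna2"])) / 2.0
            ribo_log = strain_log_means(state["ribo"])
            te = state["te"]
            keep = te.index[te["defined"]]
            suite = conditional_independence_suite(
                rna_log.loc[keep], ribo_log.loc[keep], protein.values.loc[keep]
            )
            results["conditional_independence"] = suite
            cl = state["classified"]
            ratio = protein.values["SHR"] - protein.values["BN"]
            try:
                results["protein_class_shift"] = protein_class_shift(
                    ratio, cl["class_label"], cl["ribo_fc"]
                )
            except ValueError as e:
                notices.append(f"protein class shift skipped: {e}")
            hashed["conditional_independence"] = suite
    else:
        notices.append("proteome stage skipped (disabled)")

    if config.run_mirna:

        @stage("mirna")
        def _mirna():
            counts, targets = simulate_mirna(config.sim, state["truth"])
            scaled = quantile_scale(counts)
            de = quasipoisson_de(scaled)
            de_set = set(de.index[(de["qvalue"] <= config.mirna_fdr).fillna(False)])
            results["mirna_de"] = de
            enr = target_enrichment(
                de_set, targets, {"heart": state["classified"]["class_label"]}
            )
            results["mirna_enrichment"] = enr
            if enr == NO_DE_MIRNAS:
                notices.append("miRNA enrichment: no DE miRNAs")
            hashed["mirna_de"] = de
    else:
        notices.append("miRNA stage skipped (disabled)")

    if config.run_eqtl:

        @stage("eqtl")
        def _eqtl():
            genotypes, ri_counts = simulate_ri_panel(config.sim, state["truth"])
            # one library per RI strain: estimate dispersion across the whole
            # panel (conservative under genotype effects)
            disp = estimate_dispersion(ri_counts, np.zeros(len(genotypes), dtype=int))
            genes = ri_counts.genes
            if config.eqtl_max_genes and len(genes) > config.eqtl_max_genes:
                rng = np.random.default_rng(config.stage_seed("eqtl_subset"))
                keep = np.sort(rng.choice(len(genes), config.eqtl_max_genes, replace=False))
                ri_counts = CountMatrix(
                    ri_counts.counts.iloc[keep], ri_counts.sample_meta.copy()
                )
                notices.append(f"eQTL scan restricted to {config.eqtl_max_genes} genes")
            scan = eqtl_scan(
                ri_counts, genotypes, disp,
                n_perm=config.eqtl_n_perm, seed=config.stage_seed("eqtl"),
                fdr=config.eqtl_fdr,
            )
            results["eqtl"] = scan
            cl = state["classified"]["class_label"].reindex(scan.index)
            results["eqtl_class_enrichment"] = class_eqtl_enrichment(cl, scan["eqtl"])
            hashed["eqtl"] = scan
    else:
        notices.append("eQTL stage skipped (disabled)")

    if config.run_cis:

        @stage("cis")
        def _cis():
            pwms = toy_pwms(config.n_pwms, config.pwm_width, seed=config.stage_seed("pwms"))
            variants, seqs = simulate_utr_variants(config.sim, state["truth"], pwms)
            utr_lengths = pd.Series(
                {g: len(s) for g, s in seqs.items()}, name="utr_length"
            )
            cl = state["classified"]["class_label"]
            results["snp_density"] = snp_density_compare(variants, utr_lengths, cl)
            scored = variants[variants["class_label"].isin(["reinforced", "forwarded"])]
            if config.motif_max_snps and len(scored) > config.motif_max_snps:
                rng = np.random.default_rng(config.stage_seed("cis_subset"))
                scored = scored.iloc[
                    np.sort(rng.choice(len(scored), config.motif_max_snps, replace=False))
                ]
            impacts = impact_table(
                scored, pwms, n_shuffles=config.motif_n_shuffles,
                seed=config.stage_seed("cis"),
            )
            snp_cls = scored["gene"].map(cl)  # snp_id -> observed gene class
            pwm_tests = pwm_class_test(impacts, snp_cls)
            results["pwm_class_test"] = pwm_tests
            hashed["pwm_class_test"] = pwm_tests
    else:
        notices.append("cis stage skipped (disabled)")

    @stage("ora")
    def _ora():
        truth = state["truth"].genes
        cl = state["classified"]
        rng = np.random.default_rng(config.stage_seed("ora"))
        universe = list(truth.index)
        de_genes = set(cl.index[cl["class_label"].isin([CLASS_FORWARDED, CLASS_REINFORCED])])
        pathways = {}
        de_pool = sorted(de_genes)
        for i in range(3):  # regulated pathways: half their members are DE
            members = set(rng.choice(de_pool, 25, replace=False)) | set(
                rng.choice(universe, 25, replace=False)
            )
            pathways[f"regulated_{i}"] = members
        for i in range(7):
            pathways[f"background_{i}"] = set(rng.choice(universe, 50, replace=False))
        results["ora"] = ora_hypergeometric(de_genes, pathways, universe)

    manifest = {
        "riboflow_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "seed": config.seed,
        "class_counts": results.get("class_counts", {}),
        "notices": notices,
        "content_hash": _hash_frames(hashed),
    }
    out = {"results": results, "manifest": manifest, "timings": timings}

    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        for name, df in hashed.items():
            df.to_csv(os.path.join(out_dir, f"{name}.tsv"), sep="\t")
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return out
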