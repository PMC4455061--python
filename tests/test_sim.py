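"""Generator contracts: determinism, class structure, marginal count law,
and the truth consistency of every auxiliary layer."""

import numpy as np
import pandas as pd
import pytest

from riboflow.cisreg import toy_pwms
from riboflow.sim import (
    SimConfig,
    _nb_draw,
    simulate_counts,
    simulate_mirna,
    simulate_proteome,
    simulate_ri_panel,
    simulate_utr_variants,
)


def test_config_validation_names_offending_field():
    with pytest.raises(ValueError, match="n_reps_per_strain"):
        SimConfig(n_reps_per_strain=1)
    with pytest.raises(ValueError, match="class_proportions"):
        SimConfig(class_proportions={"forwarded": 0.7, "none": 0.2})
    with pytest.raises(ValueError, match="reinforcement_slope"):
        SimConfig(reinforcement_slope=0.9)
    with pytest.raises(ValueError, match="library_size"):
        SimConfig(library_size=-1)
    with pytest.raises(ValueError, match="dispersion_mean"):
        SimConfig(dispersion_mean=float("nan"))


def test_null_model_all_none():
    cfg = SimConfig(n_genes=400, class_proportions={"none": 1.0}, seed=0)
    rna1, rna2, ribo, truth = simulate_counts(cfg)
    assert (truth.genes["beta_rna"] == 0).all()
    assert (truth.genes["beta_ribo"] == 0).all()
    strains = rna1.sample_meta["strain"].to_numpy()
    m_bn = rna1.counts.loc[:, strains == "BN"].mean(axis=1)
    m_shr = rna1.counts.loc[:, strains == "SHR"].mean(axis=1)
    ratio = (m_shr + 1) / (m_bn + 1)
    assert abs(np.log2(ratio).mean()) < 0.05


def test_seed_determinism_all_layers():
    outs = []
    for _ in range(2):
        cfg = SimConfig(n_genes=150, seed=7)
        rna1, rna2, ribo, truth = simulate_counts(cfg)
        mc, targets = simulate_mirna(cfg, truth)
        geno, ri = simulate_ri_panel(cfg, truth)
        pwms = toy_pwms(3, 8, seed=7)
        variants, seqs = simulate_utr_variants(cfg, truth, pwms)
        outs.append((rna1.counts, rna2.counts, ribo.counts, truth.genes,
                     mc.counts, targets, geno, ri.counts, variants, seqs))
    a, b = outs
    for x, y in zip(a, b):
        if isinstance(x, pd.DataFrame):
            pd.testing.assert_frame_equal(x, y)
        else:
            assert x == y


def test_forwarded_strain_ratio_matches_effect():
    # per-gene mean(SHR)/mean(BN) recovers 2^beta within Monte Carlo error
    cfg = SimConfig(
        n_genes=1000,
        class_proportions={"forwarded": 1.0},
        effect_size_log2=(1.0, 0.0),
        effect_min_log2=1.0,
        seed=3,
    )
    rna1, rna2, ribo, truth = simulate_counts(cfg)
    for cm in (rna1, rna2, ribo):
        strains = cm.sample_meta["strain"].to_numpy()
        m_bn = cm.counts.loc[:, strains == "BN"].mean(axis=1).to_numpy()
        m_shr = cm.counts.loc[:, strains == "SHR"].mean(axis=1).to_numpy()
        keep = m_bn > 20  # low-count genes have asymmetric ratio noise
        log_err = np.log2(m_shr[keep] / m_bn[keep]) - truth.genes["beta_rna"].to_numpy()[keep]
        se = log_err.std() / np.sqrt(keep.sum())
        assert abs(log_err.mean()) < 3 * se + 0.01


def test_truth_class_effect_invariants(small_study):
    t = small_study["truth"].genes
    cfg = small_study["config"]
    buf = t[t["class_label"] == "buffered"]
    rnf = t[t["class_label"] == "reinforced"]
    none = t[t["class_label"] == "none"]
    assert (buf["beta_rna"].abs() >= cfg.effect_min_log2).all()
    assert np.allclose(buf["beta_ribo"], cfg.buffering_slope * buf["beta_rna"])
    assert np.allclose(rnf["beta_ribo"], cfg.reinforcement_slope * rnf["beta_rna"])
    assert (rnf["beta_ribo"] != 0).all()
    assert (none[["beta_rna", "beta_ribo"]] == 0).all().all()


def test_nb_marginal_law():
    # sample variance tracks mu + alpha mu^2 over many replicate draws
    rng = np.random.default_rng(0)
    mu = np.full((4, 800), [50.0, 200.0, 1000.0, 5000.0][0])
    mu = np.tile(np.array([50.0, 200.0, 1000.0, 5000.0])[:, None], (1, 800))
    alpha = np.full(4, 0.05)
    draws = _nb_draw(rng, mu, alpha)
    v = draws.var(axis=1, ddof=1)
    expect = mu[:, 0] + 0.05 * mu[:, 0] ** 2
    assert np.all(np.abs(v / expect - 1) < 0.25)


def test_library_totals_concentrate_at_target():
    # relative total error is governed by dispersion, not Poisson sqrt(depth)
    cfg = SimConfig(n_genes=2000, seed=9)
    rna1, *_ = simulate_counts(cfg)
    totals = rna1.counts.sum(axis=0).to_numpy()
    assert np.all(np.abs(totals / totals.mean() - 1) < 0.05)


# ------------------------------------------------------------ proteome --

def test_proteome_noise_free_tracks_ribo(small_study):
    truth, ribo = small_study["truth"], small_study["ribo"]
    prot = simulate_proteome(truth, ribo, noise_sd=0.0, b=1.0, seed=1)
    cpm = ribo.counts / ribo.counts.sum(axis=0) * 1e6
    strains = ribo.sample_meta["strain"]
    for s in ("BN", "SHR"):
        expect = np.log(cpm.loc[:, (strains == s).to_numpy()].mean(axis=1) + 0.5)
        assert np.allclose(prot.values[s], expect)


def test_proteome_direction_follows_ribo_effect(small_study):
    truth, ribo = small_study["truth"], small_study["ribo"]
    prot = simulate_proteome(truth, ribo, noise_sd=0.1, seed=2)
    up = truth.genes.index[truth.genes["beta_ribo"] > 0]
    ratio = prot.values.loc[up, "SHR"] - prot.values.loc[up, "BN"]
    assert ratio.median() > 0


def test_proteome_rejects_negative_noise(small_study):
    with pytest.raises(ValueError, match="noise_sd"):
        simulate_proteome(small_study["truth"], small_study["ribo"], noise_sd=-0.1)


# -------------------------------------------------------------- miRNA --

def test_mirna_target_odds_ratio_recovered(small_study):
    cfg = SimConfig(n_genes=1200, target_odds_ratio=4.0, seed=42)
    truth = small_study["truth"]
    _, targets = simulate_mirna(cfg, truth)
    union = set().union(*(targets[m] for m in truth.mirnas.index[truth.mirnas["is_de"]]
                          if m in targets))
    cls = truth.genes["class_label"]
    a = cls.index[cls == "reinforced"]
    b = cls.index[cls == "forwarded"]
    at = sum(g in union for g in a)
    bt = sum(g in union for g in b)
    orat = (at / (len(a) - at)) / (bt / (len(b) - bt))
    assert 2.5 < orat < 6.0


def test_mirna_rejects_bad_inputs(small_study):
    truth = small_study["truth"]
    with pytest.raises(ValueError, match="n_mirna"):
        simulate_mirna(SimConfig(n_genes=1200, n_mirna=1, seed=1), truth)
    with pytest.raises(ValueError, match="target_odds_ratio"):
        cfg = SimConfig(n_genes=1200, seed=1)
        cfg.target_odds_ratio = 0.0
        simulate_mirna(cfg, truth)


# ------------------------------------------------------------ RI panel --

def test_ri_panel_genotype_contract(small_study):
    cfg = small_study["config"]
    geno, ri = simulate_ri_panel(cfg, small_study["truth"])
    vals = geno.to_numpy()
    assert set(np.unique(vals)) <= {0, 1}
    assert (vals.min(axis=0) == 0).all() and (vals.max(axis=0) == 1).all()
    assert ri.counts.shape == (cfg.n_genes, cfg.n_ri_strains)
    with pytest.raises(ValueError, match="n_markers"):
        simulate_ri_panel(SimConfig(n_genes=100, n_markers=1, seed=0), small_study["truth"])


def test_ri_eqtl_truth_only_in_rna_driven_classes(small_study):
    truth = small_study["truth"]
    simulate_ri_panel(small_study["config"], truth)
    cls = truth.genes["class_label"]
    for gene in truth.eqtl:
        assert cls[gene] in ("forwarded", "buffered")


# ---------------------------------------------------------- 3'UTR SNPs --

def test_utr_variants_contract(small_study):
    truth = small_study["truth"]
    pwms = toy_pwms(3, 8, seed=5)
    variants, seqs = simulate_utr_variants(small_study["config"], truth, pwms)
    assert (variants["flank5"].str.len() == 50).all()
    assert (variants["flank3"].str.len() == 50).all()
    assert (variants["ref"] != variants["alt"]).all()
    # flank + allele reconstructs the UTR context
    v = variants.iloc[0]
    seq = seqs[v["gene"]]
    pos = v["pos"] - 1
    assert seq[pos - 50:pos] == v["flank5"]
    assert seq[pos] == v["ref"]
    assert seq[pos + 1:pos + 51] == v["flank3"]
    # planted in-motif SNPs carry the planted PWM id
    in_motif = variants[variants["in_motif"]]
    assert (in_motif["pwm_id"] == pwms.pwms[0].id).all()
    assert (in_motif["class_label"] == "reinforced").all()


def test_utr_density_ratio_recovered():
    cfg = SimConfig(
        n_genes=600,
        class_proportions={"reinforced": 0.5, "forwarded": 0.5},
        snp_density_ratio=2.0,
        seed=8,
    )
    *_, truth = simulate_counts(cfg)
    variants, seqs = simulate_utr_variants(cfg, truth, toy_pwms(2, 8, seed=1))
    lens = pd.Series({g: len(s) for g, s in seqs.items()})
    cls = truth.genes["class_label"]
    dens = variants.groupby("gene").size().reindex(lens.index).fillna(0) / (lens / 1e3)
    ratio = dens[cls == "reinforced"].mean() / dens[cls == "forwarded"].mean()
    assert 1.7 < ratio < 2.3
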