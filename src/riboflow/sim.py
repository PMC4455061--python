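"""Multi-layer synthetic data generator with ground truth.

Emulates the statistical structure of a two-strain (BN vs SHR) ribosome
profiling study: negative-binomial counts for two RNA-seq assays and one
Ribo-seq assay over biological replicates, with genes drawn from four
regulatory modes —

``forwarded``
    a transcriptional strain effect propagated 1:1 to translation,
``buffered``
    an RNA-level effect attenuated at the translational level (ratio
    ``buffering_slope`` < 1),
``reinforced``
    a translational effect with at most a sub-threshold RNA component
    (ratio ``reinforcement_slope`` > 1),
``none``
    no strain effect on either layer.

On top of the count layers the generator can emit a protein layer driven by
the Ribo-seq layer, differentially expressed miRNAs whose targets are
enriched among reinforced genes, a recombinant-inbred genotype panel with
injected eQTL effects, and 3'UTR sequences with class-dependent SNP density
and motif-disrupting variants.  Every layer draws from its own RNG stream
split off the master seed, so adding one layer never perturbs another.

Strain effects are applied symmetrically on the log scale
(``mu_SHR = q * 2^{+beta/2}``, ``mu_BN = q * 2^{-beta/2}``) so that the
per-gene strain ratio is exactly ``2^beta`` while library totals stay
nearly balanced between strains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, SimTruth

# RNG stream ids, one per layer
_STREAM_COUNTS = 1
_STREAM_PROTEIN = 2
_STREAM_MIRNA = 3
_STREAM_RI = 4
_STREAM_UTR = 5

_CLASSES = ("forwarded", "buffered", "reinforced", "none")


def _layer_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe a clearly powered two-strain design: 5 biological
    replicates per strain, ~2e6 exonic reads per library, NB dispersion
    0.05, and two- to four-fold strain effects (|log2 effect| >= 1) among
    regulated genes.  ``buffering_slope = 0`` and a large
    ``reinforcement_slope`` generate the pure forms of the two
    post-transcriptional modes; intermediate values emulate partial
    buffering/amplification.
    """

    n_genes: int = 6000
    n_reps_per_strain: int = 5
    class_proportions: dict = field(
        default_factory=lambda: {
            "forwarded": 1.0 / 6.0,
            "buffered": 1.0 / 6.0,
            "reinforced": 1.0 / 6.0,
            "none": 0.5,
        }
    )
    effect_size_log2: tuple = (2.0, 0.5)  # (mean, sd) of |beta| before truncation
    effect_min_log2: float = 1.0
    reinforcement_slope: float = 8.0
    buffering_slope: float = 0.0
    dispersion_mean: float = 0.05
    dispersion_shape: float | None = None  # None -> constant dispersion
    library_size: float = 2e6
    expression_log_sd: float = 1.0
    te_baseline: float = 1.0
    te_log_sd: float = 0.5
    te_class_factor: dict = field(default_factory=lambda: {"buffered": 0.5})
    cds_length_mean: float = 1500.0
    cds_length_log_sd: float = 0.6
    protein_noise_sd: float = 0.3
    # miRNA layer
    n_mirna: int = 300
    mirna_reps: int = 4
    mirna_depth: float = 1e5
    mirna_dispersion: float = 0.02
    mirna_de_fraction: float = 0.3
    mirna_effect_log2: float = 1.0
    target_base_odds: float = 0.25
    target_odds_ratio: float = 4.0
    # recombinant-inbred panel
    n_ri_strains: int = 30
    n_markers: int = 20
    marker_block_size: int = 4
    eqtl_fraction: float = 0.5
    eqtl_effect_log2: float = 1.5
    ri_library_size: float = 2e6
    # 3'UTR variant layer
    utr_mean_length: float = 1000.0
    utr_log_sd: float = 0.5
    snp_rate_per_kb: float = 2.0
    snp_density_ratio: float = 2.0
    motif_snp_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        scalars = {
            "n_genes": self.n_genes,
            "n_reps_per_strain": self.n_reps_per_strain,
            "effect_min_log2": self.effect_min_log2,
            "dispersion_mean": self.dispersion_mean,
            "library_size": self.library_size,
            "expression_log_sd": self.expression_log_sd,
            "te_baseline": self.te_baseline,
            "te_log_sd": self.te_log_sd,
            "protein_noise_sd": self.protein_noise_sd,
            "n_mirna": self.n_mirna,
            "mirna_depth": self.mirna_depth,
            "mirna_dispersion": self.mirna_dispersion,
            "mirna_de_fraction": self.mirna_de_fraction,
            "target_base_odds": self.target_base_odds,
            "target_odds_ratio": self.target_odds_ratio,
            "n_ri_strains": self.n_ri_strains,
            "n_markers": self.n_markers,
            "eqtl_fraction": self.eqtl_fraction,
            "eqtl_effect_log2": self.eqtl_effect_log2,
            "utr_mean_length": self.utr_mean_length,
            "snp_rate_per_kb": self.snp_rate_per_kb,
            "snp_density_ratio": self.snp_density_ratio,
            "motif_snp_fraction": self.motif_snp_fraction,
        }
        for name, v in scalars.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"config field {name!r} must be finite and non-negative, got {v}")
        if self.n_reps_per_strain < 2:
            raise ValueError("config field 'n_reps_per_strain' must be >= 2")
        if not (self.reinforcement_slope > 1.0):
            raise ValueError("config field 'reinforcement_slope' must be > 1")
        if not (0.0 <= self.buffering_slope < 1.0):
            raise ValueError("config field 'buffering_slope' must be in [0, 1)")
        mean, sd = self.effect_size_log2
        if not (np.isfinite(mean) and np.isfinite(sd)) or mean < 0 or sd < 0:
            raise ValueError("config field 'effect_size_log2' must be finite non-negative (mean, sd)")
        bad = set(self.class_proportions) - set(_CLASSES)
        if bad:
            raise ValueError(f"config field 'class_proportions' has unknown classes: {sorted(bad)}")
        total = float(sum(self.class_proportions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"config field 'class_proportions' must sum to 1, got {total}")
        if self.target_odds_ratio <= 0:
            raise ValueError("config field 'target_odds_ratio' must be > 0")
        bad_te = set(self.te_class_factor) - set(_CLASSES)
        if bad_te:
            raise ValueError(f"config field 'te_class_factor' has unknown classes: {sorted(bad_te)}")
        for c, f in self.te_class_factor.items():
            if not np.isfinite(f) or f <= 0:
                raise ValueError(f"config field 'te_class_factor[{c}]' must be finite and positive")


# ----------------------------------------------------------------------
# counts layer
# ----------------------------------------------------------------------

def _class_counts(n_genes: int, proportions: dict) -> dict:
    """Largest-remainder apportionment of genes to classes."""
    props = {c: proportions.get(c, 0.0) for c in _CLASSES}
    raw = {c: n_genes * p for c, p in props.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n_genes - sum(counts.values())
    for c in sorted(_CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB2 sample: Poisson-gamma mixture so alpha may vary per gene."""
    alpha = np.broadcast_to(np.asarray(alpha, float), np.shape(mu)[:1])[:, None]
    mu = np.asarray(mu, float)
    if np.all(alpha <= 1e-12):
        return rng.poisson(mu)
    shape = 1.0 / np.maximum(alpha, 1e-12)
    lam = rng.gamma(shape, mu / shape)
    lam = np.where(alpha <= 1e-12, mu, lam)
    return rng.poisson(lam)


def simulate_counts(config: SimConfig):
    """Generate the three count layers and the ground truth.

    Returns ``(rna1, rna2, ribo, truth)`` where the three
    :class:`~riboflow.containers.CountMatrix` objects share gene ids and
    truth records each gene's class and per-layer log2 strain effect.
    """
    rng = _layer_rng(config.seed, _STREAM_COUNTS)
    n = config.n_genes
    genes = pd.Index([f"gene{i:05d}" for i in range(n)], name="gene")

    counts_per_class = _class_counts(n, config.class_proportions)
    labels = np.concatenate([np.repeat(c, k) for c, k in counts_per_class.items()])
    rng.shuffle(labels)

    mean, sd = config.effect_size_log2
    mag = rng.normal(mean, sd, size=n)
    while np.any(mag < config.effect_min_log2):
        bad = mag < config.effect_min_log2
        mag[bad] = rng.normal(mean, sd, size=bad.sum())
    sign = rng.choice([-1.0, 1.0], size=n)
    beta = sign * mag

    beta_rna = np.zeros(n)
    beta_ribo = np.zeros(n)
    fwd = labels == "forwarded"
    buf = labels == "buffered"
    rnf = labels == "reinforced"
    beta_rna[fwd] = beta[fwd]
    beta_ribo[fwd] = beta[fwd]
    beta_rna[buf] = beta[buf]
    beta_ribo[buf] = config.buffering_slope * beta[buf]
    beta_ribo[rnf] = beta[rnf]
    beta_rna[rnf] = beta[rnf] / config.reinforcement_slope

    q = np.exp(rng.normal(0.0, config.expression_log_sd, size=n))
    te = config.te_baseline * np.exp(rng.normal(0.0, config.te_log_sd, size=n))
    for cls_name, factor in config.te_class_factor.items():
        te[labels == cls_name] *= factor
    cds_len = np.exp(
        rng.normal(np.log(config.cds_length_mean), config.cds_length_log_sd, size=n)
    ).round().astype(np.int64)
    if config.dispersion_shape is None:
        alpha = np.full(n, config.dispersion_mean)
    else:
        alpha = rng.gamma(
            config.dispersion_shape, config.dispersion_mean / config.dispersion_shape, size=n
        )

    reps = config.n_reps_per_strain
    strains = np.array(["BN"] * reps + ["SHR"] * reps)
    x = (strains == "SHR").astype(float)  # sample-level strain indicator

    def layer(beta_layer: np.ndarray, te_scale: np.ndarray, assay: str) -> CountMatrix:
        base = q * te_scale
        scale = config.library_size / base.sum()
        # centered effect: per-gene SHR/BN ratio is exactly 2^beta
        mu = scale * base[:, None] * 2.0 ** (beta_layer[:, None] * (x[None, :] - 0.5))
        vals = _nb_draw(rng, mu, alpha)
        cols = [f"{assay}_{s}{i % reps + 1}" for i, s in enumerate(strains)]
        meta = pd.DataFrame(
            {
                "strain": strains,
                "tissue": "heart",
                "animal": [f"{s}{i % reps + 1}" for i, s in enumerate(strains)],
                "assay": assay,
            },
            index=pd.Index(cols, name="sample"),
        )
        return CountMatrix(pd.DataFrame(vals, index=genes, columns=cols), meta)

    ones = np.ones(n)
    rna1 = layer(beta_rna, ones, "RNA1")
    rna2 = layer(beta_rna, ones, "RNA2")
    ribo = layer(beta_ribo, te, "Ribo")

    truth_genes = pd.DataFrame(
        {
            "class_label": labels,
            "beta_rna": beta_rna,
            "beta_ribo": beta_ribo,
            "te_log2_ratio": beta_ribo - beta_rna,
            "te_baseline": te,
            "base_expression": q,
            "dispersion": alpha,
            "cds_length": cds_len,
        },
        index=genes,
    )
    return rna1, rna2, ribo, SimTruth(genes=truth_genes)


# ----------------------------------------------------------------------
# protein layer
# ----------------------------------------------------------------------

@dataclass
class ProteinTable:
    """Per-gene, per-strain log-scale protein abundances."""

    values: pd.DataFrame  # genes x strains
    meta: dict = field(default_factory=dict)


def simulate_proteome(
    truth: SimTruth,
    ribo_counts: CountMatrix,
    noise_sd: float,
    a: float = 0.0,
    b: float = 1.0,
    seed: int = 0,
    source_assay: str = "Ribo",
) -> ProteinTable:
    """Protein layer generated from the measured translation layer.

    For each strain, ``log protein = a + b * log(mean normalized counts) +
    N(0, noise_sd^2)``, making protein conditionally independent of RNA
    given the Ribo layer — the causal chain the conditional-independence
    suite is designed to detect.  Pass RNA counts as ``ribo_counts`` (and
    ``source_assay`` accordingly) to generate the mis-specified chain.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    missing = ribo_counts.genes.difference(truth.genes.index)
    if len(missing):
        raise ValueError(f"ribo_counts has genes absent from truth: {list(missing[:3])}")
    rng = _layer_rng(seed, _STREAM_PROTEIN)
    cpm = ribo_counts.counts / ribo_counts.counts.sum(axis=0) * 1e6
    strains = ribo_counts.sample_meta["strain"]
    out = {}
    for strain in sorted(strains.unique()):
        m = cpm.loc[:, (strains == strain).to_numpy()].mean(axis=1)
        out[strain] = a + b * np.log(m + 0.5) + rng.normal(0.0, noise_sd, size=len(m))
    values = pd.DataFrame(out, index=ribo_counts.genes)
    return ProteinTable(values, meta={"a": a, "b": b, "noise_sd": noise_sd, "source": source_assay})


# ----------------------------------------------------------------------
# miRNA layer
# ----------------------------------------------------------------------

def simulate_mirna(config: SimConfig, truth: SimTruth, seed: int | None = None):
    """miRNA counts plus a target map enriched among reinforced genes.

    A fraction of miRNAs carry a strain effect; targets of those DE miRNAs
    are drawn with ``target_odds_ratio``-fold higher odds from reinforced
    than from forwarded genes.  Returns ``(CountMatrix, target_map)`` and
    records miRNA truth on ``truth``.
    """
    if config.n_mirna < 2:
        raise ValueError("n_mirna must be >= 2")
    if config.target_odds_ratio <= 0:
        raise ValueError("target_odds_ratio must be > 0")
    rng = _layer_rng(config.seed if seed is None else seed, _STREAM_MIRNA)
    n = config.n_mirna
    ids = pd.Index([f"mir{i:04d}" for i in range(n)], name="mirna")

    is_de = rng.random(n) < config.mirna_de_fraction
    sign = rng.choice([-1.0, 1.0], size=n)
    beta = np.where(is_de, sign * config.mirna_effect_log2, 0.0)

    q = np.exp(rng.normal(0.0, 1.0, size=n))
    reps = config.mirna_reps
    strains = np.array(["BN"] * reps + ["SHR"] * reps)
    x = (strains == "SHR").astype(float)
    scale = config.mirna_depth / q.sum()
    mu = scale * q[:, None] * 2.0 ** (beta[:, None] * (x[None, :] - 0.5))
    vals = _nb_draw(rng, mu, np.full(n, config.mirna_dispersion))
    cols = [f"miRNA_{s}{i % reps + 1}" for i, s in enumerate(strains)]
    meta = pd.DataFrame(
        {
            "strain": strains,
            "tissue": "heart",
            "animal": [f"m{s}{i % reps + 1}" for i, s in enumerate(strains)],
            "assay": "miRNA",
        },
        index=pd.Index(cols, name="sample"),
    )
    counts = CountMatrix(pd.DataFrame(vals, index=ids, columns=cols), meta)

    # Target map: per-gene probability of being in the DE-miRNA target union
    # depends on the gene's class through the configured odds ratio.
    classes = truth.genes["class_label"]
    odds = pd.Series(config.target_base_odds, index=classes.index)
    odds[classes == "reinforced"] *= config.target_odds_ratio
    p_target = (odds / (1.0 + odds)).to_numpy()
    in_union = rng.random(len(classes)) < p_target

    de_ids = list(ids[is_de])
    targets: dict[str, set] = {m: set() for m in ids}
    union_genes = classes.index[in_union]
    if de_ids:
        for g in union_genes:
            k = 1 + rng.integers(0, min(3, len(de_ids)))
            for m in rng.choice(de_ids, size=k, replace=False):
                targets[m].add(g)
    # background targets for non-DE miRNAs
    non_de = list(ids[~is_de])
    all_genes = classes.index.to_numpy()
    for m in non_de:
        k = rng.poisson(5)
        for g in rng.choice(all_genes, size=min(k, len(all_genes)), replace=False):
            targets[m].add(g)

    truth.mirnas = pd.DataFrame({"is_de": is_de, "log2fc": beta}, index=ids)
    truth.targets = {m: s for m, s in targets.items() if s}
    return counts, dict(truth.targets)


# ----------------------------------------------------------------------
# recombinant-inbred panel
# ----------------------------------------------------------------------

def simulate_ri_panel(config: SimConfig, truth: SimTruth, seed: int | None = None):
    """Block-structured biallelic RI genotypes plus one expression library
    per RI strain, with eQTL effects injected into a fraction of the
    RNA-regulated (forwarded and buffered) genes.

    Returns ``(genotypes, CountMatrix)`` where ``genotypes`` is a strains x
    markers DataFrame of {0,1}.
    """
    if config.n_ri_strains < 8:
        raise ValueError("n_ri_strains must be >= 8")
    if config.n_markers < 2:
        raise ValueError("n_markers must be >= 2")
    rng = _layer_rng(config.seed if seed is None else seed, _STREAM_RI)
    n_s, n_m = config.n_ri_strains, config.n_markers
    block = max(1, int(config.marker_block_size))

    geno = np.zeros((n_s, n_m), dtype=np.int64)
    for j in range(n_m):
        if j % block == 0:
            geno[:, j] = rng.integers(0, 2, size=n_s)
        else:
            flip = rng.random(n_s) < 0.05
            geno[:, j] = np.where(flip, 1 - geno[:, j - 1], geno[:, j - 1])
    # enforce polymorphism
    for j in range(n_m):
        if geno[:, j].min() == geno[:, j].max():
            i = rng.integers(0, n_s)
            geno[i, j] = 1 - geno[i, j]

    classes = truth.genes["class_label"]
    rna_driven = classes.isin(["forwarded", "buffered"]).to_numpy()
    has_eqtl = rna_driven & (rng.random(len(classes)) < config.eqtl_fraction)
    marker_of = rng.integers(0, n_m, size=len(classes))

    q = truth.genes["base_expression"].to_numpy()
    alpha = truth.genes["dispersion"].to_numpy()
    beta = np.where(has_eqtl, config.eqtl_effect_log2, 0.0)
    g_of_gene = geno[:, marker_of].T  # genes x strains
    scale = config.ri_library_size / q.sum()
    mu = scale * q[:, None] * 2.0 ** (beta[:, None] * (g_of_gene - 0.5))
    vals = _nb_draw(rng, mu, alpha)

    strain_ids = [f"RI{i + 1:02d}" for i in range(n_s)]
    meta = pd.DataFrame(
        {
            "strain": strain_ids,
            "tissue": "heart",
            "animal": strain_ids,
            "assay": "RNA_RI",
        },
        index=pd.Index(strain_ids, name="sample"),
    )
    counts = CountMatrix(pd.DataFrame(vals, index=truth.genes.index, columns=strain_ids), meta)
    genotypes = pd.DataFrame(
        geno, index=pd.Index(strain_ids, name="strain"),
        columns=[f"m{j:03d}" for j in range(n_m)],
    )
    truth.eqtl = {
        g: int(marker_of[i]) for i, g in enumerate(classes.index) if has_eqtl[i]
    }
    return genotypes, counts


# ----------------------------------------------------------------------
# 3'UTR variants
# ----------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_utr_variants(config: SimConfig, truth: SimTruth, pwms, seed: int | None = None):
    """3'UTR sequences and SNPs with class-dependent density.

    Reinforced genes get ``snp_density_ratio``-fold the per-kb SNP rate of
    other classes, and a fraction ``motif_snp_fraction`` of their SNPs is
    placed at the most informative position of a planted consensus site of
    ``pwms[0]`` with the most disruptive alternative base.  Every SNP
    carries 50 bp flanks on each side.

    Returns ``(variants, utr_sequences)``: a DataFrame (one row per SNP:
    gene, pos, ref, alt, flank5, flank3, class_label, in_motif, pwm_id)
    and a dict gene -> sequence.
    """
    if len(pwms.pwms) == 0:
        raise ValueError("PWMSet must be non-empty")
    if config.utr_mean_length <= 0:
        raise ValueError("utr_mean_length must be positive")
    rng = _layer_rng(config.seed if seed is None else seed, _STREAM_UTR)
    planted = pwms.pwms[0]
    consensus_idx = planted.matrix.argmax(axis=0)  # per-column consensus base
    width = planted.matrix.shape[1]

    classes = truth.genes["class_label"]
    seqs: dict[str, str] = {}
    rows = []
    flank = 50
    for gene, cls in classes.items():
        length = max(2 * flank + width + 10,
                     int(np.exp(rng.normal(np.log(config.utr_mean_length), config.utr_log_sd))))
        seq = rng.integers(0, 4, size=length)
        site_start = -1
        if cls == "reinforced":
            site_start = int(rng.integers(flank, length - flank - width))
            seq[site_start:site_start + width] = consensus_idx
        rate = config.snp_rate_per_kb * (config.snp_density_ratio if cls == "reinforced" else 1.0)
        n_snp = rng.poisson(rate * length / 1000.0)
        positions = set()
        for _ in range(n_snp):
            in_motif = False
            pwm_id = ""
            if cls == "reinforced" and rng.random() < config.motif_snp_fraction:
                # disruptive SNP somewhere in the planted site: the alt allele
                # is the least-favored base of that column
                col = int(rng.integers(0, width))
                pos = site_start + col
                ref_i = int(seq[pos])
                col_probs = planted.matrix[:, col]
                alt_i = int(col_probs.argmin())
                if alt_i == ref_i:
                    alt_i = int(col_probs.argsort()[1])
                in_motif, pwm_id = True, planted.id
            else:
                pos = int(rng.integers(flank, length - flank))
                if site_start >= 0 and site_start <= pos < site_start + width:
                    in_motif, pwm_id = True, planted.id
                ref_i = int(seq[pos])
                alt_i = int(rng.choice([b for b in range(4) if b != ref_i]))
            if pos in positions:
                continue
            positions.add(pos)
            rows.append((gene, pos, ref_i, alt_i, in_motif, pwm_id, cls, length))
        seqs[gene] = "".join(_BASES[seq])

    recs = []
    for i, (gene, pos, ref_i, alt_i, in_motif, pwm_id, cls, length) in enumerate(rows):
        s = seqs[gene]
        recs.append(
            {
                "snp_id": f"snp{i:05d}",
                "gene": gene,
                "pos": pos + 1,  # 1-based within UTR
                "ref": _BASES[ref_i],
                "alt": _BASES[alt_i],
                "flank5": s[pos - flank:pos],
                "flank3": s[pos + 1:pos + 1 + flank],
                "class_label": cls,
                "in_motif": bool(in_motif),
                "pwm_id": pwm_id,
                "utr_length": length,
            }
        )
    variants = pd.DataFrame(recs).set_index("snp_id") if recs else pd.DataFrame(
        columns=["gene", "pos", "ref", "alt", "flank5", "flank3",
                 "class_label", "in_motif", "pwm_id", "utr_length"]
    )
    truth.snps = variants[["gene", "in_motif", "pwm_id"]].copy() if len(variants) else variants
    return variants, seqs
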