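"""3'UTR variant analysis: SNP density, PWM binding-affinity impact, ORA.

Binding affinity follows the TRAP biophysical model: for each sequence
window the mismatch energy against the PWM consensus is
``E = (1/lambda) * sum_pos ln(p_max(pos) / p_base(pos))`` and the window's
occupancy is ``R0 e^{-E} / (1 + R0 e^{-E})``; affinity is the sum of
occupancies over all windows on both strands (defaults ``lambda = 0.7``,
``R0 = exp(0.584 * width - 5.66)``).  A SNP's impact on a motif is the
absolute log-ratio of the empirical binding p-values of the two alleles,
with the null distribution built from composition-preserving shuffles of
the 101-base allele sequence.  Per PWM, impacts of SNPs in reinforced
(RIBO_only) genes are compared against SNPs in forwarded (RNA+RIBO) genes
with a one-sided Mann-Whitney test, BH-adjusted across PWMs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CLASS_FORWARDED, CLASS_REINFORCED

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = np.array([3, 2, 1, 0, 4])


@dataclass
class PWM:
    """Position weight matrix: rows A, C, G, T of per-position probabilities."""

    id: str
    matrix: np.ndarray  # (4, width)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValueError(f"PWM {self.id!r}: need a 4 x width matrix")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(f"PWM {self.id!r}: columns must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))


@dataclass
class PWMSet:
    pwms: list = field(default_factory=list)
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        fixed = []
        for p in self.pwms:
            if p.matrix.shape[1] < 4:
                raise ValueError(f"PWM {p.id!r}: set members need width >= 4")
            m = np.asarray(p.matrix, dtype=float) + self.pseudocount
            fixed.append(PWM(p.id, m / m.sum(axis=0, keepdims=True)))
        self.pwms = fixed

    def __iter__(self):
        return iter(self.pwms)

    def __len__(self):
        return len(self.pwms)


def toy_pwms(n_pwms: int = 5, width: int = 8, seed: int = 0, info: float = 0.9) -> PWMSet:
    """Small synthetic PWM set: each motif concentrates probability ``info``
    on a random consensus base per column.  Handy planted/decoy fixtures."""
    rng = np.random.default_rng(seed)
    pwms = []
    for i in range(n_pwms):
        cons = rng.integers(0, 4, size=width)
        m = np.full((4, width), (1.0 - info) / 3.0)
        m[cons, np.arange(width)] = info
        pwms.append(PWM(f"pwm{i:02d}", m))
    return PWMSet(pwms)


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in seq.upper()], dtype=np.int8)
    except KeyError as e:  # pragma: no cover - message only
        raise ValueError(f"invalid base {e.args[0]!r}") from None


def default_r0(width: int) -> float:
    return float(np.exp(0.584 * width - 5.66))


def _log_probs(pwm: PWM) -> np.ndarray:
    """(5, width) log-probability lookup; row 4 (N) is the column mean."""
    m = pwm.matrix
    return np.log(np.vstack([m, m.mean(axis=0)]))


def trap_affinity_batch(seqs: np.ndarray, pwm: PWM, lambda_param: float = 0.7, r0: float | None = None) -> np.ndarray:
    """TRAP affinity for a batch of equal-length encoded sequences (B, L)."""
    seqs = np.atleast_2d(np.asarray(seqs, dtype=np.int8))
    L, w = seqs.shape[1], pwm.width
    if L < w:
        raise ValueError("sequence shorter than PWM width")
    if r0 is None:
        r0 = default_r0(w)
    logp = _log_probs(pwm)
    log_pmax = float(np.log(pwm.matrix.max(axis=0)).sum())
    total = np.zeros(seqs.shape[0])
    for strand in (seqs, _COMPLEMENT[seqs][:, ::-1]):
        win = np.lib.stride_tricks.sliding_window_view(strand, w, axis=1)  # (B, nW, w)
        log_pseq = logp[win, np.arange(w)].sum(axis=2)
        energy = (log_pmax - log_pseq) / lambda_param
        x = r0 * np.exp(-energy)
        total += (x / (1.0 + x)).sum(axis=1)
    return total


def trap_affinity(sequence: str, pwm: PWM, lambda_param: float = 0.7, r0: float | None = None) -> float:
    """TRAP affinity of one sequence (both strands summed)."""
    return float(trap_affinity_batch(encode(sequence)[None, :], pwm, lambda_param, r0)[0])


def _shuffled(rng: np.random.Generator, seq: np.ndarray, n: int) -> np.ndarray:
    return rng.permuted(np.tile(seq, (n, 1)), axis=1)


def affinity_pvalue(
    sequence,
    pwm: PWM,
    n_shuffles: int = 200,
    seed: int = 0,
    lambda_param: float = 0.7,
    r0: float | None = None,
) -> float:
    """Empirical binding p-value against composition-preserving shuffles.

    ``p = (1 + #{shuffled affinity >= observed}) / (n_shuffles + 1)``.
    """
    if n_shuffles < 200:
        raise ValueError("n_shuffles must be >= 200")
    seq = encode(sequence) if isinstance(sequence, str) else np.asarray(sequence, dtype=np.int8)
    if seq.size < pwm.width:
        raise ValueError("background too short for this PWM")
    rng = np.random.default_rng(seed)
    obs = trap_affinity_batch(seq[None, :], pwm, lambda_param, r0)[0]
    null = trap_affinity_batch(_shuffled(rng, seq, n_shuffles), pwm, lambda_param, r0)
    return (1.0 + float((null >= obs - 1e-12).sum())) / (n_shuffles + 1.0)


def snp_motif_impact(
    variant,
    pwm: PWM,
    n_shuffles: int = 200,
    seed: int = 0,
    lambda_param: float = 0.7,
    r0: float | None = None,
    utr_seq: str | None = None,
) -> dict:
    """Affinity impact of one SNP on one PWM.

    ``variant`` needs fields ``flank5``, ``ref``, ``alt``, ``flank3`` (and
    ``pos``/``gene`` if ``utr_seq`` is supplied for a reference check).
    Impact is ``|ln p_ref - ln p_alt|`` with both empirical p-values
    computed against shuffles of the respective 101-base allele sequence
    under a shared seed.
    """
    ref_seq = f"{variant['flank5']}{variant['ref']}{variant['flank3']}"
    alt_seq = f"{variant['flank5']}{variant['alt']}{variant['flank3']}"
    if utr_seq is not None:
        pos = int(variant["pos"]) - 1
        if utr_seq[pos].upper() != str(variant["ref"]).upper():
            raise ValueError(
                f"reference mismatch at {variant.get('gene', '?')}:{pos + 1}: "
                f"UTR has {utr_seq[pos]!r}, variant says {variant['ref']!r}"
            )
    p_ref = affinity_pvalue(ref_seq, pwm, n_shuffles, seed, lambda_param, r0)
    p_alt = affinity_pvalue(alt_seq, pwm, n_shuffles, seed, lambda_param, r0)
    impact = 0.0 if ref_seq == alt_seq else abs(np.log(p_ref) - np.log(p_alt))
    return {"affinity_ref": trap_affinity(ref_seq, pwm, lambda_param, r0),
            "affinity_alt": trap_affinity(alt_seq, pwm, lambda_param, r0),
            "p_ref": p_ref, "p_alt": p_alt, "impact": float(impact)}


def impact_table(
    variants: pd.DataFrame,
    pwms: PWMSet,
    n_shuffles: int = 200,
    seed: int = 0,
    lambda_param: float = 0.7,
) -> pd.DataFrame:
    """Affinity impact of every SNP against every PWM (long format).

    Vectorizes over SNPs: all allele sequences share the 101-base layout,
    so observed and shuffled affinities are computed in batches per PWM.
    Shuffles are shared between the two alleles of a SNP (paired design).
    """
    if len(variants) == 0:
        return pd.DataFrame(columns=["snp_id", "pwm_id", "p_ref", "p_alt", "impact"])
    rng = np.random.default_rng(seed)
    ref = np.stack([encode(f"{v.flank5}{v.ref}{v.flank3}") for v in variants.itertuples()])
    alt = np.stack([encode(f"{v.flank5}{v.alt}{v.flank3}") for v in variants.itertuples()])
    n_snp, L = ref.shape
    # one shuffle index set per SNP, reused across PWMs and alleles
    order = np.argsort(rng.random((n_snp, n_shuffles, L)), axis=2)
    rows = []
    for pwm in pwms:
        a_ref = trap_affinity_batch(ref, pwm, lambda_param)
        a_alt = trap_affinity_batch(alt, pwm, lambda_param)
        p_ref = np.empty(n_snp)
        p_alt = np.empty(n_snp)
        for i in range(n_snp):
            null_ref = trap_affinity_batch(ref[i][order[i]], pwm, lambda_param)
            null_alt = trap_affinity_batch(alt[i][order[i]], pwm, lambda_param)
            p_ref[i] = (1.0 + (null_ref >= a_ref[i] - 1e-12).sum()) / (n_shuffles + 1.0)
            p_alt[i] = (1.0 + (null_alt >= a_alt[i] - 1e-12).sum()) / (n_shuffles + 1.0)
        impact = np.abs(np.log(p_ref) - np.log(p_alt))
        rows.append(
            pd.DataFrame(
                {
                    "snp_id": variants.index,
                    "pwm_id": pwm.id,
                    "p_ref": p_ref,
                    "p_alt": p_alt,
                    "impact": impact,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def pwm_class_test(
    impacts: pd.DataFrame,
    snp_classes: pd.Series,
    class_a: str = CLASS_REINFORCED,
    class_b: str = CLASS_FORWARDED,
) -> pd.DataFrame:
    """Per-PWM one-sided Mann-Whitney: are impacts larger for SNPs in
    reinforced genes than in forwarded genes?  BH-adjusted across PWMs.

    ``impacts`` is the long table from :func:`impact_table`; ``snp_classes``
    maps snp_id -> gene class.  PWMs with fewer than 2 SNPs in either class
    are skipped (reported with NaN).
    """
    cls = impacts["snp_id"].map(snp_classes)
    rows = []
    for pwm_id, sub in impacts.groupby("pwm_id", sort=True):
        a = sub.loc[(cls[sub.index] == class_a).to_numpy(), "impact"].to_numpy()
        b = sub.loc[(cls[sub.index] == class_b).to_numpy(), "impact"].to_numpy()
        if a.size < 2 or b.size < 2:
            rows.append({"pwm_id": pwm_id, "n_a": a.size, "n_b": b.size,
                         "U": np.nan, "pvalue": np.nan, "skipped": True})
            continue
        u, p = stats.mannwhitneyu(a, b, alternative="greater")
        rows.append({"pwm_id": pwm_id, "n_a": a.size, "n_b": b.size,
                     "U": float(u), "pvalue": float(p), "skipped": False})
    out = pd.DataFrame(rows).set_index("pwm_id")
    ok = ~out["skipped"].to_numpy()
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok] = multipletests(out.loc[ok, "pvalue"].to_numpy(), method="fdr_bh")[1]
    out["qvalue"] = q
    return out


def snp_density_compare(
    variants: pd.DataFrame,
    utr_lengths: pd.Series,
    classes: pd.Series,
    pairs=((CLASS_REINFORCED, CLASS_FORWARDED),),
    sided: str = "two-sided",
) -> pd.DataFrame:
    """Per-gene 3'UTR SNP density (SNPs per kb) compared between classes.

    Genes with annotated UTRs and zero SNPs count with density 0; genes
    carrying variants but lacking a UTR length are excluded (reported).
    """
    n_snps = variants.groupby("gene").size()
    lengths = utr_lengths[np.isfinite(utr_lengths) & (utr_lengths > 0)]
    orphan = set(n_snps.index) - set(lengths.index)
    density = (n_snps.reindex(lengths.index).fillna(0.0) / (lengths / 1e3)).rename("snp_per_kb")
    rows = []
    for a, b in pairs:
        da = density[classes.reindex(density.index) == a].dropna()
        db = density[classes.reindex(density.index) == b].dropna()
        if da.empty or db.empty:
            raise ValueError(f"empty class in pair ({a}, {b})")
        u, p = stats.mannwhitneyu(da, db, alternative=sided)
        rows.append(
            {
                "class_a": a, "class_b": b,
                "median_a": float(da.median()), "median_b": float(db.median()),
                "U": float(u), "pvalue": float(p),
                "n_excluded_no_utr": len(orphan),
            }
        )
    return pd.DataFrame(rows)


def ora_hypergeometric(
    gene_set,
    pathway_sets: dict,
    universe,
    min_overlap: int = 2,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene set in pathway sets.

    Upper-tail p-value per pathway; pathways overlapping the gene set in
    fewer than ``min_overlap`` genes are excluded; Bonferroni adjustment
    over the pathways actually tested.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(gene_set) & universe
    rows = []
    for name, members in pathway_sets.items():
        members = set(members) & universe
        k = len(members & hits)
        if k < min_overlap:
            continue
        p = stats.hypergeom.sf(k - 1, len(universe), len(members), len(hits))
        rows.append({"pathway": name, "overlap": k, "pathway_size": len(members),
                     "pvalue": float(p)})
    out = pd.DataFrame(rows, columns=["pathway", "overlap", "pathway_size", "pvalue"])
    if len(out):
        out["padj"] = np.minimum(out["pvalue"] * len(out), 1.0)
        out = out.set_index("pathway").sort_values("pvalue")
    else:
        out["padj"] = []
        out = out.set_index("pathway")
    return out
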