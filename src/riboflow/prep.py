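"""Count-level preparation: depth matching, normalization, Ribo-seq QC.

Depth matching mirrors the study design in which every animal contributes
one library per assay: within each animal, all libraries are downsampled
without replacement to the smallest library total, removing depth as a
confounder between sequencing technologies.  Normalization follows the
median-of-ratios convention of the DESeq family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix


def _downsample_column(rng: np.random.Generator, col: np.ndarray, target: int) -> np.ndarray:
    """Multivariate-hypergeometric downsampling of one library to ``target``
    reads: reads are physical items sampled without replacement."""
    total = int(col.sum())
    assert 0 <= target <= total, "target exceeds library total"
    if target == total:
        return col.copy()
    return rng.multivariate_hypergeometric(col, target, method="marginals")


def match_depth(matrices: list[CountMatrix], seed: int, scope: str = "animal") -> list[CountMatrix]:
    """Downsample libraries so totals match within each animal.

    Every animal must appear in every assay across ``matrices``.  For each
    animal the target is the minimum column total among that animal's
    libraries; each library is then downsampled to it by sampling reads
    without replacement (multivariate hypergeometric), deterministically
    under ``seed``.  With ``scope="global"`` a single target — the minimum
    over all samples — is used instead.

    Returns new matrices in the same order; inputs are not modified.
    """
    if scope not in ("animal", "global"):
        raise ValueError("scope must be 'animal' or 'global'")
    rng = np.random.default_rng(seed)
    assays = [set(m.sample_meta["assay"]) for m in matrices]
    animal_sets = [set(m.sample_meta["animal"]) for m in matrices]
    all_animals = set().union(*animal_sets)
    for animal in sorted(all_animals):
        for m, aset, asy in zip(matrices, animal_sets, assays):
            if animal not in aset:
                raise ValueError(
                    f"animal {animal!r} is missing from assay(s) {sorted(asy)}"
                )

    totals = {}  # (matrix idx, sample) -> total
    by_animal: dict[str, list] = {a: [] for a in all_animals}
    for i, m in enumerate(matrices):
        col_tot = m.counts.sum(axis=0)
        for sample in m.samples:
            animal = m.sample_meta.loc[sample, "animal"]
            totals[(i, sample)] = int(col_tot[sample])
            by_animal[animal].append((i, sample))

    if scope == "global":
        global_target = min(totals.values())
        targets = {k: global_target for k in totals}
    else:
        targets = {}
        for animal, keys in by_animal.items():
            t = min(totals[k] for k in keys)
            for k in keys:
                targets[k] = t

    out = []
    for i, m in enumerate(matrices):
        new = m.counts.copy()
        for sample in m.samples:
            col = m.counts[sample].to_numpy(dtype=np.int64)
            new[sample] = _downsample_column(rng, col, targets[(i, sample)])
        out.append(CountMatrix(new, m.sample_meta.copy()))
    return out


@dataclass
class SizeFactors:
    """Per-sample positive scale factors, geometric mean 1."""

    factors: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("size factors must be positive")

    def to_numpy(self) -> np.ndarray:
        return self.factors.to_numpy(dtype=float)


def size_factors(counts: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors (DESeq convention), rescaled to
    geometric mean 1.

    Only genes with nonzero counts in every sample enter the median; an
    error advises filtering if no such gene exists.
    """
    k = counts.values().astype(float)
    expressed = (k > 0).all(axis=1)
    if not expressed.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; filter all-zero genes first"
        )
    ke = k[expressed]
    log_geo = np.log(ke).mean(axis=1, keepdims=True)
    ratios = np.log(ke) - log_geo
    log_s = np.median(ratios, axis=0)
    log_s = log_s - log_s.mean()  # geometric mean 1
    return SizeFactors(pd.Series(np.exp(log_s), index=counts.samples, name="size_factor"))


@dataclass
class ReadStartSet:
    """5' read-start positions relative to annotated start codons.

    ``offsets`` are signed integers (negative = upstream of the start
    codon); ``genes`` name the gene each read was assigned to, with genes
    absent from the annotation reported separately by
    :func:`frame_periodicity`.
    """

    genes: np.ndarray
    offsets: np.ndarray
    lengths: np.ndarray


def frame_periodicity(starts: ReadStartSet, psite_offset: int = 12, annotation=None):
    """Triplet periodicity and start-peak diagnostics for Ribo-seq.

    Shifts each 5' read start by ``psite_offset`` to its P-site and reports
    the fraction of reads in each codon frame plus the modal unshifted
    5'-start offset (the start peak; ~-12 for 29-mers of initiating
    ribosomes).  Reads on genes absent from ``annotation`` (an iterable of
    valid gene ids, optional) are counted and excluded.

    Returns a dict with keys ``frame_fractions``, ``start_peak_offset``,
    ``n_used`` and ``n_unannotated``.
    """
    offsets = np.asarray(starts.offsets, dtype=np.int64)
    genes = np.asarray(starts.genes)
    if offsets.size == 0:
        raise ValueError("empty read-start set")
    if annotation is not None:
        valid = np.isin(genes, np.asarray(list(annotation)))
    else:
        valid = np.ones(offsets.shape, dtype=bool)
    n_un = int((~valid).sum())
    offs = offsets[valid]
    if offs.size == 0:
        raise ValueError("no read starts on annotated genes")
    frames = np.mod(offs + psite_offset, 3)
    fracs = np.bincount(frames, minlength=3) / offs.size
    vals, counts = np.unique(offs, return_counts=True)
    peak = int(vals[np.argmax(counts)])
    return {
        "frame_fractions": tuple(float(f) for f in fracs),
        "start_peak_offset": peak,
        "n_used": int(offs.size),
        "n_unannotated": n_un,
    }
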