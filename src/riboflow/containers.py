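"""Core in-memory containers shared across the pipeline.

The universal input is a gene-by-sample matrix of non-negative integer read
counts together with per-sample metadata (strain, tissue, animal, assay).
Everything downstream — depth matching, normalization, differential
expression, translational-efficiency scoring — consumes this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Metadata columns every sample must carry.
META_COLUMNS = ("strain", "tissue", "animal", "assay")

#: Regulatory-mode labels used throughout.
CLASS_FORWARDED = "RNA+RIBO"
CLASS_BUFFERED = "RNA_only"
CLASS_REINFORCED = "RIBO_only"
CLASS_NONE = "none"
CLASS_DISCORDANT = "discordant"

CLASS_LABELS = (
    CLASS_FORWARDED,
    CLASS_BUFFERED,
    CLASS_REINFORCED,
    CLASS_NONE,
    CLASS_DISCORDANT,
)

#: Map from generator-truth class names to the observed-classification labels.
TRUTH_TO_CLASS = {
    "forwarded": CLASS_FORWARDED,
    "buffered": CLASS_BUFFERED,
    "reinforced": CLASS_REINFORCED,
    "none": CLASS_NONE,
}


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, genes as rows (unique index),
        samples as columns.
    sample_meta
        DataFrame indexed by sample id with columns ``strain``, ``tissue``,
        ``animal`` and ``assay``; must cover every column of ``counts``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            dup = self.counts.index[self.counts.index.duplicated()][:3].tolist()
            raise ValueError(f"duplicate gene ids: {dup}")
        vals = self.counts.to_numpy()
        if np.issubdtype(vals.dtype, np.floating):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [c for c in self.counts.columns if c not in self.sample_meta.index]
        if missing:
            raise ValueError(f"samples missing metadata: {missing}")
        absent = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if absent:
            raise ValueError(f"sample_meta lacks columns: {absent}")
        # align metadata rows with count columns
        self.sample_meta = self.sample_meta.loc[list(self.counts.columns)]

    # -- convenience ---------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def values(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=np.int64)

    def subset_samples(self, mask) -> "CountMatrix":
        cols = self.counts.columns[np.asarray(mask)]
        return CountMatrix(self.counts[cols].copy(), self.sample_meta.loc[cols].copy())

    def strain_indicator(self, reference: str = "BN") -> np.ndarray:
        """0/1 vector per sample: 0 for the reference strain, 1 otherwise."""
        return (self.sample_meta["strain"].to_numpy() != reference).astype(np.int64)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, s = self.counts.shape
        assays = sorted(set(self.sample_meta["assay"]))
        return f"CountMatrix({g} genes x {s} samples, assays={assays})"


@dataclass
class SimTruth:
    """Ground truth emitted by the synthetic generator.

    Attributes
    ----------
    genes
        DataFrame indexed by gene id with columns ``class_label`` (forwarded /
        buffered / reinforced / none), ``beta_rna`` and ``beta_ribo``
        (log2 strain effects, SHR over BN), ``te_log2_ratio`` (strain log2
        ratio of translational efficiency), ``te_baseline`` and
        ``base_expression``.
    mirnas
        DataFrame indexed by miRNA id with columns ``is_de`` and
        ``log2fc``; empty until :func:`simulate_mirna` runs.
    targets
        Mapping miRNA id -> set of target gene ids.
    eqtl
        Mapping gene id -> causal marker index (genes without an entry have
        no causal marker).
    snps
        DataFrame indexed by snp id with columns ``gene``, ``in_motif``,
        ``pwm_id``; empty until :func:`simulate_utr_variants` runs.
    """

    genes: pd.DataFrame
    mirnas: pd.DataFrame = field(default_factory=pd.DataFrame)
    targets: dict = field(default_factory=dict)
    eqtl: dict = field(default_factory=dict)
    snps: pd.DataFrame = field(default_factory=pd.DataFrame)

    def class_of(self) -> pd.Series:
        return self.genes["class_label"]
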