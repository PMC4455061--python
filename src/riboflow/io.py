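"""Readers and writers for the pipeline's standard formats.

Counts travel as TSV (genes x samples) with a sidecar TSV of sample
metadata; genotypes and truth tables as TSV; UTR sequences as FASTA;
variants as VCF (CHROM = gene id, POS = 1-based offset within the UTR,
flanks and class in INFO); PWMs in MEME minimal motif format.  Coordinates
follow each format's native convention: BED is 0-based half-open, VCF is
1-based.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .cisreg import PWM, PWMSet
from .containers import CountMatrix


# ---------------------------------------------------------------- TSV --

def write_counts(cm: CountMatrix, path: str, meta_path: str | None = None) -> None:
    cm.counts.to_csv(path, sep="\t")
    if meta_path is None:
        meta_path = _meta_path(path)
    cm.sample_meta.to_csv(meta_path, sep="\t")


def _meta_path(path: str) -> str:
    root, ext = os.path.splitext(path)
    return f"{root}.samples{ext or '.tsv'}"


def read_counts(path: str, meta_path: str | None = None) -> CountMatrix:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][:3].tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dup}")
    if meta_path is None:
        meta_path = _meta_path(path)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return CountMatrix(counts, meta)


def write_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t")


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_genotypes(path: str) -> pd.DataFrame:
    g = pd.read_csv(path, sep="\t", index_col=0)
    vals = g.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{path}: genotypes must be 0/1 (homozygous RI lines)")
    return g.astype(np.int64)


# ---------------------------------------------------------------- BED --

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_annotation(path: str) -> pd.DataFrame:
    """BED6 gene annotation; 0-based half-open, so length = end - start."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    if bed.shape[1] < 4:
        raise ValueError(f"{path}: need at least 4 BED columns (chrom start end name)")
    bed = bed.iloc[:, :6]
    bed.columns = _BED_COLS[: bed.shape[1]]
    if (bed["end"] <= bed["start"]).any():
        bad = bed.index[(bed["end"] <= bed["start"])][0]
        raise ValueError(f"{path} line {bad + 1}: end <= start")
    bed["length"] = bed["end"] - bed["start"]
    return bed.set_index("name")


# -------------------------------------------------------------- FASTA --

def write_fasta(seqs: dict, path: str, width: int = 70) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seq_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    seq_write(records, path, "fasta")


def read_fasta(path: str) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------- VCF --

_VCF_INFO = (
    '##INFO=<ID=F5,Number=1,Type=String,Description="50 bp 5-prime flank">\n'
    '##INFO=<ID=F3,Number=1,Type=String,Description="50 bp 3-prime flank">\n'
    '##INFO=<ID=CLASS,Number=1,Type=String,Description="gene regulatory class">\n'
    '##INFO=<ID=INMOTIF,Number=0,Type=Flag,Description="SNP inside a planted motif site">\n'
    '##INFO=<ID=PWM,Number=1,Type=String,Description="planted PWM id">\n'
)


def write_vcf(variants: pd.DataFrame, path: str, contig_lengths: dict | None = None) -> None:
    """Variants to VCF: CHROM = gene id, POS = 1-based offset in the UTR."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(_VCF_INFO)
        if contig_lengths:
            for name, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={int(ln)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants.itertuples():
            info = f"F5={v.flank5};F3={v.flank3};CLASS={v.class_label}"
            if getattr(v, "in_motif", False):
                info += ";INMOTIF"
            if getattr(v, "pwm_id", ""):
                info += f";PWM={v.pwm_id}"
            fh.write(
                f"{v.gene}\t{int(v.pos)}\t{v.Index}\t{v.ref}\t{v.alt}\t.\t.\t{info}\n"
            )


def read_vcf(path: str, utr_seqs: dict | None = None) -> pd.DataFrame:
    """VCF back into the variant table; optionally checks REF against the
    UTR FASTA sequence and raises "reference mismatch" on disagreement."""
    import pysam

    rows = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            ref, alt = rec.ref, rec.alts[0]
            if utr_seqs is not None and rec.chrom in utr_seqs:
                base = utr_seqs[rec.chrom][rec.pos - 1]
                if base.upper() != ref.upper():
                    raise ValueError(
                        f"reference mismatch at {rec.chrom}:{rec.pos}: "
                        f"FASTA has {base!r}, VCF says {ref!r}"
                    )
            info = rec.info
            rows.append(
                {
                    "snp_id": rec.id,
                    "gene": rec.chrom,
                    "pos": rec.pos,
                    "ref": ref,
                    "alt": alt,
                    "flank5": info.get("F5", ""),
                    "flank3": info.get("F3", ""),
                    "class_label": info.get("CLASS", ""),
                    "in_motif": bool(info.get("INMOTIF", False)),
                    "pwm_id": info.get("PWM", ""),
                }
            )
    return pd.DataFrame(rows).set_index("snp_id")


# --------------------------------------------------------------- MEME --

def write_meme(pwms: PWMSet, path: str) -> None:
    """MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.width} nsites= 1000000 E= 0\n"
            )
            for col in p.matrix.T:
                fh.write(" ".join(f"{x:.6f}" for x in col) + "\n")
            fh.write("\n")


def read_meme(path: str, pseudocount: float = 1e-3) -> PWMSet:
    from Bio import motifs

    with open(path) as fh:
        parsed = motifs.parse(fh, "minimal")
    pwms = []
    for m in parsed:
        mat = np.array([m.pwm[b] for b in "ACGT"], dtype=float)
        pwms.append(PWM(m.name, mat / mat.sum(axis=0, keepdims=True)))
    return PWMSet(pwms, pseudocount=pseudocount)
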