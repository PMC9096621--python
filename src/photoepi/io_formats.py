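"""Readers and writers for the external formats the pipeline touches.

Conventions enforced on ingest:

* GFF3 is 1-based inclusive; it is converted to 0-based half-open here.
* Cytosine reports follow the Bismark CX/coverage dialect: one row per
  cytosine with ``chrom, pos(1-based), strand, meth_count, unmeth_count,
  context`` and any extra trailing columns ignored.
* BED is already 0-based half-open and passes through unchanged.
* JASPAR PFM text is parsed with Biopython's motif parser.

Everything downstream of this module sees a single coordinate convention.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .core import CONTEXTS, CountMatrix, GeneModel, GenomicInterval, PFM

DEFAULT_GENE_TYPES = ("gene",)
DEFAULT_TE_TYPES = ("transposable_element", "repeat_region")

CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth", "context"]


class FormatError(ValueError):
    """A file violated the expected format."""


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path, gene_types=DEFAULT_GENE_TYPES, te_types=DEFAULT_TE_TYPES):
    """Read gene and TE features from a GFF3 file as :class:`GeneModel` s.

    Only rows whose type is in *gene_types* or *te_types* are retained; which
    GFF3 types count as TEs varies between annotation dialects and is
    therefore configurable. Coordinates are converted from GFF3's 1-based
    inclusive to 0-based half-open.
    """
    gene_types = set(gene_types)
    te_types = set(te_types)
    models: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 columns, got {len(fields)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in gene_types and ftype not in te_types:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from None
            if end_i < start_i:
                raise FormatError(f"{path}: line {lineno}: end < start")
            attr_map = _parse_gff3_attributes(attrs, path, lineno)
            if "ID" not in attr_map:
                raise FormatError(f"{path}: line {lineno}: feature without ID attribute")
            fid = attr_map["ID"]
            if fid in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate feature ID {fid!r}")
            seen.add(fid)
            feature_class = "gene" if ftype in gene_types else "TE"
            if feature_class == "TE" and strand not in ("+", "-"):
                strand = "."
            models.append(
                GeneModel(
                    gene_id=fid,
                    interval=GenomicInterval(chrom, start_i - 1, end_i, strand, name=fid),
                    feature_class=feature_class,
                )
            )
    return models


def _parse_gff3_attributes(attrs, path, lineno):
    out = {}
    for item in attrs.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise FormatError(f"{path}: line {lineno}: malformed attribute {item!r}")
        key, value = item.split("=", 1)
        out[key] = value
    return out


def write_gff3(models, path):
    """Write GeneModels back to GFF3 (gene / transposable_element rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            ftype = "gene" if m.feature_class == "gene" else "transposable_element"
            iv = m.interval
            fh.write(
                f"{iv.chrom}\tphotoepi\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={m.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Cytosine reports


def read_cytosine_report(path, min_total=0, as_frame=True):
    """Read a Bismark-style cytosine report.

    Sites whose coverage (meth + unmeth) is below *min_total* are dropped —
    the study's analyses considered only cytosines with >= 10x coverage, so
    callers typically pass ``min_total=10``. Positions are converted from
    1-based to 0-based.

    Returns a DataFrame with columns chrom, pos, strand, context, meth, total
    (or a list of :class:`CytosineSite` when ``as_frame=False``).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=range(6),
        names=CYTOSINE_COLUMNS,
        dtype={"chrom": str, "strand": str, "context": str},
    )
    if len(df) == 0:
        df = pd.DataFrame(columns=["chrom", "pos", "strand", "context", "meth", "total"])
        return df if as_frame else []
    bad_ctx = ~df["context"].isin(CONTEXTS)
    if bad_ctx.any():
        tok = df.loc[bad_ctx, "context"].iloc[0]
        raise FormatError(f"{path}: unknown context token {tok!r}")
    if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
        raise FormatError(f"{path}: negative count")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise FormatError(f"{path}: invalid strand {df.loc[bad_strand, 'strand'].iloc[0]!r}")
    df["pos"] = df["pos"].astype(np.int64) - 1
    df["total"] = df["meth"] + df["unmeth"]
    df = df[df["total"] >= min_total].reset_index(drop=True)
    df = df[["chrom", "pos", "strand", "context", "meth", "total"]]
    if as_frame:
        return df
    from .core import CytosineSite

    return [
        CytosineSite(r.chrom, int(r.pos), r.strand, r.context, int(r.meth), int(r.total))
        for r in df.itertuples()
    ]


def write_cytosine_report(sites, path):
    """Write sites (DataFrame with chrom,pos,strand,context,meth,total) as a report.

    Positions are written 1-based; round-trips losslessly through
    :func:`read_cytosine_report`.
    """
    df = sites if isinstance(sites, pd.DataFrame) else _sites_to_frame(sites)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"].astype(np.int64) + 1,
            "strand": df["strand"],
            "meth": df["meth"].astype(np.int64),
            "unmeth": (df["total"] - df["meth"]).astype(np.int64),
            "context": df["context"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def _sites_to_frame(sites):
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "strand": [s.strand for s in sites],
            "context": [s.context for s in sites],
            "meth": [s.meth for s in sites],
            "total": [s.total for s in sites],
        }
    )


# ---------------------------------------------------------------------------
# BED


def read_bed(path):
    """Read BED3/BED6 into a list of :class:`GenomicInterval`."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(GenomicInterval(chrom, start, end, strand, name=name))
    return intervals


def write_bed(intervals, path, scores=None):
    """Write intervals as BED6 (BED3 plus name/score/strand columns).

    Coordinates are emitted as-is (already 0-based half-open); the written
    file round-trips through :func:`read_bed`.
    """
    if scores is not None and len(scores) != len(intervals):
        raise ValueError("scores length must match intervals")
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            score = scores[i] if scores is not None else 0
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# JASPAR PFMs


def read_jaspar_pfm(path):
    """Read one or more motifs from JASPAR-format text into :class:`PFM` s."""
    with open(path) as fh:
        text = fh.read()
    try:
        parsed = bio_motifs.parse(io.StringIO(text), "jaspar")
        records = list(parsed)
    except Exception as exc:  # Biopython raises bare Exceptions on bad input
        raise FormatError(f"{path}: not valid JASPAR PFM text ({exc})") from exc
    if not records:
        raise FormatError(f"{path}: no motifs found")
    out = []
    for rec in records:
        counts = np.array([rec.counts[b] for b in "ACGT"], dtype=float)
        motif_id = rec.matrix_id or rec.name
        out.append(PFM(motif_id=motif_id, counts=counts))
    return out


def write_jaspar_pfm(pfms, path):
    with open(path, "w") as fh:
        for pfm in pfms:
            fh.write(f">{pfm.motif_id}\n")
            for base, row in zip("ACGT", pfm.counts):
                cells = " ".join(f"{v:g}" for v in row)
                fh.write(f"{base} [ {cells} ]\n")


# ---------------------------------------------------------------------------
# Count matrices


def read_count_matrix(path, lib_sizes=None):
    """Read a TSV count matrix (first column feature ids, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    counts = df.to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise FormatError(f"{path}: non-integer counts")
        counts = counts.astype(np.int64)
    return CountMatrix(df.index.astype(str), df.columns.astype(str), counts, lib_sizes)


def write_count_matrix(matrix, path):
    pd.DataFrame(
        matrix.counts, index=matrix.feature_ids, columns=matrix.sample_ids
    ).rename_axis("feature_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences, path, width=80):
    """Write {name: sequence-string} to FASTA."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path):
    """Random-access genome handle (pyfaidx); index built on first use."""
    from pyfaidx import Fasta

    return Fasta(str(path))
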