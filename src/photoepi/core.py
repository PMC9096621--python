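"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based, half-open (BED convention). The format
readers in :mod:`photoepi.io_formats` are the only place where ±1 coordinate
arithmetic happens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CONTEXTS = ("CG", "CHG", "CHH")
STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of bases shared with *other* (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    """An annotated feature: a protein-coding gene or a transposable element."""

    gene_id: str
    interval: GenomicInterval
    feature_class: str = "gene"  # "gene" or "TE"

    def __post_init__(self):
        if self.feature_class not in ("gene", "TE"):
            raise ValueError(f"unknown feature_class {self.feature_class!r}")
        if self.feature_class == "gene" and self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id} must be stranded")

    @property
    def tss(self) -> int:
        """Transcription start site (0-based position of the first transcribed base)."""
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1


@dataclass(frozen=True)
class CytosineSite:
    """One cytosine with its methylation evidence in one sample.

    ``context`` is the trinucleotide methylation context (CG, CHG or CHH with
    H = A, C or T), read 5'->3' on the cytosine's own strand.
    """

    chrom: str
    pos: int  # 0-based
    strand: str
    context: str
    meth: int
    total: int

    def __post_init__(self):
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.meth < 0 or self.total < 0:
            raise ValueError("negative count")
        if self.meth > self.total:
            raise ValueError(f"meth {self.meth} > total {self.total}")

    @property
    def level(self) -> float:
        return self.meth / self.total if self.total else float("nan")


class CountMatrix:
    """Integer feature x sample count matrix with per-sample library sizes.

    Library sizes default to column sums; they may be overridden explicitly
    (e.g. when features are a subset of everything sequenced).
    """

    def __init__(self, feature_ids, sample_ids, counts, lib_sizes=None):
        self.feature_ids = list(feature_ids)
        self.sample_ids = list(sample_ids)
        self.counts = np.asarray(counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if lib_sizes is None:
            lib_sizes = self.counts.sum(axis=0)
        self.lib_sizes = np.asarray(lib_sizes, dtype=float)
        if (self.lib_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def shape(self):
        return self.counts.shape

    def cpm(self) -> np.ndarray:
        """Counts per million, using the stored library sizes."""
        return self.counts / self.lib_sizes[None, :] * 1e6

    def subset_features(self, keep) -> "CountMatrix":
        """New matrix restricted to the boolean mask / index array *keep*.

        Library sizes are carried over unchanged (filtering features does not
        change how deep each library was sequenced).
        """
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return CountMatrix(
            [self.feature_ids[i] for i in idx],
            self.sample_ids,
            self.counts[idx, :],
            self.lib_sizes,
        )

    def __eq__(self, other):
        return (
            isinstance(other, CountMatrix)
            and self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
            and np.allclose(self.lib_sizes, other.lib_sizes)
        )


@dataclass
class PFM:
    """Position frequency matrix: per-column base counts, rows A, C, G, T."""

    motif_id: str
    counts: np.ndarray  # shape (4, L)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("PFM counts must be a 4 x L matrix (rows A,C,G,T)")
        if self.counts.shape[1] < 1:
            raise ValueError("PFM must have at least one column")
        if (self.counts < 0).any():
            raise ValueError("PFM counts must be non-negative")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("every PFM column needs a positive count sum")

    def __len__(self) -> int:
        return self.counts.shape[1]
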