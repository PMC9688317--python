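"""Barcode deconvolution: turn barcode-bearing reads into an shRNA x sample count table.

Reads from a pooled shRNA screen carry a fixed-length DNA barcode between two
constant flanking anchors (the nested-PCR amplicon structure). Deconvolution
locates the left anchor in each read, extracts the barcode, and assigns it to a
library entry allowing a configurable number of mismatches. Ambiguous
assignments (two library barcodes equidistant at the minimum) are never
guessed: such reads count as unassigned.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from Bio import SeqIO

__all__ = [
    "BarcodeLibrary",
    "CountTable",
    "extract_barcode",
    "assign",
    "count_reads",
    "hamming",
]

#: default number of left-anchor bases that must match exactly
DEFAULT_ANCHOR_SUFFIX = 8

_AMBIGUOUS = object()  # sentinel in the mismatch index


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class BarcodeLibrary:
    """Map from DNA barcode to shRNA construct and target gene.

    Parameters
    ----------
    entries : pandas.DataFrame
        Columns ``barcode``, ``shrna_id``, ``gene``. Barcodes must be unique
        and of uniform length; shRNA ids must be unique.
    anchors : tuple of str
        ``(left, right)`` constant flanks surrounding the barcode in a read.
    """

    entries: pd.DataFrame
    anchors: tuple[str, str] = ("ACCGGTTAGCTAAGCG", "GCTAGCCGATTCGATA")
    _exact: dict = field(default=None, repr=False, compare=False)
    _one_mm: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        required = {"barcode", "shrna_id", "gene"}
        if not required.issubset(self.entries.columns):
            raise ValueError(f"library entries need columns {sorted(required)}")
        bcs = self.entries["barcode"]
        if bcs.duplicated().any():
            raise ValueError("library barcodes are not unique")
        if self.entries["shrna_id"].duplicated().any():
            raise ValueError("shrna_id values are not unique")
        if bcs.str.len().nunique() > 1:
            raise ValueError("library barcodes have mixed lengths")

    @property
    def barcode_length(self) -> int:
        return len(self.entries["barcode"].iloc[0])

    @property
    def shrna_ids(self) -> pd.Index:
        return pd.Index(self.entries["shrna_id"])

    @property
    def genes(self) -> pd.Series:
        """shrna_id -> gene mapping."""
        return self.entries.set_index("shrna_id")["gene"]

    # -- index construction -------------------------------------------------
    def _build_index(self) -> None:
        self._exact = dict(zip(self.entries["barcode"], self.entries["shrna_id"]))
        one_mm: dict = {}
        for bc, sid in self._exact.items():
            for i in range(len(bc)):
                for base in "ACGT":
                    if base == bc[i]:
                        continue
                    variant = bc[:i] + base + bc[i + 1 :]
                    if variant in one_mm and one_mm[variant] != sid:
                        one_mm[variant] = _AMBIGUOUS
                    else:
                        one_mm[variant] = sid
        self._one_mm = one_mm

    def lookup(self, barcode: str, max_mismatch: int):
        """Resolve a barcode to an shrna_id or None (miss/ambiguous)."""
        if self._exact is None:
            self._build_index()
        sid = self._exact.get(barcode)
        if sid is not None:
            return sid
        if max_mismatch >= 1 and len(barcode) == self.barcode_length:
            sid = self._one_mm.get(barcode)
            if sid is not None and sid is not _AMBIGUOUS:
                return sid
        return None

    # -- I/O -----------------------------------------------------------------
    @classmethod
    def from_csv(cls, path, anchors: tuple[str, str] | None = None) -> "BarcodeLibrary":
        entries = pd.read_csv(path, dtype=str)
        kwargs = {} if anchors is None else {"anchors": anchors}
        return cls(entries=entries, **kwargs)

    def to_csv(self, path) -> None:
        self.entries[["barcode", "shrna_id", "gene"]].to_csv(path, index=False)


@dataclass
class CountTable:
    """shRNA x sample read counts plus per-sample unassigned tallies.

    Invariant: per sample, ``counts`` column sum + ``unassigned`` equals
    ``total_reads``.
    """

    counts: pd.DataFrame  # index shrna_id, columns samples
    genes: pd.Series  # shrna_id -> gene
    unassigned: pd.Series  # per-sample

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.unassigned = self.unassigned.reindex(self.counts.columns).fillna(0).astype(int)

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def total_reads(self) -> pd.Series:
        return self.counts.sum(axis=0) + self.unassigned

    def to_csv(self, path) -> None:
        """Long-format ``shrna_id,gene,sample,count`` CSV."""
        long = (
            self.counts.rename_axis("shrna_id")
            .reset_index()
            .melt(id_vars="shrna_id", var_name="sample", value_name="count")
        )
        long.insert(1, "gene", long["shrna_id"].map(self.genes).to_numpy())
        long.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CountTable":
        long = pd.read_csv(path)
        counts = long.pivot(index="shrna_id", columns="sample", values="count").fillna(0).astype(int)
        counts.columns.name = None
        genes = long.drop_duplicates("shrna_id").set_index("shrna_id")["gene"]
        genes = genes.reindex(counts.index)
        return cls(counts=counts, genes=genes, unassigned=pd.Series(0, index=counts.columns))

    def summary(self) -> pd.DataFrame:
        """Per-sample totals and assignment rate."""
        assigned = self.counts.sum(axis=0)
        total = self.total_reads
        rate = (assigned / total.replace(0, pd.NA)).astype(float)
        return pd.DataFrame(
            {"total": total, "assigned": assigned, "unassigned": self.unassigned, "assignment_rate": rate}
        ).rename_axis("sample")


def extract_barcode(
    read_sequence: str,
    anchors: tuple[str, str],
    barcode_length: int,
    anchor_suffix: int = DEFAULT_ANCHOR_SUFFIX,
) -> str | None:
    """Extract the barcode following the left anchor, or None on a miss.

    Matching is exact on the last ``anchor_suffix`` bases of the left anchor;
    the barcode is the ``barcode_length`` bases immediately after it. Returns
    None when the anchor is absent or the read is truncated inside the barcode.
    """
    left = anchors[0][-anchor_suffix:] if anchor_suffix else anchors[0]
    pos = read_sequence.find(left)
    if pos < 0:
        return None
    start = pos + len(left)
    bc = read_sequence[start : start + barcode_length]
    if len(bc) < barcode_length:
        return None
    return bc


def assign(barcode: str, library: BarcodeLibrary, max_mismatch: int = 1):
    """Assign a barcode to an shrna_id, or None.

    An exact match wins outright. Otherwise the unique library barcode within
    ``max_mismatch`` (0 or 1) is used; if two or more library barcodes tie at
    the minimum distance the read is unassignable and None is returned.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    return library.lookup(barcode, max_mismatch)


def _open_maybe_gzip(path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def count_reads(
    fastq_path,
    library: BarcodeLibrary,
    max_mismatch: int = 1,
    sample_name: str = "sample",
    anchor_suffix: int = DEFAULT_ANCHOR_SUFFIX,
) -> CountTable:
    """Count barcode-assigned reads in a FASTQ file against a library.

    Reads are scanned on the given strand only (amplicon orientation is fixed
    by the nested PCR design); quality scores are ignored. A malformed FASTQ
    record raises a ValueError naming the record index.
    """
    tallies = {sid: 0 for sid in library.shrna_ids}
    unassigned = 0
    bl = library.barcode_length
    handle = _open_maybe_gzip(fastq_path)
    try:
        record_iter = SeqIO.parse(handle, "fastq")
        idx = 0
        while True:
            try:
                record = next(record_iter)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record at index {idx}: {exc}") from exc
            seq = str(record.seq).upper()
            bc = extract_barcode(seq, library.anchors, bl, anchor_suffix)
            sid = library.lookup(bc, max_mismatch) if bc is not None else None
            if sid is None:
                unassigned += 1
            else:
                tallies[sid] += 1
            idx += 1
    finally:
        handle.close()
    counts = pd.DataFrame({sample_name: pd.Series(tallies)}).rename_axis("shrna_id")
    counts = counts.loc[library.shrna_ids]
    return CountTable(
        counts=counts,
        genes=library.genes,
        unassigned=pd.Series({sample_name: unassigned}),
    )
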