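"""Genomic coordinate contract and I/O for cleavage-track data.

Every coordinate in this package is 0-based, half-open (the BED convention):
an interval ``[start, end)`` of length ``end - start``.  DNase I cleavage
events are placed at the 0-based position of the 5'-most aligned base of a
read on its own strand; for a minus-strand read that is the highest-coordinate
aligned base.  No per-strand offset is applied by default (``minus_offset``
exposes one for transposase-style chemistries).

Formats handled here: FASTA genomes (via :mod:`pyfaidx`), SAM/BAM alignments
(via :mod:`pysam`), per-base bedGraph tracks, BED3+ interval files (via
:mod:`pandas`), and minimal VCF 4.x with per-sample GT calls (read via
:mod:`pysam`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pyfaidx
import pysam

__all__ = [
    "GenomicInterval",
    "GenomeSequence",
    "CleavageProfile",
    "VariantRecord",
    "GT_HOM_REF",
    "GT_HET",
    "GT_HOM_ALT",
    "GT_MISSING",
    "read_genome",
    "write_fasta",
    "extract_cleavages",
    "read_bedgraph",
    "write_bedgraph",
    "read_bed",
    "bed_intervals",
    "write_bed",
    "read_variants",
    "write_vcf",
]

GT_HOM_REF = "hom_ref"
GT_HET = "het"
GT_HOM_ALT = "hom_alt"
GT_MISSING = "missing"

_VALID_BASES = frozenset("ACGTN")
_ILLEGAL_RE = re.compile(r"[^ACGTN]")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)`` on ``contig``."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_position(self, contig: str, position: int) -> bool:
        return contig == self.contig and self.start <= position < self.end

    def padded(self, pad: int, contig_length: int | None = None) -> "GenomicInterval":
        """Expand by ``pad`` on both sides, clipped to the contig bounds."""
        start = max(0, self.start - pad)
        end = self.end + pad
        if contig_length is not None:
            end = min(end, contig_length)
        return GenomicInterval(self.contig, start, end)


class GenomeSequence:
    """An in-memory genome: contig name -> uppercase A/C/G/T/N string."""

    def __init__(self, contigs: Mapping[str, str]):
        self.contigs: dict[str, str] = {}
        for name, seq in contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} has zero length")
            seq = seq.upper()
            m = _ILLEGAL_RE.search(seq)
            if m:
                raise ValueError(
                    f"contig {name!r} has illegal character {m.group()!r} "
                    f"at position {m.start()}"
                )
            self.contigs[name] = seq

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def fetch(self, interval: GenomicInterval) -> str:
        seq = self.contigs[interval.contig]
        if interval.end > len(seq):
            raise ValueError(
                f"interval {interval} extends beyond contig length {len(seq)}"
            )
        return seq[interval.start : interval.end]


@dataclass
class CleavageProfile:
    """Per-nucleotide observed cleavage counts over an interval, one sample.

    ``counts_plus[i]`` / ``counts_minus[i]`` hold cleavages whose 5' end maps
    to ``interval.start + i`` on the respective strand.  ``total_tags`` is the
    library-wide number of uniquely mapped cleavages and is used only for
    depth normalisation; it defaults to the in-interval sum.
    """

    interval: GenomicInterval
    counts_plus: np.ndarray
    counts_minus: np.ndarray
    total_tags: int | None = None

    def __post_init__(self) -> None:
        self.counts_plus = np.asarray(self.counts_plus)
        self.counts_minus = np.asarray(self.counts_minus)
        n = len(self.interval)
        if self.counts_plus.shape != (n,) or self.counts_minus.shape != (n,):
            raise ValueError("count array lengths must equal interval length")
        if (self.counts_plus < 0).any() or (self.counts_minus < 0).any():
            raise ValueError("cleavage counts must be non-negative")
        insum = int(self.counts_plus.sum() + self.counts_minus.sum())
        if self.total_tags is None:
            self.total_tags = insum
        elif self.total_tags < insum:
            raise ValueError("total_tags smaller than in-interval cleavage sum")

    @property
    def combined(self) -> np.ndarray:
        return self.counts_plus + self.counts_minus

    def slice(self, sub: GenomicInterval) -> "CleavageProfile":
        if sub.contig != self.interval.contig:
            raise ValueError("sub-interval on different contig")
        if sub.start < self.interval.start or sub.end > self.interval.end:
            raise ValueError("sub-interval outside profile interval")
        lo = sub.start - self.interval.start
        hi = sub.end - self.interval.start
        return CleavageProfile(
            sub, self.counts_plus[lo:hi], self.counts_minus[lo:hi], self.total_tags
        )


@dataclass
class VariantRecord:
    """A biallelic SNV with per-sample genotype class."""

    contig: str
    position: int  # 0-based
    ref: str
    alt: str
    genotypes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for allele, label in ((self.ref, "ref"), (self.alt, "alt")):
            if len(allele) != 1 or allele not in "ACGT":
                raise ValueError(f"{label} allele {allele!r} is not a single base")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        for s, g in self.genotypes.items():
            if g not in (GT_HOM_REF, GT_HET, GT_HOM_ALT, GT_MISSING):
                raise ValueError(f"unknown genotype {g!r} for sample {s!r}")


# ---------------------------------------------------------------------------
# FASTA


def read_genome(path: str | Path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence` (uppercased, N kept)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
    contigs = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return GenomeSequence(contigs)


def write_fasta(path: str | Path, contigs: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Alignments -> cleavage counts


def _read_retained(read: "pysam.AlignedSegment", min_mapq: int) -> bool:
    if (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
        or read.is_qcfail
    ):
        return False
    return read.mapping_quality >= min_mapq


def _count_retained(path: str | Path, min_mapq: int) -> int:
    with pysam.AlignmentFile(str(path)) as af:
        return sum(1 for r in af.fetch(until_eof=True) if _read_retained(r, min_mapq))


def extract_cleavages(
    alignments: "str | Path | pysam.AlignmentFile",
    interval: GenomicInterval,
    *,
    total_tags: int | None = None,
    min_mapq: int = 0,
    minus_offset: int = 0,
) -> CleavageProfile:
    """Convert aligned reads to strand-aware per-base cleavage counts.

    A plus-strand read contributes one cleavage at its leftmost aligned base;
    a minus-strand read at its rightmost aligned base (its 5' end), shifted by
    ``minus_offset`` (default 0).  Duplicate / unmapped / secondary /
    supplementary / QC-fail reads are excluded, as are reads below
    ``min_mapq``.  If ``total_tags`` is not given and ``alignments`` is a
    path, the retained-read count over the whole file is used; for an open
    handle the in-interval sum is used.
    """
    own = isinstance(alignments, (str, Path))
    af = pysam.AlignmentFile(str(alignments)) if own else alignments

    n = len(interval)
    plus = np.zeros(n, dtype=np.int64)
    minus = np.zeros(n, dtype=np.int64)

    margin = abs(minus_offset) + 1
    fetch_start = max(0, interval.start - margin)
    fetch_end = interval.end + margin
    try:
        reads: Iterable = af.fetch(interval.contig, fetch_start, fetch_end)
        reads = list(reads)
    except ValueError:
        # no index (e.g. plain SAM): stream the file and filter by contig
        reads = [
            r
            for r in af.fetch(until_eof=True)
            if not r.is_unmapped and r.reference_name == interval.contig
        ]

    for read in reads:
        if not _read_retained(read, min_mapq):
            continue
        if read.is_reverse:
            pos = read.reference_end - 1 + minus_offset
            if interval.start <= pos < interval.end:
                minus[pos - interval.start] += 1
        else:
            pos = read.reference_start
            if interval.start <= pos < interval.end:
                plus[pos - interval.start] += 1

    if total_tags is None:
        if own:
            total_tags = _count_retained(alignments, min_mapq)
        else:
            total_tags = int(plus.sum() + minus.sum())
    if own:
        af.close()
    return CleavageProfile(interval, plus, minus, total_tags)


# ---------------------------------------------------------------------------
# bedGraph


def _fmt_value(v: float, precision: int) -> str:
    if float(v) == int(v):
        return str(int(v))
    return f"{v:.{precision}f}".rstrip("0").rstrip(".")


def write_bedgraph(
    dest,
    interval: GenomicInterval,
    values: Sequence[float] | np.ndarray,
    *,
    precision: int = 6,
) -> None:
    """Write a per-base track as bedGraph; zero runs are omitted.

    ``dest`` may be a path or an open text handle (for appending several
    intervals into one file).
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (len(interval),):
        raise ValueError("value array length must equal interval length")
    if not np.all(np.isfinite(values)):
        raise ValueError("track values must be finite")
    own = isinstance(dest, (str, Path))
    fh = open(dest, "w") if own else dest
    try:
        # run-length encode
        change = np.flatnonzero(np.diff(values)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(values)]])
        for s, e in zip(starts, ends):
            v = values[s]
            if v == 0:
                continue
            fh.write(
                f"{interval.contig}\t{interval.start + s}\t"
                f"{interval.start + e}\t{_fmt_value(v, precision)}\n"
            )
    finally:
        if own:
            fh.close()


def read_bedgraph(path: str | Path, interval: GenomicInterval) -> np.ndarray:
    """Read a bedGraph into a dense per-base array over ``interval``.

    Lines outside the interval (or on other contigs) are ignored; positions
    without a record are zero.  Malformed lines raise with their line number.
    """
    out = np.zeros(len(interval), dtype=float)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns")
            contig = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if end <= start:
                raise ValueError(
                    f"{path}: line {lineno}: end {end} <= start {start}"
                )
            if contig != interval.contig:
                continue
            lo = max(start, interval.start) - interval.start
            hi = min(end, interval.end) - interval.start
            if hi > lo:
                out[lo:hi] = value
    return out


# ---------------------------------------------------------------------------
# BED


_BED_COLUMNS = ["contig", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3+ into a DataFrame (contig, start, end, then optional cols)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        dtype={0: str},
        names=range(12),  # tolerate ragged BED3..BED12 rows
    )
    df = df.dropna(axis=1, how="all")
    ncol = df.shape[1]
    if ncol < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    names = _BED_COLUMNS[: min(ncol, 6)] + [f"col{i}" for i in range(7, ncol + 1)]
    df.columns = names
    bad = df.index[(df["end"] <= df["start"]) | (df["start"] < 0)]
    if len(bad):
        raise ValueError(f"{path}: line {bad[0] + 1}: invalid interval bounds")
    return df


def bed_intervals(source: str | Path | pd.DataFrame) -> list[GenomicInterval]:
    df = source if isinstance(source, pd.DataFrame) else read_bed(source)
    return [
        GenomicInterval(str(c), int(s), int(e))
        for c, s, e in zip(df["contig"], df["start"], df["end"])
    ]


def write_bed(
    path: str | Path, rows: pd.DataFrame | Iterable[GenomicInterval]
) -> None:
    if isinstance(rows, pd.DataFrame):
        rows.to_csv(path, sep="\t", header=False, index=False)
        return
    with open(path, "w") as fh:
        for iv in rows:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# VCF


_GT_FROM_TUPLE = {
    (0, 0): GT_HOM_REF,
    (0, 1): GT_HET,
    (1, 0): GT_HET,
    (1, 1): GT_HOM_ALT,
}

_GT_TO_STRING = {
    GT_HOM_REF: "0/0",
    GT_HET: "0/1",
    GT_HOM_ALT: "1/1",
    GT_MISSING: "./.",
}


def read_variants(path: str | Path) -> list[VariantRecord]:
    """Read biallelic SNVs (GT field required); other records are skipped."""
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                continue
            genotypes = {}
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or None in gt:
                    genotypes[s] = GT_MISSING
                else:
                    genotypes[s] = _GT_FROM_TUPLE.get(tuple(gt), GT_MISSING)
            out.append(VariantRecord(rec.contig, rec.start, ref, alt, genotypes))
    return out


def write_vcf(
    path: str | Path,
    variants: Sequence[VariantRecord],
    sample_names: Sequence[str] | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    if sample_names is None:
        names: list[str] = []
        for v in variants:
            for s in v.genotypes:
                if s not in names:
                    names.append(s)
        sample_names = names
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        else:
            for c in dict.fromkeys(v.contig for v in variants):
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = "\t".join(sample_names)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for i, v in enumerate(variants):
            gts = "\t".join(
                _GT_TO_STRING[v.genotypes.get(s, GT_MISSING)] for s in sample_names
            )
            fh.write(
                f"{v.contig}\t{v.position + 1}\tv{i}\t{v.ref}\t{v.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )
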