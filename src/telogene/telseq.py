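"""Telomere-length estimation from sequencing reads.

Telomeres are arrays of the hexamer TTAGGG.  In shotgun whole-genome
sequencing the number of reads made up of this repeat is proportional to the
total telomeric content of the genome, so a length estimate in base pairs can
be formed from the ratio of telomeric reads to a GC-matched background read
count:

    tl_bp = (tel_reads / gc_reads) * c

where ``tel_reads`` counts reads containing at least ``k`` copies of the
motif (default ``k=12``, chosen for ~150 bp reads), ``gc_reads`` counts reads
whose GC content falls in a fixed window (default 48-52%, matching the ~50%
GC of the repeat itself), and ``c`` is the genomic length at that GC content
divided by the number of chromosome ends.  GC-matching the denominator
absorbs sample-to-sample differences in GC-dependent coverage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pysam

TELOMERE_MOTIF = "TTAGGG"
TELOMERE_MOTIF_RC = "CCCTAA"

_VALID_RE = re.compile(r"^[ACGTN]*$")


class DegenerateInputError(ValueError):
    """Raised when an estimate is undefined on the given input."""


@dataclass(frozen=True)
class TLEstimate:
    """Result of a telomere-length estimation on one sample.

    Attributes
    ----------
    tel_reads : int
        Reads containing at least ``k`` non-overlapping motif copies.
    gc_reads : int
        Reads with GC fraction inside the normalization window.
    length_constant_c : float
        Genomic length (bp) at matching GC divided by number of chromosome
        ends; converts the read-count ratio to base pairs per end.
    tl_bp : float
        Estimated telomere length in base pairs.
    k : int
        Motif-repeat threshold.
    read_length : int or None
        Nominal read length, if known.
    """

    tel_reads: int
    gc_reads: int
    length_constant_c: float
    tl_bp: float
    k: int
    read_length: int | None = None


def _validate_read(read: str) -> str:
    read = read.upper()
    if not _VALID_RE.match(read):
        bad = sorted(set(read) - set("ACGTN"))
        raise ValueError(f"read contains invalid characters: {bad}")
    return read


def count_motif_repeats(read: str, motif: str = TELOMERE_MOTIF,
                        *, both_strands: bool = False,
                        overlapping: bool = False) -> int:
    """Count occurrences of ``motif`` in ``read``.

    By default counts non-overlapping exact matches scanning left to right
    (``str.count`` semantics).  ``both_strands=True`` also scans the reverse
    complement motif and returns the per-read maximum; ``overlapping=True``
    counts overlapping occurrences instead.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    read = _validate_read(read)
    if not read:
        return 0

    def _count(m: str) -> int:
        if overlapping:
            return len(re.findall(f"(?={re.escape(m)})", read))
        return read.count(m)

    n = _count(motif)
    if both_strands:
        rc = motif.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        n = max(n, _count(rc))
    return n


def gc_fraction(read: str) -> float:
    """GC fraction of a read; N bases count as non-GC."""
    read = _validate_read(read)
    if not read:
        raise ValueError("gc_fraction undefined for empty read")
    return (read.count("G") + read.count("C")) / len(read)


def estimate_tl(reads: Iterable[str], c: float, *, k: int = 12,
                gc_window: tuple[float, float] = (0.48, 0.52),
                motif: str = TELOMERE_MOTIF,
                both_strands: bool = False,
                overlapping: bool = False,
                read_length: int | None = None) -> TLEstimate:
    """Estimate telomere length (bp) for one sample.

    Parameters
    ----------
    reads : iterable of str
        Read sequences (orientation as stored).
    c : float
        Length constant: genomic length at matching GC content divided by
        the number of chromosome ends.  Must be supplied explicitly.
    k : int
        Minimum number of motif repeats for a read to count as telomeric.
    gc_window : (low, high)
        Inclusive GC-fraction window for the normalization denominator.

    Raises
    ------
    DegenerateInputError
        If no read falls in the GC window (the ratio is undefined).
    """
    if c <= 0:
        raise ValueError(f"length constant c must be > 0, got {c}")
    lo, hi = gc_window
    if not (0 <= lo <= hi <= 1):
        raise ValueError(f"invalid GC window {gc_window}")
    tel = 0
    gc = 0
    for read in reads:
        read = _validate_read(read)
        if not read:
            continue
        if count_motif_repeats(read, motif, both_strands=both_strands,
                               overlapping=overlapping) >= k:
            tel += 1
        frac = (read.count("G") + read.count("C")) / len(read)
        if lo <= frac <= hi:
            gc += 1
    if gc == 0:
        raise DegenerateInputError(
            "no reads in the GC normalization window; estimate undefined")
    return TLEstimate(tel_reads=tel, gc_reads=gc, length_constant_c=c,
                      tl_bp=(tel / gc) * c, k=k, read_length=read_length)


def read_fastq(path: str) -> list[str]:
    """Read sequences from a FASTQ/FASTA file."""
    with pysam.FastxFile(str(path)) as fx:
        return [entry.sequence for entry in fx]


def read_sam(path: str) -> list[str]:
    """Read sequences from a SAM/BAM file (alignment status ignored)."""
    seqs = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af.fetch(until_eof=True):
            if rec.query_sequence:
                seqs.append(rec.query_sequence)
    return seqs


def estimate_tl_table(samples: dict[str, Sequence[str]], c: float,
                      **kwargs) -> "pandas.DataFrame":  # noqa: F821
    """Estimate TL for several samples; returns a tidy table."""
    import pandas as pd

    rows = []
    for name, reads in samples.items():
        est = estimate_tl(reads, c, **kwargs)
        rows.append({"sample": name, "tel_reads": est.tel_reads,
                     "gc_reads": est.gc_reads, "tl_bp": est.tl_bp})
    return pd.DataFrame(rows)
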