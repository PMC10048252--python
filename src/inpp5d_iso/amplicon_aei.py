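"""Amplicon read sets -> per-sample allele counts at the reporter SNP.

Implements the allele-counting half of the AEI assay: parsing a
bracket-notation reporter-SNP k-mer (e.g. ``GCCGGCCC[G/A]GCCGAGG`` for
rs1141328), barcode demultiplexing of pooled amplicon reads, and exact or
1-mismatch k-mer allele counting over both strands.

Matching policy: a read is assigned to an allele when any window of the
read (or of its reverse complement, when enabled) matches that allele's
k-mer with at most ``max_mismatch`` mismatches, where the variant base
itself must always match exactly.  Reads matching both k-mers are counted
as ambiguous, never double-counted; reads matching neither are unassigned.
"""

from __future__ import annotations

import gzip
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlleleKmerPair",
    "AlleleCounts",
    "RatioResult",
    "UndefinedRatioError",
    "parse_allele_kmer",
    "demultiplex",
    "count_alleles",
    "allelic_ratio",
    "reverse_complement",
    "read_fastq_sequences",
    "counts_to_frame",
    "RS1141328_KMER_SPEC",
]

RS1141328_KMER_SPEC = "GCCGGCCC[G/A]GCCGAGG"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class UndefinedRatioError(ValueError):
    """Raised when the allele-2 count is zero and the ratio is undefined."""


@dataclass(frozen=True)
class AlleleKmerPair:
    """The two allele-discriminating k-mers expanded from bracket notation."""

    kmer_allele1: str
    kmer_allele2: str
    snp_offset: int          # 0-based position of the variant base
    k: int
    allele_labels: tuple     # e.g. ("G", "A")

    def __post_init__(self):
        a, b = self.kmer_allele1, self.kmer_allele2
        if len(a) != self.k or len(b) != self.k:
            raise ValueError("k-mers must both have length k")
        diff = [i for i in range(self.k) if a[i] != b[i]]
        if diff != [self.snp_offset]:
            raise ValueError("k-mers must differ at snp_offset and nowhere else")


_BRACKET_RE = re.compile(r"\[([^/\]]*)/([^/\]]*)\]")


def parse_allele_kmer(spec: str) -> AlleleKmerPair:
    """Expand a bracket-notation SNP k-mer spec into the two allele k-mers.

    ``"GCCGGCCC[G/A]GCCGAGG"`` yields 16-mers differing only at offset 8.
    """
    blocks = _BRACKET_RE.findall(spec)
    if "[" in _BRACKET_RE.sub("", spec) or "]" in _BRACKET_RE.sub("", spec):
        raise ValueError(f"malformed bracket block in spec: {spec!r}")
    if len(blocks) == 0:
        raise ValueError(f"no [X/Y] allele block found in spec: {spec!r}")
    if len(blocks) > 1:
        raise ValueError(f"multiple allele blocks found in spec: {spec!r}")
    a1, a2 = blocks[0]
    if len(a1) != 1 or len(a2) != 1:
        raise ValueError(f"alleles must be single bases, got [{a1}/{a2}]")
    if a1 == a2:
        raise ValueError(f"identical alleles in spec: [{a1}/{a2}]")
    m = _BRACKET_RE.search(spec)
    left, right = spec[:m.start()], spec[m.end():]
    for part, name in ((left, "left flank"), (right, "right flank"),
                       (a1 + a2, "alleles")):
        bad = set(part) - set("ACGT")
        if bad:
            raise ValueError(f"non-nucleotide characters in {name}: "
                             f"{sorted(bad)}")
    return AlleleKmerPair(
        kmer_allele1=left + a1 + right,
        kmer_allele2=left + a2 + right,
        snp_offset=len(left),
        k=len(left) + 1 + len(right),
        allele_labels=(a1, a2),
    )


@dataclass
class AlleleCounts:
    """Per-sample read counts for one material at the reporter SNP."""

    sample_id: str
    material: str                 # "cDNA" | "gDNA"
    n_allele1: int
    n_allele2: int
    n_ambiguous: int
    n_unassigned: int

    def __post_init__(self):
        for name in ("n_allele1", "n_allele2", "n_ambiguous", "n_unassigned"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_total(self) -> int:
        return (self.n_allele1 + self.n_allele2 + self.n_ambiguous
                + self.n_unassigned)


def counts_to_frame(counts: Iterable[AlleleCounts]) -> pd.DataFrame:
    rows = []
    for c in counts:
        rows.append({"sample_id": c.sample_id, "material": c.material,
                     "n_allele1": c.n_allele1, "n_allele2": c.n_allele2,
                     "n_ambiguous": c.n_ambiguous,
                     "n_unassigned": c.n_unassigned, "n_total": c.n_total})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# demultiplexing

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(reads: Sequence, barcode_map: Mapping[str, str],
                max_barcode_mismatch: int = 0):
    """Partition reads by barcode prefix; barcodes are trimmed on assignment.

    ``barcode_map`` maps sample keys to barcode sequences, which must be
    unique, equal-length and pairwise Hamming distance > 2*max_mismatch so
    that assignment is unambiguous.  Returns ``(buckets, unassigned)`` where
    buckets maps each sample key to its trimmed read list; every input read
    lands in exactly one bucket or in the unassigned pool.

    Reads may be plain sequence strings or objects with a ``sequence``
    attribute (trimming preserves the type for strings; objects yield their
    trimmed sequence strings).
    """
    barcodes = list(barcode_map.values())
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("barcodes must be unique")
    lengths = {len(b) for b in barcodes}
    if len(lengths) != 1:
        raise ValueError("barcodes must have equal length")
    bl = lengths.pop()
    for i, a in enumerate(barcodes):
        for b in barcodes[i + 1:]:
            if _hamming(a, b) <= 2 * max_barcode_mismatch:
                raise ValueError(
                    f"ambiguous barcode map: {a!r} and {b!r} are within "
                    f"Hamming distance {2 * max_barcode_mismatch}")
    buckets = {key: [] for key in barcode_map}
    unassigned = []
    by_barcode = {v: k for k, v in barcode_map.items()}
    for read in reads:
        seq = read if isinstance(read, str) else read.sequence
        prefix = seq[:bl]
        key = by_barcode.get(prefix)
        if key is None and max_barcode_mismatch > 0:
            for bc, k in by_barcode.items():
                if _hamming(prefix, bc) <= max_barcode_mismatch:
                    key = k
                    break
        if key is None:
            unassigned.append(read)
        else:
            buckets[key].append(seq[bl:])
    return buckets, unassigned


# --------------------------------------------------------------------------
# allele counting

def _scan_mismatch(seq: str, kmer: str, snp_offset: int,
                   max_mismatch: int) -> bool:
    """Any-window match allowing mismatches anywhere except the SNP base."""
    k = len(kmer)
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    q = np.frombuffer(kmer.encode(), dtype=np.uint8)
    n_win = s.size - k + 1
    if n_win <= 0:
        return False
    windows = np.lib.stride_tricks.sliding_window_view(s, k)
    neq = windows != q
    snp_ok = ~neq[:, snp_offset]
    mism = neq.sum(axis=1) - neq[:, snp_offset]
    return bool(np.any(snp_ok & (mism <= max_mismatch)))


def _matches(seq: str, kmer: str, kmer_rc: str, snp_offset: int,
             snp_offset_rc: int, allow_revcomp: bool,
             max_mismatch: int) -> bool:
    if max_mismatch == 0:
        if kmer in seq:
            return True
        return allow_revcomp and kmer_rc in seq
    if _scan_mismatch(seq, kmer, snp_offset, max_mismatch):
        return True
    return allow_revcomp and _scan_mismatch(seq, kmer_rc, snp_offset_rc,
                                            max_mismatch)


def count_alleles(read_set: Iterable, kmer_pair: AlleleKmerPair,
                  allow_revcomp: bool = True, max_mismatch: int = 0,
                  sample_id: str = "", material: str = "cDNA") -> AlleleCounts:
    """Count reads supporting each allele of the reporter SNP.

    Scans every window of each read (and of its reverse complement when
    ``allow_revcomp``) against both allele k-mers.  Mismatch tolerance is
    0 (exact) or 1, and the variant base must always match.  An empty read
    set yields all-zero counts; a read shorter than k is an error.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    k = kmer_pair.k
    k1, k2 = kmer_pair.kmer_allele1, kmer_pair.kmer_allele2
    k1_rc, k2_rc = reverse_complement(k1), reverse_complement(k2)
    off = kmer_pair.snp_offset
    off_rc = k - 1 - off
    n1 = n2 = n_amb = n_un = 0
    for read in read_set:
        seq = read if isinstance(read, str) else read.sequence
        if len(seq) < k:
            raise ValueError(
                f"read length {len(seq)} shorter than k-mer length {k}")
        m1 = _matches(seq, k1, k1_rc, off, off_rc, allow_revcomp, max_mismatch)
        m2 = _matches(seq, k2, k2_rc, off, off_rc, allow_revcomp, max_mismatch)
        if m1 and m2:
            n_amb += 1
        elif m1:
            n1 += 1
        elif m2:
            n2 += 1
        else:
            n_un += 1
    return AlleleCounts(sample_id=sample_id, material=material,
                        n_allele1=n1, n_allele2=n2, n_ambiguous=n_amb,
                        n_unassigned=n_un)


@dataclass(frozen=True)
class RatioResult:
    """Allelic ratio (allele1:allele2) with the depth-filter verdict."""

    ratio: float
    informative_depth: int
    passes_depth: bool


def allelic_ratio(counts: AlleleCounts, min_depth: int = 100) -> RatioResult:
    """Allele-1 : allele-2 ratio (G:A for rs1141328).

    Samples whose informative depth (allele1+allele2) falls below
    ``min_depth`` are flagged for exclusion from downstream statistics.
    A zero allele-2 count raises ``UndefinedRatioError``.
    """
    depth = counts.n_allele1 + counts.n_allele2
    if counts.n_allele2 == 0:
        raise UndefinedRatioError(
            f"sample {counts.sample_id!r}: allele-2 count is zero; "
            "the allelic ratio is undefined")
    return RatioResult(ratio=counts.n_allele1 / counts.n_allele2,
                       informative_depth=depth,
                       passes_depth=depth >= min_depth)


# --------------------------------------------------------------------------
# file I/O

def read_fastq_sequences(path) -> list[str]:
    """Read sequences from a (possibly gzipped) 4-line FASTQ file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    seqs = []
    with opener(path, "rt") as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                seqs.append(line.strip())
    return seqs


def write_run_report(path, *, kmer_spec: str, allow_revcomp: bool,
                     max_mismatch: int, min_depth: int,
                     counts: Sequence[AlleleCounts]):
    """Emit a JSON run report of the counting policy and per-sample totals."""
    report = {
        "kmer_spec": kmer_spec,
        "allow_revcomp": allow_revcomp,
        "max_mismatch": max_mismatch,
        "min_depth": min_depth,
        "n_samples": len(counts),
        "total_reads": int(sum(c.n_total for c in counts)),
        "total_assigned": int(sum(c.n_allele1 + c.n_allele2 for c in counts)),
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
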