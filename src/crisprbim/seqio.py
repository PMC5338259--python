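"""Sequence records, FASTA/GenBank I/O and small genome utilities.

This module holds the plumbing the rest of the package is built on:
a light :class:`SequenceRecord` container, readers/writers for FASTA and
GenBank flat files (delegated to Biopython), and the handful of genome
utilities used to characterize phage genomes — GC content, a six-frame
ORF scan, in-silico PCR with the locus-delimiting primers, reverse
complement and IUPAC degenerate-base matching.

Coordinates are 0-based half-open internally; user-facing tables convert
to 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "FeatureSpan",
    "OrfCall",
    "PcrResult",
    "read_fasta",
    "write_fasta",
    "read_genbank",
    "write_genbank",
    "gc_content",
    "orf_scan",
    "in_silico_pcr",
    "revcomp",
    "iupac_match",
    "iupac_pattern_match",
    "hamming",
]

#: IUPAC degenerate nucleotide codes -> the set of bases each matches.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")
_DEGENERATE = set("RYSWKMBDHV")
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class FeatureSpan:
    """An annotated interval on a genome (e.g. an *orf* span)."""

    label: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.label!r}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.label!r}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SequenceRecord:
    """An identified nucleotide sequence with optional feature annotations.

    Sequences are normalized on construction: uppercased, U converted to T,
    degenerate IUPAC codes collapsed to N. Anything outside the IUPAC
    alphabet is rejected.
    """

    id: str
    seq: str
    description: str = ""
    features: list[FeatureSpan] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq = normalize_seq(self.seq, context=self.id)
        for f in self.features:
            if f.end > len(self.seq):
                raise ValueError(
                    f"record {self.id!r}: feature {f.label!r} extends past "
                    f"sequence end ({f.end} > {len(self.seq)})"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class OrfCall:
    """One open reading frame: start codon to first in-frame stop.

    ``frame`` is 0-2 for the forward strand, 3-5 for the reverse strand;
    ``start``/``end`` are forward-strand coordinates (0-based half-open,
    stop codon included in the span); ``aa_length`` counts codons from the
    start codon up to but excluding the stop.
    """

    frame: int
    start: int
    end: int
    strand: str
    aa_length: int


@dataclass
class PcrResult:
    """Outcome of an in-silico PCR: zero, one or several amplicons."""

    amplicons: list[SequenceRecord]
    multiple_products: bool = False

    @property
    def found(self) -> bool:
        return bool(self.amplicons)


def normalize_seq(seq: str, context: str = "") -> str:
    """Uppercase, U→T, degenerate codes→N; reject non-IUPAC characters."""
    s = seq.upper().replace("U", "T")
    out = []
    for i, ch in enumerate(s):
        if ch in "ACGTN":
            out.append(ch)
        elif ch in _DEGENERATE:
            out.append("N")
        else:
            where = f" in {context!r}" if context else ""
            raise ValueError(f"non-IUPAC character {ch!r} at position {i}{where}")
    if not out:
        raise ValueError(f"empty sequence{' in ' + repr(context) if context else ''}")
    return "".join(out)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-record) FASTA file into normalized records.

    Raises on empty files and on duplicate record ids.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(id=rec.id, seq=str(rec.seq), description=rec.description)
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _feature_label(feat: SeqFeature) -> str:
    for key in ("locus_tag", "gene", "product"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return feat.type


def read_genbank(path: str | Path) -> SequenceRecord:
    """Read one GenBank flat-file record; CDS/gene features become spans.

    The feature label is taken from locus_tag, gene or product qualifiers,
    first available in that order.
    """
    try:
        rec = SeqIO.read(str(path), "genbank")
        seq = str(rec.seq)
    except Exception as exc:  # undefined/truncated sequence: no ORIGIN block
        raise ValueError(
            f"cannot read GenBank record in {path} (missing ORIGIN block?): {exc}"
        ) from exc
    if not seq:
        raise ValueError(f"GenBank record in {path} has no ORIGIN sequence")
    features = []
    for feat in rec.features:
        if feat.type not in ("CDS", "gene"):
            continue
        strand = "-" if feat.location.strand == -1 else "+"
        features.append(
            FeatureSpan(
                label=_feature_label(feat),
                start=int(feat.location.start),
                end=int(feat.location.end),
                strand=strand,
            )
        )
    return SequenceRecord(
        id=rec.id, seq=seq, description=rec.description or "", features=features
    )


def write_genbank(record: SequenceRecord, path: str | Path) -> None:
    """Write a record with its feature spans as a GenBank flat file (CDS features)."""
    rec = SeqRecord(
        Seq(record.seq),
        id=record.id,
        name=record.id[:16],
        description=record.description,
        annotations={"molecule_type": "DNA"},
    )
    for f in record.features:
        strand = -1 if f.strand == "-" else 1
        rec.features.append(
            SeqFeature(
                FeatureLocation(f.start, f.end, strand=strand),
                type="CDS",
                qualifiers={"locus_tag": [f.label]},
            )
        )
    SeqIO.write([rec], str(path), "genbank")


def gc_content(seq: str) -> float:
    """GC percentage: 100·(G+C)/(A+C+G+T). N is excluded from the denominator."""
    s = normalize_seq(seq)
    gc = s.count("G") + s.count("C")
    denom = len(s) - s.count("N")
    if denom == 0:
        raise ValueError("sequence contains only N; GC content undefined")
    return 100.0 * gc / denom


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    bad = set(seq.upper()) - set("ACGTNRYSWKMBDHV")
    if bad:
        raise ValueError(f"cannot reverse-complement characters {sorted(bad)}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


def iupac_match(base: str, iupac_code: str) -> bool:
    """Does ``base`` fall in the degeneracy class of ``iupac_code``?

    N in the query base never matches exactly: it is treated as a mismatch
    against every code narrower than N.
    """
    if iupac_code not in IUPAC_CODES:
        raise ValueError(f"unknown IUPAC code {iupac_code!r}")
    if base == "N":
        return iupac_code == "N"
    if base not in IUPAC_CODES:
        raise ValueError(f"unknown base {base!r}")
    return base in IUPAC_CODES[iupac_code]


def iupac_pattern_match(seq: str, pattern: str) -> bool:
    """Position-wise IUPAC match of ``seq`` against a degenerate ``pattern``."""
    if len(seq) != len(pattern):
        raise ValueError(
            f"length mismatch: sequence {len(seq)} vs pattern {len(pattern)}"
        )
    return all(iupac_match(b, p) for b, p in zip(seq, pattern))


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings (N mismatches everything)."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def _scan_frames_forward(seq: str, min_aa: int, starts: frozenset[str], limit: int | None):
    """Yield (frame, start, end, aa_length) for forward-frame ORFs.

    ``limit``: only ORFs with start < limit are emitted (circular-scan dedup).
    Per stop codon, only the longest ORF (earliest in-frame start since the
    previous stop) is reported. ORFs without an in-frame stop are discarded.
    """
    n = len(seq)
    for frame in range(3):
        earliest_start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in _STOPS:
                if earliest_start is not None:
                    aa = (pos - earliest_start) // 3
                    if aa >= min_aa and (limit is None or earliest_start < limit):
                        yield frame, earliest_start, pos + 3, aa
                earliest_start = None
            elif earliest_start is None and codon in starts:
                earliest_start = pos


def orf_scan(
    record: SequenceRecord | str,
    min_aa: int = 30,
    starts: Sequence[str] = ("ATG", "TTG", "GTG"),
    circular: bool = False,
) -> list[OrfCall]:
    """Six-frame ORF scan: start codon (ATG/TTG/GTG) to first in-frame stop.

    Only ORFs of at least ``min_aa`` codons (start codon counted, stop
    excluded) are reported, the longest per stop-codon group. With
    ``circular=True`` the scan wraps across the origin and origin-spanning
    ORFs are reported once with end coordinates past the sequence length.
    """
    seq = record.seq if isinstance(record, SequenceRecord) else normalize_seq(record)
    start_set = frozenset(s.upper().replace("U", "T") for s in starts)
    n = len(seq)
    scan_seq = seq + seq if circular else seq
    limit = n if circular else None

    calls: list[OrfCall] = []
    for frame, s, e, aa in _scan_frames_forward(scan_seq, min_aa, start_set, limit):
        if circular and e - s > n:
            continue  # wrapped more than a full genome
        calls.append(OrfCall(frame=s % 3, start=s, end=e, strand="+", aa_length=aa))

    rc = revcomp(seq)
    rc_scan = rc + rc if circular else rc
    for frame, s, e, aa in _scan_frames_forward(rc_scan, min_aa, start_set, limit):
        if circular and e - s > n:
            continue
        # map reverse-strand coordinates back onto the forward strand
        f_start, f_end = n - e, n - s
        if circular and f_start < 0:
            f_start, f_end = f_start + n, f_end + n
        calls.append(
            OrfCall(frame=3 + s % 3, start=f_start, end=f_end, strand="-", aa_length=aa)
        )
    calls.sort(key=lambda c: (c.start, c.end, c.strand, c.frame))
    return calls


def _find_approx(haystack: str, needle: str, max_mismatch: int) -> list[int]:
    L = len(needle)
    hits = []
    for i in range(len(haystack) - L + 1):
        if hamming(haystack[i : i + L], needle) <= max_mismatch:
            hits.append(i)
    return hits


def in_silico_pcr(
    record: SequenceRecord,
    fwd_primer: str,
    rev_primer: str,
    max_mismatch: int = 0,
) -> PcrResult:
    """Predict PCR products: forward primer on +, reverse primer on −.

    Each forward site is paired with the nearest downstream reverse site
    (real PCR strongly favors the shortest product). Returns all products;
    ``multiple_products`` flags more than one. Primers absent or mis-ordered
    yield an empty (but valid) result, distinct from an error.
    """
    fwd = normalize_seq(fwd_primer)
    rev = normalize_seq(rev_primer)
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be at least 15 nt")
    rev_rc = revcomp(rev)
    fwd_sites = _find_approx(record.seq, fwd, max_mismatch)
    rev_sites = _find_approx(record.seq, rev_rc, max_mismatch)

    amplicons: list[SequenceRecord] = []
    for fs in fwd_sites:
        downstream = [rs for rs in rev_sites if rs >= fs + len(fwd)]
        if not downstream:
            continue
        rs = min(downstream)
        amp = record.seq[fs : rs + len(rev_rc)]
        amplicons.append(
            SequenceRecord(
                id=f"{record.id}_amplicon_{fs + 1}",
                seq=amp,
                description=f"in-silico PCR product {fs + 1}..{rs + len(rev_rc)} (1-based)",
            )
        )
    return PcrResult(amplicons=amplicons, multiple_products=len(amplicons) > 1)
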