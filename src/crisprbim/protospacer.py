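"""Mismatch-tolerant spacer→protospacer search and PAM analysis.

Spacers are matched against phage genomes as fixed-length windows on both
strands under a Hamming (substitution-only) distance; every window within
the tolerance is a hit. The protospacer adjacent motif (PAM) is the short
window immediately 3′ of the protospacer on the protospacer strand; hits
are checked against a degenerate IUPAC consensus (default NNAGAAW) and a
consensus can be rebuilt from a hit collection. Targeting prediction
follows the perfect-match rule: interference requires a full-length
(e.g. 30/30) match next to a consensus PAM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .seqio import (
    IUPAC_CODES,
    FeatureSpan,
    SequenceRecord,
    iupac_match,
    revcomp,
)

__all__ = [
    "ProtospacerHit",
    "PamProfile",
    "find_protospacers",
    "extract_pam",
    "match_pam",
    "pam_consensus",
    "predict_targeting",
    "annotate_hit",
]

PAM_CONSENSUS = "NNAGAAW"


@dataclass
class ProtospacerHit:
    """One spacer match on a genome (forward coordinates, 0-based half-open)."""

    spacer_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    pam_seq: Optional[str] = None
    pam_ok: Optional[bool] = None
    pam_truncated: bool = False
    gene_label: str = ""

    @property
    def matched_nt(self) -> int:
        return (self.end - self.start) - self.mismatches


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _window_mismatches(genome: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Mismatch count of ``query`` against every genome window (vectorized)."""
    L = len(query)
    if len(genome) < L:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(genome, L)
    mism = (windows != query).sum(axis=1)
    # N anywhere is a mismatch even when both sides are N
    n_code = ord("N")
    both_n = ((windows == n_code) & (query == n_code)).sum(axis=1)
    return mism + both_n


def find_protospacers(
    spacer: str,
    genome: SequenceRecord,
    max_mismatch: int = 3,
    spacer_id: str = "spacer",
) -> list[ProtospacerHit]:
    """All windows on both strands within ``max_mismatch`` of the spacer.

    Minus-strand windows are compared against the reverse complement of
    the spacer; coordinates are always reported on the forward strand.
    Hits are sorted by (mismatches, start, strand). A genome shorter than
    the spacer yields an empty list.
    """
    if len(spacer) < 20:
        raise ValueError(f"spacer too short ({len(spacer)} nt; need >= 20)")
    g = _encode(genome.seq)
    hits: list[ProtospacerHit] = []
    L = len(spacer)
    for strand, query in (("+", spacer.upper()), ("-", revcomp(spacer))):
        mism = _window_mismatches(g, _encode(query))
        for pos in np.nonzero(mism <= max_mismatch)[0]:
            hits.append(
                ProtospacerHit(
                    spacer_id=spacer_id,
                    genome_id=genome.id,
                    start=int(pos),
                    end=int(pos) + L,
                    strand=strand,
                    mismatches=int(mism[pos]),
                )
            )
    hits.sort(key=lambda h: (h.mismatches, h.start, h.strand))
    return hits


def extract_pam(
    hit: ProtospacerHit, genome: SequenceRecord, pam_len: int = 7
) -> str:
    """The ``pam_len`` bases immediately 3′ of the protospacer, on its strand.

    For minus-strand hits this is the forward-strand window 5′ of the hit
    start, reverse-complemented. At a genome edge the PAM is truncated and
    flagged. Sets ``hit.pam_seq``/``hit.pam_truncated`` and returns the PAM.
    """
    if hit.strand == "+":
        pam = genome.seq[hit.end : hit.end + pam_len]
    else:
        lo = max(0, hit.start - pam_len)
        pam = revcomp(genome.seq[lo : hit.start])
    hit.pam_seq = pam
    hit.pam_truncated = len(pam) < pam_len
    return pam


def match_pam(pam_seq: str, consensus: str = PAM_CONSENSUS) -> bool:
    """Position-wise IUPAC match of a PAM against the consensus."""
    if len(pam_seq) != len(consensus):
        raise ValueError(
            f"PAM length {len(pam_seq)} does not match consensus length {len(consensus)}"
        )
    return all(iupac_match(b, c) for b, c in zip(pam_seq.upper(), consensus.upper()))


@dataclass
class PamProfile:
    """Per-position nucleotide counts over a PAM collection + IUPAC consensus."""

    counts: list[dict[str, int]]
    consensus: str
    threshold: float
    n_pams: int = 0

    def to_dict(self) -> dict:
        return {
            "consensus": self.consensus,
            "threshold": self.threshold,
            "n_pams": self.n_pams,
            "counts": self.counts,
        }


# IUPAC codes ordered by degeneracy class size, then alphabetically:
# the "smallest class covering a base set" search scans this order.
_CODES_BY_SIZE = sorted(IUPAC_CODES, key=lambda c: (len(IUPAC_CODES[c]), c))


def _column_consensus(column: dict[str, int], n: int, threshold: float) -> str:
    best_base, best_count = max(sorted(column.items()), key=lambda kv: kv[1])
    if best_count / n >= threshold:
        return best_base
    present = {b for b, c in column.items() if c / n >= (1.0 - threshold)}
    for code in _CODES_BY_SIZE:
        if present <= IUPAC_CODES[code]:
            return code
    return "N"


def pam_consensus(
    hits_or_pams: Sequence[ProtospacerHit | str], threshold: float = 0.9
) -> PamProfile:
    """Build a positional profile and IUPAC consensus from observed PAMs.

    Per column: a single base is called when its frequency reaches
    ``threshold``; otherwise the smallest IUPAC degeneracy class covering
    every base with frequency at least 1−threshold; N as the fallback.
    Truncated PAMs are excluded; at least two full-length PAMs required.
    """
    pams = []
    for h in hits_or_pams:
        if isinstance(h, ProtospacerHit):
            if h.pam_seq is None or h.pam_truncated:
                continue
            pams.append(h.pam_seq.upper())
        else:
            pams.append(h.upper())
    if len(pams) < 2:
        raise ValueError("need at least 2 full-length PAMs to build a consensus")
    width = len(pams[0])
    if any(len(p) != width for p in pams):
        raise ValueError("PAMs of unequal length")

    counts: list[dict[str, int]] = []
    consensus = []
    for col in range(width):
        column: dict[str, int] = {}
        for p in pams:
            column[p[col]] = column.get(p[col], 0) + 1
        counts.append(dict(sorted(column.items())))
        consensus.append(_column_consensus(column, len(pams), threshold))
    return PamProfile(
        counts=counts, consensus="".join(consensus), threshold=threshold, n_pams=len(pams)
    )


@dataclass
class TargetingCall:
    targeting: bool
    best_hit: Optional[ProtospacerHit]
    rationale: str


def predict_targeting(
    spacer: str,
    genome: SequenceRecord,
    consensus: str = PAM_CONSENSUS,
    max_mismatch: int = 3,
    spacer_id: str = "spacer",
) -> TargetingCall:
    """Would this spacer confer resistance against this phage?

    Targeting requires a perfect full-length protospacer match (0
    mismatches) flanked by a consensus PAM; near matches (e.g. 27/30) do
    not interfere and the rationale reports the best match found.
    """
    hits = find_protospacers(spacer, genome, max_mismatch=max_mismatch, spacer_id=spacer_id)
    for h in hits:
        extract_pam(h, genome, pam_len=len(consensus))
        h.pam_ok = (not h.pam_truncated) and match_pam(h.pam_seq, consensus)
    for h in hits:
        if h.mismatches == 0 and h.pam_ok:
            return TargetingCall(
                True, h, f"perfect match {h.matched_nt}/{h.end - h.start} with consensus PAM {h.pam_seq}"
            )
    if hits:
        best = hits[0]
        L = best.end - best.start
        reason = f"best match {best.matched_nt}/{L}"
        if best.mismatches == 0 and not best.pam_ok:
            reason += f", PAM {best.pam_seq} does not match {consensus}"
        return TargetingCall(False, best, reason)
    return TargetingCall(False, None, f"no match within {max_mismatch} mismatches")


def annotate_hit(hit: ProtospacerHit, features: Sequence[FeatureSpan]) -> ProtospacerHit:
    """Label a hit with the maximally overlapping feature (ties: leftmost)."""
    best: Optional[FeatureSpan] = None
    best_ov = 0
    for f in features:
        ov = min(hit.end, f.end) - max(hit.start, f.start)
        if ov > best_ov or (ov == best_ov and ov > 0 and best and f.start < best.start):
            best, best_ov = f, ov
    hit.gene_label = best.label if best else ""
    return hit
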