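"""Decompose CRISPR locus sequences into leader + repeat-spacer units.

A CRISPR array is a leader region followed by alternating direct repeats
and unique spacers (n spacers bounded by n+1 repeats) and a trailer after
the terminal repeat. :func:`parse_array` locates the repeat copies by a
left-to-right greedy Hamming scan (substitutions only, no indels) and cuts
the locus into leader / spacers / trailer; the decomposition is loss-free,
so the parsed array reconstructs the input byte-exactly.

Two spacer numbering conventions coexist in the literature. Internally the
canonical index counts from the leader-proximal end (``leader_index``,
1 = newest); the trailer-anchored index used in published figures is kept
alongside (``trailer_index``), the two summing to n+1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .seqio import SequenceRecord, hamming, normalize_seq

__all__ = [
    "Spacer",
    "RepeatSpacerArray",
    "parse_array",
    "detect_repeat",
    "render_array_map",
]


@dataclass
class Spacer:
    seq: str
    leader_index: int  # 1 = leader-proximal (newest)
    trailer_index: int  # 1 = trailer-proximal (oldest); leader+paper = n+1


@dataclass
class RepeatSpacerArray:
    """Leader + ordered spacers + repeat (+ per-copy variants) for one locus."""

    strain_id: str
    locus_id: str
    leader: str
    repeat: str
    spacers: list[Spacer]
    trailer: str
    #: observed sequence of each repeat copy, leader-proximal first
    #: (length == len(spacers) + 1); equals ``repeat`` when exact.
    repeat_observed: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.repeat_observed:
            self.repeat_observed = [self.repeat] * (len(self.spacers) + 1)

    def __len__(self) -> int:
        return len(self.spacers)

    @property
    def spacer_seqs(self) -> list[str]:
        return [s.seq for s in self.spacers]

    def repeat_variants(self) -> list[list[tuple[int, str]]]:
        """Per repeat copy, the (offset, observed base) substitutions."""
        return [
            [(i, obs[i]) for i in range(len(self.repeat)) if obs[i] != self.repeat[i]]
            for obs in self.repeat_observed
        ]

    def reconstruct(self) -> str:
        """Re-emit the locus sequence: leader R s1 R s2 ... R trailer."""
        parts = [self.leader]
        for i, sp in enumerate(self.spacers):
            parts.append(self.repeat_observed[i])
            parts.append(sp.seq)
        parts.append(self.repeat_observed[len(self.spacers)])
        parts.append(self.trailer)
        return "".join(parts)


def _renumber(seqs: list[str]) -> list[Spacer]:
    n = len(seqs)
    return [Spacer(seq=s, leader_index=i + 1, trailer_index=n - i) for i, s in enumerate(seqs)]


def parse_array(
    locus: SequenceRecord | str,
    repeat: str,
    max_repeat_mismatch: int = 2,
    spacer_len_range: tuple[int, int] = (20, 45),
    strain_id: str | None = None,
    locus_id: str = "CR1",
) -> RepeatSpacerArray:
    """Cut a locus into leader + repeat-spacer units.

    Repeat copies are found as non-overlapping occurrences with at most
    ``max_repeat_mismatch`` substitutions, scanned left to right (greedy
    leftmost). Segments between consecutive copies become spacers; the
    segment before the first copy is the leader, after the last the
    trailer. An inter-repeat segment outside ``spacer_len_range`` aborts
    the parse — the usual symptom of a wrong repeat or a chimeric locus.
    """
    if isinstance(locus, SequenceRecord):
        seq = locus.seq
        sid = strain_id if strain_id is not None else locus.id
    else:
        seq = normalize_seq(locus)
        sid = strain_id if strain_id is not None else "unnamed"
    repeat = normalize_seq(repeat)
    if len(repeat) < 20:
        raise ValueError(f"repeat too short ({len(repeat)} nt; need >= 20)")

    L = len(repeat)
    occurrences: list[int] = []
    observed: list[str] = []
    i = 0
    while i <= len(seq) - L:
        window = seq[i : i + L]
        if hamming(window, repeat) <= max_repeat_mismatch:
            occurrences.append(i)
            observed.append(window)
            i += L
        else:
            i += 1
    if not occurrences:
        raise ValueError(
            f"{sid}/{locus_id}: repeat not found (<= {max_repeat_mismatch} mismatches)"
        )

    leader = seq[: occurrences[0]]
    trailer = seq[occurrences[-1] + L :]
    lo, hi = spacer_len_range
    spacer_seqs: list[str] = []
    for a, b in zip(occurrences, occurrences[1:]):
        seg = seq[a + L : b]
        if not (lo <= len(seg) <= hi):
            raise ValueError(
                f"{sid}/{locus_id}: inter-repeat segment {seg!r} "
                f"({len(seg)} nt) outside spacer length range [{lo}, {hi}] — "
                "wrong repeat or chimeric locus?"
            )
        spacer_seqs.append(seg)

    return RepeatSpacerArray(
        strain_id=sid,
        locus_id=locus_id,
        leader=leader,
        repeat=repeat,
        spacers=_renumber(spacer_seqs),
        trailer=trailer,
        repeat_observed=observed,
    )


def detect_repeat(
    locus: SequenceRecord | str,
    k: int = 18,
    min_count: int = 3,
    consensus_threshold: float = 0.9,
) -> str:
    """Guess the direct repeat of a locus when it is not known.

    Takes the most frequent k-mer with at least ``min_count`` occurrences
    (ties broken by leftmost first occurrence) and extends it on both sides
    while the flanking column agrees in at least ``consensus_threshold`` of
    the occurrences.
    """
    seq = locus.seq if isinstance(locus, SequenceRecord) else normalize_seq(locus)
    if len(seq) < 3 * k:
        raise ValueError(f"locus too short for repeat detection (need >= {3 * k} nt)")

    counts: Counter[str] = Counter()
    first_pos: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        counts[kmer] += 1
        first_pos.setdefault(kmer, i)
    best = max(
        (km for km, c in counts.items() if c >= min_count),
        key=lambda km: (counts[km], -first_pos[km]),
        default=None,
    )
    if best is None:
        raise ValueError(
            f"no {k}-mer occurs >= {min_count} times; supply the repeat explicitly"
        )

    starts = [i for i in range(len(seq) - k + 1) if seq[i : i + k] == best]
    left, right = 0, 0  # extension widths
    n = len(starts)

    def column_ok(offset: int) -> bool:
        positions = [s + offset for s in starts]
        if any(p < 0 or p >= len(seq) for p in positions):
            return False
        col = Counter(seq[p] for p in positions)
        return col.most_common(1)[0][1] / n >= consensus_threshold

    while column_ok(-(left + 1)):
        left += 1
    while column_ok(k + right):
        right += 1
    s0 = starts[0]
    return seq[s0 - left : s0 + k + right]


_GLYPHS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def render_array_map(arrays: list[RepeatSpacerArray], catalog) -> str:
    """Render arrays as one text row each, spacers as shared glyph codes.

    Each unique catalog spacer gets a deterministic glyph (identical
    spacers share glyphs across rows); rows are anchored at the leader end,
    mirroring published spacer-map figures with repeats removed.
    """
    ids = sorted(catalog.entries)
    width = 1 if len(ids) <= len(_GLYPHS) else 2
    glyph: dict[str, str] = {}
    for i, cid in enumerate(ids):
        if width == 1:
            glyph[cid] = _GLYPHS[i]
        else:
            glyph[cid] = _GLYPHS[i // len(_GLYPHS)] + _GLYPHS[i % len(_GLYPHS)]
    rows = []
    for arr in arrays:
        codes = [
            glyph[catalog.membership[(arr.strain_id, arr.locus_id, sp.leader_index)]]
            for sp in arr.spacers
        ]
        rows.append(f"{arr.strain_id}/{arr.locus_id}\t" + " ".join(codes))
    return "\n".join(rows)
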