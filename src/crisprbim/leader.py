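"""Leader 3′-end comparison and insertion-site sequence context analysis.

New spacers are normally anchored at the 3′ end of the leader (the
leader-anchoring sequence, LAS); when that anchor is degraded, integration
can occur downstream of array-internal sequences resembling it. This
module extracts the 3′-terminal context of the unit immediately upstream
of an acquired spacer (leader for polar acquisitions, a pre-existing
spacer for ectopic ones), builds positional nucleotide profiles over such
contexts (positions counted from the 3′ end, −1 adjacent to the downstream
repeat), and compares leader 3′ ends between strains by global alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .arrays import RepeatSpacerArray
from .diff import Acquisition, ArrayDiff

__all__ = [
    "InsertionContext",
    "PositionalProfile",
    "LeaderEdit",
    "LeaderEditReport",
    "upstream_context",
    "positional_profile",
    "compare_leaders",
]


@dataclass
class InsertionContext:
    """3′-terminal sequence of the unit upstream of one acquired spacer."""

    bim_id: str
    upstream_unit: str  # "leader" | "spacer(<trailer_index>)" | "new_spacer(<pos>)"
    context_seq: str
    first_repeat_base: str
    truncated: bool = False


def upstream_context(
    array: RepeatSpacerArray,
    diff: ArrayDiff,
    acquisition: Acquisition,
    n: int = 7,
) -> InsertionContext:
    """Context of the unit immediately leader-side of an acquired spacer.

    ``array`` is the BIM array the acquisition lives in. For an acquisition
    in first position the upstream unit is the leader. The context is the
    unit's last ``n`` nucleotides (shorter units are flagged truncated);
    the first base of the downstream repeat is recorded alongside because
    it can compensate a missing −1 anchor base.
    """
    if acquisition not in diff.acquisitions:
        raise ValueError("acquisition does not belong to the given diff")
    pos = acquisition.bim_leader_index
    if pos == 1:
        label, unit_seq = "leader", array.leader
    else:
        up = pos - 1
        unit_seq = array.spacers[up - 1].seq
        acquired = {a.bim_leader_index for a in diff.acquisitions}
        if up in acquired:
            label = f"new_spacer({up})"
        else:
            anc = {b: a for a, b in diff.unchanged}.get(up)
            label = f"spacer({diff.n_ancestor + 1 - anc})" if anc else f"bim_spacer({up})"
    context = unit_seq[-n:] if unit_seq else ""
    return InsertionContext(
        bim_id=diff.bim_id,
        upstream_unit=label,
        context_seq=context,
        first_repeat_base=array.repeat[0],
        truncated=len(context) < n,
    )


@dataclass
class PositionalProfile:
    """Per-position (−1, −2, … from the 3′ end) nucleotide counts/fractions."""

    positions: tuple[int, ...]
    counts: dict[int, dict[str, int]]
    fractions: dict[int, dict[str, float]]
    n_contexts: int
    #: fraction of contexts with G at −1 OR a downstream repeat starting
    #: with G (the compensated anchor statistic), kept separate from the
    #: raw −1 column.
    compensated_g_fraction: float = 0.0

    def fraction(self, position: int, base: str) -> float:
        return self.fractions.get(position, {}).get(base, 0.0)

    def to_dict(self) -> dict:
        return {
            "positions": list(self.positions),
            "n_contexts": self.n_contexts,
            "counts": {str(p): c for p, c in self.counts.items()},
            "fractions": {str(p): f for p, f in self.fractions.items()},
            "compensated_g_fraction": self.compensated_g_fraction,
        }


def positional_profile(
    contexts: Sequence[InsertionContext | str],
    positions: Sequence[int] = (-1, -2, -3),
) -> PositionalProfile:
    """Nucleotide counts and fractions at 3′-anchored positions.

    Accepts :class:`InsertionContext` objects or bare context strings
    (strings contribute no repeat base to the compensated statistic).
    """
    if not contexts:
        raise ValueError("need at least one context")
    seqs: list[str] = []
    repeat_bases: list[Optional[str]] = []
    bim_ids: list[str] = []
    for c in contexts:
        if isinstance(c, InsertionContext):
            seqs.append(c.context_seq)
            repeat_bases.append(c.first_repeat_base)
            bim_ids.append(c.bim_id)
        else:
            seqs.append(c)
            repeat_bases.append(None)

    counts: dict[int, dict[str, int]] = {}
    fractions: dict[int, dict[str, float]] = {}
    for p in positions:
        col: dict[str, int] = {}
        contributing = 0
        for s in seqs:
            if len(s) >= -p:
                col[s[p]] = col.get(s[p], 0) + 1
                contributing += 1
        counts[p] = dict(sorted(col.items()))
        fractions[p] = (
            {b: c / contributing for b, c in counts[p].items()} if contributing else {}
        )

    compensated = 0
    for s, rb in zip(seqs, repeat_bases):
        g_at_minus1 = len(s) >= 1 and s[-1] == "G"
        if g_at_minus1 or rb == "G":
            compensated += 1
    return PositionalProfile(
        positions=tuple(positions),
        counts=counts,
        fractions=fractions,
        n_contexts=len(seqs),
        compensated_g_fraction=compensated / len(seqs),
    )


@dataclass
class LeaderEdit:
    op: str  # "substitution" | "deletion" | "insertion"
    position: int  # 3'-anchored on the first leader: -1 = last nucleotide
    ref: str  # base in leaderA ("" for insertions)
    alt: str  # base in leaderB ("" for deletions)


@dataclass
class LeaderEditReport:
    edits: list[LeaderEdit] = field(default_factory=list)
    distance: int = 0
    window: int = 10

    @property
    def identical(self) -> bool:
        return not self.edits


def compare_leaders(leaderA: str, leaderB: str, window: int = 10) -> LeaderEditReport:
    """Globally align two leaders; report edits in the 3′-terminal window.

    The full leaders are aligned with unit edit costs (clipping both to a
    fixed window first would manufacture spurious edge edits whenever the
    leaders differ in length). Edits falling within the last ``window``
    positions are reported relative to ``leaderA``, positions counted from
    its 3′ end (−1 = last base, 0 = appended after the last base): a
    deletion is a base of A absent from B, an insertion a base of B absent
    from A. Traceback from the 3′ end prefers matches, then substitutions,
    then deletions, so terminal indel runs are reported at their 3′-most
    position. ``distance`` is the full-leader edit distance.
    """
    if not leaderA or not leaderB:
        raise ValueError("leaders must be non-empty")
    a = leaderA.upper()
    b = leaderB.upper()
    la, lb = len(a), len(b)
    D = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        D[i][0] = i
    for j in range(lb + 1):
        D[0][j] = j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            sub = D[i - 1][j - 1] + (a[i - 1] != b[j - 1])
            D[i][j] = min(sub, D[i - 1][j] + 1, D[i][j - 1] + 1)

    edits: list[LeaderEdit] = []
    i, j = la, lb
    while i > 0 or j > 0:
        if i > 0 and j > 0 and D[i][j] == D[i - 1][j - 1] + (a[i - 1] != b[j - 1]):
            if a[i - 1] != b[j - 1]:
                edits.append(
                    LeaderEdit("substitution", i - 1 - la, a[i - 1], b[j - 1])
                )
            i, j = i - 1, j - 1
        elif i > 0 and D[i][j] == D[i - 1][j] + 1:
            edits.append(LeaderEdit("deletion", i - 1 - la, a[i - 1], ""))
            i -= 1
        else:
            edits.append(LeaderEdit("insertion", i - la, "", b[j - 1]))
            j -= 1
    edits.reverse()
    windowed = [e for e in edits if e.position >= -window]
    return LeaderEditReport(edits=windowed, distance=D[la][lb], window=window)
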