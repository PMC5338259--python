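"""Align a mutant (BIM) array to its ancestor and classify the changes.

The two arrays are compared as sequences of spacer tokens (token equality
= spacer match at a configurable Hamming tolerance). A global alignment
with score +2 per matched token and −1 per inserted or deleted token — no
substitutions: a replaced spacer is a deletion plus an acquisition — gives
the edit script. Among co-optimal alignments the canonical one is the
lexicographically smallest move string under the order
insertion < match < deletion, read leader-to-trailer: this places acquired
spacers as leader-proximal as possible, so a 5′-end (polar) placement is
preferred whenever it is co-optimal and the novel ectopic class is never
over-called.

Acquisitions are classified *polar* when every array position on their
leader side is itself an acquisition (a contiguous new 5′ block), else
*ectopic* (inserted between pre-existing spacers). An acquired spacer
whose sequence matches an ancestral one is flagged as a duplication.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .arrays import RepeatSpacerArray

__all__ = [
    "Acquisition",
    "ArrayDiff",
    "CohortSummary",
    "diff_arrays",
    "classify_acquisitions",
    "apply_diff",
    "summarize_cohort",
]

MATCH_SCORE = 2
GAP_SCORE = -1


@dataclass
class Acquisition:
    """One spacer present in the BIM but not matched in the ancestor."""

    spacer_seq: str
    bim_leader_index: int  # position of the new spacer in the BIM array (1-based)
    insertion_after_leader_index: int  # ancestral leader_index upstream; 0 = 5'-end
    klass: Optional[str] = None  # "polar" | "ectopic"
    duplicate_of: Optional[int] = None  # ancestral leader_index it duplicates


@dataclass
class ArrayDiff:
    """Classified edit script turning the ancestor into the BIM array."""

    bim_id: str
    ancestor_id: str
    n_ancestor: int
    n_bim: int
    acquisitions: list[Acquisition] = field(default_factory=list)
    deletions: list[int] = field(default_factory=list)  # ancestral leader_index
    unchanged: list[tuple[int, int]] = field(default_factory=list)  # (anc, bim)
    no_match_warning: bool = False

    @property
    def label(self) -> Optional[str]:
        """BIM-level label: polar if all acquisitions polar, ectopic if any ectopic."""
        if not self.acquisitions:
            return None
        if any(a.klass == "ectopic" for a in self.acquisitions):
            return "ectopic"
        return "polar"

    def to_dict(self) -> dict:
        return {
            "bim_id": self.bim_id,
            "ancestor_id": self.ancestor_id,
            "label": self.label,
            "acquisitions": [
                {
                    "spacer_seq": a.spacer_seq,
                    "bim_leader_index": a.bim_leader_index,
                    "insertion_after_leader_index": a.insertion_after_leader_index,
                    "class": a.klass,
                    "duplicate_of": a.duplicate_of,
                }
                for a in self.acquisitions
            ],
            "deletions": list(self.deletions),
            "unchanged": [list(p) for p in self.unchanged],
            "no_match_warning": self.no_match_warning,
        }


def _tokens_equal(a: str, b: str, max_mismatch: int) -> bool:
    if len(a) != len(b):
        return False
    if max_mismatch == 0:
        return a == b
    return sum(1 for x, y in zip(a, b) if x != y) <= max_mismatch


def diff_arrays(
    ancestor: RepeatSpacerArray,
    bim: RepeatSpacerArray,
    max_mismatch: int = 0,
) -> ArrayDiff:
    """Compute the canonical classified edit script between two arrays.

    Deterministic: identical inputs give identical diffs. Raises if the
    ancestor is empty; sets ``no_match_warning`` when no token matches
    (likely unrelated arrays).
    """
    if len(ancestor) == 0:
        raise ValueError("ancestor array has no spacers")
    A = ancestor.spacer_seqs
    B = bim.spacer_seqs
    m, n = len(A), len(B)

    # Suffix-optimal scores: S[i][j] = best score aligning A[i:] with B[j:].
    S = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        S[i][n] = -(m - i)
    for j in range(n + 1):
        S[m][j] = -(n - j)
    for i in range(m - 1, -1, -1):
        for j in range(n - 1, -1, -1):
            best = max(S[i][j + 1] + GAP_SCORE, S[i + 1][j] + GAP_SCORE)
            if _tokens_equal(A[i], B[j], max_mismatch):
                best = max(best, S[i + 1][j + 1] + MATCH_SCORE)
            S[i][j] = best

    # Greedy traceback from the front, preferring insertion, then match,
    # then deletion whenever co-optimal: yields the lexicographically
    # smallest optimal move string (insertions leftmost).
    i = j = 0
    acquisitions: list[Acquisition] = []
    deletions: list[int] = []
    unchanged: list[tuple[int, int]] = []
    last_matched_anc = 0
    while i < m or j < n:
        if j < n and S[i][j] == S[i][j + 1] + GAP_SCORE:
            acquisitions.append(
                Acquisition(
                    spacer_seq=B[j],
                    bim_leader_index=j + 1,
                    insertion_after_leader_index=last_matched_anc,
                )
            )
            j += 1
        elif (
            i < m
            and j < n
            and _tokens_equal(A[i], B[j], max_mismatch)
            and S[i][j] == S[i + 1][j + 1] + MATCH_SCORE
        ):
            unchanged.append((i + 1, j + 1))
            last_matched_anc = i + 1
            i += 1
            j += 1
        else:
            deletions.append(i + 1)
            i += 1

    for acq in acquisitions:
        for k, anc_seq in enumerate(A):
            if _tokens_equal(anc_seq, acq.spacer_seq, max_mismatch):
                acq.duplicate_of = k + 1
                break

    diff = ArrayDiff(
        bim_id=bim.strain_id,
        ancestor_id=ancestor.strain_id,
        n_ancestor=m,
        n_bim=n,
        acquisitions=acquisitions,
        deletions=deletions,
        unchanged=unchanged,
        no_match_warning=(not unchanged),
    )
    return classify_acquisitions(diff)


def classify_acquisitions(diff: ArrayDiff) -> ArrayDiff:
    """Set the polar/ectopic class on each acquisition of a diff.

    Polar: the acquisition sits in the contiguous block of acquisitions at
    the leader end of the BIM array (every position on its leader side is
    itself an acquisition). Anything else is ectopic.
    """
    acquired_positions = {a.bim_leader_index for a in diff.acquisitions}
    block = 0
    while (block + 1) in acquired_positions:
        block += 1
    for a in diff.acquisitions:
        a.klass = "polar" if a.bim_leader_index <= block else "ectopic"
    return diff


def apply_diff(ancestor: RepeatSpacerArray, diff: ArrayDiff) -> list[str]:
    """Apply an edit script to the ancestor's spacer list; returns BIM spacers."""
    A = ancestor.spacer_seqs
    deleted = set(diff.deletions)
    kept = [(i + 1, s) for i, s in enumerate(A) if (i + 1) not in deleted]
    out: list[Optional[str]] = [None] * diff.n_bim
    for a in diff.acquisitions:
        out[a.bim_leader_index - 1] = a.spacer_seq
    it = iter(kept)
    for pos in range(diff.n_bim):
        if out[pos] is None:
            out[pos] = next(it)[1]
    return [s for s in out if s is not None]


@dataclass
class CohortSummary:
    """Aggregated acquisition statistics over a cohort of BIM diffs."""

    n_bims: int
    n_with_acquisition: int
    n_polar_only: int
    n_ectopic: int
    n_single_polar: int
    #: multiset of ectopic insertion sites as (downstream, upstream)
    #: trailer-anchored ("paper") spacer index pairs
    ectopic_positions: Counter = field(default_factory=Counter)
    deletion_counts: dict[str, int] = field(default_factory=dict)
    #: (bim_id, ancestral leader_index duplicated, trailer index duplicated)
    duplication_events: list[tuple[str, int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_bims": self.n_bims,
            "n_with_acquisition": self.n_with_acquisition,
            "n_polar_only": self.n_polar_only,
            "n_ectopic": self.n_ectopic,
            "n_single_polar": self.n_single_polar,
            "ectopic_positions": {
                f"{a},{b}": c for (a, b), c in sorted(self.ectopic_positions.items())
            },
            "deletion_counts": dict(sorted(self.deletion_counts.items())),
            "duplication_events": [list(e) for e in self.duplication_events],
        }


def summarize_cohort(diffs: list[ArrayDiff]) -> CohortSummary:
    """Aggregate per-BIM diffs (all against the same ancestor) into a summary."""
    ancestors = {d.ancestor_id for d in diffs}
    if len(ancestors) > 1:
        raise ValueError(f"diffs come from mixed ancestors: {sorted(ancestors)}")
    summary = CohortSummary(
        n_bims=len(diffs),
        n_with_acquisition=sum(1 for d in diffs if d.acquisitions),
        n_polar_only=sum(1 for d in diffs if d.label == "polar"),
        n_ectopic=sum(1 for d in diffs if d.label == "ectopic"),
        n_single_polar=sum(
            1 for d in diffs if len(d.acquisitions) == 1 and d.label == "polar"
        ),
    )
    for d in diffs:
        summary.deletion_counts[d.bim_id] = len(d.deletions)
        N = d.n_ancestor
        for a in d.acquisitions:
            if a.klass == "ectopic":
                k = a.insertion_after_leader_index
                summary.ectopic_positions[(N - k, N + 1 - k)] += 1
            if a.duplicate_of is not None:
                summary.duplication_events.append(
                    (d.bim_id, a.duplicate_of, N + 1 - a.duplicate_of)
                )
    return summary
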