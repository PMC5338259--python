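"""Cross-strain spacer content comparison.

Spacers from several arrays are clustered into a catalog of canonical
spacers (single-linkage, Hamming distance, equal lengths only); shared
spacer counts between strains are then catalog-membership intersections,
with within-array duplicates counted by multiplicity.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

from .arrays import RepeatSpacerArray
from .seqio import hamming

__all__ = ["SpacerCatalog", "build_catalog", "shared_spacers"]


def _short_id(seq: str) -> str:
    return hashlib.sha1(seq.encode()).hexdigest()[:8]


@dataclass
class SpacerCatalog:
    """Canonical spacer ids and the membership of every array position."""

    entries: dict[str, str] = field(default_factory=dict)  # id -> representative seq
    membership: dict[tuple[str, str, int], str] = field(default_factory=dict)
    tolerance: int = 0

    def ids_of(self, array: RepeatSpacerArray) -> list[str]:
        return [
            self.membership[(array.strain_id, array.locus_id, sp.leader_index)]
            for sp in array.spacers
        ]


def build_catalog(arrays: list[RepeatSpacerArray], max_mismatch: int = 0) -> SpacerCatalog:
    """Cluster all spacers of the given arrays into canonical entries.

    Single-linkage over Hamming distance <= ``max_mismatch`` between
    equal-length spacers (unequal lengths never cluster). The canonical
    representative of a cluster is its lexicographically smallest member;
    the stable short id is a hash of that representative.
    """
    occ: list[tuple[tuple[str, str, int], str]] = []
    for arr in arrays:
        for sp in arr.spacers:
            occ.append(((arr.strain_id, arr.locus_id, sp.leader_index), sp.seq))

    uniq = sorted({seq for _, seq in occ})
    parent = list(range(len(uniq)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(uniq):
        by_len.setdefault(len(s), []).append(i)
    if max_mismatch > 0:
        for members in by_len.values():
            for ai in range(len(members)):
                for bi in range(ai + 1, len(members)):
                    a, b = members[ai], members[bi]
                    if hamming(uniq[a], uniq[b]) <= max_mismatch:
                        union(a, b)

    cluster_rep: dict[int, str] = {}
    for i, s in enumerate(uniq):
        r = find(i)
        if r not in cluster_rep or s < cluster_rep[r]:
            cluster_rep[r] = s

    seq_to_id = {uniq[i]: _short_id(cluster_rep[find(i)]) for i in range(len(uniq))}
    cat = SpacerCatalog(tolerance=max_mismatch)
    for rep in cluster_rep.values():
        cat.entries[_short_id(rep)] = rep
    for key, seq in occ:
        cat.membership[key] = seq_to_id[seq]
    return cat


def shared_spacers(
    arrayA: RepeatSpacerArray,
    arrayB: RepeatSpacerArray,
    max_mismatch: int = 0,
) -> tuple[int, list[tuple[int, int]]]:
    """Count catalog spacers present in both arrays.

    A spacer present k_A and k_B times counts min(k_A, k_B) times. Returns
    the count and the matched (leader_index_A, leader_index_B) pairs, paired
    occurrence-by-occurrence in leader order.
    """
    cat = build_catalog([arrayA, arrayB], max_mismatch=max_mismatch)
    ids_a = cat.ids_of(arrayA)
    ids_b = cat.ids_of(arrayB)
    pos_b: dict[str, list[int]] = {}
    for j, cid in enumerate(ids_b):
        pos_b.setdefault(cid, []).append(j + 1)
    pairs: list[tuple[int, int]] = []
    used: dict[str, int] = {}
    for i, cid in enumerate(ids_a):
        k = used.get(cid, 0)
        if cid in pos_b and k < len(pos_b[cid]):
            pairs.append((i + 1, pos_b[cid][k]))
            used[cid] = k + 1
    return len(pairs), pairs
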