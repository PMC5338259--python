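"""Independent brute-force oracles used to cross-check the implementations.

These deliberately take the slow, enumerative path: the token-alignment
oracle enumerates every monotone matching between equal tokens; the
protospacer oracle slides a window base-by-base in pure Python; the ORF
oracle walks forward from every start codon. None of them shares code
with the implementations they check.
"""

from __future__ import annotations

from crisprbim.arrays import RepeatSpacerArray, Spacer

_STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTN", "TGCAN")


def make_array(seqs, strain_id="arr", leader="AAAATTTT", repeat="G" + "C" * 35,
               trailer="TTTT"):
    """Build a RepeatSpacerArray directly from a list of spacer sequences."""
    n = len(seqs)
    return RepeatSpacerArray(
        strain_id=strain_id,
        locus_id="CR1",
        leader=leader,
        repeat=repeat,
        spacers=[Spacer(seq=s, leader_index=i + 1, trailer_index=n - i)
                 for i, s in enumerate(seqs)],
        trailer=trailer,
    )


def oracle_token_diff(A: list[str], B: list[str]) -> dict:
    """Minimal-edit alignment of token lists by exhaustive enumeration.

    Score: +2 per matched (equal) token, -1 per inserted/deleted token, no
    substitutions. Among co-optimal alignments, the canonical one has the
    lexicographically smallest move string reading leader-to-trailer with
    insertion < match < deletion (within a gap, insertions before
    deletions). Returns acquisitions (1-based B positions), deletions
    (1-based A positions) and matched pairs.
    """
    m, n = len(A), len(B)
    best: list = [None]  # (score, move_string, pairs)

    def finalize(pairs):
        k = len(pairs)
        score = 2 * k - (m - k) - (n - k)
        moves = []
        pi = pj = 0
        for a, b in pairs:
            moves.append("a" * (b - pj))  # insertions first within each gap
            moves.append("c" * (a - pi))
            moves.append("b")
            pi, pj = a + 1, b + 1
        moves.append("a" * (n - pj))
        moves.append("c" * (m - pi))
        ms = "".join(moves)
        cand = (-score, ms, pairs)
        if best[0] is None or cand < best[0]:
            best[0] = cand

    def rec(i, j, pairs):
        if i == m:
            finalize(list(pairs))
            return
        rec(i + 1, j, pairs)  # A[i] unmatched (deleted)
        for j2 in range(j, n):
            if A[i] == B[j2]:
                pairs.append((i, j2))
                rec(i + 1, j2 + 1, pairs)
                pairs.pop()

    rec(0, 0, [])
    _, moves, pairs = best[0]
    acquisitions, deletions = [], []
    i = j = 0
    for mv in moves:
        if mv == "a":
            acquisitions.append(j + 1)
            j += 1
        elif mv == "b":
            i += 1
            j += 1
        else:
            deletions.append(i + 1)
            i += 1
    return {
        "acquisitions": acquisitions,
        "deletions": deletions,
        "pairs": [(a + 1, b + 1) for a, b in pairs],
        "score": -best[0][0],
    }


def naive_protospacer_scan(spacer: str, genome: str, max_mismatch: int):
    """Pure-Python sliding-window Hamming scan over both strands."""
    rc = spacer.translate(_COMP)[::-1]
    L = len(spacer)
    hits = []
    for strand, q in (("+", spacer), ("-", rc)):
        for i in range(len(genome) - L + 1):
            d = 0
            for x, y in zip(genome[i : i + L], q):
                if x != y or x == "N" or y == "N":
                    d += 1
                    if d > max_mismatch:
                        break
            if d <= max_mismatch:
                hits.append((d, i, strand))
    return sorted(hits)


def brute_force_orfs(seq: str, min_aa: int = 30, starts=("ATG", "TTG", "GTG")):
    """Enumerate ORFs by walking forward from every start codon.

    Returns the set of (strand, start, end, aa_length) tuples in forward
    coordinates, keeping only the longest ORF per (strand, stop) group.
    """
    out = {}
    n = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else seq.translate(_COMP)[::-1]
        for pos in range(n - 2):
            if s[pos : pos + 3] not in starts:
                continue
            stop = None
            for p in range(pos + 3, n - 2, 3):
                if s[p : p + 3] in _STOPS:
                    stop = p
                    break
            if stop is None:
                continue
            aa = (stop - pos) // 3
            if aa < min_aa:
                continue
            key = (strand, stop)
            if key not in out or pos < out[key][0]:
                out[key] = (pos, stop, aa)
    calls = set()
    for (strand, _), (pos, stop, aa) in out.items():
        if strand == "+":
            calls.add((strand, pos, stop + 3, aa))
        else:
            calls.add((strand, n - (stop + 3), n - pos, aa))
    return calls


def sliding_window_repeat_scan(locus: str, repeat: str, max_mismatch: int):
    """Greedy leftmost non-overlapping approximate repeat occurrences."""
    L = len(repeat)
    occ = []
    i = 0
    while i <= len(locus) - L:
        d = sum(1 for x, y in zip(locus[i : i + L], repeat) if x != y)
        if d <= max_mismatch:
            occ.append(i)
            i += L
        else:
            i += 1
    return occ
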