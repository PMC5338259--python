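"""Generators for phage-challenge study inputs, with ground truth.

Everything the pipeline consumes can be simulated here: phage genomes
with planted protospacers flanked by consensus-conforming PAMs, ancestral
repeat-spacer arrays, and cohorts of bacteriophage-insensitive mutants
(BIMs) carrying planted polar/ectopic acquisitions, deletions and
duplications, together with a per-BIM truth table for recovery testing.

:func:`build_worked_example` emits the deterministic packaged worked
example: a 23-spacer ancestral CRISPR1 array ("Uy02-like"), 23 BIM loci
reproducing the published cohort structure (14 polar / 9 ectopic at 5
distinct internal sites / 12 single-polar / 1- and 8-spacer deletions /
spacer duplications), a companion ~34.5 kb phage genome at 39% GC
containing every novel acquired spacer as a perfect protospacer next to
an NNAGAAW PAM, and a reference leader differing from the ancestral one
by a single terminal G. Spacer and repeat sequences in the fixture are
synthetic stand-ins, not deposited sequences.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .arrays import RepeatSpacerArray, Spacer
from .diff import CohortSummary
from .seqio import (
    IUPAC_CODES,
    FeatureSpan,
    SequenceRecord,
    revcomp,
    write_fasta,
    write_genbank,
)

__all__ = [
    "DEFAULT_REPEAT",
    "PlantedSite",
    "CohortSpec",
    "BimTruth",
    "CohortTruth",
    "generate_genome",
    "generate_ancestor",
    "simulate_cohort",
    "build_worked_example",
    "FixtureBundle",
]

#: Synthetic 36-nt direct repeat used by the generators and the packaged
#: fixture. It is NOT a published repeat sequence; it starts with G so
#: that a missing −1 anchor guanine in an upstream unit is compensated by
#: the first repeat base, as described for natural arrays.
DEFAULT_REPEAT = "GACTTCAAGGTCCTTAGCATGGTAACGTTCCAGAAC"

_BASES = np.array(list("ACGT"))


def _spawn_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=length, p=p))


@dataclass(frozen=True)
class PlantedSite:
    """One planted protospacer + PAM on a simulated genome."""

    index: int
    start: int  # 0-based, forward strand
    end: int
    seq: str
    pam: str
    strand: str = "+"


def _random_pam(rng: np.random.Generator, consensus: str) -> str:
    return "".join(rng.choice(sorted(IUPAC_CODES[c])) for c in consensus)


def generate_genome(
    length: int = 34500,
    gc: float = 0.39,
    n_protospacers: int = 24,
    pam_consensus: str = "NNAGAAW",
    seed: Optional[int] = None,
    protospacer_len: int = 30,
    genome_id: str = "sim_phage",
) -> tuple[SequenceRecord, list[PlantedSite]]:
    """An i.i.d.-base genome at the target GC with planted protospacer sites.

    Sites are non-overlapping, one per equal-width genome bin at a random
    offset, each the planted protospacer followed immediately by a PAM
    drawn uniformly from the consensus-conforming strings. Planted
    protospacer sequences are pairwise distinct (also across strands).
    """
    if length < n_protospacers * 40:
        raise ValueError(
            f"genome of {length} nt cannot host {n_protospacers} protospacer "
            "sites (need >= 40 nt each)"
        )
    rng = np.random.default_rng(seed)
    genome = list(_random_seq(rng, length, gc=gc))

    footprint = protospacer_len + len(pam_consensus)
    bin_len = length // n_protospacers
    sites: list[PlantedSite] = []
    seen: set[str] = set()
    for i in range(n_protospacers):
        while True:
            proto = _random_seq(rng, protospacer_len, gc=gc)
            if proto not in seen and revcomp(proto) not in seen:
                seen.add(proto)
                break
        pam = _random_pam(rng, pam_consensus)
        offset = int(rng.integers(0, bin_len - footprint + 1))
        start = i * bin_len + offset
        genome[start : start + footprint] = list(proto + pam)
        sites.append(
            PlantedSite(index=i, start=start, end=start + protospacer_len, seq=proto, pam=pam)
        )
    record = SequenceRecord(
        id=genome_id,
        seq="".join(genome),
        description=f"simulated phage genome, {length} nt, GC target {gc:.2f}",
    )
    return record, sites


def generate_ancestor(
    n_spacers: int = 23,
    spacer_len: int = 30,
    repeat: str = DEFAULT_REPEAT,
    leader: Optional[str] = None,
    trailer: Optional[str] = None,
    seed: Optional[int] = None,
    gc: float = 0.39,
    strain_id: str = "ancestor",
    locus_id: str = "CR1",
) -> RepeatSpacerArray:
    """An ancestral array of pairwise-distinct random spacers.

    The locus sequence is recovered with ``array.reconstruct()`` (leader,
    n+1 repeat copies, n spacers, trailer).
    """
    rng = np.random.default_rng(seed)
    if leader is None:
        leader = _random_seq(rng, 100, gc=0.30)  # leaders are AT-rich
    if trailer is None:
        trailer = _random_seq(rng, 40, gc=gc)
    seen: set[str] = set()
    seqs: list[str] = []
    while len(seqs) < n_spacers:
        s = _random_seq(rng, spacer_len, gc=gc)
        if s not in seen:
            seen.add(s)
            seqs.append(s)
    spacers = [
        Spacer(seq=s, leader_index=i + 1, trailer_index=n_spacers - i)
        for i, s in enumerate(seqs)
    ]
    return RepeatSpacerArray(
        strain_id=strain_id,
        locus_id=locus_id,
        leader=leader,
        repeat=repeat,
        spacers=spacers,
        trailer=trailer,
    )


@dataclass
class CohortSpec:
    """Composition of a simulated BIM cohort.

    Defaults mirror the published challenge cohort: 23 BIMs, 14 of them
    polar-only (12 single acquisitions, two multi-acquisition BIMs of 2
    and 3 new spacers whose extra spacers duplicate leader-proximal
    ancestral ones), deletion blocks of 1 and 8 spacers in two of the
    single-polar BIMs, and 9 ectopic BIMs. ``ectopic_mode`` chooses how
    internal insertion sites are drawn: ``uniform`` over all internal
    boundaries, or ``anchored`` only downstream of spacers whose 3′ end
    matches ``anchor_pattern`` (IUPAC, 3′-aligned; default ``AN`` = adenine
    at −2).
    """

    n_bims: int = 23
    fraction_polar: float = 14 / 23
    n_single_polar: int = 12
    duplication_spec: tuple[int, ...] = (2, 3)  # acquisitions per multi-polar BIM
    deletion_spec: tuple[int, ...] = (1, 8)  # deletion block sizes (single-polar BIMs)
    n_unchanged: int = 0  # BIMs with no planted event at all
    ectopic_mode: str = "uniform"
    anchor_pattern: str = "AN"
    seed: int = 0

    @property
    def n_acquiring(self) -> int:
        return self.n_bims - self.n_unchanged

    @property
    def n_polar(self) -> int:
        return round(self.fraction_polar * self.n_acquiring)

    @property
    def n_ectopic(self) -> int:
        return self.n_acquiring - self.n_polar

    def validate(self) -> None:
        if self.ectopic_mode not in ("uniform", "anchored"):
            raise ValueError(f"unknown ectopic_mode {self.ectopic_mode!r}")
        if self.n_unchanged < 0 or self.n_unchanged > self.n_bims:
            raise ValueError("n_unchanged outside [0, n_bims]")
        if self.n_single_polar + len(self.duplication_spec) != self.n_polar:
            raise ValueError(
                "inconsistent cohort spec: n_single_polar + multi-polar BIMs "
                f"({self.n_single_polar} + {len(self.duplication_spec)}) != "
                f"round(fraction_polar * n_acquiring) = {self.n_polar}"
            )
        if len(self.deletion_spec) > self.n_single_polar:
            raise ValueError("more deletion blocks than single-polar BIMs")
        if any(k < 2 for k in self.duplication_spec):
            raise ValueError("multi-polar BIMs need >= 2 acquisitions")


@dataclass
class BimTruth:
    """Planted events for one BIM, mirroring the diff edit-script fields."""

    bim_id: str
    acquisitions: list[dict] = field(default_factory=list)
    deletions: list[int] = field(default_factory=list)

    @property
    def label(self) -> Optional[str]:
        if not self.acquisitions:
            return None
        if any(a["class"] == "ectopic" for a in self.acquisitions):
            return "ectopic"
        return "polar"


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort, comparable to a diff summary."""

    ancestor_id: str
    n_ancestor: int
    bims: list[BimTruth] = field(default_factory=list)

    def summary(self) -> CohortSummary:
        """Aggregate the planted events directly (no alignment involved)."""
        s = CohortSummary(
            n_bims=len(self.bims),
            n_with_acquisition=sum(1 for b in self.bims if b.acquisitions),
            n_polar_only=sum(1 for b in self.bims if b.label == "polar"),
            n_ectopic=sum(1 for b in self.bims if b.label == "ectopic"),
            n_single_polar=sum(
                1 for b in self.bims if len(b.acquisitions) == 1 and b.label == "polar"
            ),
        )
        N = self.n_ancestor
        for b in self.bims:
            s.deletion_counts[b.bim_id] = len(b.deletions)
            for a in b.acquisitions:
                if a["class"] == "ectopic":
                    k = a["insertion_after_leader_index"]
                    s.ectopic_positions[(N - k, N + 1 - k)] += 1
                if a.get("duplicate_of") is not None:
                    s.duplication_events.append(
                        (b.bim_id, a["duplicate_of"], N + 1 - a["duplicate_of"])
                    )
        return s

    def to_dict(self) -> dict:
        return {
            "ancestor_id": self.ancestor_id,
            "n_ancestor": self.n_ancestor,
            "bims": [
                {
                    "bim_id": b.bim_id,
                    "label": b.label,
                    "acquisitions": b.acquisitions,
                    "deletions": b.deletions,
                }
                for b in self.bims
            ],
        }


def _acq(seq: str, pos: int, after: int, klass: str, dup: Optional[int] = None) -> dict:
    return {
        "spacer_seq": seq,
        "bim_leader_index": pos,
        "insertion_after_leader_index": after,
        "class": klass,
        "duplicate_of": dup,
    }


def _bim_locus(ancestor: RepeatSpacerArray, bim_id: str, spacer_seqs: list[str]) -> SequenceRecord:
    n = len(spacer_seqs)
    arr = RepeatSpacerArray(
        strain_id=bim_id,
        locus_id=ancestor.locus_id,
        leader=ancestor.leader,
        repeat=ancestor.repeat,
        spacers=[
            Spacer(seq=s, leader_index=i + 1, trailer_index=n - i)
            for i, s in enumerate(spacer_seqs)
        ],
        trailer=ancestor.trailer,
    )
    return SequenceRecord(id=bim_id, seq=arr.reconstruct(), description=f"{ancestor.locus_id} locus")


def _matches_anchor(seq: str, pattern: str) -> bool:
    tail = seq[-len(pattern) :]
    if len(tail) < len(pattern):
        return False
    return all(tail[i] in IUPAC_CODES[pattern[i]] for i in range(len(pattern)))


def simulate_cohort(
    ancestor: RepeatSpacerArray,
    sites: Sequence[PlantedSite],
    spec: CohortSpec,
) -> tuple[list[SequenceRecord], CohortTruth]:
    """Emit BIM locus records carrying planted events, plus the truth table.

    Novel spacer sequences are copied from the genome's planted
    protospacer sites (each adjacent to a consensus PAM), one unused site
    per novel spacer. Multi-polar BIMs duplicate leader-proximal ancestral
    spacers ahead of their one novel spacer. In anchored mode, ectopic
    insertion sites are drawn only downstream of ancestral spacers whose
    3′ end matches ``spec.anchor_pattern``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    N = len(ancestor)
    anc = ancestor.spacer_seqs
    n_novel = spec.n_single_polar + len(spec.duplication_spec) + spec.n_ectopic
    pool = [s.seq for s in sites if s.seq not in set(anc)]
    if len(pool) < n_novel:
        raise ValueError(
            f"genome provides {len(pool)} unused protospacer sites; need {n_novel}"
        )
    novel = [pool[i] for i in rng.permutation(len(pool))[:n_novel]]

    if spec.ectopic_mode == "anchored":
        eligible = [
            k for k in range(1, N) if _matches_anchor(anc[k - 1], spec.anchor_pattern)
        ]
        if not eligible:
            raise ValueError(
                f"anchored mode: no ancestral spacer 3' end matches {spec.anchor_pattern!r}"
            )
    else:
        eligible = list(range(1, N))

    roles: list[tuple] = [("single", None)] * spec.n_single_polar
    for i, d in enumerate(spec.deletion_spec):
        roles[i] = ("single", d)
    roles += [("multi", k) for k in spec.duplication_spec]
    roles += [("ectopic", None)] * spec.n_ectopic
    roles += [("none", None)] * spec.n_unchanged
    order = rng.permutation(len(roles))

    records: list[SequenceRecord] = []
    truth = CohortTruth(ancestor_id=ancestor.strain_id, n_ancestor=N)
    ni = 0  # next novel spacer
    for b in range(spec.n_bims):
        bim_id = f"BIM{b + 1}"
        role, par = roles[order[b]]
        bt = BimTruth(bim_id=bim_id)
        if role == "none":
            spacers = list(anc)
        elif role == "single":
            new = novel[ni]
            ni += 1
            kept = anc
            if par:  # deletion block of `par` spacers
                start = int(rng.integers(1, N - par + 2))  # leader_index of block start
                bt.deletions = list(range(start, start + par))
                kept = [s for i, s in enumerate(anc) if (i + 1) not in set(bt.deletions)]
            spacers = [new] + kept
            bt.acquisitions = [_acq(new, 1, 0, "polar")]
        elif role == "multi":
            k = par  # total acquisitions; k-1 duplicates of spacers 1..k-1
            new = novel[ni]
            ni += 1
            dups = anc[: k - 1]
            spacers = dups + [new] + anc
            bt.acquisitions = [
                _acq(anc[i], i + 1, 0, "polar", dup=i + 1) for i in range(k - 1)
            ] + [_acq(new, k, 0, "polar")]
        else:  # ectopic
            new = novel[ni]
            ni += 1
            k = int(eligible[rng.integers(0, len(eligible))])
            spacers = anc[:k] + [new] + anc[k:]
            bt.acquisitions = [_acq(new, k + 1, k, "ectopic")]
        records.append(_bim_locus(ancestor, bim_id, spacers))
        truth.bims.append(bt)
    return records, truth


@dataclass
class FixtureBundle:
    """The packaged worked example, in memory and (optionally) on disk."""

    ancestor: RepeatSpacerArray
    bim_records: list[SequenceRecord]
    genome: SequenceRecord
    sites: list[PlantedSite]
    truth: CohortTruth
    uy02_leader: str
    reference_leader: str
    repeat: str
    paths: dict[str, Path] = field(default_factory=dict)


# Ectopic BIMs of the published cohort: bim_id -> ancestral leader_index k
# after which the new spacer sits (site "between trailer-anchored spacers
# N-k and N+1-k"): (1,2)x2, (8,9), (14,15)x2, (15,16)x3, (21,22).
_ECTOPIC_SITES = {
    "BIM1": 8,
    "BIM3": 22,
    "BIM4": 9,
    "BIM7": 9,
    "BIM10": 22,
    "BIM12": 8,
    "BIM14": 2,
    "BIM19": 15,
    "BIM20": 8,
}
_PLAIN_SINGLE = ["BIM5", "BIM8", "BIM9", "BIM11", "BIM13", "BIM16", "BIM17", "BIM18", "BIM22", "BIM23"]
_DELETION_BIMS = {"BIM15": [4], "BIM2": [4, 5, 6, 7, 8, 9, 10, 11]}


def build_worked_example(outdir: Optional[str | Path] = None, seed: int = 42) -> FixtureBundle:
    """Deterministically build the packaged Uy02/phage-128-like fixture.

    23 BIMs: 12 single-polar (BIM15 with a 1-spacer deletion, BIM2 with an
    8-spacer deletion), BIM21 with 2 and BIM6 with 3 polar acquisitions
    (duplicating the two leader-proximal ancestral spacers), and 9 ectopic
    BIMs at the five published internal sites. The five ancestral spacers
    upstream of the ectopic sites carry an adenine at 3′ position −2 (5/5)
    and a guanine at −1 (4/5; the fifth is compensated by the repeat's
    leading G). The ancestral leader ends ATTTGA; the companion reference
    leader ends ATTTGAG. All nucleotide sequences are synthetic stand-ins.

    When ``outdir`` is given, writes ancestor.fasta, bims.fasta,
    phage.fasta, phage.gb, leaders.fasta, truth.json and README.md there.
    """
    rng = np.random.default_rng(seed)
    repeat = DEFAULT_REPEAT
    core_leader = _random_seq(rng, 93, gc=0.30)
    uy02_leader = core_leader + "ATTTGA"
    reference_leader = core_leader + "ATTTGAG"

    ancestor = generate_ancestor(
        n_spacers=23,
        repeat=repeat,
        leader=uy02_leader,
        seed=_spawn_seed(rng),
        strain_id="Uy02_CR1",
    )
    # Upstream-unit 3' ends at the five ectopic sites: A at -2 everywhere,
    # G at -1 except the site whose trailer-anchored index is 9 (k=15),
    # which the repeat's leading G compensates.
    for k in sorted(set(_ECTOPIC_SITES.values())):
        sp = ancestor.spacers[k - 1]
        tail = "AT" if k == 15 else "AG"
        sp.seq = sp.seq[:-2] + tail
    assert len({s.seq for s in ancestor.spacers}) == 23, "spacer collision in fixture"

    genome, sites = generate_genome(
        length=34500,
        gc=0.39,
        n_protospacers=30,
        seed=_spawn_seed(rng),
        genome_id="phage128like",
    )
    # orf-style features so protospacer hits can be gene-labelled
    span = len(genome.seq) // 40
    genome.features = [
        FeatureSpan(label=f"orf{i + 1}", start=i * span, end=i * span + span - 60, strand="+")
        for i in range(40)
    ]

    anc = ancestor.spacer_seqs
    novel = iter(site.seq for site in sites)
    records: list[SequenceRecord] = []
    truth = CohortTruth(ancestor_id=ancestor.strain_id, n_ancestor=23)
    for b in range(1, 24):
        bim_id = f"BIM{b}"
        bt = BimTruth(bim_id=bim_id)
        if bim_id in _ECTOPIC_SITES:
            k = _ECTOPIC_SITES[bim_id]
            new = next(novel)
            spacers = anc[:k] + [new] + anc[k:]
            bt.acquisitions = [_acq(new, k + 1, k, "ectopic")]
        elif bim_id == "BIM21":
            new = next(novel)
            spacers = [anc[0], new] + anc
            bt.acquisitions = [_acq(anc[0], 1, 0, "polar", dup=1), _acq(new, 2, 0, "polar")]
        elif bim_id == "BIM6":
            new = next(novel)
            spacers = [anc[0], anc[1], new] + anc
            bt.acquisitions = [
                _acq(anc[0], 1, 0, "polar", dup=1),
                _acq(anc[1], 2, 0, "polar", dup=2),
                _acq(new, 3, 0, "polar"),
            ]
        else:  # single polar, possibly with a deletion block
            new = next(novel)
            dele = _DELETION_BIMS.get(bim_id, [])
            kept = [s for i, s in enumerate(anc) if (i + 1) not in set(dele)]
            spacers = [new] + kept
            bt.acquisitions = [_acq(new, 1, 0, "polar")]
            bt.deletions = list(dele)
        records.append(_bim_locus(ancestor, bim_id, spacers))
        truth.bims.append(bt)

    bundle = FixtureBundle(
        ancestor=ancestor,
        bim_records=records,
        genome=genome,
        sites=sites,
        truth=truth,
        uy02_leader=uy02_leader,
        reference_leader=reference_leader,
        repeat=repeat,
    )
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        anc_rec = SequenceRecord(
            id=ancestor.strain_id, seq=ancestor.reconstruct(), description="ancestral CR1 locus"
        )
        write_fasta([anc_rec], out / "ancestor.fasta")
        write_fasta(records, out / "bims.fasta")
        write_fasta([genome], out / "phage.fasta")
        write_genbank(genome, out / "phage.gb")
        write_fasta(
            [
                SequenceRecord(id="Uy02_leader", seq=uy02_leader),
                SequenceRecord(id="DGCC7710like_leader", seq=reference_leader),
            ],
            out / "leaders.fasta",
        )
        payload = truth.to_dict()
        payload["repeat"] = repeat
        payload["seed"] = seed
        payload["planted_sites"] = [
            {"index": s.index, "start": s.start, "end": s.end, "seq": s.seq, "pam": s.pam}
            for s in sites
        ]
        (out / "truth.json").write_text(json.dumps(payload, indent=2) + "\n")
        (out / "README.md").write_text(_FIXTURE_README)
        bundle.paths = {
            name: out / name
            for name in (
                "ancestor.fasta",
                "bims.fasta",
                "phage.fasta",
                "phage.gb",
                "leaders.fasta",
                "truth.json",
                "README.md",
            )
        }
    return bundle


_FIXTURE_README = """\
# Worked-example fixture (synthetic)

Deterministic synthetic stand-in for a phage-challenge cohort of a
23-spacer CRISPR1 strain. Cohort *structure* follows the published
counts — 23 BIMs, 14 polar-only (12 single; two with deletion blocks of
1 and 8 spacers; BIM21/BIM6 with 2/3 acquisitions duplicating the two
newest ancestral spacers), 9 ectopic BIMs at 5 distinct internal sites,
upstream units with A at -2 (5/5) and G at -1 (4/5, fifth compensated by
the repeat's leading G), ancestral leader ending ATTTGA vs reference
leader ATTTGAG. All nucleotide sequences (spacers, repeat, leader core,
phage genome) are generated, NOT the deposited ones; deletion-block
positions and the plain single-polar BIM ids are invented. The phage
genome carries every novel acquired spacer as a perfect protospacer next
to an NNAGAAW-conforming PAM.

Files: ancestor.fasta, bims.fasta (23 BIM loci), phage.fasta, phage.gb
(orf-style features), leaders.fasta (ancestral + reference leader),
truth.json (planted events, repeat, planted protospacer sites).
"""


def cohort_summary_counter(summary: CohortSummary) -> Counter:
    """Convenience: ectopic site multiset of a summary (trailer numbering)."""
    return Counter(summary.ectopic_positions)
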