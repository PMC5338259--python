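"""End-to-end analysis flow: parse → diff → classify → map → PAM → contexts.

:func:`run_pipeline` wires the modules into the full phage-challenge
analysis: parse the ancestral and BIM loci into arrays, diff every BIM
against the ancestor and classify acquisitions, map novel acquired
spacers onto the phage genome with PAM extraction and consensus, and
extract the upstream sequence contexts of ectopic insertions. Outputs are
written as TSV/JSON plus a human-readable summary; a manifest records the
outputs and a config hash. Any stage error aborts the run, removes
partial outputs, and names the stage and offending record.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import diff as diffmod
from . import leader as leadermod
from . import protospacer as pmod
from .arrays import RepeatSpacerArray, parse_array
from .seqio import SequenceRecord, read_fasta, read_genbank

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


@dataclass
class RunConfig:
    """Tunables of the analysis flow; serializes to YAML and round-trips."""

    repeat: str = ""
    locus_id: str = "CR1"
    max_repeat_mismatch: int = 2
    spacer_len_range: tuple[int, int] = (20, 45)
    spacer_match_mismatch: int = 0  # token equality for ancestor/BIM diffing
    protospacer_max_mismatch: int = 3
    pam_consensus: str = "NNAGAAW"
    pam_len: int = 7
    pam_side: str = "3prime"  # documented: PAM window is 3' of the protospacer
    numbering: str = "trailer"  # spacer numbering in reports: trailer | leader
    context_window: int = 7
    seed: int = 0
    outdir: str = "crisprbim_out"

    def __post_init__(self) -> None:
        for name in ("max_repeat_mismatch", "spacer_match_mismatch", "protospacer_max_mismatch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.spacer_len_range = tuple(self.spacer_len_range)  # type: ignore[assignment]

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["spacer_len_range"] = list(self.spacer_len_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, record: str, message: str):
        self.stage = stage
        self.record = record
        super().__init__(f"[stage={stage}, record={record}] {message}")



def _stage(stage: str, record: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, record, str(exc)) from exc


def run_pipeline(
    config: RunConfig,
    ancestor_fasta: str | Path,
    bims_fasta: str | Path,
    phage_path: Optional[str | Path] = None,
) -> dict:
    """Run the full analysis; returns the summary dict written to disk.

    ``phage_path`` may be FASTA or GenBank (extension .gb/.gbk/.genbank);
    omit it to skip protospacer mapping. The repeat must be set in the
    config. Outputs under ``config.outdir``: arrays.tsv, diffs.json,
    cohort_summary.tsv, protospacer_hits.tsv, pam_profile.json,
    las_contexts.tsv, summary.txt, manifest.json.
    """
    if not config.repeat:
        raise PipelineError("config", "-", "no repeat sequence configured")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        written.append(path)

    try:
        anc_records = _stage("read", str(ancestor_fasta), read_fasta, ancestor_fasta)
        bim_records = _stage("read", str(bims_fasta), read_fasta, bims_fasta)

        def parse(rec: SequenceRecord) -> RepeatSpacerArray:
            return _stage(
                "parse",
                rec.id,
                parse_array,
                rec,
                config.repeat,
                max_repeat_mismatch=config.max_repeat_mismatch,
                spacer_len_range=config.spacer_len_range,
                locus_id=config.locus_id,
            )

        ancestor = parse(anc_records[0])
        bim_arrays = [parse(r) for r in bim_records]
        n_anc = len(ancestor)

        rows = []
        for arr in [ancestor] + bim_arrays:
            for sp in arr.spacers:
                rows.append(
                    {
                        "strain_id": arr.strain_id,
                        "locus_id": arr.locus_id,
                        "leader_index": sp.leader_index,
                        "trailer_index": sp.trailer_index,
                        "spacer_seq": sp.seq,
                    }
                )
        arrays_df = pd.DataFrame(rows)
        emit("arrays.tsv", lambda p: arrays_df.to_csv(p, sep="\t", index=False))

        diffs = [
            _stage("diff", arr.strain_id, diffmod.diff_arrays, ancestor, arr,
                   config.spacer_match_mismatch)
            for arr in bim_arrays
        ]
        emit(
            "diffs.json",
            lambda p: p.write_text(json.dumps([d.to_dict() for d in diffs], indent=2) + "\n"),
        )

        summary = _stage("summarize", "-", diffmod.summarize_cohort, diffs)
        sdict = summary.to_dict()
        srows = [
            {
                "bim_id": d.bim_id,
                "label": d.label or "none",
                "n_acquisitions": len(d.acquisitions),
                "n_deletions": len(d.deletions),
                "n_duplications": sum(1 for a in d.acquisitions if a.duplicate_of),
                "ectopic_sites": ";".join(
                    f"{d.n_ancestor - a.insertion_after_leader_index},"
                    f"{d.n_ancestor + 1 - a.insertion_after_leader_index}"
                    for a in d.acquisitions
                    if a.klass == "ectopic"
                ),
            }
            for d in diffs
        ]
        emit(
            "cohort_summary.tsv",
            lambda p: pd.DataFrame(srows).to_csv(p, sep="\t", index=False),
        )

        # --- protospacer mapping of novel (non-duplicate) acquisitions ---
        hits_rows: list[dict] = []
        pam_profile = None
        genome: Optional[SequenceRecord] = None
        if phage_path is not None:
            suffix = Path(phage_path).suffix.lower()
            if suffix in (".gb", ".gbk", ".genbank"):
                genome = _stage("read", str(phage_path), read_genbank, phage_path)
            else:
                genome = _stage("read", str(phage_path), read_fasta, phage_path)[0]
            best_hits: list[pmod.ProtospacerHit] = []
            for d in diffs:
                for a in d.acquisitions:
                    if a.duplicate_of is not None:
                        continue
                    sp_id = f"{d.bim_id}_acq{a.bim_leader_index}"
                    hits = _stage(
                        "map", sp_id, pmod.find_protospacers, a.spacer_seq, genome,
                        config.protospacer_max_mismatch, sp_id,
                    )
                    for h in hits:
                        pmod.extract_pam(h, genome, pam_len=config.pam_len)
                        h.pam_ok = (not h.pam_truncated) and pmod.match_pam(
                            h.pam_seq, config.pam_consensus
                        )
                        pmod.annotate_hit(h, genome.features)
                        hits_rows.append(
                            {
                                "spacer_id": h.spacer_id,
                                "genome_id": h.genome_id,
                                "start1": h.start + 1,
                                "end1": h.end,
                                "strand": h.strand,
                                "mismatches": h.mismatches,
                                "matched_nt": h.matched_nt,
                                "pam": h.pam_seq,
                                "pam_ok": h.pam_ok,
                                "gene": h.gene_label,
                            }
                        )
                    if hits:
                        best_hits.append(hits[0])
            emit(
                "protospacer_hits.tsv",
                lambda p: pd.DataFrame(hits_rows).to_csv(p, sep="\t", index=False),
            )
            perfect = [h for h in best_hits if h.mismatches == 0 and not h.pam_truncated]
            if len(perfect) >= 2:
                pam_profile = _stage("pam", "-", pmod.pam_consensus, perfect)
                emit(
                    "pam_profile.json",
                    lambda p: p.write_text(json.dumps(pam_profile.to_dict(), indent=2) + "\n"),
                )

        # --- LAS contexts of ectopic acquisitions ---
        contexts: list[leadermod.InsertionContext] = []
        for arr, d in zip(bim_arrays, diffs):
            for a in d.acquisitions:
                if a.klass == "ectopic":
                    contexts.append(
                        _stage(
                            "las", d.bim_id, leadermod.upstream_context,
                            arr, d, a, config.context_window,
                        )
                    )
        ctx_rows = [
            {
                "bim_id": c.bim_id,
                "upstream_unit": c.upstream_unit,
                "context_seq": c.context_seq,
                "first_repeat_base": c.first_repeat_base,
            }
            for c in contexts
        ]
        emit(
            "las_contexts.tsv",
            lambda p: pd.DataFrame(ctx_rows).to_csv(p, sep="\t", index=False),
        )
        profile = None
        if contexts:
            # profile over distinct upstream units, as in the published
            # per-site analysis (repeated sites contribute once)
            by_unit = {}
            for c in contexts:
                by_unit.setdefault(c.upstream_unit, c)
            profile = leadermod.positional_profile(list(by_unit.values()))
            emit(
                "las_profile.json",
                lambda p: p.write_text(json.dumps(profile.to_dict(), indent=2) + "\n"),
            )

        # --- human-readable summary ---
        lines = [
            f"cohort of {sdict['n_bims']} BIMs vs ancestor {ancestor.strain_id} "
            f"({n_anc} spacers)",
            f"  with >=1 new spacer : {sdict['n_with_acquisition']}",
            f"  polar-only (5'-end) : {sdict['n_polar_only']}",
            f"  ectopic (in-array)  : {sdict['n_ectopic']} at "
            f"{len(sdict['ectopic_positions'])} distinct positions",
            f"  single polar        : {sdict['n_single_polar']}",
        ]
        for pos, cnt in sorted(sdict["ectopic_positions"].items()):
            lines.append(f"    between spacers {pos} : {cnt} BIM(s)")
        dels = {b: c for b, c in sdict["deletion_counts"].items() if c}
        if dels:
            lines.append("  deletions: " + ", ".join(f"{b}:{c}" for b, c in sorted(dels.items())))
        if sdict["duplication_events"]:
            lines.append(
                "  duplications: "
                + ", ".join(f"{b} dup #{p}" for b, _, p in sdict["duplication_events"])
            )
        if pam_profile is not None:
            lines.append(
                f"  PAM consensus over {pam_profile.n_pams} perfect hits: "
                f"{pam_profile.consensus}"
            )
        if profile is not None:
            lines.append(
                f"  ectopic upstream contexts (n={profile.n_contexts} distinct units): "
                f"A at -2 = {profile.fraction(-2, 'A'):.2f}, "
                f"G at -1 = {profile.fraction(-1, 'G'):.2f}, "
                f"G at -1 or repeat-G = {profile.compensated_g_fraction:.2f}"
            )
        text = "\n".join(lines) + "\n"
        emit("summary.txt", lambda p: p.write_text(text))

        result = {
            "summary": sdict,
            "n_ancestor_spacers": n_anc,
            "n_hits": len(hits_rows),
            "pam_consensus_observed": pam_profile.consensus if pam_profile else None,
            "las_profile": profile.to_dict() if profile else None,
            "config_digest": config.digest(),
            "outputs": [str(p) for p in written],
        }
        emit("manifest.json", lambda p: p.write_text(json.dumps(result, indent=2) + "\n"))
        return result
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
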