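"""End-to-end orchestration: transcripts + MS observations → toxin catalogue.

Stages: read transcripts → six-frame translation and ORF extraction →
precursor segmentation → cysteine-framework classification → intact-mass
matching (acid and amide oxidized forms) against the MALDI lists →
MS/MS fragment search and mature-peptide coverage → rational naming →
summary tables. Deterministic given inputs and configuration; every
threshold used is recorded in the run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .framework import (
    Classification,
    CysteineFramework,
    SuperfamilyDefinition,
    classify_superfamily,
    extract_framework,
    load_superfamily_definitions,
)
from .mapping import (
    FragmentMatch,
    MsmsFragment,
    ScoringScheme,
    compute_coverage,
    read_fragment_tsv,
    search_fragments,
)
from .mass import (
    MassMatch,
    ObservedMass,
    detect_amidation_pairs,
    match_masses,
    oxidized_mods,
    read_mass_csv,
)
from .naming import ToxinName, assign_name
from .precursor import Precursor, SignalConfig, segment_precursor
from .translate import Transcript, read_transcript_fasta, transcript_orfs


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending record."""

    def __init__(self, stage: str, record: str, message: str):
        super().__init__(f"[{stage}] {record}: {message}")
        self.stage = stage
        self.record = record


@dataclass
class PipelineConfig:
    """Paths and thresholds of one pipeline run."""

    transcripts: Optional[str] = None
    maldi: Optional[str] = None
    fragments: Optional[str] = None
    superfamilies: Optional[str] = None  # None -> packaged scheme
    min_orf_len: int = 40
    min_cysteines: int = 4
    mass_tol: float = 0.5  # Da, intact MALDI MS1 matching
    pair_tol: float = 0.05  # Da, amide/acid pair detection
    fragment_min_score: float = 25.0
    family: str = "theraphotoxin"
    genus: str = "Pamphobeteus"
    species: str = "verdolaga"

    def threshold_dict(self) -> dict:
        d = asdict(self)
        for key in ("transcripts", "maldi", "fragments", "superfamilies"):
            d.pop(key, None)
        return d


@dataclass
class ToxinRecord:
    name: ToxinName
    precursor: Precursor
    framework: CysteineFramework
    classification: Classification
    abundance: Optional[float] = None
    mass_evidence: list[MassMatch] = field(default_factory=list)
    fragment_evidence: list[FragmentMatch] = field(default_factory=list)
    coverage: float = 0.0
    amide_and_acid_observed: bool = False

    @property
    def superfamily(self) -> str:
        return self.classification.superfamily


@dataclass
class SuperfamilySummaryRow:
    superfamily: str
    canonical: str
    n_cys: int
    min_length: int
    max_length: int
    members: int


@dataclass
class ToxinCatalogue:
    records: list[ToxinRecord]
    summary: list[SuperfamilySummaryRow]
    amidation_pairs: int = 0
    config: Optional[PipelineConfig] = None


def completeness_percent(complete: int, total: int) -> float:
    """Ortholog-completeness percentage, rounded to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= complete <= total:
        raise ValueError("complete must lie in [0, total]")
    return round(100.0 * complete / total, 1)


def _novel_key(canonical: str, novel_order: dict[str, str]) -> str:
    if canonical not in novel_order:
        novel_order[canonical] = f"novel-{len(novel_order) + 1}"
    return novel_order[canonical]


def summarize_superfamilies(
    records: Sequence[ToxinRecord] | ToxinCatalogue,
    defs: Optional[Sequence[SuperfamilyDefinition]] = None,
) -> list[SuperfamilySummaryRow]:
    """One row per observed superfamily: pattern, n_cys, length span, count.

    Sorted by definition order (SF1..SFn) with novel patterns appended
    as novel-1, novel-2, ... in first-observation order.
    """
    if isinstance(records, ToxinCatalogue):
        records = records.records
    defs = defs if defs is not None else load_superfamily_definitions()
    def_order = {d.name: i for i, d in enumerate(defs)}
    groups: dict[str, list[ToxinRecord]] = {}
    novel_order: dict[str, str] = {}
    for rec in records:
        name = rec.superfamily
        if name == "novel":
            name = _novel_key(rec.framework.canonical, novel_order)
        groups.setdefault(name, []).append(rec)

    def sort_key(name: str):
        if name in def_order:
            return (0, def_order[name])
        return (1, int(name.split("-")[1]))

    rows = []
    for name in sorted(groups, key=sort_key):
        members = groups[name]
        lengths = [len(r.precursor.mature) for r in members]
        rows.append(
            SuperfamilySummaryRow(
                superfamily=name,
                canonical=members[0].framework.canonical,
                n_cys=members[0].framework.n_cys,
                min_length=min(lengths),
                max_length=max(lengths),
                members=len(members),
            )
        )
    return rows


def build_catalogue(
    transcripts: Sequence[Transcript],
    observed: Sequence[ObservedMass] = (),
    fragments: Sequence[MsmsFragment] = (),
    defs: Optional[Sequence[SuperfamilyDefinition]] = None,
    cfg: Optional[PipelineConfig] = None,
    signal_cfg: Optional[SignalConfig] = None,
) -> ToxinCatalogue:
    """The in-memory pipeline: everything after file reading."""
    cfg = cfg or PipelineConfig()
    defs = list(defs) if defs is not None else load_superfamily_definitions()

    # 1-2. translation + segmentation: every ORF of a transcript is
    # segmented; the toxin candidate is the secreted (signal-bearing),
    # most cysteine-rich one. Spurious long ORFs in other frames rarely
    # carry a plausible signal peptide, so this beats longest-ORF picking.
    candidates: list[tuple[Precursor, Optional[float]]] = []
    for t in transcripts:
        try:
            orfs = transcript_orfs(t, min_len=cfg.min_orf_len)
        except ValueError as exc:
            raise PipelineError("translate", t.id, str(exc)) from exc
        best: Optional[tuple[tuple[int, int], Precursor]] = None
        for orf in orfs:
            p = segment_precursor(orf, orf_ref=t.id, signal_cfg=signal_cfg)
            if "no_signal" in p.flags:
                continue
            n_cys = p.mature.count("C")
            if n_cys < cfg.min_cysteines:
                continue
            key = (n_cys, len(p.protein))
            if best is None or key > best[0]:
                best = (key, p)
        if best is not None:
            candidates.append((best[1], t.abundance))

    # 3. classification
    records: list[ToxinRecord] = []
    for p, tpm in candidates:
        fw = extract_framework(p.mature, peptide_ref=p.orf_ref)
        records.append(
            ToxinRecord(
                name=None,  # assigned below
                precursor=p,
                framework=fw,
                classification=classify_superfamily(fw, defs),
                abundance=tpm,
            )
        )

    # 4. intact-mass evidence: oxidized acid and amide forms
    if observed:
        mass_candidates = [
            (
                r.precursor.orf_ref,
                r.precursor.mature,
                [
                    oxidized_mods(r.precursor.mature),
                    oxidized_mods(r.precursor.mature, amide=True),
                ],
            )
            for r in records
        ]
        all_matches = match_masses(mass_candidates, list(observed), tol=cfg.mass_tol)
        by_ref: dict[str, list[MassMatch]] = {}
        for m in all_matches:
            by_ref.setdefault(m.peptide_ref, []).append(m)
        for r in records:
            r.mass_evidence = by_ref.get(r.precursor.orf_ref, [])
            forms = {m.mod_set.c_terminal_amide for m in r.mass_evidence}
            r.amide_and_acid_observed = forms == {True, False}
    n_pairs = len(detect_amidation_pairs(list(observed), cfg.pair_tol)) if observed else 0

    # 5. fragment evidence + coverage
    if fragments and records:
        hits = search_fragments(
            list(fragments),
            [r.precursor for r in records],
            min_score=cfg.fragment_min_score,
        )
        by_target: dict[str, list[FragmentMatch]] = {}
        for matches in hits.values():
            if matches:
                top = matches[0]  # best target per fragment
                by_target.setdefault(top.target_ref, []).append(top)
        for r in records:
            r.fragment_evidence = by_target.get(r.precursor.orf_ref, [])
            r.coverage = compute_coverage(
                r.fragment_evidence, len(r.precursor.mature)
            )

    # 6. naming: by decreasing abundance, paralog per superfamily,
    #    isoform letters distinguish members within a paralog group
    records.sort(key=lambda r: (-(r.abundance or 0.0), r.precursor.orf_ref))
    sf_counter: dict[str, int] = {}
    u_index = 0
    used_names: set[str] = set()
    for r in records:
        u_index += 1
        sf_counter[r.superfamily] = sf_counter.get(r.superfamily, 0) + 1
        paralog = sf_counter[r.superfamily]
        isoform = "a"
        while True:
            name = assign_name(
                "unknown",
                cfg.family,
                cfg.genus,
                cfg.species,
                paralog=paralog,
                isoform=isoform,
                variant=1,
                u_index=u_index,
            )
            if name.render() not in used_names:
                break
            isoform = chr(ord(isoform) + 1)
        used_names.add(name.render())
        r.name = name

    summary = summarize_superfamilies(records, defs)
    return ToxinCatalogue(
        records=records, summary=summary, amidation_pairs=n_pairs, config=cfg
    )


def catalogue_frame(catalogue: ToxinCatalogue) -> pd.DataFrame:
    rows = []
    for r in catalogue.records:
        rows.append(
            {
                "name": r.name.render(),
                "transcript_id": r.precursor.orf_ref,
                "superfamily": r.superfamily,
                "canonical": r.framework.canonical,
                "n_cys": r.framework.n_cys,
                "signal": r.precursor.signal,
                "propeptide": r.precursor.propeptide,
                "mature": r.precursor.mature,
                "mature_length": len(r.precursor.mature),
                "tpm": r.abundance,
                "n_mass_matches": len(r.mass_evidence),
                "amide_and_acid": r.amide_and_acid_observed,
                "n_fragment_matches": len(r.fragment_evidence),
                "coverage_percent": round(r.coverage, 1),
                "flags": ";".join(r.precursor.flags) or "-",
            }
        )
    return pd.DataFrame(rows)


def summary_frame(catalogue: ToxinCatalogue) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "superfamily": s.superfamily,
                "canonical": s.canonical,
                "n_cys": s.n_cys,
                "mature_length": f"{s.min_length}-{s.max_length}"
                if s.min_length != s.max_length
                else str(s.min_length),
                "members": s.members,
            }
            for s in catalogue.summary
        ]
    )


def _sha256(path: Optional[str]) -> Optional[str]:
    if path is None:
        return None
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig, outdir=None) -> ToxinCatalogue:
    """File-based pipeline run; optionally persists all stage outputs.

    Writes catalogue.tsv, superfamilies.tsv, matches.tsv, catalogue.fasta
    (mature peptides) and manifest.json under ``outdir`` when given.
    Reruns on identical inputs produce byte-identical outputs.
    """
    if cfg.transcripts is None:
        raise PipelineError("input", "config", "transcripts path is required")
    transcripts = read_transcript_fasta(cfg.transcripts)
    observed = read_mass_csv(cfg.maldi) if cfg.maldi else []
    fragments = read_fragment_tsv(cfg.fragments) if cfg.fragments else []
    defs = load_superfamily_definitions(cfg.superfamilies)
    catalogue = build_catalogue(transcripts, observed, fragments, defs, cfg)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        catalogue_frame(catalogue).to_csv(
            outdir / "catalogue.tsv", sep="\t", index=False
        )
        summary_frame(catalogue).to_csv(
            outdir / "superfamilies.tsv", sep="\t", index=False
        )
        match_rows = [
            {
                "fragment_id": m.fragment_ref,
                "target": m.target_ref,
                "start": m.target_span[0],
                "end": m.target_span[1],
                "identity_percent": round(m.percent_identity, 1),
                "score": m.score,
                "region": m.region or "-",
            }
            for r in catalogue.records
            for m in r.fragment_evidence
        ]
        pd.DataFrame(
            match_rows,
            columns=[
                "fragment_id", "target", "start", "end",
                "identity_percent", "score", "region",
            ],
        ).to_csv(outdir / "matches.tsv", sep="\t", index=False)
        with open(outdir / "catalogue.fasta", "w") as fh:
            for r in catalogue.records:
                fh.write(f">{r.name.render()} {r.precursor.orf_ref}\n")
                fh.write(r.precursor.mature + "\n")
        manifest = {
            "version": __version__,
            "config": cfg.threshold_dict(),
            "inputs": {
                "transcripts": _sha256(cfg.transcripts),
                "maldi": _sha256(cfg.maldi),
                "fragments": _sha256(cfg.fragments),
            },
            "n_transcripts": len(transcripts),
            "n_records": len(catalogue.records),
            "amidation_pairs": catalogue.amidation_pairs,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return catalogue
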