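"""Synthetic venom-gland transcriptomes and MS observations.

The generator plants ground truth for every pipeline stage: toxin genes
are built backwards from a chosen superfamily (mature peptide realizing
the canonical cysteine pattern within the superfamily's length range,
propeptide ending in a processing quadruplet ...E-x-x-R, hydrophobic
signal peptide obeying the (-3,-1) rule), reverse-translated with random
synonymous codons, wrapped in UTRs and given lognormal expression.
Intact-mass (MALDI-style) lists carry the fully oxidized acid form of
each mature peptide plus, for a configurable fraction of genes, the
C-terminally amidated form ~1 Da below it. Tryptic fragment lists mimic
in-gel digestion: cleavage after K/R except before P, up to a configured
number of missed cleavages, cysteines carbamidomethylated.

Everything is driven by one integer seed; identical seeds give
byte-identical outputs.

The defaults emulate the study conditions of a single tarantula
venom-gland library: 26 cysteine-rich toxin genes spread over the eight
superfamilies in their observed proportions, plus 10% decoy
housekeeping-like transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .framework import SuperfamilyDefinition, load_superfamily_definitions
from .mapping import MsmsFragment, write_fragment_tsv
from .mass import ObservedMass, mz, oxidized_mods, peptide_mass, ModificationSet, write_mass_csv
from .translate import Transcript

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in _TABLE.forward_table.items():
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
for _codons in _AA_TO_CODONS.values():
    _codons.sort()
_STOP_CODONS = sorted(_TABLE.stop_codons)

#: Observed superfamily membership used for the default gene mix.
DEFAULT_SF_COUNTS = {
    "SF1": 1, "SF2": 1, "SF3": 2, "SF4": 4,
    "SF5": 2, "SF6": 6, "SF7": 2, "SF8": 8,
}

_HYDROPHOBIC = "LVIF"  # deliberately excludes A (small residue)
_SPACER = "WNY"  # non-small, non-hydrophobic-core
_SMALL = "AGST"
_ACIDIC = "DENQ"
_NON_CYS = "ADEFGHIKLMNPQRSTVWY"
_NON_CYS_NON_ARG = _NON_CYS.replace("R", "")
_POLAR_NTERM = "DENQKRSTH"


@dataclass
class GeneratorConfig:
    n_toxin_genes: int = 26
    superfamily_mix: Optional[dict[str, float]] = None  # None -> observed mix
    amidation_fraction: float = 0.5
    mass_noise_sd: float = 0.0
    missed_cleavages: int = 2
    utr_len_range: tuple[int, int] = (30, 150)
    seed: int = 0
    expression_meanlog: float = 3.0
    expression_sdlog: float = 1.5
    decoy_fraction: float = 0.1
    n_fractions: int = 5
    min_fragment_len: int = 6

    def __post_init__(self) -> None:
        if self.superfamily_mix is not None:
            total = sum(self.superfamily_mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("superfamily mix proportions must sum to 1")
        if self.amidation_fraction < 0 or self.amidation_fraction > 1:
            raise ValueError("amidation_fraction must be in [0, 1]")
        if self.mass_noise_sd < 0:
            raise ValueError("mass_noise_sd must be >= 0")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")


@dataclass
class GeneTruth:
    transcript_id: str
    superfamily: str
    signal: str
    propeptide: str
    mature: str
    mass_acid: float
    mass_amide: float
    amidated: bool = False
    fraction: Optional[str] = None
    tpm: Optional[float] = None

    @property
    def protein(self) -> str:
        return self.signal + self.propeptide + self.mature


@dataclass
class FragmentTruth:
    fragment_id: str
    gene_id: str
    start: int  # span within the mature peptide
    end: int


@dataclass
class SyntheticTruth:
    genes: list[GeneTruth] = field(default_factory=list)
    fragments: list[FragmentTruth] = field(default_factory=list)

    def gene(self, transcript_id: str) -> GeneTruth:
        for g in self.genes:
            if g.transcript_id == transcript_id:
                return g
        raise KeyError(transcript_id)


@dataclass
class SyntheticBundle:
    transcripts: list[Transcript]
    truth: SyntheticTruth
    observed: list[ObservedMass]
    fragments: list[MsmsFragment]
    config: GeneratorConfig


def _draw(rng, letters: str, k: int) -> str:
    return "".join(letters[i] for i in rng.integers(0, len(letters), size=k))


def _make_signal(rng) -> str:
    """Hydrophobic-core signal peptide with a unique (-3,-1) site at its end."""
    hyd = _draw(rng, _HYDROPHOBIC, int(rng.integers(7, 10)))
    spacer = _draw(rng, _SPACER, int(rng.integers(2, 4)))
    c_region = (
        _SMALL[rng.integers(0, len(_SMALL))]
        + _SPACER[rng.integers(0, len(_SPACER))]
        + "A"
    )
    return "M" + "K" + hyd + spacer + c_region


def _make_propeptide(rng) -> str:
    body = _draw(rng, _ACIDIC, int(rng.integers(6, 13)))
    return body + "E" + _draw(rng, "DNQ", 2) + "R"


def _make_mature(sf: SuperfamilyDefinition, rng) -> str:
    """Realize the canonical cysteine pattern within the length range."""
    runs = [len(part) for part in sf.canonical.split("-")]
    n_interior = len(runs) - 1
    min_len = sf.n_cys + n_interior
    lo, hi = sf.length_range if sf.length_range else (min_len + 10, min_len + 40)
    if hi < min_len:
        raise ValueError(
            f"{sf.name}: length range up to {hi} cannot realize "
            f"{sf.canonical!r} (needs >= {min_len})"
        )
    lo = max(lo, min_len)
    length = int(rng.integers(lo, hi + 1))
    extra = length - sf.n_cys - n_interior
    # distribute surplus residues over leading / interior / trailing gaps
    slots = n_interior + 2
    add = rng.multinomial(extra, [1.0 / slots] * slots)
    gaps = [int(add[0])] + [1 + int(a) for a in add[1:-1]] + [int(add[-1])]
    out: list[str] = []
    first_cys_seen = False
    for run, gap in zip(runs + [0], gaps):
        pool = _NON_CYS if first_cys_seen else _NON_CYS_NON_ARG
        out.append(_draw(rng, pool, gap))
        out.append("C" * run)
        if run:
            first_cys_seen = True
    mature = "".join(out)
    assert len(mature) == length
    return mature


def _encode(rng, protein: str, utr_len_range: tuple[int, int]) -> str:
    codons = [
        _AA_TO_CODONS[aa][rng.integers(0, len(_AA_TO_CODONS[aa]))]
        for aa in protein
    ]
    stop = _STOP_CODONS[rng.integers(0, len(_STOP_CODONS))]
    lo, hi = utr_len_range
    utr5 = _draw(rng, "ACGT", int(rng.integers(lo, hi + 1)))
    utr3 = _draw(rng, "ACGT", int(rng.integers(lo, hi + 1)))
    # in-frame stop at the 5'UTR boundary so the planted ORF starts at its ATG
    utr5 = (utr5 + "TAA") if len(utr5) else "TAA"
    return utr5 + "".join(codons) + stop + utr3


def generate_precursor_gene(
    sf: SuperfamilyDefinition,
    rng: np.random.Generator,
    gene_id: str = "tox1",
    utr_len_range: tuple[int, int] = (30, 150),
) -> tuple[Transcript, GeneTruth]:
    """One planted toxin gene for a superfamily.

    The protein is signal + propeptide (ending in the processing
    quadruplet) + mature realizing the superfamily's canonical cysteine
    pattern; the transcript adds synonymous-codon CDS and random UTRs.
    """
    signal = _make_signal(rng)
    propeptide = _make_propeptide(rng)
    mature = _make_mature(sf, rng)
    protein = signal + propeptide + mature
    sequence = _encode(rng, protein, utr_len_range)
    truth = GeneTruth(
        transcript_id=gene_id,
        superfamily=sf.name,
        signal=signal,
        propeptide=propeptide,
        mature=mature,
        mass_acid=peptide_mass(mature, oxidized_mods(mature)),
        mass_amide=peptide_mass(mature, oxidized_mods(mature, amide=True)),
    )
    return Transcript(id=gene_id, sequence=sequence), truth


def _make_decoy(rng, gene_id: str, utr_len_range) -> Transcript:
    """Housekeeping-like ORF without a signal peptide (polar N terminus)."""
    length = int(rng.integers(80, 201))
    protein = "M" + _draw(rng, _POLAR_NTERM, 19) + _draw(
        rng, _NON_CYS, length - 20
    )
    return Transcript(id=gene_id, sequence=_encode(rng, protein, utr_len_range))


def _allocate_counts(mix: dict[str, float], n: int) -> dict[str, int]:
    """Deterministic largest-remainder allocation of n genes to superfamilies."""
    names = sorted(mix)
    raw = {name: n * mix[name] for name in names}
    counts = {name: int(raw[name]) for name in names}
    short = n - sum(counts.values())
    by_remainder = sorted(names, key=lambda m: (-(raw[m] - counts[m]), m))
    for name in by_remainder[:short]:
        counts[name] += 1
    return counts


def generate_transcriptome(
    cfg: GeneratorConfig,
    defs: Optional[list[SuperfamilyDefinition]] = None,
) -> tuple[list[Transcript], SyntheticTruth]:
    """Toxin + decoy transcripts with TPM abundances and planted truth.

    TPM follows the standard definition from simulated lognormal counts:
    TPM_i = 1e6 * (c_i / l_i) / sum_j (c_j / l_j), so the column sums to
    one million.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    defs = defs or load_superfamily_definitions()
    by_name = {d.name: d for d in defs}
    if cfg.superfamily_mix is None:
        total = sum(DEFAULT_SF_COUNTS.values())
        mix = {k: v / total for k, v in DEFAULT_SF_COUNTS.items()}
    else:
        mix = cfg.superfamily_mix
    unknown = set(mix) - set(by_name)
    if unknown:
        raise ValueError(f"superfamily mix names unknown superfamilies {sorted(unknown)}")

    counts = _allocate_counts(mix, cfg.n_toxin_genes)
    truth = SyntheticTruth()
    transcripts: list[Transcript] = []
    i = 0
    for name in sorted(counts):
        for _ in range(counts[name]):
            i += 1
            t, g = generate_precursor_gene(
                by_name[name], rng, gene_id=f"tox{i:04d}",
                utr_len_range=cfg.utr_len_range,
            )
            transcripts.append(t)
            truth.genes.append(g)
    n_decoys = round(cfg.decoy_fraction * cfg.n_toxin_genes)
    for d in range(1, n_decoys + 1):
        transcripts.append(_make_decoy(rng, f"dec{d:04d}", cfg.utr_len_range))

    if transcripts:
        counts_sim = rng.lognormal(
            cfg.expression_meanlog, cfg.expression_sdlog, size=len(transcripts)
        )
        lengths = np.array([len(t.sequence) for t in transcripts], dtype=float)
        rate = counts_sim / lengths
        tpms = 1e6 * rate / rate.sum()
        for t, tpm in zip(transcripts, tpms):
            t.abundance = float(tpm)
        for g in truth.genes:
            g.tpm = next(
                t.abundance for t in transcripts if t.id == g.transcript_id
            )
    return transcripts, truth


def simulate_maldi(
    truth: SyntheticTruth, cfg: GeneratorConfig
) -> list[ObservedMass]:
    """Per-fraction intact neutral-mass lists for the planted matures.

    Every mature contributes its fully oxidized acid mass; an
    ``amidation_fraction`` of genes also contributes the amidated form
    (0.98402 Da lighter). Gaussian noise with sd ``mass_noise_sd`` is
    added independently to each observation. Updates ``truth`` in place
    with each gene's fraction and amidation status.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    observed: list[ObservedMass] = []
    for g in truth.genes:
        fraction = f"F{int(rng.integers(1, cfg.n_fractions + 1))}"
        g.fraction = fraction
        g.amidated = bool(rng.random() < cfg.amidation_fraction)
        masses = [g.mass_acid] + ([g.mass_amide] if g.amidated else [])
        for m in masses:
            noisy = m + (rng.normal(0.0, cfg.mass_noise_sd) if cfg.mass_noise_sd else 0.0)
            observed.append(ObservedMass(fraction_id=fraction, neutral_mass=noisy))
    return observed


def tryptic_peptides(
    seq: str, missed_cleavages: int = 2, min_len: int = 1
) -> list[tuple[int, int]]:
    """Spans of tryptic peptides: cleave after K/R except before P."""
    sites = [0]
    for i, aa in enumerate(seq):
        if aa in "KR" and (i + 1 == len(seq) or seq[i + 1] != "P"):
            sites.append(i + 1)
    if sites[-1] != len(seq):
        sites.append(len(seq))
    spans = []
    for a in range(len(sites) - 1):
        for b in range(a + 1, min(a + 2 + missed_cleavages, len(sites))):
            s, e = sites[a], sites[b]
            if e - s >= min_len:
                spans.append((s, e))
    return spans


def simulate_tryptic_fragments(
    truth: SyntheticTruth, cfg: GeneratorConfig
) -> list[MsmsFragment]:
    """In-silico tryptic fragments of the planted mature peptides.

    Cysteines are carbamidomethylated for the m/z computation (reduced
    and alkylated sample prep); charge is 1 plus the count of basic
    residues, capped at 4. Flanking residues are recorded in
    dot-notation; '-' marks a peptide terminus. Fragment spans are
    appended to ``truth.fragments``.
    """
    rng = np.random.default_rng([cfg.seed, 2])  # reserved for future subsampling
    del rng
    fragments: list[MsmsFragment] = []
    for g in truth.genes:
        mature = g.mature
        for k, (s, e) in enumerate(
            tryptic_peptides(mature, cfg.missed_cleavages, cfg.min_fragment_len), 1
        ):
            pep = mature[s:e]
            mods = ModificationSet(carbamidomethyl_cys=pep.count("C"))
            m = peptide_mass(pep, mods)
            z = min(4, 1 + sum(pep.count(b) for b in "KRH"))
            frag_id = f"{g.transcript_id}/t{k}"
            fragments.append(
                MsmsFragment(
                    id=frag_id,
                    sequence=pep,
                    mz=mz(m, z),
                    z=z,
                    flank_n=mature[s - 1] if s > 0 else None,
                    flank_c=mature[e] if e < len(mature) else None,
                )
            )
            truth.fragments.append(FragmentTruth(frag_id, g.transcript_id, s, e))
    return fragments


def simulate_bundle(cfg: GeneratorConfig) -> SyntheticBundle:
    """Full synthetic dataset: transcriptome, MALDI lists and fragments."""
    transcripts, truth = generate_transcriptome(cfg)
    observed = simulate_maldi(truth, cfg)
    fragments = simulate_tryptic_fragments(truth, cfg)
    return SyntheticBundle(transcripts, truth, observed, fragments, cfg)


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, Path]:
    """Write transcripts.fasta, maldi.csv, fragments.tsv and truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "transcripts": outdir / "transcripts.fasta",
        "maldi": outdir / "maldi.csv",
        "fragments": outdir / "fragments.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_fragments": outdir / "truth_fragments.tsv",
    }
    with open(paths["transcripts"], "w") as fh:
        for t in bundle.transcripts:
            tpm = f" TPM={t.abundance:.4f}" if t.abundance is not None else ""
            fh.write(f">{t.id}{tpm}\n")
            for i in range(0, len(t.sequence), 70):
                fh.write(t.sequence[i : i + 70] + "\n")
    write_mass_csv(bundle.observed, paths["maldi"])
    write_fragment_tsv(bundle.fragments, paths["fragments"])
    pd.DataFrame(
        [
            {
                "transcript_id": g.transcript_id,
                "superfamily": g.superfamily,
                "signal": g.signal,
                "propeptide": g.propeptide,
                "mature": g.mature,
                "mass_acid": round(g.mass_acid, 5),
                "mass_amide": round(g.mass_amide, 5),
                "amidated": g.amidated,
                "fraction": g.fraction,
                "tpm": g.tpm,
            }
            for g in bundle.truth.genes
        ]
    ).to_csv(paths["truth_genes"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"fragment_id": f.fragment_id, "gene_id": f.gene_id,
             "start": f.start, "end": f.end}
            for f in bundle.truth.fragments
        ]
    ).to_csv(paths["truth_fragments"], sep="\t", index=False)
    return paths
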