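"""Precursor segmentation: signal peptide + propeptide + mature toxin.

Spider toxin precursors follow a conserved architecture: an N-terminal
secretion signal, an acidic propeptide, and a cysteine-rich mature
peptide released by two cleavages. Segmentation here is rule based and
deterministic:

* Signal peptide — a Kyte–Doolittle hydrophobic core must exist near the
  N terminus, and the cleavage site must satisfy the (-3,-1) small-residue
  rule (A/G/S/C/T at the -1 and -3 positions), echoing the von Heijne
  signal-peptidase preference.
* Propeptide — cleavage after an arginine whose three preceding residues
  include at least one glutamate (the "processing quadruplet" motif of
  arachnid toxin precursors), taking the last such site before the first
  cysteine of the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .translate import OpenReadingFrame

#: Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

SMALL_RESIDUES = frozenset("AGSCT")


@dataclass
class SignalConfig:
    """Tunables of the signal-peptide heuristic.

    ``kd_threshold`` is the minimum mean Kyte-Doolittle hydropathy of a
    ``window``-residue stretch (searched within ``core_region``, 1-based
    residue numbers) required to call a hydrophobic core. Cleavage
    positions are counted in residues from the N terminus and restricted
    to ``[min_pos, max_pos]``.
    """

    window: int = 7
    kd_threshold: float = 1.6
    core_region: tuple[int, int] = (2, 20)
    min_pos: int = 10
    max_pos: int = 35
    min_protein_len: int = 25


@dataclass
class SignalPrediction:
    found: bool
    position: int  # residues in the signal peptide (cleave after this many)
    score: float  # hydrophobic-core strength (max window mean KD)


@dataclass
class Precursor:
    """A segmented ORF. Invariant: signal + propeptide + mature == protein."""

    orf_ref: str
    signal: str
    propeptide: str
    mature: str
    signal_score: float
    cleavage_rule: str  # "PQM" | "fallback" | "user"
    flags: list[str] = field(default_factory=list)

    @property
    def protein(self) -> str:
        return self.signal + self.propeptide + self.mature

    @property
    def mature_offset(self) -> int:
        return len(self.signal) + len(self.propeptide)

    def __post_init__(self) -> None:
        if not self.mature:
            raise ValueError(f"precursor {self.orf_ref!r}: empty mature peptide")


def _window_mean(values: Sequence[float], start: int, end: int) -> float:
    chunk = values[start:end]
    return sum(chunk) / len(chunk) if chunk else 0.0


def predict_signal_cleavage(
    protein: str, cfg: SignalConfig | None = None
) -> SignalPrediction:
    """Locate the signal-peptidase cleavage site, if any.

    Candidate sites must obey the (-3,-1) small-residue rule within
    ``[min_pos, max_pos]``. Each candidate is scored as the mean
    hydropathy of the 7-residue window ending at its -3 position minus
    the mean hydropathy of the two residues following the cut: a genuine
    site lies just downstream of the hydrophobic core and just upstream
    of the polar propeptide/mature region. Highest score wins; ties go to
    the earliest site. Returns ``found=False`` when no hydrophobic core
    or no admissible site exists.
    """
    cfg = cfg or SignalConfig()
    if not protein or protein[0] != "M":
        raise ValueError("protein must start with M")
    if len(protein) < cfg.min_protein_len:
        raise ValueError(
            f"protein too short for signal prediction "
            f"({len(protein)} < {cfg.min_protein_len})"
        )
    kd = [KYTE_DOOLITTLE.get(a, 0.0) for a in protein]

    lo, hi = cfg.core_region
    core_score = float("-inf")
    for start in range(lo - 1, min(hi, len(protein) - cfg.window + 1)):
        core_score = max(core_score, _window_mean(kd, start, start + cfg.window))
    if core_score < cfg.kd_threshold:
        return SignalPrediction(False, 0, max(core_score, 0.0))

    best_pos, best_site_score = 0, float("-inf")
    for pos in range(cfg.min_pos, min(cfg.max_pos, len(protein) - 1) + 1):
        # 1-based residue `pos` is index pos-1; -1 and -3 residues:
        if protein[pos - 1] not in SMALL_RESIDUES:
            continue
        if protein[pos - 3] not in SMALL_RESIDUES:
            continue
        upstream = _window_mean(kd, pos - 9, pos - 2)
        downstream = _window_mean(kd, pos, min(pos + 2, len(protein)))
        site_score = upstream - downstream
        if site_score > best_site_score:
            best_pos, best_site_score = pos, site_score
    if best_pos == 0:
        return SignalPrediction(False, 0, core_score)
    return SignalPrediction(True, best_pos, core_score)


def predict_propeptide_cleavage(post_signal: str) -> int:
    """Mature-start offset within the post-signal sequence.

    Candidates are arginines with >=1 glutamate among the three
    preceding residues (processing quadruplet) lying before the first
    cysteine; the last candidate wins. With no candidate the offset is 0
    (no propeptide).
    """
    if not post_signal:
        raise ValueError("empty post-signal sequence")
    first_c = post_signal.find("C")
    limit = first_c if first_c >= 0 else len(post_signal)
    offset = 0
    for i in range(limit):
        if post_signal[i] != "R" or i + 1 >= len(post_signal):
            continue
        if "E" in post_signal[max(0, i - 3) : i]:
            offset = i + 1
    return offset


def segment_precursor(
    orf: OpenReadingFrame | str,
    orf_ref: str | None = None,
    signal_cfg: SignalConfig | None = None,
    min_mature_len: int = 10,
) -> Precursor:
    """Segment an ORF protein into signal, propeptide and mature peptide.

    With no detectable signal peptide the whole protein is returned as
    mature and flagged ``no_signal``; matures shorter than
    ``min_mature_len`` are flagged ``short_mature`` but kept.
    """
    if isinstance(orf, OpenReadingFrame):
        protein = orf.protein
        ref = orf_ref or orf.id
    else:
        protein = orf
        ref = orf_ref or "orf"

    flags: list[str] = []
    try:
        signal = predict_signal_cleavage(protein, signal_cfg)
    except ValueError:
        signal = SignalPrediction(False, 0, 0.0)
        flags.append("too_short_for_signal")

    if not signal.found:
        flags.append("no_signal")
        precursor = Precursor(
            orf_ref=ref,
            signal="",
            propeptide="",
            mature=protein,
            signal_score=signal.score,
            cleavage_rule="fallback",
            flags=flags,
        )
    else:
        post = protein[signal.position :]
        offset = predict_propeptide_cleavage(post)
        rule = "PQM" if offset > 0 else "fallback"
        precursor = Precursor(
            orf_ref=ref,
            signal=protein[: signal.position],
            propeptide=post[:offset],
            mature=post[offset:],
            signal_score=signal.score,
            cleavage_rule=rule,
            flags=flags,
        )
    if len(precursor.mature) < min_mature_len:
        precursor.flags.append("short_mature")
    if precursor.mature.count("C") % 2 == 1:
        precursor.flags.append("odd_cysteine_count")
    assert precursor.protein == protein
    return precursor
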