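"""Transcript input, six-frame translation and ORF extraction.

Assembled venom-gland transcripts arrive as nucleotide FASTA. Toxin
precursors are short secreted proteins, so candidate coding regions are
found by translating every transcript in all six reading frames and
collecting methionine-initiated segments above a minimum length.

Conventions: coordinates are 0-based half-open throughout; frames are
+1/+2/+3 (forward strand, offsets 0/1/2) and -1/-2/-3 (reverse
complement, offsets 0/1/2); stop codons render as '*' and any codon
containing 'N' renders as 'X'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

from Bio import SeqIO
from Bio.Data import CodonTable

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
FRAMES = (1, 2, 3, -1, -2, -3)

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    _CODON_TO_AA[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaParseError(ValueError):
    """Raised for structurally invalid FASTA or disallowed characters."""


@dataclass
class Transcript:
    """An assembled transcript: id, A/C/G/T/N sequence, optional TPM."""

    id: str
    sequence: str
    abundance: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        bad = set(self.sequence) - NUCLEOTIDE_ALPHABET
        if bad:
            raise ValueError(
                f"transcript {self.id!r}: illegal characters {sorted(bad)}"
            )
        if self.abundance is not None and self.abundance < 0:
            raise ValueError(f"transcript {self.id!r}: negative abundance")


@dataclass
class OpenReadingFrame:
    """A methionine-initiated, stop-free protein segment of one frame.

    ``aa_start``/``aa_end`` are 0-based half-open coordinates within the
    frame's full translation. ``complete`` is False when the segment runs
    to the end of the frame without a stop codon.
    """

    transcript_id: str
    frame: int
    aa_start: int
    aa_end: int
    protein: str
    complete: bool = True

    @property
    def id(self) -> str:
        sign = "+" if self.frame > 0 else ""
        return f"{self.transcript_id}|{sign}{self.frame}|{self.aa_start}-{self.aa_end}"

    def __post_init__(self) -> None:
        if self.frame not in FRAMES:
            raise ValueError(f"invalid frame {self.frame}")
        if not self.protein or self.protein[0] != "M":
            raise ValueError("ORF protein must begin with M")
        if "*" in self.protein:
            raise ValueError("ORF protein must not contain a stop")
        if self.aa_end - self.aa_start != len(self.protein):
            raise ValueError("ORF coordinates inconsistent with protein length")

    def nucleotide_span(self, transcript_length: int) -> tuple[int, int]:
        """Map protein coordinates back to forward-strand nucleotides."""
        offset = abs(self.frame) - 1
        if self.frame > 0:
            start = offset + 3 * self.aa_start
            end = offset + 3 * self.aa_end
        else:
            # coordinates are on the reverse complement; flip to forward
            end = transcript_length - offset - 3 * self.aa_start
            start = transcript_length - offset - 3 * self.aa_end
        return start, end


def _parse_tpm(description: str) -> Optional[float]:
    for token in description.split():
        if token.upper().startswith("TPM="):
            try:
                return float(token.split("=", 1)[1])
            except ValueError:
                return None
    return None


def read_transcript_fasta(path) -> list[Transcript]:
    """Read transcripts from FASTA: uppercased, U converted to T.

    A ``TPM=<value>`` token in the description is parsed into
    ``abundance``. Malformed records raise :class:`FastaParseError`
    naming the offending line; an empty file returns ``[]`` with a
    warning.
    """
    path = str(path)
    with open(path) as handle:
        lines = handle.readlines()

    seen_header = False
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            seen_header = True
            continue
        if not seen_header:
            raise FastaParseError(
                f"{path}:{lineno}: sequence data before first '>' header"
            )
        bad = set(stripped.upper().replace("U", "T")) - NUCLEOTIDE_ALPHABET
        if bad:
            raise FastaParseError(
                f"{path}:{lineno}: illegal sequence characters {sorted(bad)}"
            )
    if not seen_header:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
        return []

    transcripts = []
    for record in SeqIO.parse(path, "fasta"):
        seq = str(record.seq).upper().replace("U", "T")
        transcripts.append(
            Transcript(id=record.id, sequence=seq, abundance=_parse_tpm(record.description))
        )
    return transcripts


def translate_frame(sequence: str, frame: int) -> str:
    """Translate one frame; trailing partial codons are dropped."""
    if frame not in FRAMES:
        raise ValueError(f"invalid frame {frame}")
    if frame > 0:
        strand = sequence
    else:
        strand = sequence.translate(_COMPLEMENT)[::-1]
    offset = abs(frame) - 1
    coding = strand[offset:]
    aa = []
    for i in range(0, len(coding) - 2, 3):
        codon = coding[i : i + 3]
        aa.append("X" if "N" in codon else _CODON_TO_AA[codon])
    return "".join(aa)


def six_frame_translate(t: Transcript) -> dict[int, str]:
    """All six frame translations keyed by frame (+1..+3, -1..-3)."""
    if len(t.sequence) < 3:
        raise ValueError(
            f"transcript {t.id!r}: sequence shorter than one codon"
        )
    return {frame: translate_frame(t.sequence, frame) for frame in FRAMES}


def extract_orfs(
    frames: dict[int, str],
    min_len: int = 40,
    transcript_id: str = "",
    include_incomplete: bool = True,
) -> list[OpenReadingFrame]:
    """Maximal M...(stop|frame end) segments of length >= ``min_len``.

    Within each stop-delimited stretch the segment starts at the first
    methionine (the maximal M-initiated reading). Results are sorted
    longest-first, ties broken by frame order then start coordinate.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    orfs = []
    for frame in FRAMES:
        aa = frames.get(frame)
        if aa is None:
            continue
        segment_start = 0
        for segment in aa.split("*"):
            m = segment.find("M")
            if m >= 0:
                protein = segment[m:]
                complete = segment_start + len(segment) < len(aa)
                if len(protein) >= min_len and (complete or include_incomplete):
                    start = segment_start + m
                    orfs.append(
                        OpenReadingFrame(
                            transcript_id=transcript_id,
                            frame=frame,
                            aa_start=start,
                            aa_end=start + len(protein),
                            protein=protein,
                            complete=complete,
                        )
                    )
            segment_start += len(segment) + 1
    orfs.sort(key=lambda o: (-len(o.protein), FRAMES.index(o.frame), o.aa_start))
    return orfs


def transcript_orfs(
    t: Transcript, min_len: int = 40, include_incomplete: bool = True
) -> list[OpenReadingFrame]:
    """Convenience: six-frame translate then extract ORFs."""
    return extract_orfs(
        six_frame_translate(t),
        min_len=min_len,
        transcript_id=t.id,
        include_incomplete=include_incomplete,
    )
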