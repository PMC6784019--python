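"""Independent reference implementations used only to check knotminer.

These deliberately share no code with the package: exhaustive
alignment-path enumeration, Biopython's PairwiseAligner, pyteomics
atomic-composition masses, and plain-regex signature expansion.
"""

from __future__ import annotations

import re

from Bio import Align

from knotminer.mapping import ScoringScheme, substitution_score
from knotminer.signatures import (
    AnyRun,
    Literal,
    ResidueAlt,
    Wildcard,
    parse_signature,
)


def exhaustive_local_score(query: str, target: str, scheme: ScoringScheme) -> float:
    """Best local-alignment score by enumerating every alignment path.

    Every substring pair is aligned by brute recursion over column
    choices (match, gap-in-query, gap-in-target) with affine gap state.
    Exponential: only for very short sequences.
    """

    def align_all(a: str, b: str) -> float:
        def go(i: int, j: int, last: str) -> float:
            if i == len(a) and j == len(b):
                return 0.0
            best = float("-inf")
            if i < len(a) and j < len(b):
                best = max(
                    best,
                    substitution_score(scheme, a[i], b[j]) + go(i + 1, j + 1, "M"),
                )
            if i < len(a):
                cost = (
                    scheme.gap_extend
                    if last == "U"
                    else scheme.gap_open + scheme.gap_extend
                )
                best = max(best, cost + go(i + 1, j, "U"))
            if j < len(b):
                cost = (
                    scheme.gap_extend
                    if last == "L"
                    else scheme.gap_open + scheme.gap_extend
                )
                best = max(best, cost + go(i, j + 1, "L"))
            return best

        return go(0, 0, "start")

    best = 0.0
    for qs in range(len(query)):
        for qe in range(qs + 1, len(query) + 1):
            for ts in range(len(target)):
                for te in range(ts + 1, len(target) + 1):
                    best = max(best, align_all(query[qs:qe], target[ts:te]))
    return best


def biopython_local_score(query: str, target: str, scheme: ScoringScheme) -> float:
    """Smith-Waterman score via Bio.Align.PairwiseAligner, same scoring."""
    letters = "ACDEFGHIKLMNPQRSTVWYX"
    matrix = Align.substitution_matrices.Array(alphabet=letters, dims=2)
    for a in letters:
        for b in letters:
            matrix[a, b] = substitution_score(scheme, a, b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # first gap residue costs open+extend, later ones extend
    aligner.open_gap_score = scheme.gap_open + scheme.gap_extend
    aligner.extend_gap_score = scheme.gap_extend
    return float(aligner.score(query, target))


def signature_regex(pattern: str) -> re.Pattern:
    """Independent regex expansion of the signature mini-language."""
    parts = []
    for tok in parse_signature(pattern):
        if isinstance(tok, Literal):
            parts.append(re.escape(tok.residue))
        elif isinstance(tok, ResidueAlt):
            parts.append("[" + "".join(sorted(tok.residues)) + "]")
        elif isinstance(tok, Wildcard):
            alts = "|".join(f".{{{k}}}" for k in sorted(tok.lengths, reverse=True))
            parts.append(f"(?:{alts})")
        elif isinstance(tok, AnyRun):
            parts.append(".*")
    return re.compile("".join(parts))
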