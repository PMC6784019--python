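"""Domain-signature mini-language for cysteine-rich peptide motifs.

Signatures describe cysteine scaffolds with exact spacer lengths, e.g.
the whey-acidic-protein (WAP) four-disulfide core
``Xn CP X6/8 C X6 C X5 C X5 CC X3/4 C X3 C Xn``. Grammar:

* a residue letter — literal match;
* ``X`` — one arbitrary residue; ``X5`` — exactly five; ``X6/8`` — six
  or eight (any number of ``/`` alternatives); ``Xn`` — any number >= 0;
* ``(P/R/A)`` — one residue from the alternation;
* whitespace and underscores are ignored.

Matching is leftmost-longest: the first start position admitting a
match is reported with the longest span achievable there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class SignatureError(ValueError):
    """Signature grammar violation, carrying the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"position {position}: {message}")
        self.position = position


@dataclass(frozen=True)
class Literal:
    residue: str


@dataclass(frozen=True)
class Wildcard:
    lengths: tuple[int, ...]  # exact admissible spacer lengths


@dataclass(frozen=True)
class AnyRun:
    pass  # X_n: any length >= 0


@dataclass(frozen=True)
class ResidueAlt:
    residues: frozenset[str]


Token = Union[Literal, Wildcard, AnyRun, ResidueAlt]


@dataclass
class DomainSignature:
    """A named signature with its parsed token list."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        self.tokens = parse_signature(self.pattern)


@dataclass
class SignatureMatch:
    matched: bool
    span: Optional[tuple[int, int]] = None


def _clean(pattern: str) -> str:
    return "".join(ch for ch in pattern if ch not in " \t\n_")


def parse_signature(pattern: str) -> list[Token]:
    """Parse a signature string into tokens; errors carry positions."""
    s = _clean(pattern)
    tokens: list[Token] = []
    i = 0
    while i < len(s):
        ch = s[i]
        if ch == "(":
            j = s.find(")", i)
            if j < 0:
                raise SignatureError("unclosed '('", i)
            residues = s[i + 1 : j].split("/")
            if not residues or any(
                len(r) != 1 or r not in AA_LETTERS for r in residues
            ):
                raise SignatureError(
                    f"bad residue alternation {s[i : j + 1]!r}", i
                )
            tokens.append(ResidueAlt(frozenset(residues)))
            i = j + 1
        elif ch == "X":
            i += 1
            if i < len(s) and s[i] == "n":
                tokens.append(AnyRun())
                i += 1
            elif i < len(s) and s[i].isdigit():
                lengths = []
                while True:
                    j = i
                    while j < len(s) and s[j].isdigit():
                        j += 1
                    lengths.append(int(s[i:j]))
                    i = j
                    if i < len(s) and s[i] == "/":
                        i += 1
                        if i >= len(s) or not s[i].isdigit():
                            raise SignatureError("expected digits after '/'", i)
                    else:
                        break
                tokens.append(Wildcard(tuple(sorted(set(lengths)))))
            else:
                tokens.append(Wildcard((1,)))
        elif ch in AA_LETTERS:
            tokens.append(Literal(ch))
            i += 1
        else:
            raise SignatureError(f"unexpected character {ch!r}", i)
    if not tokens:
        raise SignatureError("empty signature", 0)
    return tokens


def _match_from(tokens: list[Token], seq: str, ti: int, pos: int,
                memo: dict) -> Optional[int]:
    """Longest end index reachable matching tokens[ti:] at seq[pos:]."""
    if ti == len(tokens):
        return pos
    key = (ti, pos)
    if key in memo:
        return memo[key]
    tok = tokens[ti]
    best: Optional[int] = None
    if isinstance(tok, Literal):
        if pos < len(seq) and seq[pos] == tok.residue:
            best = _match_from(tokens, seq, ti + 1, pos + 1, memo)
    elif isinstance(tok, ResidueAlt):
        if pos < len(seq) and seq[pos] in tok.residues:
            best = _match_from(tokens, seq, ti + 1, pos + 1, memo)
    elif isinstance(tok, Wildcard):
        for k in sorted(tok.lengths, reverse=True):
            if pos + k <= len(seq):
                end = _match_from(tokens, seq, ti + 1, pos + k, memo)
                if end is not None and (best is None or end > best):
                    best = end
    elif isinstance(tok, AnyRun):
        for k in range(len(seq) - pos, -1, -1):
            end = _match_from(tokens, seq, ti + 1, pos + k, memo)
            if end is not None and (best is None or end > best):
                best = end
    memo[key] = best
    return best


def match_signature(seq: str, sig: DomainSignature | str) -> SignatureMatch:
    """Leftmost-longest signature match within ``seq``."""
    if isinstance(sig, str):
        sig = DomainSignature(name="anonymous", pattern=sig)
    for start in range(len(seq) + 1):
        end = _match_from(sig.tokens, seq, 0, start, {})
        if end is not None:
            return SignatureMatch(True, (start, end))
    return SignatureMatch(False, None)


def realize_signature(sig: DomainSignature | str, rng, filler: str = "ACDEFGHIKLMNPQRSTVWY") -> str:
    """Generate one random sequence satisfying a signature.

    ``Xn`` runs draw a length in [0, 6]. Wildcard positions draw from
    ``filler`` excluding cysteine so that planted cysteine scaffolds stay
    exact.
    """
    if isinstance(sig, str):
        sig = DomainSignature(name="anonymous", pattern=sig)
    non_cys = [a for a in filler if a != "C"]
    out = []
    for tok in sig.tokens:
        if isinstance(tok, Literal):
            out.append(tok.residue)
        elif isinstance(tok, ResidueAlt):
            out.append(rng.choice(sorted(tok.residues)))
        elif isinstance(tok, Wildcard):
            k = int(rng.choice(list(tok.lengths)))
            out.extend(rng.choice(non_cys) for _ in range(k))
        elif isinstance(tok, AnyRun):
            k = int(rng.integers(0, 7))
            out.extend(rng.choice(non_cys) for _ in range(k))
    return "".join(out)


#: Signatures transcribed from the superfamily descriptions (WAP, SVWC,
#: astakine cytokines and the two knottin sub-groups).
BUILTIN_SIGNATURES: dict[str, str] = {
    "WAP": "Xn CP X6/8 C X6 C X5 C X5 CC X3/4 C X3 C Xn",
    "SVWC": "X13 C X18/19 C X4 C X9 C X8/11/12 C X11 CC X4 C",
    "astakine": "Xn C X5/6 C X4 CC X11 C X9 C X15/28/30 C X1 C X5 C X4/6 C Xn",
    "GX2RYS-motif": "G X2 R Y S X (P/R/A) X C",
    "LXYP-motif": "L X Y P",
    "group4a": "X20 C X6 C X5 CC X11 C X14 C X2 C X6 C X2",
    "group4b": "X1 C X6 C X6 CC X4 C X1 C X6 C X1 C Xn",
}


def builtin_signature(name: str) -> DomainSignature:
    try:
        return DomainSignature(name=name, pattern=BUILTIN_SIGNATURES[name])
    except KeyError:
        raise KeyError(f"unknown signature {name!r}") from None
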