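"""Mapping de novo MS/MS fragment sequences onto translated transcripts.

Fragments sequenced from tandem MS carry two systematic ambiguities that
ordinary alignment tools mishandle: isobaric leucine/isoleucine cannot
be distinguished (identical residue mass), and unassignable positions
are written 'X'. The local aligner here therefore treats I/L as
identical by default, lets 'X' align to any residue at score 0, and
excludes X columns from the identity denominator — so a fragment like
CVFSCDXEK counts as a full match to CVFSCDIEK.

Scoring is Smith–Waterman with BLOSUM62 substitution scores and affine
gaps (a gap of length k costs gap_open + k * gap_extend).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence, Union

import pandas as pd
from Bio.Align import substitution_matrices

from .precursor import Precursor

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class MsmsFragment:
    """A de novo sequenced tryptic fragment with its observed ion."""

    id: str
    sequence: str
    mz: float
    z: int
    flank_n: Optional[str] = None  # preceding residue ("K." context)
    flank_c: Optional[str] = None  # following residue (".E" context)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"fragment {self.id!r}: empty sequence")
        if self.z < 1:
            raise ValueError(f"fragment {self.id!r}: charge must be >= 1")

    @property
    def dot_notation(self) -> str:
        n = self.flank_n or "-"
        c = self.flank_c or "-"
        return f"{n}.{self.sequence}.{c}"


@dataclass(frozen=True)
class ScoringScheme:
    matrix_name: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -1.0
    il_equivalent: bool = True
    x_policy: str = "match_any"

    def __post_init__(self) -> None:
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        if self.x_policy != "match_any":
            raise ValueError(f"unsupported x_policy {self.x_policy!r}")


@lru_cache(maxsize=8)
def _substitution_dict(scheme: ScoringScheme) -> dict[tuple[str, str], float]:
    base = substitution_matrices.load(scheme.matrix_name)
    table: dict[tuple[str, str], float] = {}
    letters = AA20 + "X"
    for a in letters:
        for b in letters:
            if a == "X" or b == "X":
                table[(a, b)] = 0.0
            else:
                table[(a, b)] = float(base[a, b])
    if scheme.il_equivalent:
        il = max(table[("I", "I")], table[("L", "L")])
        for a, b in (("I", "L"), ("L", "I"), ("I", "I"), ("L", "L")):
            table[(a, b)] = il
    return table


def substitution_score(scheme: ScoringScheme, a: str, b: str) -> float:
    try:
        return _substitution_dict(scheme)[(a, b)]
    except KeyError:
        raise ValueError(f"residue pair ({a!r},{b!r}) outside alphabet") from None


@dataclass
class LocalAlignment:
    score: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    aligned_query: str
    aligned_target: str
    n_identical: int
    n_columns: int  # aligned non-gap, non-X columns
    percent_identity: float


@dataclass
class FragmentMatch:
    fragment_ref: str
    target_ref: str
    target_span: tuple[int, int]
    percent_identity: float
    score: float
    region: Optional[str] = None  # signal | propeptide | mature | spanning
    mature_span: Optional[tuple[int, int]] = None  # span in mature coordinates


def _residues_identical(a: str, b: str, il_equivalent: bool) -> bool:
    if a == b:
        return True
    return il_equivalent and {a, b} == {"I", "L"}


def local_align(
    query: str, target: str, scheme: ScoringScheme | None = None
) -> LocalAlignment:
    """Optimal Smith–Waterman local alignment of two peptide sequences.

    Identity is computed over aligned columns that are neither gaps nor
    involve 'X'; with no such column the identity is 0. Symmetric in
    query/target up to span exchange: co-optimal alignments can differ
    in identity, so the pair is canonically oriented before the DP and
    the result mapped back, making swapped calls return the same
    alignment.
    """
    if (len(query), query) > (len(target), target):
        res = local_align(target, query, scheme)
        return LocalAlignment(
            score=res.score,
            query_span=res.target_span,
            target_span=res.query_span,
            aligned_query=res.aligned_target,
            aligned_target=res.aligned_query,
            n_identical=res.n_identical,
            n_columns=res.n_columns,
            percent_identity=res.percent_identity,
        )
    scheme = scheme or ScoringScheme()
    if not query or not target:
        raise ValueError("cannot align empty sequences")
    sub = _substitution_dict(scheme)
    try:
        score_row = [[sub[(qa, ta)] for ta in target] for qa in query]
    except KeyError as exc:
        raise ValueError(f"illegal residue {exc.args[0]!r}") from None

    n, m = len(query), len(target)
    open_ext = scheme.gap_open + scheme.gap_extend
    ext = scheme.gap_extend
    NEG = float("-inf")

    # H: best alignment ending at (i, j); E: gap in query (consumes
    # target); F: gap in target (consumes query). Pointers for traceback.
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    ptr: list[list[int]] = [[0] * (m + 1) for _ in range(n + 1)]  # 0 stop,1 diag,2 up(F),3 left(E)
    eptr = [[False] * (m + 1) for _ in range(n + 1)]  # E came from E (extend)
    fptr = [[False] * (m + 1) for _ in range(n + 1)]  # F came from F

    best, best_ij = 0.0, (0, 0)
    for i in range(1, n + 1):
        Hi, Him1 = H[i], H[i - 1]
        Ei, Fi, Fim1 = E[i], F[i], F[i - 1]
        row_scores = score_row[i - 1]
        for j in range(1, m + 1):
            e_open = Hi[j - 1] + open_ext
            e_ext = Ei[j - 1] + ext
            Ei[j] = max(e_open, e_ext)
            eptr[i][j] = e_ext > e_open
            f_open = Him1[j] + open_ext
            f_ext = Fim1[j] + ext
            Fi[j] = max(f_open, f_ext)
            fptr[i][j] = f_ext > f_open
            diag = Him1[j - 1] + row_scores[j - 1]
            h = max(0.0, diag, Ei[j], Fi[j])
            Hi[j] = h
            if h == 0.0:
                ptr[i][j] = 0
            elif h == diag:
                ptr[i][j] = 1
            elif h == Fi[j]:
                ptr[i][j] = 2
            else:
                ptr[i][j] = 3
            if h > best:
                best, best_ij = h, (i, j)

    # traceback
    i, j = best_ij
    aq, at = [], []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            p = ptr[i][j]
            if p == 0:
                break
            if p == 1:
                aq.append(query[i - 1])
                at.append(target[j - 1])
                i, j = i - 1, j - 1
            elif p == 2:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            aq.append(query[i - 1])
            at.append("-")
            cont = fptr[i][j]
            i -= 1
            state = "F" if cont else "H"
        else:  # E
            aq.append("-")
            at.append(target[j - 1])
            cont = eptr[i][j]
            j -= 1
            state = "E" if cont else "H"
    aq.reverse()
    at.reverse()
    qs, ts = i, j
    qe, te = best_ij

    n_ident = n_cols = 0
    for a, b in zip(aq, at):
        if a == "-" or b == "-" or a == "X" or b == "X":
            continue
        n_cols += 1
        if _residues_identical(a, b, scheme.il_equivalent):
            n_ident += 1
    identity = 100.0 * n_ident / n_cols if n_cols else 0.0
    return LocalAlignment(
        score=best,
        query_span=(qs, qe),
        target_span=(ts, te),
        aligned_query="".join(aq),
        aligned_target="".join(at),
        n_identical=n_ident,
        n_columns=n_cols,
        percent_identity=identity,
    )


def _region_label(span: tuple[int, int], precursor: Precursor) -> str:
    sig_end = len(precursor.signal)
    pro_end = sig_end + len(precursor.propeptide)
    s, e = span
    if e <= sig_end:
        return "signal"
    if s >= pro_end:
        return "mature"
    if s >= sig_end and e <= pro_end:
        return "propeptide"
    return "spanning"


def search_fragments(
    frags: Sequence[MsmsFragment],
    db: Sequence[Union[Precursor, tuple[str, str]]],
    scheme: ScoringScheme | None = None,
    min_score: float = 25.0,
) -> dict[str, list[FragmentMatch]]:
    """Exhaustive local-alignment search of each fragment against a database.

    ``db`` entries are either :class:`Precursor` objects (aligned
    against the full precursor protein, with region labels from the
    segmentation) or plain ``(id, protein)`` tuples. Hits with score >=
    ``min_score`` are returned best-first; ties keep database order.
    """
    if not db:
        raise ValueError("empty target database")
    scheme = scheme or ScoringScheme()
    targets: list[tuple[str, str, Optional[Precursor]]] = []
    for entry in db:
        if isinstance(entry, Precursor):
            targets.append((entry.orf_ref, entry.protein, entry))
        else:
            ref, protein = entry
            targets.append((ref, protein, None))

    results: dict[str, list[FragmentMatch]] = {}
    for frag in frags:
        hits = []
        for order, (ref, protein, precursor) in enumerate(targets):
            aln = local_align(frag.sequence, protein, scheme)
            if aln.score < min_score:
                continue
            region = mature_span = None
            if precursor is not None:
                region = _region_label(aln.target_span, precursor)
                off = precursor.mature_offset
                s = max(aln.target_span[0], off) - off
                e = min(aln.target_span[1], off + len(precursor.mature)) - off
                if e > s:
                    mature_span = (s, e)
            hits.append(
                (
                    -aln.score,
                    order,
                    ref,
                    FragmentMatch(
                        fragment_ref=frag.id,
                        target_ref=ref,
                        target_span=aln.target_span,
                        percent_identity=aln.percent_identity,
                        score=aln.score,
                        region=region,
                        mature_span=mature_span,
                    ),
                )
            )
        hits.sort(key=lambda h: (h[0], h[1], h[2]))
        results[frag.id] = [h[3] for h in hits]
    return results


def union_length(spans: Sequence[tuple[int, int]]) -> int:
    """Total length covered by a union of half-open intervals."""
    total, cur_end = 0, None
    for s, e in sorted(spans):
        if e <= s:
            continue
        if cur_end is None or s > cur_end:
            total += e - s
            cur_end = e
        elif e > cur_end:
            total += e - cur_end
            cur_end = e
    return total


def compute_coverage(
    matches: Sequence[FragmentMatch], mature_len: int
) -> float:
    """Percent of the mature peptide covered by fragment matches.

    Uses each match's mature-coordinate span (matches without one, e.g.
    hits entirely in the signal or propeptide, contribute nothing).
    Monotone in added matches and bounded by 100.
    """
    if mature_len <= 0:
        raise ValueError("mature length must be positive")
    spans = [
        (max(0, s), min(mature_len, e))
        for s, e in (m.mature_span for m in matches if m.mature_span)
    ]
    return 100.0 * union_length(spans) / mature_len


def read_fragment_tsv(path) -> list[MsmsFragment]:
    """Read fragments: columns id, sequence, mz, z[, flank_n, flank_c]."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "sequence", "mz", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")

    def _flank(value) -> Optional[str]:
        if value is None or (isinstance(value, float) and pd.isna(value)):
            return None
        value = str(value)
        return None if value in ("-", "") else value

    return [
        MsmsFragment(
            id=str(row.id),
            sequence=str(row.sequence),
            mz=float(row.mz),
            z=int(row.z),
            flank_n=_flank(getattr(row, "flank_n", None)),
            flank_c=_flank(getattr(row, "flank_c", None)),
        )
        for row in df.itertuples()
    ]


def write_fragment_tsv(frags: Sequence[MsmsFragment], path) -> None:
    rows = [
        {
            "id": f.id,
            "sequence": f.sequence,
            "mz": round(f.mz, 4),
            "z": f.z,
            "flank_n": f.flank_n or "-",
            "flank_c": f.flank_c or "-",
        }
        for f in frags
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
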