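"""Cysteine frameworks, superfamily classification and sequence logos.

A cysteine framework records only the order and adjacency of cysteines
in a mature peptide — ``C-C-CC-C`` means five cysteines of which the
third and fourth are adjacent. Spacer lengths are deliberately not part
of the framework (they belong to domain signatures); this is exactly the
dialect in which the eight venom superfamilies SF1–SF8 are defined, four
of which share eight cysteines and differ only in doublet position.

Disulfide connectivity is stored as validated annotation (curated
knowledge), never predicted here.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import yaml

from .signatures import DomainSignature  # noqa: F401  (re-exported surface)

LOG2_20 = math.log2(20.0)


@dataclass
class CysteineFramework:
    """Ordered cysteine positions plus the canonical adjacency pattern."""

    peptide_ref: str
    positions: list[int]
    canonical: str
    spacings: list[int]
    length: Optional[int] = None

    @property
    def n_cys(self) -> int:
        return len(self.positions)

    @property
    def empty(self) -> bool:
        return not self.positions


@dataclass
class SuperfamilyDefinition:
    name: str
    canonical: str
    n_cys: int
    length_range: Optional[tuple[int, int]] = None
    connectivity: Optional[list[tuple[int, int]]] = None
    connectivity_alt: Optional[list[tuple[int, int]]] = None
    free_cysteines: Optional[list[int]] = None
    signature: Optional[str] = None

    def __post_init__(self) -> None:
        if count_pattern_cysteines(self.canonical) != self.n_cys:
            raise ValueError(
                f"{self.name}: canonical {self.canonical!r} has "
                f"{count_pattern_cysteines(self.canonical)} cysteines, not {self.n_cys}"
            )
        for bonds in (self.connectivity, self.connectivity_alt):
            if bonds:
                result = validate_connectivity(self.n_cys, bonds)
                if not result.valid:
                    raise ValueError(f"{self.name}: {result.reason}")


@dataclass
class Classification:
    superfamily: str  # definition name or "novel"
    warnings: list[str] = field(default_factory=list)

    @property
    def novel(self) -> bool:
        return self.superfamily == "novel"


@dataclass
class ConnectivityResult:
    valid: bool
    reason: Optional[str] = None
    free: list[int] = field(default_factory=list)


@dataclass
class ConsensusMatrix:
    """Per-column residue frequencies and Shannon information (bits)."""

    columns: list[dict[str, float]]
    information: list[float]


def count_pattern_cysteines(canonical: str) -> int:
    return canonical.count("C")


def validate_pattern(canonical: str) -> None:
    if not canonical or set(canonical) - {"C", "-"}:
        raise ValueError(f"invalid canonical pattern {canonical!r}")
    if canonical.startswith("-") or canonical.endswith("-") or "--" in canonical:
        raise ValueError(f"invalid canonical pattern {canonical!r}")


def extract_framework(mature: str, peptide_ref: str = "") -> CysteineFramework:
    """Cysteine positions and canonical adjacency pattern of a peptide.

    Adjacent cysteines (gap 0) collapse into a doublet token ``CC``
    (triplets stay ``CCC`` and so on); any positive gap renders as a
    single ``-`` regardless of its length.
    """
    positions = [i for i, a in enumerate(mature) if a == "C"]
    spacings = [b - a - 1 for a, b in zip(positions, positions[1:])]
    parts: list[str] = []
    for i, pos in enumerate(positions):
        if i == 0 or pos - positions[i - 1] > 1:
            parts.append("C")
        else:
            parts[-1] += "C"
    return CysteineFramework(
        peptide_ref=peptide_ref,
        positions=positions,
        canonical="-".join(parts),
        spacings=spacings,
        length=len(mature),
    )


def classify_superfamily(
    fw: CysteineFramework, defs: Sequence[SuperfamilyDefinition]
) -> Classification:
    """Exact canonical-pattern match against the superfamily scheme.

    Length-range violations are reported as warnings, never rejections;
    an unmatched pattern classifies as ``"novel"``.
    """
    seen: dict[str, str] = {}
    for d in defs:
        if d.canonical in seen:
            raise ValueError(
                f"duplicate canonical pattern {d.canonical!r} "
                f"({seen[d.canonical]} vs {d.name})"
            )
        seen[d.canonical] = d.name
    for d in defs:
        if fw.canonical == d.canonical:
            warnings = []
            if (
                d.length_range is not None
                and fw.length is not None
                and not (d.length_range[0] <= fw.length <= d.length_range[1])
            ):
                warnings.append(
                    f"length {fw.length} outside {d.name} range "
                    f"{d.length_range[0]}-{d.length_range[1]}"
                )
            return Classification(d.name, warnings)
    return Classification("novel")


def cluster_frameworks(
    fws: Iterable[CysteineFramework],
) -> dict[str, list[CysteineFramework]]:
    """Partition frameworks by canonical pattern (first-occurrence order)."""
    groups: dict[str, list[CysteineFramework]] = {}
    for fw in fws:
        groups.setdefault(fw.canonical, []).append(fw)
    return groups


def validate_connectivity(
    fw_or_ncys: CysteineFramework | int, bonds: Sequence[tuple[int, int]]
) -> ConnectivityResult:
    """Check a disulfide-bond list against a framework.

    Bonds are 1-based cysteine indices. Valid means: in range, no
    self-pairs, no cysteine used twice. Unpaired cysteines are returned
    as the free list.
    """
    n = fw_or_ncys.n_cys if isinstance(fw_or_ncys, CysteineFramework) else fw_or_ncys
    used: set[int] = set()
    for a, b in bonds:
        if a == b:
            return ConnectivityResult(False, f"self-pair ({a},{b})")
        for idx in (a, b):
            if not 1 <= idx <= n:
                return ConnectivityResult(
                    False, f"cysteine index {idx} out of range 1..{n}"
                )
            if idx in used:
                return ConnectivityResult(False, f"cysteine {idx} used twice")
            used.add(idx)
    free = sorted(set(range(1, n + 1)) - used)
    return ConnectivityResult(True, free=free)


def consensus_logo_matrix(aligned: Sequence[str]) -> ConsensusMatrix:
    """Position frequency matrix + information content of an alignment.

    Gap characters ('-') are excluded from the frequencies. Information
    per column is log2(20) − H(column) bits under a uniform 20-residue
    background, i.e. a fully conserved column scores log2(20) ≈ 4.32
    bits. All-gap columns carry no frequencies and 0 bits.
    """
    if not aligned:
        raise ValueError("empty alignment")
    width = len(aligned[0])
    if any(len(s) != width for s in aligned):
        raise ValueError("ragged alignment: sequences differ in length")
    columns: list[dict[str, float]] = []
    information: list[float] = []
    for j in range(width):
        counts = Counter(s[j] for s in aligned if s[j] != "-")
        total = sum(counts.values())
        if total == 0:
            columns.append({})
            information.append(0.0)
            continue
        freqs = {res: c / total for res, c in counts.items()}
        entropy = -sum(p * math.log2(p) for p in freqs.values())
        columns.append(freqs)
        information.append(LOG2_20 - entropy)
    return ConsensusMatrix(columns=columns, information=information)


def _parse_bonds(raw) -> Optional[list[tuple[int, int]]]:
    if raw is None:
        return None
    return [tuple(pair) for pair in raw]


def load_superfamily_definitions(path=None) -> list[SuperfamilyDefinition]:
    """Load the superfamily scheme (the packaged SF1–SF8 table by default).

    A user file with the same YAML layout overrides the packaged scheme.
    """
    if path is None:
        text = (
            resources.files("knotminer") / "data" / "superfamilies.yaml"
        ).read_text()
    else:
        with open(path) as handle:
            text = handle.read()
    raw = yaml.safe_load(text)
    defs = []
    for entry in raw["superfamilies"]:
        length_range = entry.get("length_range")
        defs.append(
            SuperfamilyDefinition(
                name=entry["name"],
                canonical=entry["canonical"],
                n_cys=entry["n_cys"],
                length_range=tuple(length_range) if length_range else None,
                connectivity=_parse_bonds(entry.get("connectivity")),
                connectivity_alt=_parse_bonds(entry.get("connectivity_alt")),
                free_cysteines=entry.get("free_cysteines"),
                signature=entry.get("signature"),
            )
        )
    validate_pattern_uniqueness(defs)
    return defs


def validate_pattern_uniqueness(defs: Sequence[SuperfamilyDefinition]) -> None:
    patterns = [d.canonical for d in defs]
    if len(set(patterns)) != len(patterns):
        raise ValueError("superfamily definitions share a canonical pattern")
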