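"""Rational toxin nomenclature (King-style names).

A name reads ``<activity prefix>-<family>-<species abbrev><paralog>
<isoform>[_<variant>]``, e.g. ``ω-theraphotoxin-Pv3a`` or
``U29-theraphotoxin-Pv1b_1``. The Greek prefix encodes pharmacology
(ω = calcium-channel modulator, μ/β = sodium, κ = potassium); toxins of
unknown activity carry ``U`` plus a running index. The species
abbreviation defaults to genus initial (upper) + species initial
(lower), e.g. *Pamphobeteus verdolaga* → ``Pv``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

GREEK_PREFIXES = frozenset("ωμβκδτγλ")

ACTIVITY_PREFIX = {
    "cav_modulator": "ω",
    "nav": "μ",
    "kv": "κ",
}

_TAIL_RE = re.compile(r"^(?P<abbrev>[A-Z][a-z]{1,2})(?P<paralog>[1-9]\d*)"
                      r"(?P<isoform>[a-z])(?:_(?P<variant>[1-9]\d*))?$")


class NameParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"position {position}: {message}")
        self.position = position


@dataclass(frozen=True)
class ToxinName:
    activity_prefix: str  # "ω", "μ", ... or "U<idx>"
    family: str  # e.g. "theraphotoxin"
    species_abbrev: str  # 2-3 letters, e.g. "Pv"
    paralog: int
    isoform: str  # single lowercase letter
    variant: Optional[int] = None

    def __post_init__(self) -> None:
        if not (
            self.activity_prefix in GREEK_PREFIXES
            or re.fullmatch(r"U[1-9]\d*", self.activity_prefix)
        ):
            raise ValueError(f"invalid activity prefix {self.activity_prefix!r}")
        if not re.fullmatch(r"[A-Z][a-z]{1,2}", self.species_abbrev):
            raise ValueError(f"invalid species abbreviation {self.species_abbrev!r}")
        if self.paralog < 1:
            raise ValueError("paralog must be >= 1")
        if not re.fullmatch(r"[a-z]", self.isoform):
            raise ValueError(f"invalid isoform {self.isoform!r}")
        if self.variant is not None and self.variant < 1:
            raise ValueError("variant must be >= 1")

    def render(self) -> str:
        tail = f"_{self.variant}" if self.variant is not None else ""
        return (
            f"{self.activity_prefix}-{self.family}-"
            f"{self.species_abbrev}{self.paralog}{self.isoform}{tail}"
        )

    def __str__(self) -> str:
        return self.render()


def species_abbreviation(genus: str, species: str) -> str:
    if not genus or not species:
        raise ValueError("genus and species must be non-empty")
    return genus[0].upper() + species[0].lower()


def assign_name(
    activity: str,
    family: str,
    genus: str,
    species: str,
    paralog: int,
    isoform: str,
    variant: Optional[int] = None,
    u_index: Optional[int] = None,
    abbrev: Optional[str] = None,
) -> ToxinName:
    """Build a rational name from activity class and taxonomy.

    ``activity`` is one of cav_modulator / nav / kv / unknown; unknown
    requires ``u_index``. ``abbrev`` overrides the default two-letter
    species abbreviation (for collision resolution or 3-letter usage).
    """
    if activity == "unknown":
        if u_index is None or u_index < 1:
            raise ValueError("unknown activity requires a positive u_index")
        prefix = f"U{u_index}"
    elif activity in ACTIVITY_PREFIX:
        prefix = ACTIVITY_PREFIX[activity]
    else:
        raise ValueError(f"invalid activity {activity!r}")
    return ToxinName(
        activity_prefix=prefix,
        family=family,
        species_abbrev=abbrev or species_abbreviation(genus, species),
        paralog=paralog,
        isoform=isoform,
        variant=variant,
    )


def parse_name(s: str) -> ToxinName:
    """Parse a rendered name back into components (exact round-trip)."""
    parts = s.split("-")
    if len(parts) != 3:
        raise NameParseError(
            "expected three '-'-separated fields <prefix>-<family>-<tail>",
            len(parts[0]) if parts else 0,
        )
    prefix, family, tail = parts
    if not (prefix in GREEK_PREFIXES or re.fullmatch(r"U[1-9]\d*", prefix)):
        raise NameParseError(f"invalid activity prefix {prefix!r}", 0)
    if not re.fullmatch(r"[A-Za-z]+", family):
        raise NameParseError(f"invalid family {family!r}", len(prefix) + 1)
    m = _TAIL_RE.fullmatch(tail)
    if not m:
        raise NameParseError(
            f"invalid tail {tail!r} (expected e.g. Pv3a or Pv1b_1)",
            len(prefix) + len(family) + 2,
        )
    return ToxinName(
        activity_prefix=prefix,
        family=family,
        species_abbrev=m.group("abbrev"),
        paralog=int(m.group("paralog")),
        isoform=m.group("isoform"),
        variant=int(m.group("variant")) if m.group("variant") else None,
    )
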