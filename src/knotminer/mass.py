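"""Peptide masses, PTM deltas, MALDI matching and amidation pairs.

All masses are in daltons. Monoisotopic is the default and matches how
intact venom peptide masses are reported from MALDI-TOF in reflector
mode; an average-mass mode is provided for older instrument lists.

The modification model covers what venom peptidomics needs day to day:
disulfide formation (−2 H per bond), cysteine carbamidomethylation from
iodoacetamide treatment (+57.02146), C-terminal amidation (−0.98402, the
~1 Da shift that distinguishes amide from acid forms) and methionine
oxidation (+15.99491).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

# --- constants (monoisotopic, Da) ------------------------------------------
WATER_MONO = 18.0105646863
WATER_AVG = 18.01528
PROTON = 1.007276
HYDROGEN_MONO = 1.0078250319

CARBAMIDOMETHYL = 57.02146
C_TERMINAL_AMIDE = -0.98402
MET_OXIDATION = 15.99491
DISULFIDE = -2.0 * HYDROGEN_MONO  # per bond: loss of two hydrogens

#: Monoisotopic residue masses (peptide-bonded residues, Da), from the
#: standard atomic masses (H 1.00782503, C 12 exact, N 14.00307401,
#: O 15.99491462, S 31.97207100).
RESIDUE_MONO = {
    "G": 57.02146372, "A": 71.03711379, "S": 87.03202841, "P": 97.05276385,
    "V": 99.06841392, "T": 101.04767847, "C": 103.00918448, "L": 113.08406398,
    "I": 113.08406398, "N": 114.04292744, "D": 115.02694302, "Q": 128.05857751,
    "K": 128.09496302, "E": 129.04259309, "M": 131.04048461, "H": 137.05891186,
    "F": 147.06841391, "R": 156.10111102, "Y": 163.06332853, "W": 186.07931295,
}

#: Average residue masses (Da).
RESIDUE_AVG = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}


@dataclass
class ModificationSet:
    """Counts of mass-shifting modifications applied to one peptide."""

    disulfides: int = 0
    carbamidomethyl_cys: int = 0
    c_terminal_amide: bool = False
    met_oxidation: int = 0

    def validate(self, seq: str) -> None:
        if min(self.disulfides, self.carbamidomethyl_cys, self.met_oxidation) < 0:
            raise ValueError("modification counts must be >= 0")
        n_cys = seq.count("C")
        if self.disulfides > n_cys // 2:
            raise ValueError(
                f"{self.disulfides} disulfides impossible with {n_cys} cysteines"
            )
        if 2 * self.disulfides + self.carbamidomethyl_cys > n_cys:
            raise ValueError("disulfide + carbamidomethyl cysteines exceed total")
        if self.met_oxidation > seq.count("M"):
            raise ValueError("more oxidations than methionines")

    @property
    def delta(self) -> float:
        return (
            self.disulfides * DISULFIDE
            + self.carbamidomethyl_cys * CARBAMIDOMETHYL
            + (C_TERMINAL_AMIDE if self.c_terminal_amide else 0.0)
            + self.met_oxidation * MET_OXIDATION
        )


@dataclass
class ObservedMass:
    """One neutral mass from a MALDI list, tagged by HPLC fraction."""

    fraction_id: str
    neutral_mass: float
    intensity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError("neutral mass must be positive")


@dataclass
class MassMatch:
    peptide_ref: str
    observed_ref: ObservedMass
    mod_set: ModificationSet
    theoretical: float
    delta: float  # observed - theoretical


@dataclass
class AmidationPair:
    heavy: ObservedMass  # acid form (heavier)
    light: ObservedMass  # amide form (lighter by ~0.984 Da)
    delta: float  # heavy - light, raw
    rounded_delta: int


def peptide_mass(
    seq: str, mods: ModificationSet | None = None, mode: str = "mono"
) -> float:
    """Neutral peptide mass: residue sum + water + modification deltas."""
    if not seq:
        raise ValueError("empty peptide sequence")
    table = RESIDUE_MONO if mode == "mono" else RESIDUE_AVG
    if mode not in ("mono", "average"):
        raise ValueError(f"unknown mass mode {mode!r}")
    try:
        total = sum(table[a] for a in seq)
    except KeyError as exc:
        raise ValueError(f"illegal residue {exc.args[0]!r} in {seq!r}") from None
    total += WATER_MONO if mode == "mono" else WATER_AVG
    if mods is not None:
        mods.validate(seq)
        total += mods.delta
    return total


def oxidized_mods(seq: str, amide: bool = False) -> ModificationSet:
    """The "all cysteines oxidized" state: floor(n_cys/2) disulfide bonds.

    Odd cysteine counts floor the bond number, leaving one free cysteine
    (flagged elsewhere); this is how intact venom peptide masses are
    normally quoted.
    """
    return ModificationSet(disulfides=seq.count("C") // 2, c_terminal_amide=amide)


def mz(neutral_mass: float, z: int) -> float:
    """m/z of the [M + zH]^z+ ion."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    if not isinstance(z, int) or z < 1:
        raise ValueError("charge must be a positive integer")
    return (neutral_mass + z * PROTON) / z


def match_masses(
    candidates: Sequence[tuple[str, str, Sequence[ModificationSet]]],
    observed: Sequence[ObservedMass],
    tol: float = 0.5,
    mode: str = "mono",
) -> list[MassMatch]:
    """All (candidate, mod set, observation) matches within ``tol`` Da.

    ``candidates`` holds (peptide_ref, sequence, allowed mod sets).
    Matches are returned sorted by |delta|, stable within ties.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    matches = []
    for ref, seq, mod_sets in candidates:
        for mods in mod_sets:
            theoretical = peptide_mass(seq, mods, mode=mode)
            for obs in observed:
                delta = obs.neutral_mass - theoretical
                if abs(delta) <= tol:
                    matches.append(MassMatch(ref, obs, mods, theoretical, delta))
    matches.sort(key=lambda m: abs(m.delta))
    return matches


def detect_amidation_pairs(
    observed: Sequence[ObservedMass], pair_tol: float = 0.05
) -> list[AmidationPair]:
    """Find acid/amide mass pairs across fractions.

    Two observations pair when their mass difference sits within
    ``pair_tol`` of the amidation delta 0.98402 Da — the "approximately
    1 Da" signature of a C-terminal amide next to its acid form. Both
    the raw and integer-rounded difference are reported. Symmetric in
    input order.
    """
    if pair_tol <= 0:
        raise ValueError("pair tolerance must be positive")
    ordered = sorted(observed, key=lambda o: o.neutral_mass)
    pairs = []
    for i, light in enumerate(ordered):
        for heavy in ordered[i + 1 :]:
            delta = heavy.neutral_mass - light.neutral_mass
            if delta - (-C_TERMINAL_AMIDE) > pair_tol:
                break
            if abs(delta - (-C_TERMINAL_AMIDE)) <= pair_tol:
                pairs.append(AmidationPair(heavy, light, delta, round(delta)))
    return pairs


def read_mass_csv(path) -> list[ObservedMass]:
    """Read a MALDI mass list: columns fraction_id, neutral_mass[, intensity]."""
    df = pd.read_csv(path)
    required = {"fraction_id", "neutral_mass"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    has_intensity = "intensity" in df.columns
    return [
        ObservedMass(
            fraction_id=str(row.fraction_id),
            neutral_mass=float(row.neutral_mass),
            intensity=float(row.intensity) if has_intensity else None,
        )
        for row in df.itertuples()
    ]


def write_mass_csv(observed: Iterable[ObservedMass], path) -> None:
    rows = [
        {
            "fraction_id": o.fraction_id,
            "neutral_mass": round(o.neutral_mass, 5),
            "intensity": o.intensity,
        }
        for o in observed
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
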