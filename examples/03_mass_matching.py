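"""Intact-mass interpretation: oxidized masses, m/z and amidation pairs.

Computes theoretical masses of a mature peptide under its fully oxidized
acid and amide forms, matches them against a MALDI-style neutral-mass
list and scans the list for ~1 Da amide/acid pairs.
"""

from knotminer import (
    ObservedMass,
    detect_amidation_pairs,
    match_masses,
    mz,
    oxidized_mods,
    peptide_mass,
)

mature = "IFECVFSCDIEKEGKPCKPKGDKSAAAAAAAA"
acid = peptide_mass(mature, oxidized_mods(mature))
amide = peptide_mass(mature, oxidized_mods(mature, amide=True))
print(f"mature peptide ({len(mature)} aa, {mature.count('C')} Cys)")
print(f"  oxidized acid form : {acid:10.4f} Da   [M+H]+ m/z {mz(acid, 1):.4f}")
print(f"  oxidized amide form: {amide:10.4f} Da   (delta {amide - acid:+.5f})")

# a mass list as MALDI-TOF would report it, one fraction per peak set
observed = [
    ObservedMass("F21", amide),           # the native amidated toxin
    ObservedMass("F25", acid),            # its acid form in a later fraction
    ObservedMass("F21", 3399.40),         # unrelated co-eluting peptide
]
matches = match_masses(
    [("tox1", mature, [oxidized_mods(mature), oxidized_mods(mature, amide=True)])],
    observed,
    tol=0.5,
)
print(f"\n{len(matches)} mass match(es) at 0.5 Da:")
for m in matches:
    form = "amide" if m.mod_set.c_terminal_amide else "acid"
    print(f"  {m.peptide_ref} ({form}) vs {m.observed_ref.fraction_id}: "
          f"delta {m.delta:+.4f} Da")

pairs = detect_amidation_pairs(observed, pair_tol=0.05)
print(f"\n{len(pairs)} amide/acid pair(s): the ~1 Da spacing flags a "
      f"C-terminally amidated toxin next to its acid form")
for p in pairs:
    print(f"  {p.light.neutral_mass:.2f} / {p.heavy.neutral_mass:.2f} Da "
          f"-> delta {p.delta:.5f} (rounds to {p.rounded_delta} Da)")
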