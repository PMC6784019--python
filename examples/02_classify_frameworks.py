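"""Cysteine frameworks and superfamily classification.

Extracts the canonical cysteine pattern of a few mature peptides,
assigns each to a superfamily and validates a curated disulfide
connectivity against the framework.
"""

from knotminer import (
    classify_superfamily,
    cluster_frameworks,
    extract_framework,
    load_superfamily_definitions,
    match_signature,
    validate_connectivity,
)
from knotminer.signatures import builtin_signature

defs = load_superfamily_definitions()

peptides = {
    "pep1": "GIFECVFSCDIEKEGKPCCKPKG",          # C-C-CC doublet cluster
    "pep2": "ACAEFCGHICCKLMCAAA",               # C-C-CC-C (five cysteines)
    "pep3": "ACAECAGICAKCCLMCAAQ",              # C-C-C-CC-C (six cysteines)
    "pep4": "AAAA",                             # no cysteines
}
for name, seq in peptides.items():
    fw = extract_framework(seq, peptide_ref=name)
    cls = classify_superfamily(fw, defs)
    print(f"{name}: pattern={fw.canonical or '(none)'}  n_cys={fw.n_cys}  "
          f"superfamily={cls.superfamily}")

groups = cluster_frameworks(
    [extract_framework(s, n) for n, s in peptides.items() if "C" in s]
)
print(f"\n{len(groups)} distinct pattern cluster(s):", sorted(groups))

# Curated connectivity: five cysteines, bridges II-III and IV-V, Cys I free
result = validate_connectivity(5, [(2, 3), (4, 5)])
print(f"\nconnectivity II-III, IV-V on 5 cysteines: valid={result.valid}, "
      f"free cysteines={result.free}")

# Domain signature: the invertebrate-cytokine motif with one residue
# alternation, matched against a peptide carrying it
m = match_signature("KKGAARYSAPACDE", builtin_signature("GX2RYS-motif"))
print(f"GX2RYSX(P/R/A)XC motif found: {m.matched} at span {m.span}")
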