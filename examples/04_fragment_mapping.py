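"""Mapping de novo MS/MS fragments onto a precursor database.

Aligns four tryptic fragment sequences (with the I/L and 'X' ambiguities
typical of de novo sequencing) against precursor proteins, labels the
matched region and computes mature-peptide coverage.
"""

from knotminer import MsmsFragment, compute_coverage, search_fragments
from knotminer.precursor import Precursor

precursor = Precursor(
    orf_ref="c7142",
    signal="MKTLVLVAVLGLALA",
    propeptide="SEDIKLCLKIAEEER",
    mature="IFECVFSCDIEKEGKPCKPKGDKSAAAAAAAA",
    signal_score=3.0,
    cleavage_rule="PQM",
)
decoy = Precursor(
    orf_ref="dec1", signal="", propeptide="",
    mature="MQNQNQNQNQNQNQNQNQNQN", signal_score=0.0,
    cleavage_rule="fallback", flags=["no_signal"],
)

fragments = [
    MsmsFragment("a-b_1", "IKLCLKI", 444.36, 2, flank_n="K"),
    MsmsFragment("a-b_2", "IFECVFSCDIEK", 773.98, 2, flank_c="E"),
    MsmsFragment("a-b_3", "IFECVFSCDIEKEGKPCKPK", 618.64, 4, flank_c="G"),
    MsmsFragment("c_1", "CVFSCDXEK", 579.10, 2),  # X = unassigned residue
]

hits = search_fragments(fragments, [decoy, precursor], min_score=25.0)
best_per_fragment = []
for frag in fragments:
    top = hits[frag.id][0]
    best_per_fragment.append(top)
    print(f"{frag.id:6s} {frag.dot_notation:26s} -> {top.target_ref} "
          f"[{top.region}] span {top.target_span} "
          f"identity {top.percent_identity:.0f}%")

mature_hits = [m for m in best_per_fragment if m.mature_span]
coverage = compute_coverage(mature_hits, len(precursor.mature))
print(f"\nmature-peptide coverage from {len(mature_hits)} fragment(s): "
      f"{coverage:.1f}% (reported as {round(coverage)}%)")
# The X position aligns to any residue at score 0 and is excluded from
# the identity denominator, so CVFSCDXEK still counts as a full match.
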