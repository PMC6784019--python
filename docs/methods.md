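# Methods

`knotminer` infers disulfide-rich toxin precursors from two complementary
inputs — assembled venom-gland transcripts and venom mass-spectrometry
observations — and integrates them into a classified, named toxin
catalogue. This note records the models, the defaults and why they are
what they are, and what the synthetic test bed does and does not show.

## Precursor model

A toxin precursor is modelled as `signal peptide + propeptide + mature
peptide`, with the mature toxin released by two cleavages. Segmentation
is rule based and deterministic:

**Signal peptide.** Two conditions must hold. First, a hydrophobic core:
some 7-residue window inside residues 2–20 must reach a mean
Kyte–Doolittle hydropathy of at least 1.6 (configurable via
`SignalConfig`). Second, an admissible cleavage site: a position in
[10, 35] with small residues (A, G, S, C, T) at −1 and −3, the classic
signal-peptidase preference. Candidate sites are scored as

    score(p) = meanKD(window of 7 ending at p−3) − meanKD(residues p+1, p+2)

i.e. a genuine site sits just downstream of the hydrophobic core and
just upstream of a polar region. A pure upstream-hydropathy score is not
enough: when the hydrophobic stretch itself contains small residues it
admits internal pseudo-sites, and only the downstream term separates the
true C-region boundary (followed by the charged propeptide) from them.
Highest score wins; ties go to the earliest position. Proteins shorter
than 25 residues are rejected as a precondition; proteins with no core
or no admissible site are returned whole as "mature-only" and flagged
`no_signal`.

**Propeptide.** Cleavage occurs after an arginine whose three preceding
residues contain at least one glutamate — the processing quadruplet
motif (PQM) of arachnid toxin precursors. Candidates must lie before the
first cysteine of the post-signal sequence (the mature domain is where
the cysteines live); the *last* such candidate wins, and with none the
propeptide is empty. Both rules are explicit replacements for the
trained predictors normally used for this step; they are transparent,
configurable, and exactly invertible on the synthetic test bed.

The concatenation invariant `signal + propeptide + mature == protein`
holds for every output and is asserted at run time.

## Translation and ORF extraction

Transcripts are translated in all six frames (forward offsets 0/1/2 and
the same on the reverse complement); trailing partial codons are
dropped, stops render as `*`, and any codon containing `N` renders as
`X` — deliberately, even when the ambiguity is resolvable (e.g. GGN),
so that downstream mass computation never silently trusts an uncertain
residue. ORFs are maximal M-to-stop (or M-to-end) segments; within each
stop-delimited stretch the first methionine opens the ORF. The default
minimum ORF length is 40 residues: mature venom peptides of the families
handled here run 43–88 residues plus signal/propeptide, so 40 keeps
every plausible precursor while discarding most frame noise. ORFs
without a stop codon are kept but marked incomplete, both choices being
configuration.

The pipeline does **not** simply take the longest ORF per transcript:
random UTR sequence and out-of-frame readings regularly produce longer
spurious ORFs. Instead every ORF is segmented and the candidate with a
detected signal peptide and the most mature cysteines (ties: longer
protein) represents the transcript. Transcripts whose best candidate has
no signal peptide or fewer than `min_cysteines` (default 4) mature
cysteines are dropped as non-toxin.

## Cysteine frameworks and superfamilies

A framework records the *order and adjacency* of cysteines only:
adjacent cysteines collapse to a doublet token (`CC`), any positive
spacer to `-`. This dialect is exactly what separates the eight shipped
superfamilies — four of them share eight cysteines and differ only in
doublet position. Classification is exact pattern match against the
scheme (shipped as a versioned YAML, user-overridable); length-range
violations warn but never reject; unmatched patterns are `novel`.
Triplets (`CCC`) remain a distinct token and therefore classify as
novel. Disulfide connectivity is stored as curated annotation and only
*validated* (disjoint, in-range, no self-pairs, free cysteines
reported); the package never predicts connectivity.

Domain signatures (WAP four-disulfide core, single-domain von Willebrand
factor type C, astakine cytokine motifs, and the two knottin sub-group
patterns) use a small grammar: literals, `Xk` exact spacers, `Xa/b`
spacer alternation, `Xn` unbounded runs, `(P/R/A)` residue alternation;
whitespace and underscores are ignored. Matching is leftmost-longest via
memoised backtracking. The shipped astakine scheme carries one known
ambiguity in its source material about whether the isoform insert sits
between cysteines 6/7 or 7/8; the signature is stored as written and the
discrepancy is noted here rather than resolved.

Consensus/logo matrices use per-column frequencies over non-gap residues
and Shannon information `log2(20) − H` bits against a uniform
20-residue background (no composition correction — matching the default
behaviour of the common web logo tools).

## Masses and modifications

Monoisotopic residue masses are tabulated from standard atomic masses
(8 decimal places; rounding at 5 decimals accumulates past 1e-4 Da on
50-residue peptides, which is why the table is this precise). Fixed
deltas: water 18.010565, proton 1.007276, disulfide −2 × 1.0078250 per
bond, carbamidomethyl-Cys +57.02146, C-terminal amide −0.98402,
Met-oxidation +15.99491. "All cysteines oxidized" means
`floor(n_cys / 2)` disulfides; odd counts leave a flagged free cysteine.
Average-mass mode exists but monoisotopic is the default everywhere.

Intact-mass matching uses a 0.5 Da MALDI MS1 tolerance by default (a
deliberate, conservative choice for linear-mode style mass lists; the
fragment-level 0.05 Da tolerance belongs to instrument workflows we do
not reproduce and is carried as the default `pair_tol` instead).
Amide/acid pair detection flags any two observations whose mass
difference is within `pair_tol` (default 0.05 Da) of 0.98402 Da,
reporting raw and integer-rounded deltas; detection is symmetric and
order-independent. De novo instrument m/z values in fragment tables are
treated as opaque observations and never validated against the
calculator.

## Fragment mapping

Local alignment is Smith–Waterman with BLOSUM62, affine gaps (gap of
length k costs −10 − k), and two de novo MS-specific semantics:
isobaric I/L are identical by default, and `X` aligns to anything at
score 0 while being excluded from the identity denominator — so
`CVFSCDXEK` is a 100% match to `CVFSCDIEK`. Identity is computed over
aligned non-gap, non-X columns. Because co-optimal alignments can differ
in identity, the sequence pair is canonically oriented before the DP and
mapped back, making `local_align(a, b)` and `local_align(b, a)` return
identical results by construction. The reported identity is *not* the
instrument's match-score column from de novo software, and is documented
as a distinct quantity.

Fragment search aligns every fragment against every database entry
(exhaustive, no heuristic seeding), keeps hits scoring ≥ 25 (about
seven average identities — tuned to admit the short 7–9 residue
fragments real workflows produce while rejecting compositional noise),
and labels the matched region (signal/propeptide/mature/spanning) when
the target is a segmented precursor. Coverage is the union of
mature-coordinate spans over the mature length, ×100; the exact value is
returned and display rounds to whole percent.

## Nomenclature

Names follow the rational convention
`<prefix>-<family>-<abbrev><paralog><isoform>[_<variant>]` with Greek
activity prefixes (ω calcium, μ sodium, κ potassium) and `U<n>` for
unknown activity. The family string is configuration (default
`theraphotoxin`; the alternate spelling `theraphositoxin` is accepted
everywhere). U-number allocation is sequential per catalogue and
user-overridable, since published U-number choices follow no recoverable
rule. Parsing is the exact inverse of rendering; catalogue names are
made unique by advancing isoform letters.

## Synthetic data: what it emulates, what it does not

The generator builds each toxin gene backwards from its superfamily:
mature peptide realizing the canonical pattern at a length drawn from
the superfamily's observed range (surplus residues distributed
multinomially over the spacer slots), propeptide of 9–15 acidic residues
ending in `E-x-x-R`, signal peptide of a lysine, 7–9 strongly
hydrophobic residues, and a small-residue cleavage cassette. Arginine is
excluded from the mature segment before the first cysteine so the
planted PQM stays the last candidate — the generator plants exactly one
consistent truth. Proteins are reverse-translated with uniform
synonymous codons, wrapped in random UTRs (30–150 nt) with an in-frame
stop sealing the 5' junction, and mixed with 10% decoy transcripts
carrying polar N-termini (no signal). Expression is lognormal
(meanlog 3, sdlog 1.5 on counts), length-normalised to TPM summing to
10^6 — spanning roughly five orders of magnitude, as venom-gland
libraries do. Intact-mass lists carry each mature's oxidized acid mass,
plus the amide form for half the genes by default, across 5 fractions;
fragment lists are full tryptic digests (cleave after K/R except before
P, ≤2 missed cleavages, ≥6 residues, carbamidomethyl-Cys) with flanks in
dot notation. One integer seed drives independent generator streams per
stage; identical seeds give identical bytes.

Deliberately **not** emulated: sequencing reads and assembly artefacts
(chimeras, fragmented ORFs), non-toxin secreted proteins (a decoy *with*
a signal peptide would test the cysteine filter, not segmentation),
isobaric de novo sequencing errors beyond I/L, chromatographic
co-elution structure, and intensity models. Passing the planted-truth
tests therefore demonstrates the internal consistency and
invertibility of the pipeline's rules, not performance on real
assemblies, where signal-peptide heuristics and PQM variants are the
known weak points.

## Problem sizes and numerical choices in the test suite

Planted-truth recovery runs at 80 genes with a uniform superfamily mix,
noise-free, matching the conditions the recovery thresholds (≥95%
segmentation, 100% superfamily given segmentation, ≥99% pair detection)
are stated for; the shared integration fixture uses 16 genes.
Alignment correctness is checked two ways: exhaustive alignment-path
enumeration on *all* pairs over a two-letter alphabet up to length 4
(enumeration is exponential, so "all pairs" is only meaningful at tiny
sizes), plus 200–300 seeded random pairs up to length 8 against an
independent aligner under identical scoring. The mass calculator is
checked against elemental-composition masses on 1000 random peptides of
1–50 residues at 1e-4 Da. Floating-point comparisons use exact equality
only where the arithmetic is exact (counts, percentages of integers)
and 1e-9 relative tolerance otherwise.

## Known limitations

* The signal heuristic has no learned component; unusual signal peptides
  (short cores, prolines near the site) will be missed or mis-placed.
* PQM is the only propeptide rule; precursors processed at other motifs
  segment as mature-only or with a wrong boundary.
* Superfamily assignment is exact pattern matching; a single extra or
  missing cysteine sends a peptide to `novel` rather than the nearest
  family.
* Coverage ignores fragment multiplicity and intensity; it is purely
  positional.
* The catalogue assigns all records unknown activity (`U` prefixes);
  pharmacological prefixes require user-supplied activity calls.
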