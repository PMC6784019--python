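# Superfamily scheme for cysteine-rich venom peptides, version 1.
#
# canonical encodes cysteine order and adjacency only (doublets as CC);
# length_range is the observed mature-peptide length span in residues;
# connectivity lists curated disulfide bonds as 1-based cysteine index
# pairs (annotation from validated data, not prediction); where two
# alternative pairings are reported, the second is connectivity_alt.
# free_cysteines lists cysteines not engaged in any bridge.
version: 1
superfamilies:
  - name: SF1
    canonical: C-C-CC-C
    n_cys: 5
    length_range: [54, 54]
    connectivity: [[2, 3], [4, 5]]
    free_cysteines: [1]
  - name: SF2
    canonical: C-C-C-CC-C
    n_cys: 6
    length_range: [48, 48]
    connectivity: [[1, 4], [2, 5], [3, 6]]
  - name: SF3
    canonical: C-C-CC-C-C-C
    n_cys: 7
    length_range: [43, 84]
    connectivity: [[2, 5], [3, 6], [4, 7]]
    free_cysteines: [1]
  - name: SF4
    canonical: C-C-CC-C-C-C-C
    n_cys: 8
    length_range: [44, 74]
    connectivity: [[1, 8], [2, 3], [4, 5], [6, 7]]
    connectivity_alt: [[1, 7], [2, 8], [3, 6], [4, 5]]
    signature: group4a
  - name: SF5
    canonical: C-C-C-CC-C-C-C
    n_cys: 8
    length_range: [61, 65]
    connectivity: [[1, 6], [2, 7], [3, 4], [5, 8]]
  - name: SF6
    canonical: C-C-C-C-CC-C-C
    n_cys: 8
    length_range: [43, 71]
    connectivity: [[1, 6], [2, 7], [3, 5], [4, 8]]
    signature: WAP
  - name: SF7
    canonical: C-C-C-C-C-CC-C
    n_cys: 8
    length_range: [76, 80]
    connectivity: [[1, 5], [2, 6], [3, 7], [4, 8]]
    signature: SVWC
  - name: SF8
    canonical: C-C-CC-C-C-C-C-C-C
    n_cys: 10
    length_range: [67, 88]
    connectivity: [[1, 6], [2, 4], [3, 5], [7, 10], [8, 9]]
    connectivity_alt: [[1, 3], [2, 4], [5, 6], [7, 8], [9, 10]]
    signature: astakine
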