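{
 "version": "1.0",
 "description": "Nine conserved degenerate blocks of the BSP-superfamily tandem-FN2 core. Coordinates are 1-based in the 87-residue core frame anchored at the Block I cysteine. Notation: fixed residue letters, [..] alternative sets, x wildcard, h hydrophobic class.",
 "blocks": [
  {"block_id": "I",    "consensus": "C[AV]FPFxY",        "domain": "FN2_1",  "canonical_start": 1,  "canonical_length": 7},
  {"block_id": "II",   "consensus": "C[ITV]xxxS",        "consensus_bsph1": "C[ITV]xxx[AGST]", "domain": "FN2_1", "canonical_start": 15, "canonical_length": 6},
  {"block_id": "III",  "consensus": "xxWCSL[DN]",        "domain": "FN2_1",  "canonical_start": 22, "canonical_length": 7},
  {"block_id": "IV",   "consensus": "[FY]xG[RY]W[KR][FY]C", "domain": "FN2_1", "canonical_start": 31, "canonical_length": 8},
  {"block_id": "V",    "consensus": "xxD",               "domain": "linker", "canonical_start": 40, "canonical_length": 3},
  {"block_id": "VI",   "consensus": "CxFPFh[FY]",        "domain": "FN2_2",  "canonical_start": 46, "canonical_length": 7},
  {"block_id": "VII",  "consensus": "GTxxG[DESY]",       "domain": "FN2_2",  "canonical_start": 60, "canonical_length": 6},
  {"block_id": "VIII", "consensus": "hxxxWCSL[ST]",      "domain": "FN2_2",  "canonical_start": 67, "canonical_length": 9},
  {"block_id": "IX",   "consensus": "[FY][DN]xDxxW[KR][QY]C", "domain": "FN2_2", "canonical_start": 78, "canonical_length": 10}
 ]
}
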