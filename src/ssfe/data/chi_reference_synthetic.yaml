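# Synthetic stand-in reference profile for a bacterial chalcone-isomerase-like
# enzyme (CHI_era-style numbering). The residue identities at the annotated
# pocket/catalytic positions follow the published CHI_era active-site
# description; the remainder of the sequence is a synthetic filler generated
# once with a fixed RNG and frozen here, so the file is NOT a natural protein
# sequence. It exists so the pipeline, its tests, and the synthetic-family
# generator share one consistent reference-numbering frame.
reference:
  id: CHI_ref
  description: synthetic CHI-like reference scaffold (pocket residues per CHI_era numbering)
  sequence: QCGYPFIWTATICVKGTWVHWKASGWDDIHTMHSYDSWRQFHILMLDYKFWLNRCFHVGPSGHANTKHENTNHHWFANDYKCAYCVKVALERWTTWYRLRQTHLQVYPSRFWHQCMDCSVNNMPRGCGYANVPYFNYATSIWQQRDRVVTNPFCNPMHIKEECRHEIMTM

# Catalytic positions: conservation of these residues is the categorical
# activity signal (His = Michael-addition base; Tyr stabilises the 9=O
# carbonyl of the substrate).
catalytic:
  - {position: 33, residue: H, role: catalytic base}
  - {position: 48, residue: Y, role: carbonyl stabilization}

# Substrate-binding pocket in reference numbering. Roles follow the
# A-ring / B-ring split of the chalcone scaffold; position 47 is flagged
# provisional (implicated only through the D47E variant).
pocket:
  - {position: 12, residue: I, role: A-ring}
  - {position: 14, residue: V, role: A-ring}
  - {position: 29, residue: I, role: A-ring}
  - {position: 33, residue: H, role: catalytic}
  - {position: 37, residue: S, role: B-ring}
  - {position: 40, residue: Q, role: B-ring}
  - {position: 41, residue: F, role: B-ring}
  - {position: 47, residue: D, role: other, provisional: true}
  - {position: 48, residue: Y, role: catalytic}
  - {position: 50, residue: F, role: A-ring}
  - {position: 69, residue: E, role: A-ring}
  - {position: 71, residue: T, role: A-ring}
  - {position: 73, residue: H, role: B-ring}
  - {position: 75, residue: W, role: B-ring}
  - {position: 79, residue: D, role: B-ring}
  - {position: 87, residue: K, role: B-ring}
  - {position: 91, residue: E, role: B-ring}
  - {position: 101, residue: Q, role: A-ring}
  - {position: 122, residue: N, role: B-ring}
  - {position: 125, residue: R, role: B-ring}
  - {position: 135, residue: F, role: A-ring}

# Two ferredoxin-like domains. All annotated pocket positions fall inside
# the catalytic domain; loop-insertion disruption is typically seen in the
# solvent-exposed domain.
domains:
  - {label: catalytic_domain, start: 1, end: 140}
  - {label: solvent_exposed_domain, start: 141, end: 170}
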