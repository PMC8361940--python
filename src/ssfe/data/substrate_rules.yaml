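# Substrate-compatibility hints for chalcone substrates, expressed as rules
# over pocket positions in reference numbering. Each rule may carry several
# alternative condition groups; a group counts only when every one of its
# conditions is met. Weights and thresholds are engineering choices: the
# underlying residue/substrate relationships are categorical observations
# (e.g. a small residue at 79 admits a para-methoxy B-ring), not a fitted
# quantitative model.
substrates:
  # naringenin chalcone: unmodified B-ring with para-OH; the reference
  # pocket (D79 / K87 / N122 / Q40 hydrogen-bond network) is the prototype.
  - id: 1a
    threshold: 1.0
    groups:
      - name: reference_para_oh_network
        conditions:
          - {position: 79, allowed: [D, E], weight: 0.5}
          - {position: 122, allowed: [N, Q, S, T], weight: 0.5}
    disallowed: []

  # eriodictyol chalcone: meta+para-di-OH B-ring; an R at 87 together with
  # E at 47 adds hydrogen bonding to the para-hydroxy group.
  - id: 2a
    threshold: 1.0
    groups:
      - name: reference_like
        conditions:
          - {position: 79, allowed: [D, E], weight: 0.5}
          - {position: 91, allowed: [E, D, Q], weight: 0.5}
      - name: para_oh_hbond_shift
        conditions:
          - {position: 87, allowed: [R], weight: 0.5}
          - {position: 47, allowed: [E], weight: 0.5}
    disallowed: []

  # homoeriodictyol chalcone: meta-methoxy B-ring; tolerated by the
  # reference-like pocket but favoured by the shifted binding mode.
  - id: 3a
    threshold: 1.0
    groups:
      - name: para_oh_hbond_shift
        conditions:
          - {position: 87, allowed: [R], weight: 0.5}
          - {position: 47, allowed: [E], weight: 0.5}
      - name: small_79
        conditions:
          - {position: 79, allowed: [P, I, A, G, S], weight: 1.0}
    disallowed: []

  # hesperetin chalcone: para-methoxy B-ring; needs either a small residue
  # at 79 (less steric hindrance) or the E79 + G125 combination that opens
  # room for the methoxy group.
  - id: 4a
    threshold: 1.0
    groups:
      - name: small_79
        conditions:
          - {position: 79, allowed: [P, I], weight: 1.0}
      - name: e79_g125_room
        conditions:
          - {position: 79, allowed: [E], weight: 0.5}
          - {position: 125, allowed: [G], weight: 0.5}
    disallowed:
      - {position: 79, symbols: [D]}

  # 4-O-methylbutein: para-methoxy B-ring and no 6'-OH anchor; same steric
  # requirement at 79, generally marginal activity.
  - id: 5a
    threshold: 1.0
    groups:
      - name: small_79
        conditions:
          - {position: 79, allowed: [P, I], weight: 1.0}
    disallowed:
      - {position: 79, symbols: [D]}
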