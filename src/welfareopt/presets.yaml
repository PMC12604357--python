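# Named weighting scenarios (coverage, ease of indicator use, impact of
# welfare consequence, ease of hazard mitigation).  The four weights of every
# scenario sum to the same fixed total (8.0) so scenarios are comparable.
scenarios:
  - name: "Priority on coverage"
    comment: "Only optimising coverage"
    w_coverage: 8.0
    w_easiness: 0.0
    w_impact: 0.0
    w_mitigation: 0.0
  - name: "Balanced"
    comment: "Equal weighting to all factors"
    w_coverage: 2.0
    w_easiness: 2.0
    w_impact: 2.0
    w_mitigation: 2.0
  - name: "Priority on ease of indicator use"
    comment: "Favouring indicators that are easy to use"
    w_coverage: 5.0
    w_easiness: 3.0
    w_impact: 0.0
    w_mitigation: 0.0
  - name: "Priority on impact of welfare consequence"
    comment: "Favouring consequences that have a large impact on welfare"
    w_coverage: 5.0
    w_easiness: 0.0
    w_impact: 3.0
    w_mitigation: 0.0
  - name: "Priority on ease of hazard mitigation"
    comment: "Favouring hazards that are easy to mitigate"
    w_coverage: 5.0
    w_easiness: 0.0
    w_impact: 0.0
    w_mitigation: 3.0
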