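# Middle-ear character re-scoring for the second source matrix (no
# multituberculates or haramiyidans; includes Kuehneotherium).
# Polarity as in recoding_ds22.yaml.
dataset: ds21
collapse:
  - character: meckels_groove
    state_map: {0: 0, 1: 0, 2: 1}
    provenance: >-
      Groove collapsed to binary developed vs not developed/vestigial,
      matching the first data set; this also re-codes eutriconodont and
      cladothere "weakly developed" scores as "developed" (group-derived).
overrides:
  - taxon: Hadrocodium
    character: postdentary_trough
    new: 0
    provenance: Juvenile preservation argument; trough present.
  - taxon: Hadrocodium
    character: meckels_groove
    new: 0
    provenance: Groove developed.
  - taxon: Asfaltomylos
    character: postdentary_trough
    new: 0
    provenance: Trough present.
  - taxon: Asfaltomylos
    character: meckels_groove
    new: "?"
    provenance: Dentary damaged in the only specimen; uncertain.
  - taxon: Ausktribosphenos
    character: postdentary_trough
    new: 1
    provenance: Trough absent.
  - taxon: Ausktribosphenos
    character: meckels_groove
    new: 0
    provenance: Groove developed (remnant may be attrition artifact).
  - taxon: Bishops
    character: postdentary_trough
    new: 1
    provenance: Trough absent.
  - taxon: Bishops
    character: meckels_groove
    new: 0
    provenance: Groove developed.
  - taxon: Steropodon
    character: postdentary_trough
    new: 1
    provenance: No clear trough in the holotype; absent (default coding).
  - taxon: Steropodon
    character: meckels_groove
    new: "?"
    provenance: Possible pre-depositional breakage; uncertain.
  - taxon: Teinolophos
    character: postdentary_trough
    new: 1
    provenance: Trough absent.
  - taxon: Teinolophos
    character: meckels_groove
    new: 0
    provenance: Groove developed.
variants:
  steropodon_uncertain:
    - taxon: Steropodon
      character: postdentary_trough
      new: "?"
      provenance: Alternative coding of the Steropodon trough as uncertain.
  ausktribosphenos_uncertain:
    - taxon: Ausktribosphenos
      character: postdentary_trough
      new: "?"
      provenance: Alternative coding of the Ausktribosphenos trough as uncertain.
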