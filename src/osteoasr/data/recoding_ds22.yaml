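# Middle-ear character re-scoring for the first (114-taxon) source matrix.
# Polarity: postdentary_trough 0 = present, 1 = absent;
#           meckels_groove (after collapse) 0 = developed, 1 = not developed/vestigial.
dataset: ds22
collapse:
  - character: meckels_groove
    state_map: {0: 0, 1: 0, 2: 1}
    provenance: >-
      Three-state groove coding collapsed to binary: "weakly developed" is
      indistinguishable from erosion artifacts in imperfect fossils, so it is
      merged with "well developed"; remaining state is "not developed or
      vestigial".
overrides:
  - taxon: Hadrocodium
    character: postdentary_trough
    new: 0
    provenance: >-
      Juvenile specimen with limited preservation of poorly ossified areas;
      trough re-coded as present.
  - taxon: Hadrocodium
    character: meckels_groove
    new: 0
    provenance: Groove re-coded as developed (same preservation argument).
  - taxon: Asfaltomylos
    character: postdentary_trough
    new: 0
    provenance: Trough scored as present.
  - taxon: Asfaltomylos
    character: meckels_groove
    new: "?"
    provenance: >-
      Region of the dentary damaged in the only known specimen; groove
      unobservable, scored uncertain.
  - taxon: Ausktribosphenos
    character: postdentary_trough
    new: 1
    provenance: Trough interpreted as absent (illustrations show no trace).
  - taxon: Ausktribosphenos
    character: meckels_groove
    new: 0
    provenance: >-
      Groove remnant consistent with diagenetic attrition of a developed
      groove (cf. eroded juvenile platypus reconstructions); scored developed.
  - taxon: Bishops
    character: postdentary_trough
    new: 1
    provenance: Trough absent; published illustrations show no trace.
  - taxon: Bishops
    character: meckels_groove
    new: 0
    provenance: Groove considered developed.
  - taxon: Steropodon
    character: postdentary_trough
    new: 1
    provenance: Holotype shows no clear trough; scored absent (default coding).
  - taxon: Steropodon
    character: meckels_groove
    new: "?"
    provenance: >-
      Lingual depression likely pre-depositional breakage; scored uncertain.
  - taxon: Teinolophos
    character: postdentary_trough
    new: 1
    provenance: Trough clearly identifiable where present in other taxa; absent here.
  - taxon: Teinolophos
    character: meckels_groove
    new: 0
    provenance: Groove developed.
  # Group-derived rules: member lists are user configuration (the source
  # matrix's taxon content is not packaged); loader warns when empty.
  - group: euharamiyida_multituberculata_cimolodonta
    taxon: ""
    character: meckels_groove
    new: 1
    provenance: >-
      Group-level re-score to "not developed or vestigial" for euharamiyidans,
      multituberculates and cimolodontans (group-derived; supply members).
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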