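# Recipes for the 7 programmed-cell-death and 8 ferroptosis-related
# metabolic gene lists. Sources refer to set names in a GMT file.
- target_name: ferroptosis
  rule: extract
  sources: [WP_FERROPTOSIS]
  expected_size: 39
  category: pcd
- target_name: apoptosis
  rule: intersect
  sources: [HALLMARK_APOPTOSIS, REACTOME_APOPTOSIS]
  expected_size: 32
  category: pcd
- target_name: autophagy
  rule: intersect
  sources: [WP_AUTOPHAGY, REACTOME_AUTOPHAGY]
  expected_size: 28
  category: pcd
- target_name: necroptosis
  rule: intersect
  sources: [KEGG_NECROPTOSIS, REACTOME_REGULATED_NECROSIS]
  expected_size: 22
  category: pcd
- target_name: pyroptosis
  rule: literature
  sources: [LIT_PYROPTOSIS]
  expected_size: 32
  category: pcd
- target_name: paraptosis
  rule: literature
  sources: [LIT_PARAPTOSIS]
  expected_size: 12
  category: pcd
- target_name: cuproptosis
  rule: literature
  sources: [LIT_CUPROPTOSIS]
  expected_size: 10
  category: pcd
- target_name: fatty_acid_biosynthesis
  rule: literature
  sources: [PATHCARDS_FATTY_ACID_BIOSYNTHESIS]
  expected_size: 22
  category: metabolic
- target_name: glutathione_synthesis
  rule: literature
  sources: [PATHCARDS_GLUTATHIONE_SYNTHESIS]
  expected_size: 16
  category: metabolic
- target_name: iron_metabolism
  rule: literature
  sources: [LIT_IRON_METABOLISM]
  expected_size: 70
  category: metabolic
- target_name: oxidative_phosphorylation
  rule: extract
  sources: [KEGG_OXIDATIVE_PHOSPHORYLATION]
  expected_size: 83
  category: metabolic
- target_name: glycolysis
  rule: literature
  sources: [LIT_GLYCOLYSIS]
  expected_size: 29
  category: metabolic
- target_name: tca_cycle
  rule: intersect
  sources: [PATHCARDS_TCA_CYCLE, KEGG_CITRATE_CYCLE_TCA_CYCLE]
  expected_size: 23
  category: metabolic
- target_name: glutamine_metabolism
  rule: extract
  sources: [GOBP_GLUTAMINE_METABOLIC_PROCESS]
  expected_size: 23
  category: metabolic
- target_name: selenium_metabolism
  rule: literature
  sources: [LIT_SELENIUM_METABOLISM]
  expected_size: 25
  category: metabolic
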