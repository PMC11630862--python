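# Fermentation end-product completeness rules over the enzyme vocabulary.
#
# "default" reproduces the published completeness calls for the three
# enrichment MAGs (ethanol requires only alcohol dehydrogenase; some
# organisms route acetaldehyde through bifunctional or alternative
# enzymes).  "strict_ethanol" is the biochemically conservative
# alternative requiring the full acetaldehyde -> ethanol route.
version: "1"
rulesets:
  default:
    acetate:
      all: ["phosphate acetyl transferase", "acetate kinase"]
    ethanol: "alcohol dehydrogenase"
    lactate:
      any: ["lactate dehydrogenase", "d-lactate dehydrogenase"]
    succinate:
      all:
        - "fumarate hydratase"
        - any:
            - "malate dehydrogenase (quinone)"
            - "malate dehydrogenase (oxaloacetate-decarboxylating)"
            - "malate dehydrogenase (oxaloacetate-decarboxylating) (nadp+)"
    formate:
      all:
        - "formate acetyltransferase (pyruvate-formate lyase)"
        - "pyruvate-formate lyase activating enzyme"
    butyrate:
      all:
        - "acetyl-coa c-acetyltransferase"
        - "3-hydroxybutyryl-coa dehydrogenase"
        - "4-hydroxybutyryl-coa dehydratase"
        - "butyryl-coa dehydrogenase"
        - "phosphotransbutyrylase"
        - "butyrate kinase"
  strict_ethanol:
    acetate:
      all: ["phosphate acetyl transferase", "acetate kinase"]
    ethanol:
      all: ["acetaldehyde dehydrogenase", "alcohol dehydrogenase"]
    lactate:
      any: ["lactate dehydrogenase", "d-lactate dehydrogenase"]
    succinate:
      all:
        - "fumarate hydratase"
        - any:
            - "malate dehydrogenase (quinone)"
            - "malate dehydrogenase (oxaloacetate-decarboxylating)"
            - "malate dehydrogenase (oxaloacetate-decarboxylating) (nadp+)"
    formate:
      all:
        - "formate acetyltransferase (pyruvate-formate lyase)"
        - "pyruvate-formate lyase activating enzyme"
    butyrate:
      all:
        - "acetyl-coa c-acetyltransferase"
        - "3-hydroxybutyryl-coa dehydrogenase"
        - "4-hydroxybutyryl-coa dehydratase"
        - "butyryl-coa dehydrogenase"
        - "phosphotransbutyrylase"
        - "butyrate kinase"
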