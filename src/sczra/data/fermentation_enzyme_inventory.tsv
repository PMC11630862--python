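enzyme	MAG1_C_oceanisediminis	MAG2_L_amygdalina	MAG3_S_epidermidis
phosphate acetyl transferase	+	+	+
acetate kinase	+	+	+
acetaldehyde dehydrogenase	+	+	-
alcohol dehydrogenase	-	+	+
lactate dehydrogenase	+	+	+
d-lactate dehydrogenase	-	-	+
malate dehydrogenase (quinone)	+	-	+
malate dehydrogenase (oxaloacetate-decarboxylating)	+	+	+
malate dehydrogenase (oxaloacetate-decarboxylating) (nadp+)	+	-	+
fumarate hydratase	+	-	+
formate acetyltransferase (pyruvate-formate lyase)	-	+	+
pyruvate-formate lyase activating enzyme	-	+	+
pyruvate-ferredoxin oxidoreductase	-	+	-
acetyl-coa c-acetyltransferase	+	+	+
3-hydroxybutyryl-coa dehydrogenase	+	-	-
4-hydroxybutyryl-coa dehydratase	-	+	-
butyryl-coa dehydrogenase	+	-	-
phosphotransbutyrylase	+	-	-
butyrate kinase	+	+	-
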