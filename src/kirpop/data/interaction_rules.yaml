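# The twelve functional KIR-HLA receptor-ligand pairs scored per
# individual.  A rule is satisfied when the receptor gene is carried (copy
# >= 1, with any allele restriction met) and at least one HLA allele bears
# the required epitope.  The C1C2 rule for KIR2DL2 can contribute one
# interaction per epitope present (C1 and C2), so the per-individual count
# can reach 13.  KIR2DS5 binds C2 only through the *003-*008 allotypes;
# KIR3DL1 rules require an expressed (non-null) 3DL1-lineage allele;
# KIR2DS4 rules require a full-length allotype (default: the *001 group).
rules:
  - name: Bw4A-3DL1
    epitopes: [Bw4-A]
    receptor: KIR3DL1
    polarity: inhibitory
    exclude_null: true
  - name: Bw4B-3DL1
    epitopes: [Bw4-B]
    receptor: KIR3DL1
    polarity: inhibitory
    exclude_null: true
  - name: A3-3DL2
    epitopes: [A3]
    receptor: KIR3DL2
    polarity: inhibitory
  - name: A11-3DL2
    epitopes: [A11]
    receptor: KIR3DL2
    polarity: inhibitory
  - name: A11-2DS4
    epitopes: [A11]
    receptor: KIR2DS4
    polarity: activating
    exclude_null: true
    protein_subset: ["001"]
  - name: C2-2DL1
    epitopes: [C2]
    receptor: KIR2DL1
    polarity: inhibitory
  - name: C1C2-2DL2
    epitopes: [C1, C2]
    receptor: KIR2DL2
    polarity: inhibitory
    count_per_epitope: true
  - name: C1-2DL3
    epitopes: [C1]
    receptor: KIR2DL3
    polarity: inhibitory
  - name: C2-2DS1
    epitopes: [C2]
    receptor: KIR2DS1
    polarity: activating
  - name: C16-2DS2
    epitopes: [C16]
    receptor: KIR2DS2
    polarity: activating
  - name: C2-2DS5
    epitopes: [C2]
    receptor: KIR2DS5
    polarity: activating
    protein_subset: ["003", "004", "005", "006", "007", "008"]
  - name: Csub-2DS4
    epitopes: [C-2DS4-subset]
    receptor: KIR2DS4
    polarity: activating
    exclude_null: true
    protein_subset: ["001"]
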