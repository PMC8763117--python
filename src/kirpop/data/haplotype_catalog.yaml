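# Gene-content definitions of centromeric and telomeric KIR segment
# haplotypes, following the standard cen/tel segment nomenclature.  Each
# entry gives per-locus copies carried by ONE haplotype (loci omitted are
# absent).  The centromeric region spans KIR3DL3..KIR3DP1, the telomeric
# KIR2DL4..KIR3DL2.  Structural variants crossing the region boundary
# (del6 = KIR3DP1-KIR2DL4-KIR3DS1 deletion; ins4 = the reciprocal
# duplication) adjust the 3DP1 copy carried by the paired centromeric
# segment via boundary_adjust.  Users may extend this catalog.
centromeric:
  cA01:
    ab_class: A
    loci: {KIR3DL3: 1, KIR2DL3: 1, KIR2DP1: 1, KIR2DL1: 1, KIR3DP1: 1}
  cA02:
    ab_class: A
    loci: {KIR3DL3: 1, KIR2DL3: 1, KIR2DL1: 1, KIR3DP1: 1}
  cA03:
    ab_class: A
    structural_tag: del-2DL1-3DP1
    loci: {KIR3DL3: 1, KIR2DL3: 1, KIR2DP1: 1}
  cB01:
    ab_class: B
    loci: {KIR3DL3: 1, KIR2DS2: 1, KIR2DL2: 1, KIR2DL5B: 1, KIR2DS3: 1,
           KIR2DP1: 1, KIR2DL1: 1, KIR3DP1: 1}
  cB02:
    ab_class: B
    loci: {KIR3DL3: 1, KIR2DS2: 1, KIR2DL2: 1, KIR3DP1: 1}
  cB03:
    ab_class: B
    loci: {KIR3DL3: 1, KIR2DS2: 1, KIR2DL3: 1, KIR2DP1: 1, KIR2DL1: 1,
           KIR3DP1: 1}
  cB04:
    ab_class: B
    loci: {KIR3DL3: 1, KIR2DS2: 1, KIR2DL2: 1, KIR2DL5B: 1, KIR2DS3: 1,
           KIR3DP1: 1}
telomeric:
  tA01:
    ab_class: A
    loci: {KIR2DL4: 1, KIR3DL1: 1, KIR2DS4: 1, KIR3DL2: 1}
  tA02:
    ab_class: A
    loci: {KIR2DL4: 1, KIR3DL1: 1, KIR3DL2: 1}
  tB01:
    ab_class: B
    loci: {KIR2DL4: 1, KIR3DS1: 1, KIR2DL5A: 1, KIR2DS5: 1, KIR2DS1: 1,
           KIR3DL2: 1}
  tB02:
    ab_class: B
    loci: {KIR2DL4: 1, KIR3DL1: 1, KIR2DL5A: 1, KIR2DS5: 1, KIR2DS1: 1,
           KIR3DL2: 1}
  tB03:
    ab_class: B
    loci: {KIR2DL4: 1, KIR3DS1: 1, KIR2DS4: 1, KIR3DL2: 1}
  tB04:
    ab_class: B
    loci: {KIR2DL4: 1, KIR3DL1: 1, KIR2DL5A: 1, KIR2DS5: 1, KIR2DS4: 1,
           KIR3DL2: 1}
  tB05:
    ab_class: B
    loci: {KIR2DL4: 1, KIR3DS1: 1, KIR2DL5A: 1, KIR2DS5: 1, KIR2DS4: 1,
           KIR3DL2: 1}
  tB06:
    ab_class: B
    loci: {KIR2DL4: 1, KIR3DL1: 1, KIR3DS1: 1, KIR2DL5A: 1, KIR2DS5: 1,
           KIR2DS1: 1, KIR2DS4: 1, KIR3DL2: 1}
  tB07:
    ab_class: B
    structural_tag: del-3DL2
    loci: {KIR2DS1: 1, KIR2DS4: 1}
  tB01-del6:
    ab_class: B
    structural_tag: del6
    boundary_adjust: {KIR3DP1: -1}
    loci: {KIR2DL5A: 1, KIR2DS5: 1, KIR2DS1: 1, KIR3DL2: 1}
  tA01-ins4:
    ab_class: B
    structural_tag: ins4
    boundary_adjust: {KIR3DP1: 1}
    loci: {KIR2DL4: 2, KIR3DL1: 1, KIR3DS1: 1, KIR2DS4: 1, KIR3DL2: 1}
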