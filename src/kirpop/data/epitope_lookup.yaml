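# HLA class I -> KIR-epitope lookup, keyed by allele family (first field)
# with two-field overrides.  HLA-C alleles carry C1 or C2 after the
# position-80 dimorphism (Asn -> C1, Lys -> C2); C*16 additionally carries
# the C16 epitope engaged by KIR2DS2; Bw4 is carried by some HLA-A and
# HLA-B families; A3/A11 only by HLA-A*03/A*11.  The c_2ds4_subset lists
# the six HLA-C alleles recognized by full-length KIR2DS4.
hla_c_families:
  "C*01": C1
  "C*03": C1
  "C*07": C1
  "C*08": C1
  "C*12": C1
  "C*14": C1
  "C*16": C1
  "C*02": C2
  "C*04": C2
  "C*05": C2
  "C*06": C2
  "C*15": C2
  "C*17": C2
  "C*18": C2
hla_c_overrides:
  "C*16:02": C2
hla_b_bw4_families:
  ["B*13", "B*27", "B*37", "B*38", "B*44", "B*47", "B*49",
   "B*51", "B*52", "B*53", "B*57", "B*58", "B*59"]
hla_b_overrides:
  "B*27:08": none
hla_a_bw4_families: ["A*23", "A*24", "A*25", "A*32"]
c16_families: ["C*16"]
c_2ds4_subset:
  ["C*05:01", "C*02:02", "C*04:01", "C*16:01", "C*01:02", "C*14:02"]
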