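# Domain-combination rules defining the 11 ubiquitin-26S proteasome system
# (UPS) gene families.  A protein belongs to a family when ALL domains of at
# least one combination are present among its domain hits (E-value-filtered);
# `excluded` domains are removed from the protein's domain set before
# matching that family.  `priority` resolves proteins matching several
# families (rarer, multi-domain-defined families first).  Domain names track
# Pfam and are deliberately editable: the RING list in particular is a
# Pfam-version-dependent set of RING-type zinc-finger families predicted to
# act as E3 ligases, with the sporadic bacterial Prok-RING_4 excluded.
priority: [Cullin, APC, RP, CP, E1, HECT, E2, Skp1, FBX, RING, BTB]
families:
  Cullin:
    combinations:
      - [Cullin, Cullin_Nedd8]
  APC:
    combinations:
      - [Apc1]
      - [Apc2]
      - [Apc3]
      - [Apc4]
      - [Apc5]
      - [Apc8]
      - [Apc10]
      - [ANAPC4_WD40]
  RP:
    combinations:
      - [Pro_isomerase]
      - [Prot_ATP_ID_OB]
      - [RPN1_RON2_N]
      - [RPN2_C]
      - [Rpn3_C, PCI]
      - [RPN5_C, PCI]
      - [RPN6_N, PCI]
      - [RPN7, PCI]
      - [YfdX, PCI]
      - [MitMem_reg, Peptidase_M13_N]
      - [VWA_2, UIM]
  CP:
    combinations:
      - [Proteasome]
  E1:
    combinations:
      - [ThiF]
  HECT:
    combinations:
      - [HECT]
  E2:
    combinations:
      - [UQ_con]
  Skp1:
    combinations:
      - [Skp1]
      - [Skp1_POZ]
  FBX:
    combinations:
      - [F-box]
      - [F-box-like]
  RING:
    combinations:
      - [zf-C3HC4]
      - [zf-C3HC4_2]
      - [zf-C3HC4_3]
      - [zf-C3HC4_4]
      - [zf-RING_2]
      - [zf-RING_5]
      - [zf-RING_UBOX]
      - [zf-rbx1]
      - [RINGv]
    excluded: [Prok-RING_4]
  BTB:
    combinations:
      - [BTB]
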