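# Unified 4-site mapping for a Martini 2.2 POPC bilayer: one bead per site.
ff_name: martini22
resolution: CG
lipid_selector: resname POPC
sites:
  HEAD: [NC3]
  PHOS: [PO4]
  TAIL1: [C4A]
  TAIL2: [C4B]
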