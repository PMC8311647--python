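# All-atom example: sites are centers of mass of atom groups. PHOS covers the
# five phosphate-group atoms; the tails use the terminal-carbon groups that
# correspond to the last CG bead of each chain.
ff_name: charmm36
resolution: AA
lipid_selector: resname POPC
sites:
  HEAD: [N, C13, C14, C15, C12, C11]
  PHOS: [P, O11, O12, O13, O14]
  TAIL1: [C216, C217, C218]
  TAIL2: [C314, C315, C316]
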