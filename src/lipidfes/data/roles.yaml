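# Atom-role table (CHARMM36 atom-name dialect).
# Roles drive every contact definition: hydrophobic_carbon feeds the
# lipid-lipid and lipid-protein contact counts and the transport reaction
# coordinate; phosphate defines headgroup positions for leaflets, thickness
# and area per lipid; anchors/tails define tail-orientation vectors and the
# acyl order parameter.  Name ranges like C23-C216 expand over the numeric
# part.  Users may ship their own table for other dialects (e.g. synthetic
# bead fixtures register P/C2/T* names).
residues:
  POPC:
    phosphate: [P]
    hydrophobic_carbon: [C23-C216, C33-C316]
    anchor: C2
    tails:
      - [C22-C218]   # sn-2 oleoyl
      - [C32-C316]   # sn-1 palmitoyl
  C1P:
    phosphate: [P]
    hydrophobic_carbon: [C3F-C16F, C5S-C18S]
    anchor: C2S
    tails:
      - [C2F-C16F]   # N-acyl (16:0)
      - [C4S-C18S]   # sphingoid
    # heavy atoms counted as "headgroup + sphingoid backbone" for the
    # polar class of native-contact pairs (configurable default)
    headgroup_backbone: [P, O11, O12, O13, O14, C1S, C2S, C3S, NF, OF]
protein:
  hydrophobic_residues: [ALA, ILE, LEU, MET, PHE, TRP, VAL, PRO, CYS]
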