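# FPR dioxopiperazine combinatorial library: base scaffold with four anchor
# positions and the published substituent lists (5, 8, 9 and 17 entries),
# coded A.. per position.  Fragment SMILES are kept exactly as published,
# including name/SMILES mismatches (the [R] marker is the attachment atom,
# so e.g. "propyl" = CC[R] is marker carbon + two carbons); the optional
# repairs section can override any fragment by ANCHOR/CODE key.
#
# The base scaffold is a transcription of the published drawing (the figure
# itself is not machine-readable): a 2,5-diketopiperazine carrying R1/R2 on
# its carbons, linked through a pyrrolidine to a piperazine carrying R3/R4
# on its nitrogens.
scaffold:
  smiles: "O=C1NC([R2])C(=O)N(C1[R1])CC2CCCN2CC3CN([R4])CCN3[R3]"
  anchors: [R1, R2, R3, R4]

substituents:
  R1:
    - {code: A, name: 2-naphthylmethyl, smiles: "[R]C1=CC2=CC=CC=C2C=C1"}
    - {code: B, name: propyl, smiles: "CC[R]"}
    - {code: C, name: isopropyl, smiles: "[R](C)(C)"}
    - {code: D, name: butyl, smiles: "[R]CCC"}
    - {code: E, name: benzyl, smiles: "[R]C1=CC=CC=C1"}
  R2:
    - {code: A, name: 4-hydroxybenzyl, smiles: "OC1=CC=C(C=C1)[R]"}
    - {code: B, name: 2-naphthylmethyl, smiles: "[R]C1=CC2=CC=CC=C2C=C1"}
    - {code: C, name: cyclohexyl, smiles: "C1CCCCC1[R]"}
    - {code: D, name: propyl, smiles: "CC[R]"}
    - {code: E, name: hydroxymethyl, smiles: "O[R]"}
    - {code: F, name: butyl, smiles: "[R]CCC"}
    - {code: G, name: benzyl, smiles: "[R]C1=CC=CC=C1"}
    - {code: H, name: isobutyl, smiles: "CC(C)[R]"}
  R3:
    - {code: A, name: benzyl, smiles: "[R]C1=CC=CC=C1"}
    - {code: B, name: 4-hydroxybenzyl, smiles: "OC1=CC=C(C=C1)[R]"}
    - {code: C, name: butyl, smiles: "[R]CCC"}
    - {code: D, name: propyl, smiles: "CC[R]"}
    # published as "S-phenyl" with SMILES [R]1=CC=CC=C1: under the
    # marker-as-atom semantics this parses to plain phenyl (marker = ring
    # carbon), which contradicts the name; the repairs section below carries
    # the sulfur-attached alternative.
    - {code: E, name: S-phenyl, smiles: "[R]1=CC=CC=C1"}
    - {code: F, name: butyl, smiles: "[R]CCC"}
    - {code: G, name: cyclohexyl, smiles: "C1CCCCC1[R]"}
    - {code: H, name: benzyl, smiles: "[R]C1=CC=CC=C1"}
    - {code: I, name: propyl, smiles: "CC[R]"}
  R4:
    - {code: A, name: 4-methyl-1-cyclohexyl-methyl, smiles: "[R]C1CCC(C)CC1"}
    - {code: B, name: cyclohexylpropyl, smiles: "[R]CCC1CCCCC1"}
    - {code: C, name: cyclohexylmethyl, smiles: "[R]C1CCCCC1"}
    - {code: D, name: cyclopentylmethyl, smiles: "[R]C1CCCC1"}
    - {code: E, name: cycloheptylmethyl, smiles: "[R]C1CCCCCC1"}
    - {code: F, name: cyclobutylmethyl, smiles: "[R]C1CCC1"}
    - {code: G, name: 3-methylpentyl, smiles: "[R]CC(C)CC"}
    - {code: H, name: 2-biphenyl-4-yl-ethyl, smiles: "[R]CC(C=C1)=CC=C1C2=CC=CC=C2"}
    - {code: I, name: 4-tert-butyl-cyclohexylmethyl, smiles: "[R]C1CCC(C(C)(C)C)CC1"}
    - {code: J, name: 2-(3-methoxyphenyl)-ethyl, smiles: "[R]CC1=CC(OC)=CC=C1"}
    - {code: K, name: 2-(4-isobutylphenyl)-propyl, smiles: "[R]C(C1=CC=C(CC(C)C)C=C1)C"}
    - {code: L, name: m-tolylethyl, smiles: "[R]CC1=CC(C)=CC=C1"}
    - {code: M, name: p-tolylethyl, smiles: "[R]CC1=CC=C(C)C=C1"}
    - {code: N, name: 2-(4-methoxyphenyl)-ethyl, smiles: "[R]CC1=CC=C(OC)C=C1"}
    - {code: O, name: 2-(4-ethoxyphenyl)-ethyl, smiles: "[R]CC1=CC=C(OCC)C=C1"}
    - {code: P, name: phenethyl, smiles: "[R]CC1=CC=CC=C1"}
    - {code: Q, name: 3-(3,4-dimethoxyphenyl)-propyl, smiles: "[R]CCC1=CC=C(OC)C(OC)=C1"}

# Optional fragment overrides, applied only when requested
# (load_library_spec(..., apply_repairs=True)).
repairs:
  "R3/E":
    name: S-phenyl (sulfur-attached repair)
    smiles: "[R]C1=CC=CC=C1"
    anchor_element: S
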