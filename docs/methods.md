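# Methods

This note records the models and procedures implemented in `topoqsar`, the
conventions chosen where the literature admits more than one definition, and
the known limitations of each choice.

## Molecular graph model

Molecules are hydrogen-suppressed graphs: heavy atoms are vertices, bonds
are edges, and every edge counts as length 1 for distance-based descriptors
regardless of bond order. SMILES parsing, aromaticity perception and
canonicalisation are delegated to RDKit; explicit hydrogens in the input are
folded into the per-atom hydrogen count. Each atom carries two Kier–Hall
degrees: the simple degree δ (heavy-atom neighbour count, equal to its
adjacency row sum) and the valence degree δᵛ = Zv − h for second-period
elements or (Zv − h)/(Z − Zv − 1) beyond (so δᵛ(O in OH) = 5,
δᵛ(S in a thioether) = 6/9). Charged or isotopic atoms are accepted with the
neutral-element valence-electron count and a logged warning; the packaged
library is neutral throughout. Multi-fragment (dot-disconnected) input is
rejected, since every descriptor here assumes a connected graph. Aromatic
and Kekulé renderings of the same molecule yield identical descriptor
values; this is asserted by tests rather than assumed.

## Graph primitives

**Distances.** All-pairs BFS (unit edge weights).

**Detours.** The detour distance Δ_ij (longest simple path) is NP-hard in
general; it is additive across cut vertices, so the implementation
decomposes the graph into biconnected components, runs exhaustive DFS only
inside each component, and sums contributions along the unique block path of
the block–cut tree. A component larger than 30 atoms (configurable; far
above any ring system in the packaged library, whose largest block is the
10-atom naphthalene unit) raises an explicit "detour intractable" error
instead of hanging.

**Subgraph enumeration.** Connected m-edge subgraphs (m ≤ 4) are enumerated
once each with Wernicke's ESU algorithm applied to the line graph, then
typed by their internal degree sequence: *path* if every subgraph vertex has
degree ≤ 2, *cluster* if some vertex has degree ≥ 3 and none has degree 2,
*path-cluster* otherwise. These three kinds partition all connected
edge-subgraphs; ring-containing subgraphs therefore land in path or
path-cluster by their degrees, and no separate ring/chain subtype is
computed. Order 0 "subgraphs" are the single vertices.

## Descriptor definitions

- **^mχ_t** = Σ over subgraphs of order m and type t of
  Π_{vertices} (δ\*)^(−1/2), with δ\* = δ or δᵛ. If an order/type has no
  subgraphs the index is 0.
- **C^mχ_t, D^mχ_t**: the quotient and difference of the simple and valence
  index of the same order/type. Default orientation: C = χ/χᵛ,
  D = χ − χᵛ. Neither orientation is written out in the source literature,
  so both are first-class toggles; a 0/0 quotient is reported as NaN
  ("undefined"), never silently 0.
- **G_k, J_k**: with A the unit adjacency matrix and Q the
  reciprocal-square-distance matrix (zero diagonal), M = A·Q and
  c_ij = m_ij − m_ji; G_k = Σ_{i<j} |c_ij| over pairs at distance k and
  J_k = G_k/(n−1). The adjacency is unweighted (no valence variant).
  GGI10 ≡ G_10.
- **W** = Σ_{i<j} d_ij; **V_k** = number of vertices of degree k; ring count
  is the cyclomatic number.
- **ww** = ½ Σ_{i<j} (Δ_ij + Δ_ij²); on acyclic graphs this equals the
  hyper-Wiener half-sum over plain distances.
- **MAXDN**: intrinsic states I_i = ((2/L_i)²·δᵛ_i + 1)/δ_i, field
  perturbations ΔI_i = Σ_j (I_i − I_j)/(d_ij + 1)² (pairwise antisymmetric,
  summing to zero); MAXDN = max(−ΔI_i) over atoms with ΔI_i < 0, else 0.
- **BELm5**: fifth-smallest eigenvalue of the Burden matrix with diagonal
  mass_i/mass_C; off-diagonal 0.1 × bond order (aromatic 1.5) for bonded
  pairs, +0.01 when either atom is terminal, and 0.001 for non-bonded pairs.
  The exact variant used by proprietary descriptor software is undocumented,
  so a "plain" variant without the terminal increment is provided as a
  second documented convention. Rank > n atoms is undefined (NaN).
- **VEA1**: sum of components of the unit-norm adjacency principal
  eigenvector, sign fixed non-negative (guaranteed consistent by
  Perron–Frobenius on connected graphs).

## Library construction

A substituent fragment's `[R]` marker **is the attachment atom** (default: a
carbon; configurable per fragment via `anchor_element`). This reading is
forced by the packaged fragment set itself: "propyl" is written `CC[R]` (two
carbons plus the marker), "benzyl" is `[R]C1=CC=CC=C1` (the marker is the
benzylic CH₂), and "isopropyl" is `[R](C)(C)` where the marker has two
neighbours and could not be a removable placeholder. The alternative
placeholder semantics (marker deleted, its two neighbourhoods bonded
directly) is available as a toggle for fragment sets written that way.
Attachment bonds are single; assembly is RDKit graph editing followed by
sanitisation, so valence violations surface as per-molecule assembly errors
naming the anchor, and emitted canonical SMILES have freshly numbered ring
closures. Enumeration order is documented: first anchor varies slowest.

Fragments are used exactly as published, including name/SMILES mismatches
(e.g. the "cyclohexyl" fragment that is structurally cyclohexylmethyl under
the marker convention); mismatches are data, not errors. The "S-phenyl"
fragment, printed as `[R]1=CC=CC=C1`, parses under the marker convention to
a directly attached phenyl; a sulfur-attached repair (`anchor_element: S`)
ships in the config's repair table and is part of the screening sweep,
affecting the 680 library molecules using that fragment.

**Scaffold provenance.** The base scaffold of the packaged library appears
in its source only as a drawing. It was transcribed once, on chemical
grounds, as a 2,5-diketopiperazine (R1/R2 on the ring carbons, amino-acid
side-chain style) linked through a pyrrolidine to a piperazine (R3/R4 on the
nitrogens):
`O=C1NC([R2])C(=O)N(C1[R1])CC2CCCN2CC3CN([R4])CCN3[R3]`.
Any user can substitute their own transcription in the config. Screening
counts are sensitive to this choice: the discriminant balances large terms
(245.5 − 296.2·C¹χ + …), so scaffold differences of a few atoms move
hundreds of molecules across the (0, 8) window. The published DF-active
count for this library is 1403 of 6120; under this transcription and the
documented convention grid the count is 949 (812 with the S-phenyl repair),
and the downstream affinity predictions sit well above the 2.60 cut-off, so
the published stage-two counts (785 and 87) are not reproduced either. The
affinity model's descriptors were originally produced by closed-source
software whose numerical conventions are not published; evaluated ~20 log
units from zero, per-descriptor scale differences of tens of percent shift
predictions by many units. The acceptance script reports exactly what this
implementation computes; no constant was adjusted toward the published
counts.

## QSAR machinery

- **Model evaluation**: intercept + Σ coefficient × named descriptor; a
  missing or NaN term is an explicit error naming the term. The posterior
  activity probability reported alongside DF is the logistic transform of
  DF ("model-posterior (convention)": the prior log-odds are regarded as
  absorbed in the intercept; this is a convention, not a published formula).
- **Classification window**: active iff 0 < DF < 8 (DF = 0 is inactive;
  DF ≥ 8 or DF < −8 is outside the applicability domain). The Log k_i
  thresholds 2.60 (400 nM) and 1.0 (10 nM) are strict inequalities and
  exposed in config.
- **LDA**: two-class discriminant along Sw⁻¹(μ₁ − μ₀) with pooled
  within-class covariance; the intercept shifts the midpoint boundary by
  ln(p₁/p₀) for class priors (the packaged screening context used
  0.306/0.694). Wilks λ = |W|/|T| from the SSCP matrices, transformed to
  F(p, n−p−1) for the single-function case.
- **OLS**: QR-based fit reporting R², SEE = √(RSS/(n−p−1)) and the overall
  F test. LOO Q² = 1 − PRESS/SS_tot uses the exact hat-matrix identity
  e₍ᵢ₎ = eᵢ/(1 − hᵢᵢ) (verified against literal refitting in tests).
  Y-scrambling refits on a permuted response with a seeded generator.
- **PDD**: per score bin (default width 1.0, the published diagram's
  granularity not being stated numerically), with a and i the fractions of
  all actives/inactives in the bin: E_a = a/(i+1), E_i = i/(a+1).

## Test substrate and what it shows

The fixture generator provides linear alkanes C2–C10, branched isomers,
cycloalkanes C3–C8, heteroatom probes (ethanol, benzene, pyridine,
thiophene, phenol, naphthalene, …), the packaged fragment list resolved to
standalone molecules, and seeded random connected carbon skeletons (degree
≤ 4). On every fixture molecule with ≤ 12 atoms, distances, detours, all χ
indices, G_k, MAXDN and ww are checked entrywise against brute-force oracles
(BFS, exhaustive DFS, raw edge-subset enumeration, literal double sums) at
1e-9; statistics are cross-checked against scikit-learn and statsmodels.
These fixtures exercise the graph-theoretic machinery completely, but they
are small and mostly hydrocarbon: passing tests certify the mathematics, not
agreement with any particular third-party descriptor program's conventions
on drug-sized molecules.

Problem sizes used in the shipped validation runs: the full 6120-molecule
enumeration and discriminant pass, the affinity pass over the ~950
DF-actives, oracle checks on ~35 molecules ≤ 12 atoms, and LDA/OLS parameter
recovery at n = 40–240 observations.

## Known limitations

- The ring/chain (^mχ_ch) connectivity subtype is not computed.
- Stereochemistry, tautomers and 3D geometry are ignored throughout.
- Detour computation is exponential inside a biconnected component; the
  30-atom guard makes this explicit rather than silent.
- The packaged scaffold is a transcription (see above); screening counts
  inherit its uncertainty.
- Refit statistics for the original training set cannot be reproduced here
  because the underlying activity table and the original random 80/20 split
  are not available; the fitting machinery is instead validated by parameter
  recovery and oracle cross-checks on synthetic data.
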