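# topoqsar

Combinatorial construction of SMILES molecule libraries, topological
molecular descriptors computed from the hydrogen-suppressed molecular graph,
and a linear QSAR layer for screening libraries against fixed published
models — here, binding to the formylpeptide receptor (FPR), a target
implicated in chronic inflammation in systemic amyloidosis and Alzheimer's
disease.

## What it does

**Library building.** A base scaffold carries indexed anchor points
`[R1]…[Rk]`; each position has an ordered list of substituent fragments, each
a SMILES string with a single `[R]` marker denoting the atom that sits at the
anchor point. The builder validates every fragment, forms the full Cartesian
product, renumbers ring closures, and writes a `.smi` file of
`SMILES id_code` lines. The packaged config is an FPR-targeted
dioxopiperazine library: four positions with 5, 8, 9 and 17 substituents,
hence 5×8×9×17 = 6120 molecules with id codes `AAAA`…`EHIQ`.

**Descriptors.** From the hydrogen-suppressed graph (heavy atoms as
vertices, bonds as unit edges):

- Kier–Hall connectivity indices up to fourth order,
  ^mχ_t = Σ_subgraphs Π_vertices (δ\*)^(−1/2), for path, cluster and
  path-cluster subgraph types, with simple (δ) and valence (δᵛ) degrees;
  δᵛ = Zv − h for second-period atoms and (Zv − h)/(Z − Zv − 1) beyond;
- combined quotient and difference indices C^mχ_t = ^mχ_t / ^mχ_tᵛ and
  D^mχ_t = ^mχ_t − ^mχ_tᵛ (orientation is a recorded, switchable convention);
- Galvez topological charge indices G_k, J_k from the antisymmetric part of
  A·Q (Q = inverse-square-distance matrix), bucketed by topological distance;
- Wiener index W = Σ_{i<j} d_ij and constitutional counts (V1…V4 vertex
  degree counts, ring count, element counts);
- extended descriptors: hyper-detour index ww = ½Σ(Δ + Δ²) from the
  longest-simple-path (detour) matrix, MAXDN (maximal electrotopological
  negative variation), BELm5 (fifth-smallest eigenvalue of the mass-weighted
  Burden matrix) and VEA1 (adjacency principal-eigenvector coefficient sum).

**QSAR screening.** Two packaged linear models screen the library in a
cascade. The discriminant score

    DF = 245.5 − 296.2·C¹χ + 50.2·D⁴χ_pc − 0.0034·W + 4.4·V4

classifies a molecule as potentially active when 0 < DF < 8 (DF ≤ 0
inactive; outside [−8, 8) unclassified — the applicability domain). For the
DF-actives, the regression

    Log k_i = 76.50 + 0.000033·ww − 9.50·MAXDN − 15.68·BELm5 − 3.18·GGI10 − 5.12·VEA1

predicts the log binding-affinity constant (nM scale); Log k_i < 2.60
(≈400 nM) marks actives and Log k_i < 1.0 (≈10 nM) highly actives. Generic
machinery to *fit* such models is included: two-group LDA with class priors
and Wilks λ, OLS with SEE and F, leave-one-out Q², y-scrambling,
classification metrics and the pharmacological distribution diagram.

## Worked example

```sh
$ topoqsar build --out library.smi
wrote 6120 molecules to library.smi
$ head -1 library.smi
CC1CCC(CN2CCN(Cc3ccccc3)C(CN3CCCC3CN3C(=O)C(Cc4ccc(O)cc4)NC(=O)C3Cc3ccc4ccccc4c3)C2)CC1 AAAA
$ topoqsar screen library.smi --out screen.csv
screened 6120: 949 DF-active, 0 with Logki<2.60, 0 with Logki<1.0, 0 unprocessed
```

The first line of `library.smi` is molecule `AAAA` — the scaffold with the
first substituent of every list (2-naphthylmethyl, 4-hydroxybenzyl, benzyl,
4-methylcyclohexylmethyl). Screening evaluates DF for all 6120 molecules and
the affinity regression for the 949 inside the DF window; `screen.csv` holds
per-molecule DF, posterior activity probability, class label, predicted
Log k_i and activity tier.

From Python:

```python
>>> from topoqsar import parse_smiles, compute_descriptors
>>> compute_descriptors(parse_smiles("CCO"), names=["chi1p", "chiv1p", "W", "MAXDN"])
{'chi1p': 1.4142, 'chiv1p': 1.0233, 'W': 4.0, 'MAXDN': 1.25}
```

Ethanol's simple first-order connectivity is (1·2)^(−1/2) + (2·1)^(−1/2) =
√2; the valence variant replaces the oxygen degree by δᵛ(O) = 5, lowering it
to 1.0233; W sums the three pairwise distances 1+1+2; MAXDN > 0 reflects the
charge drain toward the hydroxyl oxygen.

Because two descriptor families have more than one defensible literature
definition, the C/D orientation and the Burden-matrix variant are explicit
flags (`--cd-quotient`, `--cd-difference`, `--burden`), logged on every run
and written into every output's metadata sheet.

## Layout

- `src/topoqsar/graph.py` — molecular graph, distance/detour matrices,
  subgraph enumeration
- `src/topoqsar/topo.py`, `extdesc.py`, `descriptors.py` — descriptor
  families and the named-descriptor registry
- `src/topoqsar/library.py` — fragment validation, attachment, enumeration
- `src/topoqsar/models.py`, `stats.py` — model evaluation, screening
  cascade, LDA/OLS machinery
- `src/topoqsar/io.py`, `cli.py` — file formats and the command line
- `src/topoqsar/data/` — packaged library config and model files
- `docs/methods.md` — model definitions, conventions and limitations
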