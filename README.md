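# emmfilter

Extended-metabolic-model filtering (EMMF) for untargeted metabolomics
annotation.

## The problem

Untargeted LC–MS experiments detect thousands of features, but assigning
chemical identities to them is bottlenecked by the candidate set: filtering
measured masses against a reference genome-scale metabolic model keeps every
candidate biologically relevant but misses anything the model does not
catalog, while filtering against a large structural database (PubChem-scale)
yields millions of mostly irrelevant candidates and a prohibitive annotation
cost. Enzymes are, moreover, promiscuous — they transform substrates beyond
their catalogued reactions — so real samples contain metabolites that no
reference model lists.

`emmfilter` engineers a middle ground. It mines **biotransformation
operators** from the enzymatic reactant→product pairs of a reference model,
applies them to every model metabolite to predict promiscuous products
("derivative" metabolites), and assembles the **extended metabolic model
(EMM)** — model metabolites plus derivatives. Measured feature masses are
then matched against the EMM's exact masses within a ppm window, and the
union of model matches and derivative matches forms a biologically
relevant, provenance-tracked candidate set for downstream spectral
annotation tools.

## The method

For each reactant→product pair (with a curated or MCS-inferred atom map)
the miner:

1. detects the **reaction center** — mapped atoms whose hydrogen count,
   charge, aromaticity or bond multiset changes, plus atoms adjacent to
   gained/lost fragments;
2. extracts the center's **neighborhood signature**: element, aromaticity,
   ring membership and degree at the center; (bond order, element,
   aromaticity) triples at the first shell; (two-bond-order path, terminal
   element) pairs at the second shell;
3. records an **edit script** (bond-order changes, fragment deletions,
   fragment attachments, all anchored at the center) together with the mass
   delta Δm and the reaction/EC provenance. Every operator is verified to
   round-trip: replaying the script on its source reactant reproduces the
   source product.

An operator applies to any substrate atom presenting the identical
signature, so a rule mined from one catalogued reaction predicts products
on other metabolites — a derivative with mass `m_parent + Δm`. Matching
uses the relative window `|m_obs − m_ref| / m_ref × 1e6 ≤ tol` with a
default tolerance of 10 ppm.

## Worked example

The validated showcase: a keto→carbinol reduction operator mined from the
phenylpyruvate→phenyllactate reaction, applied to 4-hydroxyphenylpyruvate,
predicts 4-hydroxyphenyllactate — a metabolite absent from the CHO-cell
reference model but experimentally confirmed in CHO cultures.

```python
from emmfilter import (parse_structure, canonical_key, monoisotopic_mass,
                       infer_atom_map, MappedReactionPair, mine_operator,
                       match_sites, apply_operator)

r = parse_structure("O=C(O)C(=O)Cc1ccccc1")        # phenylpyruvate
p = parse_structure("OC(Cc1ccccc1)C(=O)O")         # phenyllactate
pair = MappedReactionPair("R03336", r, p, infer_atom_map(r, p), ("1.1.1.110",))
(op,) = mine_operator(pair)
print(f"operator {op.operator_id}: mass delta {op.mass_delta:+.4f} Da")

hpp = parse_structure("O=C(O)C(=O)Cc1ccc(O)cc1")   # 4-hydroxyphenylpyruvate
sites = match_sites(hpp, op)
print("matched sites:", sites)
derivative = apply_operator(hpp, op, sites[0])
print("derivative:", canonical_key(derivative))
print(f"mass: {monoisotopic_mass(derivative):.4f} Da")
```

prints

```
operator e64b58a710a2: mass delta +2.0157 Da
matched sites: [3]
derivative: O=C(O)C(O)Cc1ccc(O)cc1
mass: 182.0579 Da
```

The +2.0157 Da delta is the two hydrogens gained on reduction; the single
matched site is the keto carbon (the aromatic ring and the carboxyl group
do not present the mined signature); and 182.0579 Da is the neutral
monoisotopic mass of 4-hydroxyphenyllactate (C9H10O4), which would match a
feature measured at 182.06 within 10 ppm.

## Command line

The `emmf` tool composes the same stages through files:

```sh
emmf simulate --out-dir sim --seed 7      # toy model + synthetic features
emmf run --model sim/metabolites.tsv --reactions sim/reactions.tsv \
         --features sim/features.csv --out-dir out
```

```
wrote toy model (12 metabolites, 35 reactions) and 60 features
model matched 11 and EMM matched 30 of 60 features
```

The 60 synthetic features are 30 planted at true EMM masses (≤ 5 ppm
noise) and 30 decoys (≥ 50 ppm from every true mass): the EMM recovers
all 30 planted features and no decoys, while the reference model alone
explains only 11 — the EMM's extra coverage is exactly the promiscuous
products. `out/` contains the mined operator library, the derivative table
with provenance counts, per-stage match tables, the candidate set
(`candidates.tsv`, `candidates.smi`) and `summary.json`. Individual stages
(`mine`, `build-emm`, `filter`, `assemble`, `summarize`) read and write
the same formats and reproduce `run` byte-for-byte.

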