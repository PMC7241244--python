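# Methods

## Overview

`emmfilter` implements extended-metabolic-model filtering: a reference
metabolic model (metabolites with structures, reactions with
reactant→product pairs and EC numbers) is expanded with predicted
promiscuous-enzyme products, and measured LC–MS masses are filtered
through the expanded mass list to form an annotation candidate set. The
package has three scientific layers — operator mining, model expansion,
and ppm mass filtering — plus assembly/reporting and a synthetic-data
generator that makes every stage testable offline.

## Chemistry substrate

Structures are RDKit molecules parsed from SMILES with aromaticity
perception and implicit-hydrogen assignment. Identity is a stereo-blind
canonical SMILES key: masses and matching patterns cannot see
stereochemistry, so enumerating stereoisomers as distinct derivatives
would inflate counts without adding discriminating power; stereo is kept
only when echoing input structures. The canonical key is an internal
identity and is never compared across software versions.

Monoisotopic masses are summed from a hard-coded table of
most-abundant-isotope masses (≥ 6 decimals) for C, H, N, O, P, S, F, Cl,
Br, Se and I — the elements that cover the metabolome — and any other
element is rejected loudly. Molecules are treated as neutral species; a
normalization step protonates −1 oxyanions and deprotonates +1 protonated
amines (permanent charges such as quaternary ammonium are left with a
warning). Inputs are neutralized before matching, since printed reference
masses are neutral while model structures are sometimes drawn as salts.

## Operator mining

An atom correspondence between reactant and product comes either from
atom-mapped reaction SMILES or, failing that, from a maximum-common-
substructure alignment (elements must match; bond orders may differ so
that e.g. a ketone carbon maps onto its reduced carbinol). Among multiple
MCS embeddings the one minimizing the canonical atom-rank tuple is chosen
on each side, making inference deterministic.

The reaction center is the set of mapped atoms whose hydrogen count,
formal charge, aromaticity or bond multiset differs between sides, plus
mapped atoms adjacent to unmapped (gained or lost) atoms. One operator is
mined per connected component of the center. Each component gets:

- a pattern: the neighborhood signature of an anchor atom (highest heavy-
  atom degree, ties broken by canonical rank) — center descriptor
  (element, aromatic, in-ring, degree), first shell as a sorted multiset
  of (bond order, element, aromatic) triples, second shell as a sorted
  multiset of ((bond order, bond order) path, terminal element) pairs.
  This is a deliberate, testable approximation of database-style atom
  typing, which is not fully specified anywhere reusable;
- an edit script anchored at that atom: bond-order changes to descriptor-
  identified neighbors, deletion of an acyclic branch that must equal a
  stored fragment, attachment of a stored fragment through a given bond.
  Hydrogen bookkeeping is implicit — hydrogens refill from valence after
  the heavy-atom edits — so a C=O → C–O edit adds one hydrogen to each
  atom without explicit H edits;
- a mass delta, measured by actually replaying the edit on the source
  reactant, and provenance — the set of (reaction id, EC numbers) pairs
  that produced the same (pattern, edit script).

Every mined operator must round-trip: sequentially replaying all component
edit scripts on the source reactant must reproduce the source product's
canonical key. Changes that cannot be expressed as an anchor-local script
(bond cleavage between two mapped atoms, fragments spanning several
center atoms, hydrogen-only tautomeric shifts) and center components
larger than 6 atoms are skipped with a logged warning rather than encoded
approximately. Pairs where either side has fewer than 4 heavy atoms are
excluded by default as currency-metabolite artifacts (configurable). Both
reaction directions are mined by default, since catalogued reactions run
reversibly often enough that the reverse rule is also a plausible
promiscuous activity; a switch restricts mining to the written direction.

Operators are deduplicated on (pattern, edit script) — the operator id is
a content hash of exactly those two — with provenance unioned, so a rule
recurring across many reactions reports how many reactions and distinct
EC numbers support it.

## Model expansion

Every operator is applied at every substrate atom whose signature equals
the operator's pattern (matched sites are enumerated in canonical-rank
order; neighbor choices during replay are canonical-rank-deterministic,
so the whole expansion is order-independent). Applications that do not
fit the site's actual substituents or fail valence/aromaticity
sanitization are skipped. Products whose canonical key is already a model
metabolite are discarded; the rest are deduplicated by key with parent,
operator and reaction/EC provenance merged. Statistics report unique
derivatives, unique derivative masses, and the fold changes of both over
the model.

Masses within 1e-4 Da are counted as one "unique mass" — below
instrument precision, far above accumulated float error. Repeated
operator application (depth > 1) re-applies the library to the previous
round's derivatives; the default depth is 1, matching the headline
single-application statistics, and deeper expansion is exposed as a knob.

## Mass filtering

Features carry id, measured mass, retention time, polarity and an
optional MS2 peak list; only the mass participates in matching — RT and
MS2 are pass-through payload for downstream annotation tools. The ppm
convention puts the reference (candidate) mass in the denominator:
`|m_obs − m_ref| / m_ref × 1e6`. At the 10 ppm default the alternative
convention differs by under 0.01 ppm, which the tests assert on fixtures.
Feature tables are assumed mass-neutralized upstream (the default); per-
file M+H / M−H proton correction is opt-in. Matching is a binary search
over the sorted mass index with the window
`m_obs/(1+t) ≤ m_ref ≤ m_obs/(1−t)`, verified against all-pairs
comparison.

## Candidate assembly

The candidate set is the per-feature union of model matches and
derivative matches; a structure matched both ways is reported once with
source "model" (the catalogued identity outranks the predicted route to
the same structure). Cross-references come from user-supplied local TSV
tables (structure key → KEGG/PubChem id) — never from web queries — and
candidates in no table are retained and flagged novel, since genuinely
uncatalogued predictions are the method's point. Chemical-identity counts
are reported as global distinct structure keys, with per-(feature, key)
totals alongside, because either convention is defensible. Percentages
and fold ratios are reported at two decimals; a zero denominator yields
an undefined (null) ratio, not infinity.

## Synthetic data

The generator draws metabolites from a hard-coded panel of small
metabolites (pyruvate, aryl pyruvates, phenols, small acids, and the
validation-standard compounds) and instantiates six template chemistries
— ketone reduction, aromatic hydroxylation, O-methylation, O-acetylation,
acid→amide amination, decarboxylation — as correctly atom-mapped pairs
with EC numbers from the matching enzyme class. Default study conditions:
12 metabolites (4 always-present cores), all six templates (≈ 35
reactions), 30 planted features and 30 decoys per table.

Planted features sit at true EMM masses times `(1 + u·1e-6)` with `u`
uniform on ±5 ppm; uniform bounded noise (not Gaussian) is chosen so
recall statements are exact rather than probabilistic: every planted
feature must match at 10 ppm, and at a 2 ppm gate the expected loss is
exactly `P(|u| > 2) = 0.6`. Decoys are rejected-sampled at least 50 ppm
from every true mass, so zero decoy matches is likewise guaranteed by
construction. RTs are uniform in 0.5–20 min and carry no information.

What the toy corpus does not emulate: adduct and isotopologue patterns,
RT structure, MS2 spectra, peak-picking artifacts, missing values, and
the scale and redundancy of genome-derived models. Passing tests
therefore demonstrate correctness of the mining/expansion/matching
machinery and its bookkeeping, not field performance of the candidate
sets on real instruments.

The generator's ground-truth record also stores the operator count and
derivative key set obtained by running the miner and builder at
generation time; these are self-consistency references for stage tests,
while correctness tests compare against independent brute-force
enumerators (exhaustive (metabolite, operator, atom) application; all-
pairs ppm comparison).

## Numerical and design choices

- Mass tolerance defaults: 10 ppm matching window; 1e-4 Da unique-mass
  grouping; 1e-6 Da assertion tolerance for mass-delta bookkeeping.
- Determinism: operator ids are content hashes; site and neighbor
  selection uses canonical atom ranks; exports are sorted by (feature id,
  structure key); derivative tables store shortest-round-trip floats so
  staged file-based runs reproduce in-memory runs byte-for-byte.
- One derivative per (operator, site): a site matching a pattern is
  rewritten by that operator's single edit script; alternative edits at
  the same site are distinct operators.
- Ambiguous neighbor choice during replay (two neighbors with the same
  descriptor) resolves to the lowest canonical rank; if the chosen branch
  does not carry the stored fragment the next candidate is tried, and the
  application fails cleanly if none fits.
- Degenerate inputs: empty molecules, empty reaction sets, empty indexes
  and nonpositive masses raise informative errors; an EMM with zero
  derivatives is legal and logged.

## Known limitations

- Signatures stop at two bonds; rules whose specificity lives farther out
  will over-apply (more false candidates) — inherent to the local-pattern
  approach.
- Multi-substrate transformations and stereo-specific rules are out of
  scope; one operator edits one connected center on one molecule.
- MCS-based atom mapping is a fallback, not a reaction mapper; curated
  atom-mapped inputs are preferred and used throughout the fixtures.
- The isotope table covers eleven elements; organometallics and
  exotic-element metabolites are rejected rather than mis-weighed.
- Candidate quality scoring (spectral matching, ranking) is deliberately
  external: the exports are the integration point.
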