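# Methods

## The matching problem

Two curated pathway databases describe overlapping biochemistry under
different identifier systems.  Comparing their content requires entity
correspondences, and the algorithms that compute correspondences are
imperfect — when an entity appears unlinked, that may be a genuine content
difference or a false negative of the matcher.  `concord` therefore couples
three things: rule-based correspondence inference, exact evaluation against
synthetic ground truth, and audit-sampling statistics that quantify the
error rates of a link table the way a curation team would (sample, 
adjudicate, report a rate with an exact interval).

## Compound matching rules

A cross-database compound pair is accepted iff all three hold:

1. **At least one structure feature.**
   - *Fingerprint + structure key*: Tanimoto coefficient of the bit-set
     fingerprints strictly greater than `tanimoto_threshold` (default 0.75)
     **and** equal protonation-invariant structure keys.  The second
     condition realizes a protonation-tolerant structure matcher: the key
     retains connectivity and stereo layers but drops proton/charge
     information, so compounds differing only in protonation state still
     match, while fingerprint-similar but structurally distinct compounds
     do not.
   - *Exact stereo structure*: byte-identical full structure strings
     (InChI-style; stereo and proton layers included).  Strict by design:
     it misses legitimate matches when one record lacks stereo descriptors
     or differs in protonation, which is why the other features exist.
   - *All-but-one*: for an accepted reaction pair whose substrates are all
     matched except exactly one compound on each side, and where neither
     residual is linked to anything, the residual pair is a candidate.
     This is iterated to fixpoint because every accepted compound link can
     complete another reaction pair's substrate matching.
2. **Canonical name equality.**  Names are canonicalized by lowercasing
   and deleting every character outside `[a-z0-9]`; any name (common name
   or synonym) may supply the key.  Consulting synonyms is a design choice:
   synonym lists exist precisely to absorb nomenclature variation, and the
   structure features plus the contradiction rule guard against synonym
   collisions.
3. **No contradiction.**  If a compound ends up with two or more distinct
   proposed partners, *all* implicated pairs are dropped and reported.
   Dropping everything (rather than keeping a best-scoring pair) is the
   conservative reading of "no contradictory matches"; duplicates inside a
   database are the main source of contradictions, and they should be
   repaired, not silently resolved.

Curated and imported links always outrank inference; inference never
relinks an already-linked compound.

## Reaction matching

All reactions of both databases become columns of a single sparse
stoichiometric matrix.  Row identity is the linked compound pair where a
compound link exists, else the db-qualified compound id; reactant
coefficients enter negative, products positive.  The similarity gate is
`|cos(u, v)| > cosine_threshold` (default 0.6); the absolute value makes
matching orientation-blind, so reversed reactions still match (their cosine
is −1).  At least one of three annotation features must also fire: a shared
UniProt accession, an exact full-string EC number (partial numbers like
`1.1.1.-` only match identical partial strings), or a canonicalized
activity-name match.  Contradictions void all implicated pairs, as for
compounds, and voiding happens *before* the EC fallback.

The EC fallback then links remaining unmatched reactions where an EC number
maps exactly one unmatched reaction of one database to exactly one of the
other.  It deliberately trades a little precision for recall: two genuinely
different reactions that share an EC number and sit in complementary halves
of the two databases will be paired.  On synthetic data this is the only
observed false-positive mode, and it is bounded by the configured EC
collision rate.

## Balance auditing

Each side of a reaction is summed as coefficient-weighted atom bags parsed
from molecular formulas (element symbols, counts, parenthesized groups;
charge suffixes stripped, because the audit is atom-based).  A reaction
with any formula-less participant (typically a compound class in a generic
reaction) is *skipped*, not failed.  Two flags are reported: balanced over
all elements, and balanced ignoring hydrogen.  The hydrogen-free flag
exists because databases protonate compounds under different conventions,
so hydrogen-only deltas usually reflect convention mismatch rather than a
curation defect — in the synthetic generator this is literally true: the
only sources of hydrogen-only imbalance are protonation-variant injections.

The "high quality reactions" summary is `total − duplicates − unbalanced
(counting hydrogen)`.  A record that is both duplicate and unbalanced is
subtracted twice; the summary mirrors plain per-defect bookkeeping
deliberately, and is documented as such rather than "corrected".

## Audit-sampling statistics

Sample size uses the normal approximation to the binomial at the
conservative `p₀ = 0.5`: `n = ⌈z² p₀ (1−p₀) / h²⌉`, where `z` is the
two-sided normal quantile at the chosen confidence and `h` the interval
half-width; 90% confidence and `h = 0.10` give `n = 68`.  The "confidence
interval of 10%" convention is read as half-width — the full-width reading
would demand 385 samples, contradicting the design this tooling follows.

Observed error counts get exact Clopper–Pearson intervals
(`beta.ppf(α/2, x, n−x+1)` / `beta.ppf(1−α/2, x+1, n−x)`), chosen because
they are exact and conservative; the test suite checks them against an
independent binomial tail-sum root search and verifies ≥ 89% empirical
coverage at n = 68 over 10,000 simulated draws for p ∈ {0.02, 0.13, 0.5}.

The overall accuracy summary is `100 − round₁(100·FN) − round₁(100·FP)` in
percent, with bounds obtained by the same rounded subtraction from the
interval endpoints; rounding first keeps the headline numbers consistent
with one-decimal printed rates (53/68 would otherwise print 77.9 rather
than the 78.0 implied by 13.2% + 8.8%).  Unrounded variants are returned
alongside.  Error-count extrapolation rounds `rate × population` to the
nearest integer.

## Enrichment, uniqueness, taxonomy

For a class ontology, a class's reaction set is the union over pathway
instances assigned to it or any descendant class, with super-pathway
reaction sets taken transitively through subpathways.  The background is
the analyzed database's pathway reactions (class sets cannot contain
anything else); `K` of the `N` background reactions are linked.  Each
non-empty class is tested one-sided in both directions with exact
hypergeometric tails, Bonferroni-corrected by the number of classes tested,
and called ENRICHED/DEPLETED when the adjusted p ≤ α (default 0.025).  The
two one-sided tails overlap at `P(X = k)`, so a class can never be called
both ways at α < 0.5.

A pathway is *unique* to its database when no single pathway of the other
database contains the linked counterparts of more than `max_linked_fraction`
(default 1/3, inclusive) of its reactions; taking the best single other-side
pathway resolves the otherwise ambiguous per-reaction pathway attribution.
The taxon table rolls base pathways up the taxonomy (a pathway counts under
a taxon and all its ancestors) and reports only taxa with at least
`min_taxon_pathways` (default 50) pathways.

## The synthetic generator

The generator's defaults define the study conditions under which the rule
system is evaluated: 500 compounds, 300 reactions, 70% compound and 50%
reaction sharing, 10% name mangling, 10% protonation divergence, 10% stereo
loss, 2 fingerprint noise bits (of 256), 2% duplicate injection, 5%
imbalance injection, 80% EC annotation with 5% collisions, 50%/60%
UniProt/activity sharing.  Base-pathway size means follow the
reactions-per-pathway statistics of real curated resources (4.37 for DB-A
base pathways, 6.22 for DB-B modules), with DB-B super pathways
aggregating many more modules to emulate the map/module size asymmetry.
These sizes keep the full pipeline and suite to seconds on one CPU while
leaving hundreds of true pairs per run.

Design points worth knowing:

- **Balance by construction.**  Product formulas are obtained by randomly
  re-partitioning the summed reactant atom bag (fresh reactions), by
  composing two balanced reactions through a shared intermediate, or by
  spectator extension — all balance-preserving.  Chemical plausibility of
  the molecules is a non-goal; the audit only needs atom arithmetic.
- **Fingerprints** are deterministic hashes of the structure key seeding a
  choice of 48 set bits in a 256-bit space, plus per-view toggled noise
  bits.  Equal structures are near-identical (Tanimoto ≈ 0.85+ after
  noise); unrelated structures overlap by chance at ≈ 0.10, so the 0.75
  threshold behaves like a real structure-similarity proxy.
- **Protonation variants** change the formula by ±1 H and the proton layer
  of the structure identifiers while preserving the protonation-invariant
  key; **stereo loss** drops the stereo layer from all identifiers (an
  unspecified stereo center is a different structure statement, so both
  keys change and only the name gate plus all-but-one can recover the
  pair).
- **Imbalance injection** bumps one product's stoichiometric coefficient
  (choosing a product with at least one non-hydrogen atom).  This keeps
  the defect local to one reaction — perturbing the compound's formula
  would corrupt every other reaction using that record — and guarantees
  the defect is visible to the hydrogen-free audit, cleanly separating
  injected defects from protonation-induced hydrogen deltas.
- **Sharing calibration.**  Reactions are shared first; their participants
  are forced into both views, and the remaining compounds are shared at a
  compensated rate so the realized compound-sharing fraction is unbiased
  (tested to 3 binomial standard deviations).
- **Compound classes** (generic substrates) are never shared between
  views: they carry no structure or fingerprint, so no structure-based
  rule could ever link them, and including them in the truth would make
  exact recovery unachievable by construction rather than by defect.
- Noise processes are independent per record, so expected recall can be
  budgeted analytically (e.g. compound recall ≈ 1 − stereo-loss rate
  before all-but-one rescue, minus duplicate-induced contradictions).

What the generator does **not** emulate: realistic organic structures or
SMILES, thermodynamics, correlated curation errors (a curator who
mis-names a compound often also mis-draws it), systematic protonation
conventions (real databases shift whole compound classes, not random
records), and cross-database imports that make annotation sharing
non-independent.  Passing tests therefore demonstrate that the rule system
is implemented correctly and behaves sensibly under controlled noise — not
that the same precision/recall would be achieved on any particular pair of
real databases.

## Numerical and procedural choices

- Tanimoto and cosine thresholds are strict inequalities; a pair exactly at
  the threshold is rejected.
- Tanimoto of two empty fingerprints and cosine with a zero vector are
  undefined and treated as no-match (never an accepted pair).
- Jaccard is reported to 2 decimals in reports; full precision internally.
- Flat files are written with records sorted by id and attributes in fixed
  order, so identical databases serialize byte-identically; the audit
  sampler sorts its id population before the seeded draw.  All randomness
  flows from a single `numpy` generator per stage.
- "Mean comment length" uses commented objects as the denominator (an
  all-objects denominator would conflate sparsity with brevity).
- Duplicate-reaction comparison uses coefficient multisets, so `2A → B` is
  not a duplicate of `A → B`.
- Validation normalizes participant order and merges duplicate
  participants on one side by summing coefficients (tolerant ingestion).

## Known limitations

- The EC fallback's false-positive mode under EC collisions is inherent to
  the rule, not an implementation artifact; on real data it should be
  complemented by curator review of fallback-only links.
- The contradiction rule discards all implicated pairs, so a single
  duplicate record suppresses an otherwise correct link (visible as a
  small recall loss at the default duplicate rate).
- Audit bounds propagate interval endpoints through the rounded
  subtraction; upper bounds can exceed what an exact joint interval would
  give, since FN and FP estimates are treated as independent.
- Enrichment results on the synthetic ontology are exercised for
  correctness against exhaustive enumeration, not for biological
  interpretability of the synthetic classes.
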