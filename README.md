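# concord

Concordance analysis between pairs of metabolic pathway databases.

Curated pathway resources describe the same underlying biochemistry —
metabolites, the reactions built on them, and the pathways built on
reactions — but with different identifiers, naming conventions, protonation
conventions, stereo annotation habits, and pathway boundaries.  Before two
databases can be compared (how big is the overlap? where is each one
unique? how trustworthy are the records?), the correspondences between
their compounds and reactions must be inferred, and the quality of that
inference must itself be quantified.  `concord` implements this entire
methodology as a reusable library for people who maintain, merge, or
benchmark pathway databases:

- **Compound matching** — a rule system that accepts a cross-database pair
  when at least one structure feature fires (fingerprint Tanimoto
  `T(a,b) = |a∩b| / |a∪b| > 0.75` combined with a protonation-invariant
  structure key; exact full-structure identity; or "all-but-one" inference
  from linked reactions), the canonicalized names match exactly, and no
  compound acquires two distinct partners.
- **Reaction matching** — both databases' reactions are embedded as columns
  of one stoichiometric matrix (reactants negative, products positive;
  linked compounds share a row); a pair is accepted when
  `|cos(u, v)| > 0.6` and at least one annotation feature (shared UniProt
  accession, exact EC number, canonicalized activity name) agrees, with a
  one-to-one EC fallback for the remainder.
- **Quality auditing** — duplicate records (identical structure strings;
  reactant/product multisets equal up to reversal) and atom-balance checks
  with and without hydrogen (hydrogen imbalance often reflects protonation
  conventions rather than curation errors).
- **Comparison statistics** — overlap counts with Jaccard coefficients,
  attribute coverage, pathway-size histograms, link-coverage classes
  (all/some/none of a pathway's reactions linked).
- **Accuracy estimation** — binomial audit-sampling design
  (`n = ⌈z² p₀(1−p₀) / h²⌉`; 90% confidence and 10% half-width give
  n = 68), exact Clopper–Pearson intervals for the observed false-negative
  and false-positive rates, and an overall accuracy summary
  `100 − FN% − FP%` with interval-propagated bounds.
- **Enrichment analysis** — one-sided Fisher exact tests (hypergeometric
  tails) for pathway classes enriched or depleted in cross-database links,
  Bonferroni-corrected at α = 0.025, plus taxon-level uniqueness tables.
- **Synthetic twin databases** — a generator builds a ground-truth universe
  (mass-balanced by construction) and derives two noisy views with
  controlled overlap and known correspondences, so every stage is testable
  end to end without licensed data.

## Worked example

```sh
concord generate --seed 42 --out demo
concord match-compounds --a demo/db_a --b demo/db_b --out demo/cpd_links.tsv
concord match-reactions --a demo/db_a --b demo/db_b \
    --compound-links demo/cpd_links.tsv --out demo/rxn_links.tsv
concord balance --db demo/db_a --out demo/balance_a.tsv
```

prints

```
wrote 442+439 compounds, 236+229 reactions to demo
315 compound links (15 contradictions)
138 reaction links (6 contradictions)
balance report written to demo/balance_a.tsv
```

The generator wrote two database views (flat-file directories `db_a/`,
`db_b/`) plus the ground-truth tables.  Single-pass matching linked 315
compound pairs; 15 candidate pairs were discarded because a compound had
two plausible partners (mostly injected duplicate records, which is exactly
what the contradiction rule is for).  The 138 reaction links combine the
cosine-plus-feature rule with the EC fallback.  The balance report's footer
(`unbalanced_no_h=13 unbalanced_with_h=65 skipped=3`) separates true atom
imbalance (13 reactions, the generator's injected defects) from
hydrogen-only imbalance caused by protonation-state divergence, with 3
generic reactions skipped for lack of formulas.

In Python, the two-stage pipeline (whose second pass uses reaction links
for all-but-one compound inference) and the exact ground-truth evaluation:

```python
from concord import GeneratorConfig, infer_all_correspondences
from concord.synthetic_data import generate
from concord.accuracy_estimation import evaluate_correspondences

db_a, db_b, truth = generate(GeneratorConfig(seed=2))
result = infer_all_correspondences(db_a, db_b)
print(evaluate_correspondences(result.compound_pairs(), truth, "compound"))
# EvaluationResult(tp=345, fp=0, fn=7, precision=1.0, recall=0.9801...)
```

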