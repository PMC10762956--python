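# Methods

This note documents the models, conventions and numerical choices behind
`molprobe`, and what its synthetic experiments do and do not demonstrate.

## Synthetic molecule generator

**What it emulates.** Libraries of substituted polycyclic aromatics of the
kind found in organic-semiconductor screening sets: molecules built from
conjugated cores shared across "families", decorated with common
functional groups, with a continuous electronic property (a HOMO-like
orbital energy, eV) that depends systematically on functional-group
content.

**Assembly grammar.** One core is drawn from the 11-fragment registry
(naphthalene, anthracene, tetracene, pyrene, perylene, *p*-benzoquinone,
1,4-naphthoquinone, 9,10-anthraquinone, 1,8-naphthalimide, naphthalene
diimide, perylene diimide); 0–`max_substituents` substituents are attached
by single bonds at distinct aromatic CH positions chosen uniformly at
random. Each default substituent carries exactly one group of the
15-entry SMARTS library. Assemblies that fail valence sanitization are
discarded and retried; molecules are deduplicated on canonical SMILES. A
budget of `retry_factor × n` attempts (default 200·n) bounds the search;
exhaustion raises an error rather than returning a short library.

**Planted rule.** The property is group-additive:
*y* = β₀ + Σ_g β_g·count_g + ε with ε ~ N(0, σ²). Counts are SMARTS match
counts on the assembled molecule (so if substituents interact to create an
extra match, the property honestly reflects it — the rule is exactly
recoverable from `group_counts` when σ = 0). Defaults: β₀ = −5.5 eV,
nitro −0.45, nitrile −0.35, ester/acid carbonyl −0.20, amine donor +0.30,
halogens −0.10 eV per occurrence, σ = 0.15 eV. The signs follow the usual
electron-withdrawing/donating intuition; the magnitudes and the Gaussian
noise model are conventions, not fits — real HOMO distributions are not
targeted, only their *kind* of structure. Gaussian residuals around an
additive mean are the minimal model that keeps the rule recoverable at a
controllable signal-to-noise ratio.

**Seeding.** All stages derive independent streams from one root seed via
counter-based `SeedSequence` spawning (`child_seed(root, k)`), so any
stage can be re-run in isolation and byte-identical output is guaranteed
for identical (config, rule). Structural choices and property noise use
separate streams: changing σ never changes which molecules are generated.

**What passing tests do not show.** Generated molecules are small
(one core, few substituents) and their property is exactly group-additive.
Real data has fused multi-core scaffolds, conformational effects, and
property contributions with no substructure signature. Results on the
synthetic libraries validate the *pipeline machinery* (bookkeeping,
statistics, direction of effects), not chemical accuracy of any backend.

## Labeling and splits

Classes are equal-range: threshold_i = min + i·(max−min)/k over the
labeling population's [min, max]; thresholds are computed on the **full**
dataset before splitting so class meanings are fixed across splits. A
value exactly on a threshold goes to the **higher** class — the choice is
arbitrary but documented and tested; values outside the range clamp to the
end classes.

Random splits put round(fraction·n) molecules in the test set. The
learning-curve subsets are **nested** (each smaller fraction contained in
the larger) within one shuffled 80% pool, sharing a single 20% hold-out;
nesting reduces between-point variance on the curve. Stratified k-fold
delegates to scikit-learn's `StratifiedKFold` (per-class fold counts
within 1 of proportional). Family holdouts match fragments as
*substructures* (any-match rule), so e.g. holding out naphthalene also
removes every anthracene-containing molecule; a molecule containing any
excluded fragment goes to the test side, which makes the
no-contamination guarantee on the train side checkable by brute-force
re-scan.

## Tokenization

Prompts are tokenized at the atom level: one token per atom (bracket atoms
like `[nH]` and two-letter elements Cl/Br/Si/Se/As are single tokens), per
bond symbol, ring-closure digit (incl. `%nn`) and parenthesis, with
`<missing>` reserved as a single token. Detokenization is exact
concatenation, so replacing one atom is a one-token edit and perturbed
strings differ from their parent only at the edited spans. A deliberate
consequence: the tokenizer is chemistry-aware and deterministic, unlike
the byte-pair encoders of hosted language models — token boundaries here
are part of the experimental design, not an artifact of a vocabulary.
The strict tokenizer rejects malformed input (unterminated brackets); the
lenient mode used inside backends maps unknown characters to
single-character tokens so that arbitrary perturbed text is accepted.

## Perturbation probes

- *Single-atom ablation*: every atom whose element is neither H nor C is
  replaced, one at a time, by `<missing>`.
- *Single-group ablation*: every distinct SMARTS match of a library group
  is ablated one match at a time; every atom of the match becomes its own
  `<missing>` token. Overlapping matches with identical atom sets are
  deduplicated to avoid double-counting tests.
- *Mutation*: each atom of one (uniformly chosen) match is independently
  replaced by a bare element symbol drawn uniformly from
  {B, N, O, F, Si, P, S, Cl, As, Se, Br, I}; 100 variants by default.
  Which match was mutated is recorded per variant.

Replacement is purely lexical: bonds, ring closures, parentheses, and
charges outside the atom token are untouched, and bracket atoms are
replaced wholesale (`[nH]` → `<missing>`). Ablated and mutated strings are
therefore generally **not** valid SMILES and are deliberately sent to
backends verbatim, as plain text — no re-canonicalization, no valence
repair. Probing what a text classifier does with such strings is the
point.

## Backends

The backend contract is `fit(prompt-completion pairs)` plus
`complete(text) -> str`, total over arbitrary input. An adapter to a
remote fine-tuning API would satisfy the same contract; only local,
deterministic reference implementations ship here.

**n-gram surrogate.** Counts of token n-grams (orders 1–3 by default)
feed a multinomial logistic regression over completion strings; unseen
n-grams are ignored. It is order-sensitive (through higher-order n-grams),
trains in seconds, and is deterministic given its seed — enough to
exercise every pipeline stage. An optional "gibberish head" returns the
non-label string `?` when at least a configurable fraction of input
tokens was never seen in training, emulating the erroneous free-text
completions of a language model. For the augmentation experiment the
recommended configuration drops unigrams (orders 2–3): pure unigram counts
are nearly invariant to atom reordering, which would mask the effect
under study.

**Descriptor + SVM baseline.** The full RDKit descriptor set (~210
descriptors) per molecule; molecules with more than 10% failed descriptors
are dropped (the cutoff operationalizes "significantly fewer descriptors
calculated"; any small cutoff gives the same behavior on clean input),
then descriptors with any missing value, then constant descriptors; the
top 20 by ANOVA F-score are kept and min-max scaled to [0, 1]; an RBF-SVC
(C = 1) is trained. The univariate score and kernel are defaults of this
package, documented rather than asserted as anyone else's choice.
Unparseable prompts complete to the non-label sentinel `invalid`.

## Statistics and conventions

- *Erroneous completions* (anything that is not exactly one of
  "0"…"k−1" after stripping) count as **disagreement** in agreement
  rates and as neither match nor mismatch in consistency levels (they are
  tallied separately; level + mismatches + erroneous = number of variants).
- Perturbation statistics are computed only on molecules passing the
  *correctly-predicted filter*, so they measure sensitivity of correct
  predictions rather than baseline error.
- The breakdown matrix bins molecules by number of tests (columns 1–10,
  11–20, …, last column open-ended) and agreement rate (rows: exact 0%,
  left-open/right-closed deciles (0%,10%] … (80%,90%], the open interval
  (90%,100%), and exact 100%). Exact 0%/100% get dedicated rows because
  they are qualitatively different outcomes; the column binning beyond
  the first decade is configurable.
- The augmentation experiment fits one backend on canonical prompts only
  and one on canonical + 5 non-canonical renderings per training molecule,
  then evaluates both on *identical* test renderings (canonical + 10
  non-canonical), so the contrast isolates the training-set intervention.
  Molecules too small to yield 10 distinct renderings are excluded and
  counted.

## Problem sizes

The shipped experiments use libraries of 500–3000 molecules, 2000/500
train/test for rule recovery, a 40:60 train/ablation split for group
sensitivity (mirroring the need for many ablation-eligible molecules),
600-molecule libraries with 5 seeded repeats for the augmentation
comparison, and 10 non-canonical renderings per test molecule. These
sizes give stable statistics (≥1000 ablation tests per group; binomial
standard errors a few percent) while keeping any single experiment under
a couple of minutes on one CPU.

## Known limitations

- Substituent attachment only at aromatic CH positions; no fused-ring
  growth, no multi-point linkers, no stereochemistry.
- The planted rule is linear in group counts; backends that cannot count
  (pure bag-of-tokens) can still do well when one count dominates.
- SMARTS patterns are used as shipped; some are intentionally broad
  (e.g. the enamine pattern also hits anilines and N-aryl nitrogens), so
  group counts of different groups can overlap on the same atoms.
- The n-gram surrogate is not a language model: it has no generative
  component, and its erroneous-response behavior is a calibrated
  emulation, not an emergent one.
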