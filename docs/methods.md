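# Methods

## The coding matrix

The unit of analysis is a harmonized symptom × instrument coding matrix.
Harmonization — deciding that "long pauses between breaths while asleep"
and "I have been told that I stop breathing in my sleep" are the same
symptom — is a human judgement made against reference classification
symptom lists; this package never attempts it. Labels are matched exactly
after Unicode NFC normalization and whitespace trimming; there is no fuzzy
matching, so a mislabelled symptom surfaces as a validation error rather
than a silent merge.

Codes are three-valued. An instrument's item that maps to a single
harmonized symptom makes that symptom **specific** (code 1) for the
instrument; a symptom that occurs only inside items mapping to two or more
symptoms is **compound** (code 2); absence is 0. When a symptom occurs both
ways, specificity wins — the instrument demonstrably probes it on its own,
so the compound occurrences add no ambiguity. This precedence makes the
derivation from items idempotent and independent of item order.
**Idiosyncratic** symptoms (probed by exactly one questionnaire) are a
matrix-level property, computed over non-reference columns only, and are
coded 1 like specific symptoms.

Reference classification lists (e.g. symptom lists derived from the ICSD-3
and the DSM-5 sleep-wake section) are stored as ordinary columns with a
reference flag rather than as a separate structure: they take part in the
pairwise grid (each questionnaire can be compared against them) but are
excluded from every questionnaire-to-questionnaire average, from frequency
counts, and from idiosyncrasy.

File formats are plain delimited text (comma for `.csv`, tab for `.tsv`).
The wide layout is a complete spreadsheet — a missing cell is an error,
never imputed — while the long layout permits sparse listings with implicit
zeros. Reference flags and column order travel in a JSON sidecar so a
write→read round trip is the identity, bit for bit.

## Overlap statistics

Pairwise overlap is the Jaccard coefficient J = s/(u₁ + u₂ + s) on
binarized presence (code > 0). Binarization treats compound presence as
presence: the 1/2 distinction records *how* an instrument probes a symptom,
not *whether* it does; counting only specific codes would understate the
shared content of instruments that phrase items broadly. Indices are
computed as exact integer ratios and rounded only at presentation (3
decimals in tables, matching the precision such studies print).

Three aggregate views are reported:

* **per-instrument mean** — the average of an instrument's indices against
  the non-reference peers (reference columns get a mean too, against the
  questionnaires, but never contribute to anyone else's);
* **grand mean** — the average over all C(n, 2) questionnaire pairs. When
  every pair is defined this equals the mean of the per-instrument means
  (each pair enters exactly two instrument means), and both are exposed;
* **per-category mean** — the grand mean after restricting rows to one
  category. A pair whose union is empty after restriction (neither
  instrument probes the category) is undefined — 0/0 — and is excluded
  from the mean and listed, never imputed as 0 or 1, since either
  imputation would bias category means for sparsely covered categories.

Strength labels use the conventional behavioural-science interpretation
bands. As usually printed the bands leave gaps (…–0.19, 0.20–…); they are
implemented as half-open intervals [0, 0.20), [0.20, 0.40), [0.40, 0.60),
[0.60, 0.80), [0.80, 1], each boundary belonging to the upper band, and
classification always uses the unrounded value.

## Length–overlap association

Three planned comparisons relate each questionnaire's mean overlap to its
item count, its symptom count, and its compound fraction
(n_compound/n_total). Pearson's product-moment coefficient is the default —
the standard choice when such studies report r with a t-based p — with
Spearman available as an option; p-values are two-sided from the
t distribution on n − 2 df and unadjusted (three planned comparisons, no
multiplicity correction). Degenerate inputs (a constant vector, e.g. the
compound fraction when no instrument has compound codes) yield a flagged
NaN result for that comparison without aborting the others.

## Synthetic generator

`SimConfig` describes a generative model for coding matrices; its defaults
emulate the study conditions the analysis was designed around: 60 symptoms
partitioned into nine categories, 12 questionnaires, two reference columns,
and four planted idiosyncratic symptoms. Per-category presence
probabilities are high for the core categories (insomnia 0.85, respiratory
0.85, sleepiness 0.75) and low (0.30–0.35) for the peripheral ones; under
independent presence with probability p the pairwise index converges to
p/(2 − p), so this profile yields an expected pairwise index of ≈ 0.43 —
the moderate-overlap, core-concentrated regime such questionnaire sets
exhibit. The compound-coding rate of 0.32 matches the aggregate share of
compound symptoms across published per-questionnaire counts (99 of 305).
Reference columns are synthesized as a noisy union of the questionnaires
(dropout 0.15, addition 0.10) so coverage reports exercise both missing and
extra symptoms.

Two modes exist: `independent` (the null model above, cells independent)
and `prototype` (a shared base symptom set with per-instrument flip
probability ε), which plants controllable excess overlap — real coding
matrices are strongly dependent across instruments, and the prototype mode
is the regime where overlap far exceeds the independence prediction.
Randomness comes from numpy's `default_rng` (PCG64) seeded from the
configuration, so identical configurations give identical matrices across
platforms. `superset_matrix` builds the deterministic nested-instruments
regime (instrument i probes the first kᵢ symptoms) in which length and mean
overlap are positively correlated by construction.

What the generator does **not** emulate: correlated presence within
categories beyond the shared probability, realistic symptom label
semantics, instrument-specific category gaps, or the detailed marginals of
any real questionnaire set. Passing tests on synthetic matrices therefore
demonstrate the correctness of the bookkeeping and the statistics, not that
any particular real questionnaire set has a given overlap; real-data
conclusions require the real coding spreadsheet
(`scripts/reproduce_published.py`).

Questionnaire lengths for simulated matrices use ≈ 1.5 items per probed
symptom plus Poisson(2) jitter, the ratio observed in published adult
multi-disorder sleep questionnaires (469 symptom-related items for 305
symptom slots across 12 questionnaires).

## Numerical and design choices

* "Appeared in half of the questionnaires" is implemented as
  count ≥ ⌈n/2⌉ by default with an `at_least=False` switch for the strict
  reading (== n/2); the published spreadsheet needed to settle the reading
  empirically is not redistributable, so both remain available.
* Classification coverage pools multiple reference columns by union by
  default (per-list reports remain available); a reference symptom is
  covered iff some questionnaire has code > 0 for it, and the "extra" set
  holds questionnaire symptoms absent from *all* reference columns.
* Frequency tables sort by descending count with alphabetical tie-break;
  the category view sorts category-major in matrix row order, then by
  count. All sorts are stable, so outputs are deterministic.
* The report pipeline writes UTF-8, `\n`-terminated delimited text and
  fixed-dpi PNG figures, and records a SHA-256 checksum per artifact in
  `manifest.json`; reruns on identical inputs are byte-identical. Figures
  use matplotlib; an interactive radar export would be a convenience on
  top, not part of the contract.
* The acceptance script simulates at the default study shape (60 × 12 + 2)
  and checks the analytic oracle at 10,000 symptoms — sizes at which every
  quantity is stable to the printed precision while the whole script runs
  in seconds.

## Known limitations

* The analysis is purely presence-based: item wording quality, response
  scales, and psychometric properties (reliability, validity) are out of
  scope, as is any automated lumping/splitting of symptom labels.
* Jaccard indices on short symptom lists are coarse (few attainable
  values); category means over categories with 6–8 symptoms should be read
  with that granularity in mind.
* No alternative similarity coefficients (Dice, Kulczynski) are provided;
  the module boundaries leave room for them but the contract is
  Jaccard-only.
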