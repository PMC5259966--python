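# Methods

## Model and decision rule

A query protein *P* = (*a*₁, …, *a*_L) over the 20 canonical amino
acids is assigned to the class (human / non-human) with the larger
posterior probability. With Bayes' rule and the common evidence term
cancelled, the decision statistic is the log-odds

    log_odds(P) = [log P(H) + log P(P|H)] − [log P(NH) + log P(P|NH)],

positive for human. The class-conditional likelihood is the order-n
Markov approximation of the chain rule: the probability of a sequence
is the **product** of the conditional probabilities of its positions,
computed as a sum of logs. (Some presentations of this rule typeset the
decomposition as a sum of conditional probabilities; a sum is not what
the repeated application of the conditional-probability formula
produces, and only the product form yields a normalized sequence
distribution, so the product is what this package implements.)

Assumptions worth keeping in mind: residues beyond the (n−1)-residue
context carry no information (no long-range structure, no domain
grammar); the two training corpora are representative samples of their
classes; sequences are independent given their class.

## Estimation

Conditional probabilities are maximum-likelihood ratios of windowed
counts. Windows are taken strictly within each sequence — nothing is
counted across sequence boundaries. The denominator of P(r | c) is the
**left-prefix marginal** Σ_r′ C(c r′), not the raw count of
(n−1)-windows: the final (n−1)-window of every sequence has no n-gram
continuation, and using the raw window count would make each context's
conditional distribution sum to slightly less than one. The raw window
counts are retained in the count table for diagnostics. With the
marginal convention, every context with a nonzero denominator
normalizes exactly (checked to 1e−9 in the tests, exhaustively for
orders 1–2 on the full alphabet).

Class priors are the maximum-likelihood estimates n_H/(n_H+n_NH) from
the training corpus sizes, computed **after** de-duplication (the
corpora are filtered first, then counted); a flag restores pre-filter
counts for sensitivity analysis.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `order` (n) | 3 | context length + 1, in residues; `select-order` sweeps candidates by held-out perplexity |
| `smoothing.method` | `add-k` | `none` is pure MLE (unseen n-grams score 0 → −∞ log-likelihood sentinel; unseen contexts are an explicit error) |
| `smoothing.k` | 0.01 | pseudocount per n-gram cell, dimensionless; small enough not to distort well-observed contexts, large enough to keep every query scoreable |
| `prefix` | `eq4` | score positions n..L only (classical truncated n-gram score); `chain` adds lower-order terms for positions 1..n−1 so the full chain rule telescopes and sequences shorter than n remain scoreable |
| `margin` | 0 | extra log-odds (nats) demanded before a human call; 0 is the bare posterior comparison |
| `dedup threshold` | 0.9 | greedy-clustering identity threshold, fraction of the shorter sequence |

Natural logs are used throughout; the TSV report carries both the raw
log-odds and a per-scored-position log-odds because the raw statistic
grows linearly with sequence length — the decision deliberately uses
the raw value, the per-position column is for reading the ranking
across lengths.

The default order of 3 balances resolution against data demand: the
20-letter alphabet has 400 order-3 contexts, well covered by corpora of
tens of thousands of proteins, while order 4's 8000 contexts already
thin out. The `select-order` helper makes the choice empirical for any
given corpus.

## Sanitization

FASTA residues are uppercased and stripped of whitespace/digits; the
non-canonical codes (B, Z, J, X, U, O, `*`, gaps) are handled by
policy: `drop` (default — removes the character, keeping the 20-letter
event space closed and the rest of the sequence usable), `reject`
(hard error naming the residue and position), or `map-to-x` (counts the
residues as mapped-to-X in the report before removing them; the
retained residues equal the `drop` result, since X lies outside the
modelled alphabet). Records emptied by sanitization are omitted and
counted. Duplicate FASTA ids are a hard error to protect downstream
joins.

## Redundancy filtering

Training corpora are de-duplicated by greedy, longest-first clustering:
each sequence joins the first existing representative whose identity
with it reaches the threshold, otherwise it founds a new cluster.
Identity is defined as the maximum number of identical aligned
positions in a global alignment scored match=1 / mismatch=0 / gap=0,
divided by the shorter sequence's length — with those scores the
optimal alignment score *is* the maximum match count (equivalently the
longest-common-subsequence length), which makes the definition exactly
testable against a dynamic-programming oracle. This matches the
shorter-sequence normalization convention of the standard clustering
tools in spirit; bit-compatibility with any particular tool's word
filters and banded heuristics is a non-goal. On corpora above 5000
sequences a k-mer (k=5) Jaccard prefilter skips alignments for pairs
sharing under 10% of their k-mers; the prefilter can only skip a merge,
never force one, so representatives remain valid (at worst slightly
more numerous).

## Synthetic data

The simulator draws sequences from fully specified order-m chains: the
first m residues jointly from an initial context distribution, each
later residue from the transition row of its context. One root seed is
split into per-class and per-sequence substreams (numpy `SeedSequence`
spawning), so corpora are byte-reproducible and independent of
generation order. The chain's entropy rate has a closed form —
Σ_c π(c) H(T(c, ·)) with π the stationary distribution of the context
process — which gives exact targets for two bridges the tests verify:
held-out perplexity of a matched-order model converges to
exp(entropy rate) (within 2% at 400×500-residue training sequences),
and estimated conditionals converge to the generating transition rows
(max-abs error under 0.02 at 1000×200).

What the generator does **not** emulate: real amino-acid composition,
substitution structure, indels, domains, repeats, or any long-range
dependence. Passing tests therefore demonstrate that the estimator,
scorer and decision rule are correct and powerful *when the data really
are Markov*; they do not measure how sharply real human and non-human
proteomes separate, which depends on the corpora.

Test problem sizes (4-letter reduced alphabet for brute-force
tractability, with smoke coverage on the full 20 letters): benchmark
chains are independent Dirichlet(0.3) draws at order 2, 100
sequences/class of length 300 for the headline accuracy, training-size
sweep over 10/100/1000 per class; oracle equivalence uses 200+ random
corpora of ≤5 sequences, lengths ≤8, orders ≤3.

## Numerical choices and degenerate inputs

- All probability work is in log space; a zero factor yields a −∞
  sentinel rather than an exception, and a sequence with −∞ under both
  models is a flagged "unscoreable" tie with log-odds reported as 0
  (the value is mathematically undefined; 0 keeps the TSV sortable and
  the flag preserves the information).
- Exact log-odds 0 is labelled `tie`, never arbitrarily assigned:
  symmetric inputs must give symmetric outputs.
- Report rows sort by descending log-odds with lexicographic id
  tie-break; scores print with 6 significant digits.
- Model JSON files have sorted keys and a schema version; loading
  validates counts (non-negative integers, required fields) and
  re-saving a loaded model reproduces the file byte-for-byte.
- Probability vectors in chain specs must sum to 1 within 1e−12; the
  stationary distribution is obtained by a dense linear solve after a
  strong-connectivity check over the reachable contexts (a reducible
  context process has no unique stationary law and is an error naming
  the contexts outside the recurrent class).
- Sequences shorter than the order are an explicit error under the
  truncated score and scoreable under `chain`; an order-selection sweep
  flags, rather than fails on, orders exceeding the training sequences.

## Known limitations

- Log-odds scale with length; the margin parameter is in raw nats, so
  one margin means different stringency for a 50-residue and a
  2000-residue query. Use the per-position column when comparing across
  lengths.
- Greedy clustering is order-dependent by design (longest first, ties
  by id); it is deterministic but not a globally optimal clustering.
- The quadratic alignment stage is meant for desk-scale corpora; the
  k-mer prefilter mitigates but does not remove the O(N²) pair scan.
- Two-class only; no posterior calibration, no significance estimates
  for the scores.
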