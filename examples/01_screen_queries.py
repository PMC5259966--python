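"""Train two n-gram models on labeled corpora and screen query sequences.

Simulates a 'human' and a 'non-human' reference corpus from two known
Markov chains, fits an order-3 model to each, and classifies held-out
queries from the human-like chain by Bayesian log-odds.  With real data
you would replace the simulated corpora with `read_fasta(...)` calls on
your reference FASTA files.
"""

from protlm import (
    ClassPriors,
    SmoothingConfig,
    classify_corpus,
    generate_labeled_corpora,
    train_model,
    well_separated_pair,
)

ALPHABET = "ACDE"  # reduced alphabet keeps the demo small; use CANONICAL_AA for real data

spec_h, spec_nh = well_separated_pair(ALPHABET, order=2, seed=0)
train_h, train_nh = generate_labeled_corpora(spec_h, spec_nh, 100, ("fixed", 300), seed=1)
queries, _ = generate_labeled_corpora(spec_h, spec_nh, 10, ("fixed", 300), seed=2)

cfg = SmoothingConfig(method="add-k", k=0.01, alphabet_size=len(ALPHABET))
model_h = train_model(train_h, order=3, smoothing=cfg, alphabet=ALPHABET, class_label="human")
model_nh = train_model(train_nh, order=3, smoothing=cfg, alphabet=ALPHABET, class_label="non-human")
priors = ClassPriors(0.5, 0.5)

decisions, summary = classify_corpus(queries, model_h, model_nh, priors, margin=0.0)

print(f"{summary.n_human} of {summary.total} queries called human "
      f"({summary.n_nonhuman} non-human, {summary.n_tie} tie)")
print(f"{'id':<14}{'log_odds':>10}{'per_pos':>9}  label")
for d in decisions[:5]:
    print(f"{d.id:<14}{d.log_odds:>10.2f}{d.log_odds_per_pos:>9.3f}  {d.label}")
print("# positive log-odds means the human-class model explains the sequence")
print("# better than the non-human one, after weighting by the class priors.")
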