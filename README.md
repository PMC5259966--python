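# protlm

Amino-acid n-gram language models for screening protein sequences.

A large fraction of predicted human protein-coding genes still lack
protein-level experimental evidence — the "missing proteins" of the
human proteome, the most doubtful of which sit in the "uncertain" (PE5)
evidence tier. Before committing wet-lab effort to such candidates it is
useful to ask a purely statistical question: *does this sequence read
like a native human protein?* `protlm` answers it with the statistical
machinery of language modelling, treating amino acids as words and
proteins as sentences. It is aimed at proteomics and bioinformatics
researchers who want a transparent, fully reproducible sequence-only
screen, and at anyone who needs a well-tested protein n-gram/Markov
model toolkit.

## The model

Given a protein *P* = (*a*₁, …, *a*_L), the screen compares the two
posteriors

&nbsp;&nbsp;&nbsp;&nbsp;P(H | P) &gt; P(NH | P)

for the human (H) and non-human (NH) classes. By Bayes' rule, with the
shared evidence term cancelled, this is the sign of the log-odds

&nbsp;&nbsp;&nbsp;&nbsp;log-odds(P) = [log P(H) + log P(P|H)] − [log P(NH) + log P(P|NH)].

Each class-conditional likelihood is approximated by an order-*n*
Markov (n-gram) model — every residue depends only on its *n*−1
predecessors — so that

&nbsp;&nbsp;&nbsp;&nbsp;log P(P | H) ≈ Σ_{i=n}^{L} log P(a_i | a_{i−n+1} … a_{i−1}, H),

with conditional probabilities estimated by maximum likelihood from
windowed n-gram counts over the class corpus,

&nbsp;&nbsp;&nbsp;&nbsp;P(a_i | a_{i−n+1} … a_{i−1}) = C(a_{i−n+1} … a_i) / Σ_r C(a_{i−n+1} … a_{i−1} r),

optionally with add-k smoothing (default k = 0.01) so unseen n-grams do
not zero out a whole sequence. Class priors P(H), P(NH) are the
maximum-likelihood estimates from the training corpus sizes. The
training corpora are first de-duplicated at 90% sequence identity by a
deterministic greedy clustering stage so that large protein families do
not dominate the counts.

Everything is testable without downloads: a seedable Markov-chain
simulator generates labeled corpora from fully specified transition
matrices, whose entropy rates (and hence the perplexity floor any model
can reach) have closed forms.

## Worked example

`examples/01_screen_queries.py` simulates a human-like and a
non-human-like reference corpus from two known order-2 chains, fits an
order-3 model to each, and screens ten held-out queries drawn from the
human-like chain:

```
10 of 10 queries called human (0 non-human, 0 tie)
id              log_odds  per_pos  label
classA_0001       340.08    1.141  human
classA_0002       365.19    1.225  human
classA_0003       354.79    1.191  human
classA_0004       349.18    1.172  human
classA_0005       326.30    1.095  human
```

`log_odds` is the posterior log-odds above; +340 nats means the
human-class model explains the 300-residue query overwhelmingly better.
`per_pos` divides by the number of scored positions, making sequences
of different lengths comparable. `examples/02_order_selection.py` shows
the held-out perplexity sweep bottoming out at order 3 for an order-2
source (2.29 against an entropy-rate floor of 2.31), and
`examples/03_deduplicate.py` collapses two families of near-duplicates
to their two founders at the 0.9 identity threshold.

The same workflow is available from the shell:

```bash
protlm train --human human.fasta --nonhuman nonhuman.fasta \
             --order 3 --dedup-threshold 0.9 --out-dir models/
protlm classify --human-model models/H.json --nonhuman-model models/NH.json \
                --priors models/priors.json --query pe5.fasta --out report.tsv
protlm cluster --in corpus.fasta --threshold 0.9 --out reps.fasta --map map.tsv
protlm simulate --spec spec.yaml --n 100 --length 300 --seed 42 --out a.fasta b.fasta
protlm select-order --in corpus.fasta --orders 1,2,3,4
```

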