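"""protlm — amino-acid n-gram language models for protein screening.

Train order-n Markov models on two reference corpora (e.g. reviewed
human and non-human proteins), combine them with maximum-likelihood
class priors into a Bayesian log-odds rule, and screen query sequences
for their probability of being native human gene-coding proteins.
Includes a CD-HIT-style greedy identity de-duplication stage and a
seedable Markov-chain simulator with closed-form entropy rates.
"""

from .classifier import (
    ClassificationSummary,
    ClassPriors,
    Decision,
    classify_corpus,
    estimate_priors,
    score,
)
from .errors import (
    DuplicateIdError,
    FastaFormatError,
    ModelConfigError,
    ParameterError,
    ProtlmError,
    ReducibleChainError,
    SanitizationError,
    SchemaError,
    TooShortError,
    UndefinedContextError,
)
from .ngram import (
    NgramCountTable,
    NgramModel,
    SmoothingConfig,
    conditional_prob,
    count_ngrams,
    load_model,
    log_likelihood,
    n_scored_positions,
    perplexity,
    save_model,
    train_model,
)
from .pipeline import (
    OrderScore,
    TrainResult,
    load_priors,
    save_priors,
    select_order,
    train_models,
)
from .redundancy import ClusterResult, greedy_cluster, pairwise_identity
from .sequence_io import (
    CANONICAL_AA,
    Corpus,
    ProteinSequence,
    SanitizationReport,
    read_fasta,
    sanitize,
    write_fasta,
    write_tsv_report,
)
from .synthetic import (
    ChainSpec,
    chain_entropy_rate,
    context_labels,
    generate_labeled_corpora,
    kl_rate,
    random_chain_spec,
    sample_sequence,
    uniform_iid_spec,
    well_separated_pair,
)

__version__ = "1.0.0"

__all__ = [
    "CANONICAL_AA",
    "ChainSpec",
    "ClassificationSummary",
    "ClassPriors",
    "ClusterResult",
    "Corpus",
    "Decision",
    "DuplicateIdError",
    "FastaFormatError",
    "ModelConfigError",
    "NgramCountTable",
    "NgramModel",
    "OrderScore",
    "ParameterError",
    "ProteinSequence",
    "ProtlmError",
    "ReducibleChainError",
    "SanitizationError",
    "SanitizationReport",
    "SchemaError",
    "SmoothingConfig",
    "TooShortError",
    "TrainResult",
    "UndefinedContextError",
    "chain_entropy_rate",
    "classify_corpus",
    "conditional_prob",
    "context_labels",
    "count_ngrams",
    "estimate_priors",
    "generate_labeled_corpora",
    "greedy_cluster",
    "kl_rate",
    "load_model",
    "load_priors",
    "log_likelihood",
    "n_scored_positions",
    "pairwise_identity",
    "perplexity",
    "random_chain_spec",
    "read_fasta",
    "sample_sequence",
    "sanitize",
    "save_model",
    "save_priors",
    "score",
    "select_order",
    "train_model",
    "train_models",
    "uniform_iid_spec",
    "well_separated_pair",
    "write_fasta",
    "write_tsv_report",
]
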