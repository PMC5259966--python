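"""Bayesian two-class decision rule over a pair of n-gram models.

A query protein P is called human when the human-class posterior exceeds
the non-human one, P(H|P) > P(NH|P).  With Bayes' rule and the shared
evidence term cancelled, the comparison reduces to the log-odds

    log_odds(P) = [log P(H) + log P(P|H)] - [log P(NH) + log P(P|NH)],

with each class-conditional log-likelihood supplied by that class's
n-gram model.  Class priors are the maximum-likelihood estimates from
the training corpus sizes.

Because the log-odds of an n-gram ratio grows with sequence length, the
report also carries a per-scored-position log-odds; the decision itself
uses the raw value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

from .errors import ModelConfigError, ParameterError
from .ngram import NEG_INF, NgramModel, log_likelihood, n_scored_positions
from .sequence_io import Corpus, ProteinSequence

LABEL_HUMAN = "human"
LABEL_NONHUMAN = "non-human"
LABEL_TIE = "tie"


@dataclass(frozen=True)
class ClassPriors:
    """Prior class probabilities P(H) and P(NH)."""

    p_human: float
    p_nonhuman: float

    def __post_init__(self) -> None:
        if not (self.p_human > 0 and self.p_nonhuman > 0):
            raise ParameterError("both priors must be strictly positive")
        if abs(self.p_human + self.p_nonhuman - 1.0) > 1e-12:
            raise ParameterError(
                f"priors must sum to 1, got {self.p_human + self.p_nonhuman!r}"
            )

    def log_odds(self) -> float:
        return math.log(self.p_human) - math.log(self.p_nonhuman)

    def swapped(self) -> "ClassPriors":
        return ClassPriors(p_human=self.p_nonhuman, p_nonhuman=self.p_human)


def estimate_priors(n_human: int, n_nonhuman: int) -> ClassPriors:
    """Maximum-likelihood priors from training corpus sizes."""
    if n_human < 1 or n_nonhuman < 1:
        raise ParameterError("both corpus sizes must be >= 1")
    total = n_human + n_nonhuman
    return ClassPriors(p_human=n_human / total, p_nonhuman=n_nonhuman / total)


@dataclass(frozen=True)
class Decision:
    """Per-sequence score and call.

    ``unscoreable`` marks sequences whose likelihood vanished under both
    models (possible only without smoothing); their log-odds is reported
    as 0 and the label is a flagged tie.
    """

    id: str
    length: int
    loglik_human: float
    loglik_nonhuman: float
    log_odds: float
    label: str
    n_scored: int
    log_odds_per_pos: float
    unscoreable: bool = False


@dataclass(frozen=True)
class ClassificationSummary:
    n_human: int
    n_nonhuman: int
    n_tie: int
    n_unscoreable: int
    margin: float

    @property
    def total(self) -> int:
        return self.n_human + self.n_nonhuman + self.n_tie


def _check_compatible(model_h: NgramModel, model_nh: NgramModel) -> None:
    if model_h.order != model_nh.order:
        raise ModelConfigError(
            f"model order mismatch: {model_h.order} vs {model_nh.order}"
        )
    if model_h.smoothing != model_nh.smoothing:
        raise ModelConfigError("model smoothing configuration mismatch")
    if model_h.alphabet != model_nh.alphabet:
        raise ModelConfigError("model alphabet mismatch")


def score(
    seq: ProteinSequence,
    model_h: NgramModel,
    model_nh: NgramModel,
    priors: ClassPriors,
    prefix: str = "eq4",
) -> Decision:
    """Score one sequence against the two class models.

    The label follows the sign of the log-odds: human when positive,
    non-human when negative, tie at exactly zero.  A -inf likelihood on
    one side forces the opposite label; -inf on both sides yields a
    flagged unscoreable tie.
    """
    _check_compatible(model_h, model_nh)
    ll_h = log_likelihood(model_h, seq, prefix)
    ll_nh = log_likelihood(model_nh, seq, prefix)
    pos = n_scored_positions(model_h, seq, prefix)
    if ll_h == NEG_INF and ll_nh == NEG_INF:
        return Decision(
            id=seq.id, length=seq.length, loglik_human=ll_h, loglik_nonhuman=ll_nh,
            log_odds=0.0, label=LABEL_TIE, n_scored=pos, log_odds_per_pos=0.0,
            unscoreable=True,
        )
    log_odds = (math.log(priors.p_human) + ll_h) - (math.log(priors.p_nonhuman) + ll_nh)
    if log_odds > 0:
        label = LABEL_HUMAN
    elif log_odds < 0:
        label = LABEL_NONHUMAN
    else:
        label = LABEL_TIE
    per_pos = log_odds / pos if pos > 0 and math.isfinite(log_odds) else log_odds
    return Decision(
        id=seq.id, length=seq.length, loglik_human=ll_h, loglik_nonhuman=ll_nh,
        log_odds=log_odds, label=label, n_scored=pos, log_odds_per_pos=per_pos,
    )


def classify_corpus(
    corpus: Corpus,
    model_h: NgramModel,
    model_nh: NgramModel,
    priors: ClassPriors,
    margin: float = 0.0,
    prefix: str = "eq4",
) -> tuple[list[Decision], ClassificationSummary]:
    """Score every sequence, calling human only above the margin.

    ``margin=0`` reproduces the bare posterior comparison; a positive
    margin demands that much extra log-odds before a human call.  Input
    order is preserved.
    """
    if not (margin >= 0):
        raise ParameterError(f"margin must be >= 0, got {margin}")
    if len(corpus) == 0:
        raise ParameterError("cannot classify an empty corpus")
    decisions: list[Decision] = []
    n_h = n_nh = n_tie = n_unsc = 0
    for seq in corpus:
        d = score(seq, model_h, model_nh, priors, prefix)
        if d.unscoreable:
            label = LABEL_TIE
        elif d.log_odds > margin:
            label = LABEL_HUMAN
        elif d.log_odds == 0.0:
            label = LABEL_TIE
        else:
            label = LABEL_NONHUMAN
        if label != d.label:
            d = replace(d, label=label)
        decisions.append(d)
        if d.unscoreable:
            n_unsc += 1
        if label == LABEL_HUMAN:
            n_h += 1
        elif label == LABEL_NONHUMAN:
            n_nh += 1
        else:
            n_tie += 1
    summary = ClassificationSummary(
        n_human=n_h, n_nonhuman=n_nh, n_tie=n_tie, n_unscoreable=n_unsc, margin=margin
    )
    return decisions, summary
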