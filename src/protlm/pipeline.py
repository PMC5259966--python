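"""End-to-end training and model-order selection.

The training pipeline mirrors the screening workflow: optionally
de-duplicate each reference corpus at an identity threshold, count
n-grams on what remains, and estimate the class priors from the
*post*-deduplication corpus sizes (filter first, then count).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .classifier import ClassPriors, estimate_priors
from .errors import ParameterError
from .ngram import NgramModel, SmoothingConfig, perplexity, train_model
from .redundancy import ClusterResult, greedy_cluster
from .sequence_io import CANONICAL_AA, Corpus


@dataclass(frozen=True)
class TrainResult:
    model_human: NgramModel
    model_nonhuman: NgramModel
    priors: ClassPriors
    n_human_raw: int
    n_nonhuman_raw: int
    n_human_used: int
    n_nonhuman_used: int
    cluster_human: ClusterResult | None = None
    cluster_nonhuman: ClusterResult | None = None


def train_models(
    corpus_human: Corpus,
    corpus_nonhuman: Corpus,
    order: int = 3,
    smoothing: SmoothingConfig | None = None,
    dedup_threshold: float | None = None,
    alphabet: str = CANONICAL_AA,
    priors_from_raw_counts: bool = False,
) -> TrainResult:
    """Fit the two class models and the priors in one step.

    When ``dedup_threshold`` is set, each corpus is greedily clustered at
    that identity threshold first and only the representatives are
    counted.  Priors default to the post-deduplication sizes;
    ``priors_from_raw_counts=True`` uses the raw sizes instead (for
    sensitivity analysis).
    """
    if smoothing is None:
        smoothing = SmoothingConfig(alphabet_size=len(alphabet))
    cl_h = cl_nh = None
    used_h, used_nh = corpus_human, corpus_nonhuman
    if dedup_threshold is not None:
        cl_h = greedy_cluster(corpus_human, dedup_threshold)
        cl_nh = greedy_cluster(corpus_nonhuman, dedup_threshold)
        used_h, used_nh = cl_h.representatives, cl_nh.representatives
    model_h = train_model(used_h, order, smoothing, alphabet, class_label="human")
    model_nh = train_model(used_nh, order, smoothing, alphabet, class_label="non-human")
    if priors_from_raw_counts:
        priors = estimate_priors(len(corpus_human), len(corpus_nonhuman))
    else:
        priors = estimate_priors(len(used_h), len(used_nh))
    return TrainResult(
        model_human=model_h,
        model_nonhuman=model_nh,
        priors=priors,
        n_human_raw=len(corpus_human),
        n_nonhuman_raw=len(corpus_nonhuman),
        n_human_used=len(used_h),
        n_nonhuman_used=len(used_nh),
        cluster_human=cl_h,
        cluster_nonhuman=cl_nh,
    )


def save_priors(priors: ClassPriors, result: TrainResult, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "p_human": priors.p_human,
        "p_nonhuman": priors.p_nonhuman,
        "n_human": result.n_human_used,
        "n_nonhuman": result.n_nonhuman_used,
        "n_human_raw": result.n_human_raw,
        "n_nonhuman_raw": result.n_nonhuman_raw,
    }
    with open(path, "w") as handle:
        json.dump(doc, handle, sort_keys=True, indent=1)
        handle.write("\n")
    return path


def load_priors(path: str | Path) -> ClassPriors:
    with open(path) as handle:
        doc = json.load(handle)
    return ClassPriors(p_human=doc["p_human"], p_nonhuman=doc["p_nonhuman"])


@dataclass(frozen=True)
class OrderScore:
    """Held-out perplexity for one candidate order."""

    order: int
    heldout_perplexity: float | None
    flagged: bool = False
    note: str = ""


def select_order(
    corpus: Corpus,
    orders: list[int],
    holdout_fraction: float = 0.2,
    seed: int = 0,
    smoothing: SmoothingConfig | None = None,
    alphabet: str = CANONICAL_AA,
) -> tuple[list[OrderScore], int | None]:
    """Sweep model orders by held-out perplexity.

    The corpus is split deterministically by seed; each order's model is
    trained on the training part and scored on the holdout.  Orders that
    exceed the longest training sequence are flagged rather than fatal.
    Returns the score table and the recommended (argmin) order, or None
    when every order is flagged.
    """
    if not orders:
        raise ParameterError("orders list must be non-empty")
    if not (0.0 < holdout_fraction < 1.0):
        raise ParameterError(f"holdout_fraction must be in (0, 1), got {holdout_fraction}")
    n = len(corpus)
    if n < 2:
        raise ParameterError("need at least 2 sequences to hold some out")
    if smoothing is None:
        smoothing = SmoothingConfig(alphabet_size=len(alphabet))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_hold = min(max(1, round(holdout_fraction * n)), n - 1)
    hold_idx = set(int(i) for i in perm[:n_hold])
    train_seqs = tuple(corpus[i] for i in range(n) if i not in hold_idx)
    hold_seqs = tuple(corpus[i] for i in range(n) if i in hold_idx)
    train = Corpus(label=corpus.label + "/train", sequences=train_seqs)
    hold = Corpus(label=corpus.label + "/holdout", sequences=hold_seqs)
    max_len = max(s.length for s in train)
    scores: list[OrderScore] = []
    for order in orders:
        if order < 1:
            scores.append(OrderScore(order, None, True, "order < 1"))
            continue
        if order > max_len:
            scores.append(OrderScore(order, None, True,
                                     f"order exceeds longest training sequence ({max_len})"))
            continue
        model = train_model(train, order, smoothing, alphabet)
        try:
            ppl = perplexity(model, hold)
        except ParameterError as exc:
            scores.append(OrderScore(order, None, True, str(exc)))
            continue
        scores.append(OrderScore(order, ppl))
    usable = [s for s in scores if not s.flagged and math.isfinite(s.heldout_perplexity)]
    recommended = min(usable, key=lambda s: s.heldout_perplexity).order if usable else None
    return scores, recommended
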