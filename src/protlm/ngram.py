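"""Amino-acid n-gram Markov models.

An order-``n`` model assumes each residue depends only on the ``n-1``
residues preceding it.  Conditional probabilities are estimated by
maximum likelihood from windowed n-gram counts,

    P(r | c) = C(c + r) / sum_r' C(c + r'),

optionally regularized by add-k smoothing,

    P(r | c) = (C(c + r) + k) / (sum_r' C(c + r') + k * |A|),

with |A| the alphabet size.  The denominator is the *left-prefix
marginal* of the n-gram counts, not the raw count of (n-1)-windows: the
final (n-1)-window of every sequence never extends to an n-gram, and
using the raw count would leave each context's conditional distribution
summing to less than one.  The raw window count is retained in the count
table for diagnostics.

A sequence's log-likelihood is the sum of the log conditional
probabilities of its scoreable positions (the product form of the chain
rule, computed in log space to avoid underflow).  Two prefix modes are
offered: ``eq4`` starts at position n, discarding the first n-1 residues
(the classical truncated n-gram score); ``chain`` additionally scores
positions 1..n-1 with the lower-order models so the full chain-rule
factorization telescopes and sequences shorter than the order remain
scoreable.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import (
    ModelConfigError,
    ParameterError,
    SchemaError,
    TooShortError,
    UndefinedContextError,
)
from .sequence_io import CANONICAL_AA, Corpus, ProteinSequence

SCHEMA_VERSION = 1

NEG_INF = float("-inf")


@dataclass(frozen=True)
class SmoothingConfig:
    """How unseen n-grams are handled.

    ``none`` reproduces pure maximum likelihood: unseen n-grams score
    probability zero and unseen contexts are an explicit error.  ``add-k``
    adds a pseudocount ``k`` (default 0.01) to every cell so every
    conditional probability is strictly positive.
    """

    method: str = "add-k"
    k: float = 0.01
    alphabet_size: int = 20

    def __post_init__(self) -> None:
        if self.method not in ("none", "add-k"):
            raise ParameterError(f"unknown smoothing method {self.method!r}")
        if self.method == "add-k" and not self.k > 0:
            raise ParameterError(f"add-k smoothing requires k > 0, got {self.k}")
        if self.alphabet_size < 2:
            raise ParameterError("alphabet_size must be at least 2")


@dataclass(frozen=True)
class NgramCountTable:
    """Windowed n-gram counts for one order.

    ``counts_n`` maps each observed n-gram to its count; ``counts_context``
    holds the raw (n-1)-window counts (diagnostics only — see module
    docstring); ``context_totals`` holds the left-prefix marginals used as
    conditional-probability denominators.  Windows are taken strictly
    within each sequence; nothing is counted across sequence boundaries.
    """

    order: int
    counts_n: Mapping[str, int]
    counts_context: Mapping[str, int]
    context_totals: Mapping[str, int] = field(default=None)  # type: ignore[assignment]
    total_tokens: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ParameterError(f"order must be >= 1, got {self.order}")
        if any(v < 0 for v in self.counts_n.values()):
            raise SchemaError("negative n-gram count")
        if any(v < 0 for v in self.counts_context.values()):
            raise SchemaError("negative context count")
        if self.context_totals is None:
            totals: dict[str, int] = {}
            for gram, c in self.counts_n.items():
                ctx = gram[:-1]
                totals[ctx] = totals.get(ctx, 0) + c
            object.__setattr__(self, "context_totals", totals)
        if self.total_tokens is None:
            object.__setattr__(self, "total_tokens", sum(self.counts_n.values()))


def count_ngrams(corpus: Corpus | Iterable[ProteinSequence], order: int) -> NgramCountTable:
    """Count all within-sequence windows of length ``order`` and ``order-1``.

    A sequence of length L contributes max(L - order + 1, 0) n-gram
    windows.  Emits a warning and returns an empty table when no sequence
    is long enough.
    """
    if order < 1:
        raise ParameterError(f"order must be >= 1, got {order}")
    seqs = list(corpus)
    if not seqs:
        raise ParameterError("cannot count n-grams over an empty corpus")
    counts_n: dict[str, int] = {}
    counts_ctx: dict[str, int] = {}
    m = order - 1
    for seq in seqs:
        s = seq.residues if isinstance(seq, ProteinSequence) else str(seq)
        L = len(s)
        for i in range(L - order + 1):
            g = s[i : i + order]
            counts_n[g] = counts_n.get(g, 0) + 1
        if m == 0:
            counts_ctx[""] = counts_ctx.get("", 0) + L + 1
        else:
            for i in range(L - m + 1):
                c = s[i : i + m]
                counts_ctx[c] = counts_ctx.get(c, 0) + 1
    if not counts_n:
        warnings.warn(
            f"all sequences shorter than order {order}; count table is empty",
            stacklevel=2,
        )
    return NgramCountTable(order=order, counts_n=counts_n, counts_context=counts_ctx)


@dataclass(frozen=True)
class NgramModel:
    """An order-n model plus the lower-order tables down to order 1.

    The lower orders serve the ``chain`` prefix mode and short sequences;
    the order-n table alone defines the classical truncated score.
    """

    order: int
    smoothing: SmoothingConfig
    tables: Mapping[int, NgramCountTable]
    alphabet: str = CANONICAL_AA
    class_label: str = ""

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ParameterError(f"order must be >= 1, got {self.order}")
        if len(self.alphabet) != self.smoothing.alphabet_size:
            raise ModelConfigError(
                f"alphabet has {len(self.alphabet)} letters but smoothing declares "
                f"{self.smoothing.alphabet_size}"
            )
        missing = [n for n in range(1, self.order + 1) if n not in self.tables]
        if missing:
            raise ModelConfigError(f"missing count tables for orders {missing}")

    @property
    def counts(self) -> NgramCountTable:
        return self.tables[self.order]


def train_model(
    corpus: Corpus | Iterable[ProteinSequence],
    order: int,
    smoothing: SmoothingConfig | None = None,
    alphabet: str = CANONICAL_AA,
    class_label: str = "",
) -> NgramModel:
    """Estimate an :class:`NgramModel` of the given order from a corpus."""
    if smoothing is None:
        smoothing = SmoothingConfig(alphabet_size=len(alphabet))
    seqs = list(corpus)
    tables = {n: count_ngrams(seqs, n) for n in range(1, order + 1)}
    return NgramModel(
        order=order, smoothing=smoothing, tables=tables,
        alphabet=alphabet, class_label=class_label,
    )


def conditional_prob(model: NgramModel, context: str, residue: str) -> float:
    """P(residue | context) under the model's smoothing configuration.

    The context length selects the table: a context of length m is scored
    by the order-(m+1) table, so both the model's own order and the lower
    orders (used by the ``chain`` prefix mode) are reachable.

    Raises
    ------
    UndefinedContextError
        Unseen context under ``method=none`` (never a silent 0/0).
    """
    if len(residue) != 1 or residue not in model.alphabet:
        raise ParameterError(f"residue {residue!r} not in model alphabet")
    n = len(context) + 1
    if n not in model.tables:
        raise ParameterError(
            f"context length {len(context)} has no table in an order-{model.order} model"
        )
    table = model.tables[n]
    num = table.counts_n.get(context + residue, 0)
    den = table.context_totals.get(context, 0)
    cfg = model.smoothing
    if cfg.method == "none":
        if den == 0:
            raise UndefinedContextError(
                f"context {context!r} unseen in training; undefined under MLE without smoothing"
            )
        return num / den
    return (num + cfg.k) / (den + cfg.k * cfg.alphabet_size)


def n_scored_positions(model: NgramModel, seq: ProteinSequence | str, prefix: str = "eq4") -> int:
    """Number of positions contributing log terms under the prefix mode."""
    L = len(seq.residues if isinstance(seq, ProteinSequence) else seq)
    if prefix == "chain":
        return L
    return max(L - model.order + 1, 0)


def log_likelihood(model: NgramModel, seq: ProteinSequence | str, prefix: str = "eq4") -> float:
    """Sequence log-likelihood in natural-log units.

    ``prefix='eq4'`` sums log P(a_i | a_{i-n+1}..a_{i-1}) for i = n..L;
    ``prefix='chain'`` additionally scores positions 1..n-1 with the
    lower-order tables so the full chain rule telescopes.  Any zero
    factor (including an unseen context under ``method=none``) yields the
    -inf sentinel, never an exception.

    Raises
    ------
    TooShortError
        Sequence shorter than the order under ``prefix='eq4'``.
    """
    if prefix not in ("eq4", "chain"):
        raise ParameterError(f"unknown prefix mode {prefix!r}")
    s = seq.residues if isinstance(seq, ProteinSequence) else str(seq)
    n, L = model.order, len(s)
    if L < n and prefix == "eq4":
        raise TooShortError(
            f"sequence of length {L} is shorter than order {n}; "
            "use prefix='chain' to score it with lower-order terms"
        )
    total = 0.0
    start = n - 1
    if prefix == "chain":
        for i in range(min(n - 1, L)):
            try:
                p = conditional_prob(model, s[:i], s[i])
            except UndefinedContextError:
                return NEG_INF
            if p == 0.0:
                return NEG_INF
            total += math.log(p)
    for i in range(start, L):
        try:
            p = conditional_prob(model, s[i - n + 1 : i], s[i])
        except UndefinedContextError:
            return NEG_INF
        if p == 0.0:
            return NEG_INF
        total += math.log(p)
    return total


def perplexity(model: NgramModel, corpus: Corpus | Iterable[ProteinSequence],
               prefix: str = "eq4") -> float:
    """exp(mean negative log-likelihood per scored position); lower is better.

    Any -inf sequence log-likelihood makes the perplexity +inf.
    """
    seqs = list(corpus)
    if not seqs:
        raise ParameterError("cannot compute perplexity over an empty corpus")
    total_ll = 0.0
    total_pos = 0
    for seq in seqs:
        pos = n_scored_positions(model, seq, prefix)
        if pos == 0:
            continue
        ll = log_likelihood(model, seq, prefix)
        if ll == NEG_INF:
            return float("inf")
        total_ll += ll
        total_pos += pos
    if total_pos == 0:
        raise ParameterError("no scoreable window in corpus at this order")
    return math.exp(-total_ll / total_pos)


# -- serialization ----------------------------------------------------------

def save_model(model: NgramModel, path: str | Path) -> Path:
    """Write the model as a versioned, deterministically ordered JSON file."""
    path = Path(path)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "order": model.order,
        "class_label": model.class_label,
        "alphabet": model.alphabet,
        "smoothing": {
            "method": model.smoothing.method,
            "k": model.smoothing.k,
            "alphabet_size": model.smoothing.alphabet_size,
        },
        "tables": {
            str(n): {
                "counts_n": dict(sorted(t.counts_n.items())),
                "counts_context": dict(sorted(t.counts_context.items())),
            }
            for n, t in sorted(model.tables.items())
        },
    }
    with open(path, "w") as handle:
        json.dump(doc, handle, sort_keys=True, indent=1)
        handle.write("\n")
    return path


def load_model(path: str | Path) -> NgramModel:
    """Load a model written by :func:`save_model`, validating the schema."""
    with open(path) as handle:
        doc = json.load(handle)
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"model file {path} has schema_version {version!r}; this build reads {SCHEMA_VERSION}"
        )
    for key in ("order", "smoothing", "tables", "alphabet"):
        if key not in doc:
            raise SchemaError(f"model file {path} is missing field {key!r}")
    smoothing = SmoothingConfig(**doc["smoothing"])
    tables: dict[int, NgramCountTable] = {}
    for key, raw in doc["tables"].items():
        if "counts_n" not in raw or "counts_context" not in raw:
            raise SchemaError(f"table {key!r} in {path} is missing counts_n/counts_context")
        n = int(key)
        for name in ("counts_n", "counts_context"):
            for gram, c in raw[name].items():
                if not isinstance(c, int) or c < 0:
                    raise SchemaError(
                        f"table {key!r} in {path}: {name}[{gram!r}] = {c!r} is not a "
                        "non-negative integer"
                    )
        tables[n] = NgramCountTable(
            order=n, counts_n=raw["counts_n"], counts_context=raw["counts_context"]
        )
    return NgramModel(
        order=int(doc["order"]),
        smoothing=smoothing,
        tables=tables,
        alphabet=doc["alphabet"],
        class_label=doc.get("class_label", ""),
    )
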