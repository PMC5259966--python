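"""Seedable Markov-chain generators for protein-like sequences.

Every other module is testable without downloads because this one can
produce labeled corpora from fully specified chains: the transition
matrix is known, so conditional probabilities, entropy rates and hence
achievable perplexities have closed forms to compare against.

A :class:`ChainSpec` describes a stationary order-m chain: the first m
residues are drawn jointly from ``initial_dist`` over the m-length
contexts, every later residue from ``transition[previous m residues]``.
Order 0 means i.i.d. residues.  Randomness flows through numpy
``SeedSequence`` spawning — one root seed, per-class and per-sequence
substreams — so generated corpora are byte-reproducible and independent
of generation order.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ParameterError, ReducibleChainError
from .sequence_io import CANONICAL_AA, Corpus, ProteinSequence

_PROB_TOL = 1e-12


def context_labels(alphabet: str, order: int) -> tuple[str, ...]:
    """All length-``order`` context strings in alphabet-product order."""
    if order == 0:
        return ("",)
    return tuple("".join(t) for t in itertools.product(alphabet, repeat=order))


def _check_prob_vector(v: np.ndarray, what: str, size: int) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (size,):
        raise ParameterError(f"{what}: expected {size} probabilities, got shape {v.shape}")
    if np.any(v < 0):
        raise ParameterError(f"{what}: negative probability")
    if abs(float(v.sum()) - 1.0) > _PROB_TOL:
        raise ParameterError(f"{what}: probabilities sum to {v.sum()!r}, not 1")
    return v


@dataclass(frozen=True)
class ChainSpec:
    """A fully specified order-m Markov chain over a residue alphabet.

    ``transition`` may cover only the contexts actually reachable from
    the initial distribution; sampling an undefined context is an error.
    """

    alphabet: str = CANONICAL_AA
    order: int = 0
    initial_dist: np.ndarray | None = None
    transition: Mapping[str, np.ndarray] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ParameterError(f"order must be >= 0, got {self.order}")
        if len(set(self.alphabet)) != len(self.alphabet) or not self.alphabet:
            raise ParameterError("alphabet must be non-empty with unique letters")
        A = len(self.alphabet)
        trans = {}
        for ctx, row in self.transition.items():
            if len(ctx) != self.order:
                raise ParameterError(
                    f"transition context {ctx!r} has length {len(ctx)}, expected {self.order}"
                )
            trans[ctx] = _check_prob_vector(row, f"transition[{ctx!r}]", A)
        if not trans:
            raise ParameterError("transition map must not be empty")
        object.__setattr__(self, "transition", trans)
        if self.order == 0:
            init = self.transition[""] if self.initial_dist is None else np.asarray(
                self.initial_dist, dtype=float
            )
            init = _check_prob_vector(init, "initial_dist", A)
        else:
            if self.initial_dist is None:
                raise ParameterError("initial_dist is required for order >= 1")
            init = _check_prob_vector(
                np.asarray(self.initial_dist, dtype=float), "initial_dist", A ** self.order
            )
        object.__setattr__(self, "initial_dist", init)

    def to_dict(self) -> dict:
        """Plain-python form for YAML/JSON serialization."""
        return {
            "alphabet": self.alphabet,
            "order": self.order,
            "initial_dist": [float(x) for x in self.initial_dist],
            "transition": {c: [float(x) for x in row] for c, row in sorted(self.transition.items())},
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ChainSpec":
        return cls(
            alphabet=doc["alphabet"],
            order=int(doc["order"]),
            initial_dist=np.asarray(doc["initial_dist"], dtype=float)
            if doc.get("initial_dist") is not None else None,
            transition={c: np.asarray(row, dtype=float) for c, row in doc["transition"].items()},
            seed=doc.get("seed"),
        )


def uniform_iid_spec(alphabet: str = CANONICAL_AA, seed: int | None = None) -> ChainSpec:
    """I.i.d. uniform residues; entropy rate log |alphabet|."""
    A = len(alphabet)
    return ChainSpec(alphabet=alphabet, order=0,
                     transition={"": np.full(A, 1.0 / A)}, seed=seed)


def random_chain_spec(
    alphabet: str,
    order: int,
    seed: int,
    concentration: float = 1.0,
) -> ChainSpec:
    """Draw a chain with Dirichlet-distributed transition rows.

    Smaller ``concentration`` gives spikier rows, hence lower entropy
    and chains that are easier to tell apart.  Initial distribution is
    uniform over contexts.
    """
    if concentration <= 0:
        raise ParameterError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    A = len(alphabet)
    contexts = context_labels(alphabet, order)
    transition = {
        c: rng.dirichlet(np.full(A, concentration)) for c in contexts
    }
    n_ctx = len(contexts)
    init = np.full(n_ctx, 1.0 / n_ctx) if order >= 1 else None
    return ChainSpec(alphabet=alphabet, order=order, initial_dist=init,
                     transition=transition, seed=seed)


def well_separated_pair(
    alphabet: str = "ACDE",
    order: int = 2,
    seed: int = 0,
    concentration: float = 0.3,
) -> tuple[ChainSpec, ChainSpec]:
    """Two independently drawn, hence well-separated, chains of one order.

    The default 4-letter reduced alphabet keeps brute-force checks
    tractable; the low Dirichlet concentration makes the per-position
    Kullback-Leibler gap between the classes comfortably positive.
    """
    rng = np.random.default_rng(seed)
    s1, s2 = rng.integers(0, 2**31 - 1, size=2)
    return (
        random_chain_spec(alphabet, order, int(s1), concentration),
        random_chain_spec(alphabet, order, int(s2), concentration),
    )


def sample_sequence(
    spec: ChainSpec,
    length: int,
    rng: np.random.Generator | None = None,
    id: str = "sim",
) -> ProteinSequence:
    """Draw one sequence of the given length from the chain.

    Reproducible: a fresh generator seeded identically yields the same
    sequence.  ``length`` must be at least max(order, 1).
    """
    if length < max(spec.order, 1):
        raise ParameterError(
            f"length {length} is below the chain order {spec.order} (and must be >= 1)"
        )
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    alphabet = spec.alphabet
    A = len(alphabet)
    if spec.order == 0:
        idx = rng.choice(A, size=length, p=spec.transition[""])
        return ProteinSequence(id=id, residues="".join(alphabet[i] for i in idx))
    contexts = context_labels(alphabet, spec.order)
    ctx_i = int(rng.choice(len(contexts), p=spec.initial_dist))
    chars = list(contexts[ctx_i])
    cumsums = {c: np.cumsum(row) for c, row in spec.transition.items()}
    for _ in range(length - spec.order):
        ctx = "".join(chars[-spec.order:])
        if ctx not in cumsums:
            raise ParameterError(f"transition undefined for reachable context {ctx!r}")
        u = rng.random()
        j = min(int(np.searchsorted(cumsums[ctx], u, side="right")), A - 1)
        chars.append(alphabet[j])
    return ProteinSequence(id=id, residues="".join(chars))


def _draw_lengths(length_dist, n: int, rng: np.random.Generator, min_len: int) -> list[int]:
    if isinstance(length_dist, int):
        length_dist = ("fixed", length_dist)
    kind = length_dist[0]
    if kind == "fixed":
        L = int(length_dist[1])
        if L < min_len:
            raise ParameterError(f"fixed length {L} below minimum {min_len}")
        return [L] * n
    if kind == "uniform":
        lo, hi = int(length_dist[1]), int(length_dist[2])
        if lo < min_len or hi < lo:
            raise ParameterError(
                f"uniform length bounds [{lo}, {hi}] invalid (minimum {min_len})"
            )
        return [int(x) for x in rng.integers(lo, hi + 1, size=n)]
    raise ParameterError(f"unknown length distribution {length_dist!r}")


def generate_labeled_corpora(
    spec_a: ChainSpec,
    spec_b: ChainSpec,
    n_per_class: int,
    length_dist=("fixed", 300),
    seed: int = 0,
    labels: tuple[str, str] = ("classA", "classB"),
) -> tuple[Corpus, Corpus]:
    """Two labeled corpora with systematic ids and disjoint substreams.

    Each class gets its own spawn of the root seed, and each sequence its
    own spawn within the class, so results never depend on generation
    order and are byte-identical across runs.
    """
    if n_per_class < 1:
        raise ParameterError(f"n_per_class must be >= 1, got {n_per_class}")
    root = np.random.SeedSequence(seed)
    class_streams = root.spawn(2)
    corpora = []
    for spec, label, stream in zip((spec_a, spec_b), labels, class_streams):
        children = stream.spawn(n_per_class + 1)
        len_rng = np.random.default_rng(children[0])
        min_len = max(spec.order, 1)
        lengths = _draw_lengths(length_dist, n_per_class, len_rng, min_len)
        seqs = []
        width = max(4, len(str(n_per_class)))
        for i, (L, child) in enumerate(zip(lengths, children[1:]), start=1):
            rng = np.random.default_rng(child)
            seqs.append(sample_sequence(spec, L, rng, id=f"{label}_{i:0{width}d}"))
        corpora.append(Corpus(label=label, sequences=tuple(seqs)))
    return corpora[0], corpora[1]


def chain_entropy_rate(spec: ChainSpec) -> float:
    """Asymptotic per-residue entropy of the chain, in nats.

    Computed as sum_c pi(c) * H(transition[c]) with pi the stationary
    distribution of the context process, restricted to the contexts
    reachable from the initial distribution.  Raises
    :class:`ReducibleChainError` when that restriction is not a single
    communicating class (the stationary distribution would not be
    unique), naming the contexts outside the recurrent class.
    """
    alphabet = spec.alphabet
    A = len(alphabet)
    if spec.order == 0:
        row = spec.transition[""]
        return float(-np.sum(np.where(row > 0, row * np.log(np.where(row > 0, row, 1.0)), 0.0)))

    contexts = context_labels(alphabet, spec.order)
    # reachable closure from the initial support
    start = {contexts[i] for i in np.flatnonzero(spec.initial_dist)}
    reachable: set[str] = set()
    frontier = list(start)
    while frontier:
        c = frontier.pop()
        if c in reachable:
            continue
        reachable.add(c)
        if c not in spec.transition:
            raise ParameterError(f"transition undefined for reachable context {c!r}")
        row = spec.transition[c]
        for j in np.flatnonzero(row):
            nxt = (c + alphabet[j])[1:]
            if nxt not in reachable:
                frontier.append(nxt)
    ordered = sorted(reachable)
    index = {c: i for i, c in enumerate(ordered)}
    rows, cols, vals = [], [], []
    for c in ordered:
        row = spec.transition[c]
        for j in np.flatnonzero(row):
            nxt = (c + alphabet[j])[1:]
            rows.append(index[c])
            cols.append(index[nxt])
            vals.append(float(row[j]))
    n = len(ordered)
    M = csr_matrix((vals, (rows, cols)), shape=(n, n))
    n_comp, comp = connected_components(M, directed=True, connection="strong")
    if n_comp > 1:
        sizes = np.bincount(comp)
        main = int(np.argmax(sizes))
        outside = [ordered[i] for i in range(n) if comp[i] != main]
        raise ReducibleChainError(
            f"context process is reducible; contexts outside the main class: {outside}"
        )
    # stationary distribution: solve pi^T M = pi^T with sum(pi) = 1
    dense = M.toarray()
    a = dense.T - np.eye(n)
    a[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    pi = np.linalg.solve(a, b)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    h = 0.0
    for c in ordered:
        row = spec.transition[c]
        nz = row[row > 0]
        h += pi[index[c]] * float(-np.sum(nz * np.log(nz)))
    return h


def kl_rate(spec_p: ChainSpec, spec_q: ChainSpec) -> float:
    """Per-position Kullback-Leibler divergence rate D(p || q) in nats.

    Averaged over p's stationary context distribution; +inf when q
    assigns zero probability where p does not.  Useful for checking that
    two benchmark chains are actually separated.
    """
    if spec_p.alphabet != spec_q.alphabet or spec_p.order != spec_q.order:
        raise ParameterError("KL rate requires matching alphabets and orders")
    if spec_p.order == 0:
        p, q = spec_p.transition[""], spec_q.transition[""]
        if np.any((p > 0) & (q == 0)):
            return float("inf")
        mask = p > 0
        return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))
    # reuse the stationary machinery by differentiating entropy terms
    alphabet = spec_p.alphabet
    contexts = context_labels(alphabet, spec_p.order)
    start = {contexts[i] for i in np.flatnonzero(spec_p.initial_dist)}
    reachable: set[str] = set()
    frontier = list(start)
    while frontier:
        c = frontier.pop()
        if c in reachable:
            continue
        reachable.add(c)
        row = spec_p.transition[c]
        for j in np.flatnonzero(row):
            frontier.append((c + alphabet[j])[1:])
    ordered = sorted(reachable)
    # stationary distribution of p over its reachable contexts
    index = {c: i for i, c in enumerate(ordered)}
    n = len(ordered)
    dense = np.zeros((n, n))
    for c in ordered:
        row = spec_p.transition[c]
        for j in np.flatnonzero(row):
            dense[index[c], index[(c + alphabet[j])[1:]]] += float(row[j])
    a = dense.T - np.eye(n)
    a[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    pi = np.linalg.solve(a, b)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    total = 0.0
    for c in ordered:
        p = spec_p.transition[c]
        if c not in spec_q.transition:
            return float("inf")
        q = spec_q.transition[c]
        if np.any((p > 0) & (q == 0)):
            return float("inf")
        mask = p > 0
        total += pi[index[c]] * float(np.sum(p[mask] * np.log(p[mask] / q[mask])))
    return total
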