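"""Independent brute-force reference implementations.

Deliberately naive and structured differently from the package code:
explicit window sliding, linear-space probability products, full
dynamic-programming alignment.  They exist so the package can be checked
against code that shares none of its internals.
"""

from __future__ import annotations

import math


def brute_count(seqs: list[str], order: int) -> dict[str, int]:
    """Count length-``order`` windows by explicit sliding."""
    out: dict[str, int] = {}
    for s in seqs:
        for start in range(len(s)):
            window = s[start : start + order]
            if len(window) == order:
                out[window] = out.get(window, 0) + 1
    return out


def brute_conditional(
    seqs: list[str],
    order: int,
    context: str,
    residue: str,
    alphabet: str,
    method: str = "none",
    k: float = 0.0,
) -> float:
    """MLE / add-k conditional probability from raw training strings.

    Denominator is the sum of n-gram counts over all continuations of
    the context (so every context's distribution normalizes).  Returns
    None for an undefined context under pure MLE.
    """
    ngrams = brute_count(seqs, order)
    num = ngrams.get(context + residue, 0)
    den = 0
    for r in alphabet:
        den += ngrams.get(context + r, 0)
    if method == "none":
        if den == 0:
            return None
        return num / den
    return (num + k) / (den + k * len(alphabet))


def brute_loglik(
    train_seqs: list[str],
    order: int,
    seq: str,
    alphabet: str,
    method: str = "none",
    k: float = 0.0,
) -> float:
    """Truncated n-gram log-likelihood, term by term."""
    total = 0.0
    for i in range(order - 1, len(seq)):
        ctx = seq[i - order + 1 : i]
        p = brute_conditional(train_seqs, order, ctx, seq[i], alphabet, method, k)
        if p is None or p == 0.0:
            return float("-inf")
        total += math.log(p)
    return total


def brute_chain_loglik(
    train_seqs: list[str],
    order: int,
    seq: str,
    alphabet: str,
    method: str = "none",
    k: float = 0.0,
) -> float:
    """Full chain-rule log-likelihood with lower-order prefix terms."""
    total = 0.0
    for i in range(len(seq)):
        m = min(i, order - 1)
        ctx = seq[i - m : i]
        p = brute_conditional(train_seqs, m + 1, ctx, seq[i], alphabet, method, k)
        if p is None or p == 0.0:
            return float("-inf")
        total += math.log(p)
    return total


def enum_posterior_log_odds(
    seq: str,
    train_h: list[str],
    train_nh: list[str],
    order: int,
    alphabet: str,
    p_h: float,
    p_nh: float,
    method: str = "add-k",
    k: float = 0.01,
) -> float:
    """Posterior log-odds by explicit Bayes-formula enumeration.

    Likelihoods are multiplied out in linear space (short sequences
    only), the evidence term is computed and divided through, and the
    log of the posterior ratio is returned.
    """
    def linear_lik(train: list[str]) -> float:
        prod = 1.0
        for i in range(order - 1, len(seq)):
            ctx = seq[i - order + 1 : i]
            p = brute_conditional(train, order, ctx, seq[i], alphabet, method, k)
            if p is None:
                return 0.0
            prod *= p
        return prod

    lik_h = linear_lik(train_h)
    lik_nh = linear_lik(train_nh)
    evidence = p_h * lik_h + p_nh * lik_nh
    post_h = p_h * lik_h / evidence
    post_nh = p_nh * lik_nh / evidence
    if post_nh == 0.0:
        return float("inf")
    if post_h == 0.0:
        return float("-inf")
    return math.log(post_h / post_nh)


def lcs_identity(a: str, b: str) -> float:
    """Identity via longest-common-subsequence dynamic programming.

    With match=1, mismatch=0, gap=0 the optimal global-alignment score
    equals the LCS length, so this is an independent oracle for the
    alignment-based identity.
    """
    n, m = len(a), len(b)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1]:
                dp[i][j] = dp[i - 1][j - 1] + 1
            else:
                dp[i][j] = max(dp[i - 1][j], dp[i][j - 1])
    return dp[n][m] / min(n, m)
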