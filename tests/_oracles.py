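"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately written the slow, literal way — explicit
pseudo-observations, nested loops, all-pairs enumeration — and shares no
code with the package paths it verifies.
"""

from __future__ import annotations

import math


def pseudo_count_bayes(c_sp: int, c_sn: int, n_pos: int, n_neg: int, k: int):
    """Posterior and log2 odds for one bit by literal pseudo-observation.

    Builds the actual outcome lists, appends k extra observations of each
    outcome (bit present / bit absent) per class, and counts.
    """
    pos_obs = [1] * c_sp + [0] * (n_pos - c_sp) + [1] * k + [0] * k
    neg_obs = [1] * c_sn + [0] * (n_neg - c_sn) + [1] * k + [0] * k
    p_s_pos = sum(1 for o in pos_obs if o == 1) / len(pos_obs)
    p_s_neg = sum(1 for o in neg_obs if o == 1) / len(neg_obs)
    prior_pos = n_pos / (n_pos + n_neg)
    prior_neg = n_neg / (n_pos + n_neg)
    num = p_s_pos * prior_pos
    den = p_s_pos * prior_pos + p_s_neg * prior_neg
    post_pos = num / den
    post_neg = 1.0 - post_pos
    log_odds = math.log2(post_pos / post_neg)
    return post_pos, post_neg, log_odds


def count_bits_loop(X, labels):
    """Per-cell loop count of bit occurrences by class."""
    n_bits = len(X[0]) if len(X) else 0
    c_sp = [0] * n_bits
    c_sn = [0] * n_bits
    for row, lab in zip(X, labels):
        for j in range(n_bits):
            if row[j]:
                if lab == "positive":
                    c_sp[j] += 1
                elif lab == "negative":
                    c_sn[j] += 1
    return c_sp, c_sn


def tanimoto_loop(a, b, variant: str = "binary") -> float:
    """Scalar-loop Tanimoto of two vectors."""
    if variant == "binary":
        inter = sum(1 for x, y in zip(a, b) if x == 1 and y == 1)
        union = sum(1 for x, y in zip(a, b) if x == 1 or y == 1)
        return inter / union if union else 0.0
    dot = sum(x * y for x, y in zip(a, b))
    den = sum(x * x for x in a) + sum(y * y for y in b) - dot
    return dot / den if den else 0.0


def allpairs_auc(scores, labels) -> float:
    """AUC as the fraction of concordant positive-negative pairs, ties 1/2."""
    pos = [s for s, l in zip(scores, labels) if l in (1, "positive")]
    neg = [s for s, l in zip(scores, labels) if l in (0, "negative")]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
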