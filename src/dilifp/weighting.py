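"""Bayesian per-substructure statistics and fingerprint weighting.

Each fingerprint bit *S* is scored by the posterior odds that a compound
carrying the substructure is hepatotoxic.  With class priors
``P(pos)``, ``P(neg)`` and Laplace-smoothed conditionals

    P(S|pos) = (c_SP + k) / (N_pos + k*|X|),    |X| = 2 outcomes,

Bayes' rule gives ``P(pos|S)`` and the per-bit score is the base-2 log
odds ratio

    L = log2( P(pos|S) / P(neg|S) ).

Bits with ``L >= theta`` are amplified — their weight is ``n_mult * L`` —
while all other bits keep weight 1; the weight vector is applied
element-wise to the binary fingerprint matrix.  Only positively
associated substructures are ever up-weighted: the asymmetry is
deliberate, because false negatives (missed hepatotoxicants) are the
costly error in screening.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import LabeledFingerprintDataset

__all__ = [
    "SubstructureCounts",
    "SubstructureStats",
    "WeightVector",
    "count_substructures",
    "smoothed_stats",
    "build_weight_vector",
    "apply_weights",
    "write_weight_table",
    "read_weight_table",
]


@dataclass
class SubstructureCounts:
    """Raw per-bit occurrence counts by class."""

    c_sp: np.ndarray  # positives containing each bit
    c_sn: np.ndarray  # negatives containing each bit
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        self.c_sp = np.asarray(self.c_sp, dtype=np.int64)
        self.c_sn = np.asarray(self.c_sn, dtype=np.int64)
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("need at least one compound of each class")
        if (self.c_sp < 0).any() or (self.c_sp > self.n_pos).any():
            raise ValueError("c_sp out of range [0, n_pos]")
        if (self.c_sn < 0).any() or (self.c_sn > self.n_neg).any():
            raise ValueError("c_sn out of range [0, n_neg]")


@dataclass
class SubstructureStats:
    """Smoothed conditionals, posteriors and log2 odds ratios per bit.

    Attributes
    ----------
    p_s_given_pos, p_s_given_neg : ndarray
        Laplace-smoothed probability of observing the bit in each class.
    prior_pos, prior_neg : float
        Class priors (empirical class frequencies by default).
    post_pos, post_neg : ndarray
        Posterior class probabilities given the bit is present; sum to 1.
    log_odds : ndarray
        ``log2(post_pos / post_neg)`` — the substructure score ``L``.
    """

    counts: SubstructureCounts
    k: float
    p_s_given_pos: np.ndarray
    p_s_given_neg: np.ndarray
    prior_pos: float
    prior_neg: float
    post_pos: np.ndarray
    post_neg: np.ndarray
    log_odds: np.ndarray

    @property
    def n_bits(self) -> int:
        return self.log_odds.shape[0]


@dataclass
class WeightVector:
    """Per-bit multiplicative weights derived from thresholded log odds.

    ``w[j] = n_mult * L[j]`` for selected bits (``L[j] >= theta``) and 1
    elsewhere; ``theta = inf`` is the no-weighting sentinel.
    """

    w: np.ndarray
    theta: float
    n_mult: float
    selected: np.ndarray  # sorted bit indices with L >= theta

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.selected = np.asarray(self.selected, dtype=np.int64)
        if (self.w <= 0).any():
            raise ValueError("all weights must be strictly positive")

    @property
    def n_bits(self) -> int:
        return self.w.shape[0]


def count_substructures(ds: LabeledFingerprintDataset) -> SubstructureCounts:
    """Count, per bit, how many positive and negative compounds carry it.

    Unlabeled records are ignored; at least one labeled compound of each
    class is required.
    """
    labels = ds.labels
    pos = labels == "positive"
    neg = labels == "negative"
    if not pos.any() or not neg.any():
        raise ValueError(
            f"need >=1 labeled compound of each class, got {pos.sum()} positive "
            f"and {neg.sum()} negative"
        )
    return SubstructureCounts(
        c_sp=ds.X[pos].sum(axis=0),
        c_sn=ds.X[neg].sum(axis=0),
        n_pos=int(pos.sum()),
        n_neg=int(neg.sum()),
    )


def smoothed_stats(
    counts: SubstructureCounts,
    k: float = 1.0,
    outcome_card: int = 2,
    smooth_priors: bool = False,
) -> SubstructureStats:
    """Turn raw counts into smoothed conditionals, posteriors and ``L``.

    Parameters
    ----------
    counts : SubstructureCounts
        Per-bit class counts.
    k : float
        Laplace pseudo-count; every outcome is pretended observed ``k``
        extra times.  ``k=0`` (no smoothing) is allowed only when no bit
        is entirely absent from, or present in, either class.
    outcome_card : int
        Number of outcomes per bit (present/absent), the ``|X|`` in the
        smoothing denominator.
    smooth_priors : bool
        Apply the same pseudo-count to the class priors.  Off by default:
        class counts are large, so the empirical frequencies are used.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    c_sp, c_sn = counts.c_sp, counts.c_sn
    n_pos, n_neg = counts.n_pos, counts.n_neg
    if k == 0:
        degenerate = (
            (c_sp == 0) | (c_sp == n_pos) | (c_sn == 0) | (c_sn == n_neg)
        )
        if degenerate.any():
            j = int(np.flatnonzero(degenerate)[0])
            raise ValueError(
                f"k=0 with a bit absent from or present in every member of a "
                f"class (first offender: bit {j}); use Laplace smoothing k>0"
            )

    p_sp = (c_sp + k) / (n_pos + k * outcome_card)
    p_sn = (c_sn + k) / (n_neg + k * outcome_card)
    if smooth_priors:
        total = n_pos + n_neg
        prior_pos = (n_pos + k) / (total + k * outcome_card)
        prior_neg = (n_neg + k) / (total + k * outcome_card)
    else:
        prior_pos = n_pos / (n_pos + n_neg)
        prior_neg = n_neg / (n_pos + n_neg)

    evidence = p_sp * prior_pos + p_sn * prior_neg
    post_pos = p_sp * prior_pos / evidence
    post_neg = 1.0 - post_pos
    log_odds = np.log2(post_pos / post_neg)
    return SubstructureStats(
        counts=counts,
        k=float(k),
        p_s_given_pos=p_sp,
        p_s_given_neg=p_sn,
        prior_pos=float(prior_pos),
        prior_neg=float(prior_neg),
        post_pos=post_pos,
        post_neg=post_neg,
        log_odds=log_odds,
    )


def build_weight_vector(
    stats: SubstructureStats, theta: float, n_mult: float
) -> WeightVector:
    """Select bits with ``L >= theta`` and weight them by ``n_mult * L``.

    ``theta`` must be positive (a non-positive threshold could select bits
    with non-positive weights); ``theta = inf`` yields the all-ones
    weight vector.  Ties at the threshold are selected.
    """
    if n_mult <= 0:
        raise ValueError("n_mult must be > 0")
    if not theta > 0:
        raise ValueError(
            "theta must be > 0 (a non-positive threshold would admit "
            "non-positive weights); use theta=inf to disable weighting"
        )
    L = stats.log_odds
    selected = np.flatnonzero(L >= theta)
    w = np.ones(L.shape[0], dtype=float)
    w[selected] = n_mult * L[selected]
    return WeightVector(w=w, theta=float(theta), n_mult=float(n_mult), selected=selected)


def apply_weights(X: np.ndarray, wv: WeightVector | np.ndarray) -> np.ndarray:
    """Multiply a fingerprint matrix element-wise by the weight vector."""
    w = wv.w if isinstance(wv, WeightVector) else np.asarray(wv, dtype=float)
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != w.shape[0]:
        raise ValueError(
            f"dimension mismatch: X has shape {X.shape}, weight vector length {w.shape[0]}"
        )
    return X.astype(float) * w


# ---------------------------------------------------------------------------
# Persistence: CSV table + JSON sidecar
# ---------------------------------------------------------------------------

def write_weight_table(
    wv: WeightVector,
    stats: SubstructureStats,
    csv_path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    """Write ``bit_index,L,selected,weight`` CSV plus a JSON sidecar."""
    import pandas as pd

    sel = np.zeros(wv.n_bits, dtype=bool)
    sel[wv.selected] = True
    pd.DataFrame(
        {
            "bit_index": np.arange(wv.n_bits),
            "L": stats.log_odds,
            "selected": sel.astype(int),
            "weight": wv.w,
        }
    ).to_csv(csv_path, index=False, float_format="%.17g")  # exact float round trip
    if json_path is not None:
        meta = {
            "theta": wv.theta,
            "n_mult": wv.n_mult,
            "k": stats.k,
            "n_pos": stats.counts.n_pos,
            "n_neg": stats.counts.n_neg,
            "n_selected": int(sel.sum()),
        }
        Path(json_path).write_text(json.dumps(meta, indent=2))


def read_weight_table(csv_path: str | Path, json_path: str | Path) -> WeightVector:
    """Reload a weight vector written by :func:`write_weight_table`."""
    import pandas as pd

    df = pd.read_csv(csv_path, float_precision="round_trip")
    meta = json.loads(Path(json_path).read_text())
    theta = meta["theta"]
    if isinstance(theta, str):  # "Infinity" round-trips as a string in some writers
        theta = float(theta)
    return WeightVector(
        w=df["weight"].to_numpy(float),
        theta=float(theta) if math.isfinite(float(theta)) else math.inf,
        n_mult=float(meta["n_mult"]),
        selected=df.loc[df["selected"] == 1, "bit_index"].to_numpy(np.int64),
    )
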