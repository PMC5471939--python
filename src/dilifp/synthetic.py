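"""Synthetic labeled fingerprint datasets with planted causal bits.

The generator emulates the structure of a hepatotoxicity training set —
a class-imbalanced collection of compounds described by 881 independent
binary substructure bits — without requiring any external database.  A
chosen subset of "causal" bits fires at a higher Bernoulli rate in
positives than in negatives; every other bit fires at one shared
background rate in both classes, so it carries no class signal.

Defaults mirror a realistic training collection: 180 positives vs 132
negatives, 881 bits, 10 causal bits at rates 0.6 (positives) vs 0.1
(negatives), background rate 0.1.  Bits are independent; real
fingerprints are correlated (nested substructure definitions), which
this generator deliberately does not model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import CompoundRecord, LabeledFingerprintDataset

__all__ = ["SyntheticSpec", "generate", "expected_log_odds"]


@dataclass
class SyntheticSpec:
    n_pos: int = 180
    n_neg: int = 132
    n_bits: int = 881
    causal_bits: tuple[int, ...] = tuple(range(10))
    p_causal_pos: float = 0.6
    p_causal_neg: float = 0.1
    p_background: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if self.n_bits < 1:
            raise ValueError("n_bits must be >= 1")
        bits = np.asarray(self.causal_bits, dtype=int)
        if bits.size and (bits.min() < 0 or bits.max() >= self.n_bits):
            raise ValueError("causal_bits must lie in [0, n_bits)")
        if len(set(self.causal_bits)) != len(self.causal_bits):
            raise ValueError("causal_bits must be distinct")
        for name in ("p_causal_pos", "p_causal_neg", "p_background"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name}={p} outside [0, 1]")


def generate(spec: SyntheticSpec) -> LabeledFingerprintDataset:
    """Draw a labeled dataset from the spec; deterministic given the seed.

    Compound IDs and synthetic structure keys embed the seed so that
    datasets drawn with different seeds never collide by identity.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    rates = np.full(spec.n_bits, spec.p_background)
    X = np.empty((n, spec.n_bits), dtype=np.uint8)

    rates_pos = rates.copy()
    rates_pos[list(spec.causal_bits)] = spec.p_causal_pos
    X[: spec.n_pos] = rng.random((spec.n_pos, spec.n_bits)) < rates_pos

    rates_neg = rates.copy()
    rates_neg[list(spec.causal_bits)] = spec.p_causal_neg
    X[spec.n_pos :] = rng.random((spec.n_neg, spec.n_bits)) < rates_neg

    records = [
        CompoundRecord(
            compound_id=f"s{spec.seed}-pos-{i:05d}",
            label="positive",
            structure_key=f"synth:s{spec.seed}-pos-{i:05d}",
        )
        for i in range(spec.n_pos)
    ] + [
        CompoundRecord(
            compound_id=f"s{spec.seed}-neg-{i:05d}",
            label="negative",
            structure_key=f"synth:s{spec.seed}-neg-{i:05d}",
        )
        for i in range(spec.n_neg)
    ]
    return LabeledFingerprintDataset(records=records, X=X, n_bits=spec.n_bits)


def expected_log_odds(spec: SyntheticSpec, k: float = 1.0) -> np.ndarray:
    """Population log2 odds ratio per bit under the generating rates.

    Plugs the true Bernoulli rates and class priors into the posterior
    odds (finite-sample Laplace terms omitted):

        L_j = log2(p1 * pi_pos) - log2(p0 * pi_neg)

    where ``p1``/``p0`` are the bit's rates in positives/negatives.  The
    empirical log odds estimated from generated data converge to this as
    the sample size grows.
    """
    rates_pos = np.full(spec.n_bits, spec.p_background)
    rates_neg = np.full(spec.n_bits, spec.p_background)
    if spec.causal_bits:
        rates_pos[list(spec.causal_bits)] = spec.p_causal_pos
        rates_neg[list(spec.causal_bits)] = spec.p_causal_neg
    if k == 0 and ((rates_pos <= 0).any() or (rates_neg <= 0).any()
                   or (rates_pos >= 1).any() or (rates_neg >= 1).any()):
        raise ValueError("rates at 0 or 1 require Laplace smoothing (k > 0)")
    pi_pos = spec.n_pos / (spec.n_pos + spec.n_neg)
    pi_neg = spec.n_neg / (spec.n_pos + spec.n_neg)
    with np.errstate(divide="ignore"):
        return np.log2(rates_pos * pi_pos) - np.log2(rates_neg * pi_neg)
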