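"""Kimura two-parameter substitution simulator.

A sequence is diverged from its ancestor by sampling each site from the K2P
transition-probability matrix at a chosen expected number of substitutions
per site K and transition/transversion ratio R = alpha/(2*beta).  With
a = alpha*t and b = beta*t (so K = a + 2b):

    P(transition)        = 1/4 + 1/4*exp(-4b) - 1/2*exp(-2(a+b))
    P(each transversion) = 1/4 - 1/4*exp(-4b)

which the K2P distance estimator inverts exactly in expectation.
"""

from __future__ import annotations

import numpy as np

from ._kmers import encode

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# transition partner of A,C,G,T (A<->G, C<->T)
_TRANSITION = np.array([2, 3, 0, 1], dtype=np.uint8)
# the two transversion targets of each base
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.uint8)


def k2p_site_probabilities(k: float, ts_tv: float) -> tuple[float, float]:
    """(P(transition), P(each transversion)) after expected divergence ``k``."""
    if k < 0:
        raise ValueError("divergence must be >= 0")
    if ts_tv <= 0:
        raise ValueError("ts/tv ratio must be > 0")
    a = k * ts_tv / (ts_tv + 1.0)      # alpha*t
    b = k / (2.0 * (ts_tv + 1.0))      # beta*t   (K = a + 2b)
    p_ts = 0.25 + 0.25 * np.exp(-4.0 * b) - 0.5 * np.exp(-2.0 * (a + b))
    p_tv_each = 0.25 - 0.25 * np.exp(-4.0 * b)
    return float(p_ts), float(p_tv_each)


def mutate(seq: str, k: float, ts_tv: float, rng: np.random.Generator) -> str:
    """Return ``seq`` diverged by expected ``k`` substitutions/site under K2P.

    Non-ACGT characters (N) are left untouched.
    """
    enc = encode(seq)
    p_ts, p_tv = k2p_site_probabilities(k, ts_tv)
    u = rng.random(enc.size)
    out = enc.copy()
    valid = enc <= 3
    base = np.where(valid, enc, 0)
    ts_mask = valid & (u < p_ts)
    tv1_mask = valid & (u >= p_ts) & (u < p_ts + p_tv)
    tv2_mask = valid & (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[ts_mask] = _TRANSITION[base[ts_mask]]
    out[tv1_mask] = _TRANSVERSIONS[base[tv1_mask], 0]
    out[tv2_mask] = _TRANSVERSIONS[base[tv2_mask], 1]
    chars = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    chars[valid] = _BASES[out[valid]]
    return chars.tobytes().decode("ascii")


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """i.i.d. nucleotide sequence with the stated GC fraction."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = rng.choice(4, size=length, p=p)
    return _BASES[draws].tobytes().decode("ascii")
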