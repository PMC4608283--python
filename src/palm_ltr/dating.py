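"""Insertion-time estimation from 5'/3' LTR divergence.

At insertion the two LTRs of an element are identical; they subsequently
accumulate substitutions independently.  The pipeline aligns each LTR pair
globally, computes the Kimura two-parameter distance K over gap-free
columns, and converts it to an age T = K / (2r) with a fixed per-site
yearly substitution rate r (default 1.3e-8, a commonly used average rate
for plant nuclear sequences).

Gapped columns are excluded from the transition/transversion counts; pairs
too diverged for the K2P logarithms to be defined are reported as saturated
rather than silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import Align

from ._kmers import encode

DEFAULT_RATE = 1.3e-8

_PURINE = {"A", "G"}


class SaturationError(ValueError):
    """LTR pair too diverged for the K2P correction to be defined."""


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -8.0
    aligner.extend_gap_score = -2.0
    # end gaps penalized: default global mode scores end gaps
    return aligner


def align_ltr_pair(ltr5: str, ltr3: str) -> tuple[str, str, float]:
    """Global affine-gap alignment of an LTR pair.

    Returns (aligned5, aligned3, score).  Traceback is deterministic: the
    first (high-road) optimal alignment is taken.
    """
    if not ltr5 or not ltr3:
        raise ValueError("empty LTR sequence")
    if len(ltr5) < 20 or len(ltr3) < 20:
        raise ValueError("LTR sequences must be at least 20 bp")
    aligner = _global_aligner()
    aln = aligner.align(ltr5.upper(), ltr3.upper())[0]
    a, b = str(aln[0]), str(aln[1])
    return a, b, float(aln.score)


def k2p_distance(aligned_a: str, aligned_b: str) -> tuple[float, float, float, int]:
    """Transition fraction P, transversion fraction Q and K2P distance K.

    Computed over gap-free columns only; columns with a non-ACGT base are
    also excluded.  Returns (P, Q, K, n_columns).

    Raises :class:`SaturationError` when 1-2P-Q <= 0 or 1-2Q <= 0.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences differ in length")
    ea, eb = encode(aligned_a), encode(aligned_b)
    ok = (ea <= 3) & (eb <= 3)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no gap-free columns")
    ea, eb = ea[ok], eb[ok]
    diff = ea != eb
    # transitions are A<->G (codes 0,2) and C<->T (codes 1,3): code parity equal
    transitions = diff & ((ea % 2) == (eb % 2))
    p = float(transitions.sum()) / n
    q = float(diff.sum() - transitions.sum()) / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"saturated LTR pair (P={p:.3f}, Q={q:.3f})")
    k = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return p, q, k, n


def insertion_time(k: float, rate: float = DEFAULT_RATE) -> float:
    """Insertion age in years, T = K / (2r)."""
    if k < 0:
        raise ValueError("K must be >= 0")
    if rate <= 0:
        raise ValueError("substitution rate must be > 0")
    return k / (2.0 * rate)


@dataclass
class DivergenceEstimate:
    """Per-element LTR divergence and derived insertion age."""

    element_id: str
    aligned_length: int
    p: float
    q: float
    k: float
    t_years: float
    rate: float = DEFAULT_RATE
    status: str = "ok"

    @classmethod
    def saturated(cls, element_id: str) -> "DivergenceEstimate":
        return cls(element_id, 0, math.nan, math.nan, math.nan, math.nan,
                   status="saturated")


def date_element(element_id: str, ltr5: str, ltr3: str,
                 rate: float = DEFAULT_RATE) -> DivergenceEstimate:
    """Align one LTR pair and estimate its K2P divergence and age."""
    a, b, _ = align_ltr_pair(ltr5, ltr3)
    try:
        p, q, k, n = k2p_distance(a, b)
    except SaturationError:
        return DivergenceEstimate.saturated(element_id)
    return DivergenceEstimate(element_id, n, p, q, k, insertion_time(k, rate), rate)


def date_elements(elements: list[tuple[str, str, str]],
                  rate: float = DEFAULT_RATE) -> list[DivergenceEstimate]:
    """Date a list of (element_id, ltr5, ltr3) tuples."""
    return [date_element(eid, l5, l3, rate) for eid, l5, l3 in elements]


def divergence_profile(
    estimates: list[DivergenceEstimate],
    superfamilies: dict[str, str],
    bin_width: float = 0.01,
) -> tuple[dict[str, np.ndarray], np.ndarray, list[str]]:
    """Per-superfamily histogram of K plus the ids of recent insertions.

    Returns (histograms, bin_edges, recent_ids) where ``recent_ids`` lists
    elements falling in the first bin (K < bin_width) — near-identical LTR
    pairs that signal recent transposition.
    """
    scored = [e for e in estimates if e.status == "ok"]
    if not scored:
        return {}, np.empty(0), []
    kmax = max(e.k for e in scored)
    edges = np.arange(0.0, kmax + 2 * bin_width, bin_width)
    hists: dict[str, np.ndarray] = {}
    for est in scored:
        sf = superfamilies.get(est.element_id, "NA")
        if sf not in hists:
            hists[sf] = np.zeros(edges.size - 1, dtype=int)
        idx = min(int(est.k / bin_width), edges.size - 2)
        hists[sf][idx] += 1
    recent = sorted(e.element_id for e in scored if e.k < bin_width)
    return hists, edges, recent
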