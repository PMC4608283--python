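"""Structural detection of full-length LTR retrotransposons.

An element is called when a genomic locus shows the canonical structure:
two highly similar direct repeats (the LTR pair) of plausible length and
spacing, flanked by a target-site duplication (TSD), with primer-binding
site (PBS) and polypurine tract (PPT) signals just inside the repeats.

Candidate repeats are found by exact k-mer seeding on the forward/forward
diagonal, chained per diagonal band and extended ungapped with an x-drop
rule; pair identity comes from a banded edit-distance alignment of the two
repeat copies.  Validation enforces the identity threshold, the 12 kb
element-length cap and (TSD always; PBS/PPT only under ``strict``) the
flanking signals.  LTRs are direct repeats, so the forward strand suffices;
orientation is inferred later from protein-domain frames.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from ._kmers import direct_repeat_seeds, encode, revcomp, xdrop_extend
from .io import load_trna_library

_PURINES = frozenset("AG")


@dataclass
class DetectorParams:
    seed_k: int = 13
    min_ltr: int = 100
    max_ltr: int = 6000
    min_inner: int = 500
    max_span: int = 13000          # pre-validation span ceiling for candidates
    band: int = 16                 # diagonal clustering tolerance (indel slack)
    min_identity: float = 0.80
    max_element_length: int = 12000
    tsd_range: tuple[int, int] = (4, 6)
    tsd_shift: int = 6             # boundary adjustment searched for a TSD
    pbs_min_match: int = 10
    pbs_window: int = 20
    ppt_window: int = 30
    ppt_min_purine: float = 0.80
    max_n_fraction: float = 0.10
    strict: bool = False           # require PBS and PPT, not just score them


@dataclass
class CandidatePair:
    scaffold: str
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    identity: float
    diagonal: int
    n_seeds: int

    @property
    def span(self) -> tuple[int, int]:
        return self.ltr5[0], self.ltr3[1]


@dataclass
class PBSEvidence:
    trna_id: str
    match_length: int
    offset: int          # bp from the 5' LTR end to the PBS start


@dataclass
class PPTEvidence:
    purine_fraction: float
    window: tuple[int, int]


@dataclass
class LTRElement:
    element_id: str
    scaffold: str
    start: int
    end: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    identity: float
    tsd: str | None = None
    pbs: PBSEvidence | None = None
    ppt: PPTEvidence | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Rejection:
    scaffold: str
    span: tuple[int, int]
    reason: str


@dataclass
class DetectionReport:
    n_candidates: int = 0
    rejections: list[Rejection] = field(default_factory=list)


def _pair_identity(seq: str, a: tuple[int, int], b: tuple[int, int]) -> float:
    """Identity of the two repeat copies from a global edit-distance alignment."""
    s1, s2 = seq[a[0]:a[1]], seq[b[0]:b[1]]
    res = edlib.align(s1, s2, task="distance")
    return max(0.0, 1.0 - res["editDistance"] / max(len(s1), len(s2)))


def find_candidate_pairs(sequence: str, params: DetectorParams | None = None,
                         scaffold: str = "seq") -> list[CandidatePair]:
    """Direct-repeat candidates from seeded, chained, x-drop-extended matches."""
    params = params or DetectorParams()
    if not params.min_ltr <= params.max_ltr < params.max_span:
        raise ValueError("need min_ltr <= max_ltr < max_span")
    if len(sequence) < params.min_ltr * 2 + params.min_inner:
        return []
    enc = encode(sequence)
    min_sep = params.min_ltr + params.min_inner
    ii, jj = direct_repeat_seeds(enc, params.seed_k, min_sep, params.max_span)
    if ii.size == 0:
        return []
    diag = jj - ii
    order = np.lexsort((ii, diag))
    ii, jj, diag = ii[order], jj[order], diag[order]

    candidates: list[CandidatePair] = []
    # cluster seeds into diagonal bands, then chain along the sequence
    start = 0
    breaks = np.flatnonzero(np.diff(diag) > params.band) + 1
    for grp_start, grp_end in zip(
            np.concatenate(([0], breaks)),
            np.concatenate((breaks, [diag.size]))):
        gi, gj = ii[grp_start:grp_end], jj[grp_start:grp_end]
        sub = np.argsort(gi)
        gi, gj = gi[sub], gj[sub]
        chain_breaks = np.flatnonzero(np.diff(gi) > 300) + 1
        for cs, ce in zip(np.concatenate(([0], chain_breaks)),
                          np.concatenate((chain_breaks, [gi.size]))):
            ci, cj = gi[cs:ce], gj[cs:ce]
            i0, i1 = int(ci.min()), int(ci.max()) + params.seed_k
            j0, j1 = int(cj.min()), int(cj.max()) + params.seed_k
            if i1 - i0 < params.seed_k:
                continue
            left, right = xdrop_extend(enc, i0, j0, i1, j1)
            a = (i0 - left, i1 + right)
            b = (j0 - left, j1 + right)
            ltr_len = a[1] - a[0]
            inner = b[0] - a[1]
            span = b[1] - a[0]
            if not params.min_ltr <= ltr_len <= params.max_ltr:
                continue
            if inner < params.min_inner or span > params.max_span:
                continue
            ident = _pair_identity(sequence, a, b)
            candidates.append(CandidatePair(scaffold, a, b, ident,
                                            int(cj[0] - ci[0]), int(ce - cs)))
    candidates.sort(key=lambda c: (c.ltr5[0], c.ltr3[1]))
    return candidates


def _find_tsd(sequence: str, start: int, end: int,
              params: DetectorParams) -> tuple[str, int, int] | None:
    """Search for a TSD, allowing small boundary shifts.

    Returns (tsd, adjusted_start, adjusted_end) for the smallest boundary
    adjustment whose flanks carry an exact duplication; among lengths the
    longest wins.
    """
    lo, hi = params.tsd_range
    span = range(-params.tsd_shift, params.tsd_shift + 1)
    combos = sorted(((ds, de) for ds in span for de in span),
                    key=lambda c: (abs(c[0]) + abs(c[1]), c))
    best: tuple[tuple[int, int, int], tuple[str, int, int]] | None = None
    for ds, de in combos:
        s, e = start + ds, end + de
        if s < hi or e + hi > len(sequence):
            continue
        for t in range(hi, lo - 1, -1):
            left = sequence[s - t:s]
            right = sequence[e:e + t]
            if left == right and "N" not in left:
                # canonical TG...CA termini disambiguate boundary shifts
                termini = sequence[s:s + 2] == "TG" and \
                    sequence[e - 2:e] == "CA"
                key = (int(termini), t, -(abs(ds) + abs(de)))
                if best is None or key > best[0]:
                    best = (key, (left, s, e))
                break
    return best[1] if best else None


def _find_pbs(internal: str, trna_lib: dict[str, str],
              params: DetectorParams) -> PBSEvidence | None:
    """Best complementarity of the region just inside the 5' LTR to a tRNA 3' end."""
    window = internal[:params.pbs_window + 15]
    best: PBSEvidence | None = None
    for trna_id in sorted(trna_lib):
        probe = revcomp(trna_lib[trna_id][-15:])
        for m in range(len(probe), params.pbs_min_match - 1, -1):
            found = False
            for off in range(len(probe) - m + 1):
                pos = window.find(probe[off:off + m])
                if 0 <= pos <= params.pbs_window:
                    if best is None or m > best.match_length:
                        best = PBSEvidence(trna_id, m, pos)
                    found = True
                    break
            if found:
                break
    return best


def _find_ppt(internal: str, params: DetectorParams) -> PPTEvidence | None:
    """Most purine-rich 15-mer in the window just inside the 3' LTR."""
    tail = internal[-params.ppt_window:]
    if len(tail) < 15:
        return None
    base = len(internal) - len(tail)
    best_frac, best_iv = 0.0, None
    for i in range(len(tail) - 15 + 1):
        frac = sum(c in _PURINES for c in tail[i:i + 15]) / 15.0
        if frac > best_frac:
            best_frac, best_iv = frac, (base + i, base + i + 15)
    if best_iv is not None and best_frac >= params.ppt_min_purine:
        return PPTEvidence(best_frac, best_iv)
    return None


def validate_element(candidate: CandidatePair, sequence: str,
                     params: DetectorParams | None = None,
                     trna_lib: dict[str, str] | None = None,
                     element_id: str = "elem") -> LTRElement | Rejection:
    """Apply the structural acceptance rules to one candidate repeat pair."""
    params = params or DetectorParams()
    start, end = candidate.span
    if not (0 <= start < end <= len(sequence)):
        raise ValueError("candidate coordinates outside sequence")
    if trna_lib is None:
        trna_lib = load_trna_library()

    def reject(reason: str) -> Rejection:
        return Rejection(candidate.scaffold, candidate.span, reason)

    if candidate.identity < params.min_identity:
        return reject("low_identity")
    if end - start > params.max_element_length:
        return reject("too_long")
    for iv in (candidate.ltr5, candidate.ltr3):
        ltr_seq = sequence[iv[0]:iv[1]]
        if ltr_seq.count("N") > params.max_n_fraction * len(ltr_seq):
            return reject("n_rich_ltr")

    tsd_hit = _find_tsd(sequence, start, end, params)
    if tsd_hit is None:
        return reject("no_tsd")
    tsd, adj_start, adj_end = tsd_hit
    dstart = adj_start - start
    dend = adj_end - end
    ltr5 = (candidate.ltr5[0] + dstart, candidate.ltr5[1])
    ltr3 = (candidate.ltr3[0], candidate.ltr3[1] + dend)

    internal = sequence[ltr5[1]:ltr3[0]]
    pbs = _find_pbs(internal, trna_lib, params)
    ppt = _find_ppt(internal, params)
    if params.strict and (pbs is None or ppt is None):
        return reject("no_pbs" if pbs is None else "no_ppt")

    return LTRElement(
        element_id=element_id,
        scaffold=candidate.scaffold,
        start=adj_start, end=adj_end,
        ltr5=ltr5, ltr3=ltr3,
        identity=candidate.identity,
        tsd=tsd, pbs=pbs, ppt=ppt,
    )


def detect(genome: dict[str, str], params: DetectorParams | None = None,
           trna_lib: dict[str, str] | None = None
           ) -> tuple[list[LTRElement], DetectionReport]:
    """Detect elements genome-wide; overlaps resolved by (identity, length)."""
    params = params or DetectorParams()
    if trna_lib is None:
        trna_lib = load_trna_library()
    report = DetectionReport()
    accepted: list[LTRElement] = []
    for scaffold in sorted(genome):
        seq = genome[scaffold].upper()
        cands = find_candidate_pairs(seq, params, scaffold)
        report.n_candidates += len(cands)
        validated: list[LTRElement] = []
        for cand in cands:
            res = validate_element(cand, seq, params, trna_lib)
            if isinstance(res, Rejection):
                report.rejections.append(res)
            else:
                validated.append(res)
        # greedy overlap resolution, best (identity, length) first
        validated.sort(key=lambda e: (-e.identity, -e.length, e.start))
        kept: list[LTRElement] = []
        for elem in validated:
            if not any(k.start < elem.end and elem.start < k.end for k in kept):
                kept.append(elem)
            else:
                report.rejections.append(
                    Rejection(scaffold, (elem.start, elem.end), "overlap"))
        accepted.extend(kept)
    accepted.sort(key=lambda e: (e.scaffold, e.start))
    for i, elem in enumerate(accepted):
        elem.element_id = f"LTR{i:04d}"
    return accepted, report


def element_sequences(genome: dict[str, str],
                      elements: list[LTRElement]) -> dict[str, str]:
    return {e.element_id: genome[e.scaffold][e.start:e.end] for e in elements}
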