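"""Genome-wide copy counting, repeat masking and density tracks.

Copies of family reference elements are located by exact k-mer seeding,
diagonal chaining, ungapped x-drop extension and an edit-distance identity
check of the matched segment.  A copy is complete when it covers at least
70 % of its reference at 70 % identity or better.  Because related
references cross-match, overlapping hits of different references are
collapsed to the best one and counting is done per superfamily.

Densities along scaffolds use a 1 Mbp sliding window with a 500 kbp step;
a hit belongs to every window containing its start position.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from scipy import stats

from ._kmers import encode, kmer_index, revcomp, shared_seed_hits


@dataclass
class CopyHit:
    ref_id: str
    superfamily: str
    scaffold: str
    start: int
    end: int
    strand: str
    identity: float
    coverage: float

    @property
    def complete(self) -> bool:
        return self.coverage >= 0.70 and self.identity >= 0.70


@dataclass
class WindowDensity:
    scaffold: str
    start: int
    end: int
    counts: dict[str, int]

    def density(self, track: str) -> float:
        return self.counts.get(track, 0) / ((self.end - self.start) / 1e6)


def _extend_pair(qa: np.ndarray, qb: np.ndarray, a0: int, a1: int,
                 b0: int, b1: int, match: int = 1, mismatch: int = -2,
                 xdrop: int = 15) -> tuple[int, int]:
    """Ungapped x-drop extension of an anchored match between two sequences."""
    best = cur = 0
    left = 0
    step = 1
    while a0 - step >= 0 and b0 - step >= 0:
        cur += match if (qa[a0 - step] == qb[b0 - step]
                         and qa[a0 - step] <= 3) else mismatch
        if cur > best:
            best, left = cur, step
        if best - cur > xdrop:
            break
        step += 1
    best = cur = 0
    right = 0
    step = 0
    while a1 + step < qa.size and b1 + step < qb.size:
        cur += match if (qa[a1 + step] == qb[b1 + step]
                         and qa[a1 + step] <= 3) else mismatch
        if cur > best:
            best, right = cur, step + 1
        if best - cur > xdrop:
            break
        step += 1
    return left, right


def _scan_strand(ref_id: str, ref: str, superfamily: str, scaffold: str,
                 seq: str, enc: np.ndarray, index: dict, strand: str,
                 seq_len: int, k: int, min_id: float) -> list[CopyHit]:
    ref_enc = encode(ref)
    qpos, tpos = shared_seed_hits(ref_enc, index, k)
    if qpos.size == 0:
        return []
    diag = tpos - qpos
    order = np.lexsort((tpos, diag))
    qpos, tpos, diag = qpos[order], tpos[order], diag[order]
    grp_breaks = np.flatnonzero(np.diff(diag) > 40) + 1
    hits: list[CopyHit] = []
    for gs, ge in zip(np.concatenate(([0], grp_breaks)),
                      np.concatenate((grp_breaks, [diag.size]))):
        gq, gt = qpos[gs:ge], tpos[gs:ge]
        sub = np.argsort(gt)
        gq, gt = gq[sub], gt[sub]
        cb = np.flatnonzero(np.diff(gt) > 500) + 1
        for cs, ce in zip(np.concatenate(([0], cb)),
                          np.concatenate((cb, [gt.size]))):
            cq, ct = gq[cs:ce], gt[cs:ce]
            r0, r1 = int(cq.min()), int(cq.max()) + k
            g0, g1 = int(ct.min()), int(ct.max()) + k
            # single chance k-mer matches are not credible copies
            if r1 - r0 < 2 * k:
                continue
            left, right = _extend_pair(ref_enc, enc, r0, g0, r1, g1)
            r0, r1 = r0 - left, r1 + right
            g0, g1 = g0 - left, g1 + right
            res = edlib.align(ref[r0:r1], seq[g0:g1], task="distance")
            span = max(r1 - r0, g1 - g0)
            identity = max(0.0, 1.0 - res["editDistance"] / span)
            if identity < min_id * 0.8:     # clearly spurious chains
                continue
            coverage = (r1 - r0) / len(ref)
            if strand == "+":
                fs, fe = g0, g1
            else:
                fs, fe = seq_len - g1, seq_len - g0
            hits.append(CopyHit(ref_id, superfamily, scaffold, fs, fe,
                                strand, identity, coverage))
    return hits


def find_copies(genome: dict[str, str], references: dict[str, str],
                superfamilies: dict[str, str] | None = None,
                min_id: float = 0.70, min_cov: float = 0.70,
                k: int = 13, collapse: bool = True) -> list[CopyHit]:
    """Genomic copies of reference elements on both strands.

    Returns hits meeting ``min_id``; the ``complete`` flag additionally
    requires ``min_cov`` reference coverage.  Overlapping hits of different
    references (sharing > 50 % of the shorter interval) are collapsed to the
    best (identity, coverage) one when ``collapse`` is set.
    """
    if not references:
        raise ValueError("no reference elements")
    superfamilies = superfamilies or {}
    all_hits: list[CopyHit] = []
    for scaffold in sorted(genome):
        seq = genome[scaffold].upper()
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            enc = encode(s)
            index = kmer_index(enc, k)
            for ref_id in sorted(references):
                ref = references[ref_id].upper()
                all_hits.extend(_scan_strand(
                    ref_id, ref, superfamilies.get(ref_id, "NA"), scaffold,
                    s, enc, index, strand, len(seq), k, min_id))
    all_hits = [h for h in all_hits if h.identity >= min_id]
    if collapse:
        all_hits = _collapse(all_hits)
    all_hits.sort(key=lambda h: (h.scaffold, h.start, h.ref_id))
    return all_hits


def _collapse(hits: list[CopyHit]) -> list[CopyHit]:
    # rank by matched bases so long good hits beat short perfect ones
    hits = sorted(hits, key=lambda h: (-(h.end - h.start) * h.identity,
                                       -h.identity, h.ref_id, h.scaffold,
                                       h.start))
    kept: list[CopyHit] = []
    for hit in hits:
        clash = False
        for other in kept:
            if other.scaffold != hit.scaffold:
                continue
            ov = min(hit.end, other.end) - max(hit.start, other.start)
            if ov > 0.5 * min(hit.end - hit.start, other.end - other.start):
                clash = True
                break
        if not clash:
            kept.append(hit)
    return kept


def mask_genome(genome: dict[str, str], library: dict[str, str],
                min_id: float = 0.80) -> tuple[dict[str, str], dict]:
    """Lower-case every genomic segment matching a library sequence.

    Returns the soft-masked genome and coverage statistics over all bases
    and over non-N bases.
    """
    if not library:
        raise ValueError("empty masking library")
    hits = find_copies(genome, library, min_id=min_id, collapse=False)
    masked: dict[str, str] = {}
    total = total_n = masked_bp = masked_non_n = 0
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        by_scaffold.setdefault(h.scaffold, []).append((h.start, h.end))
    for scaffold in sorted(genome):
        seq = genome[scaffold].upper()
        arr = np.zeros(len(seq), dtype=bool)
        for s, e in by_scaffold.get(scaffold, []):
            arr[s:e] = True
        chars = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        is_n = chars == ord("N")
        lower = chars + 32
        chars[arr] = lower[arr]
        masked[scaffold] = chars.tobytes().decode()
        total += len(seq)
        total_n += int(is_n.sum())
        masked_bp += int(arr.sum())
        masked_non_n += int((arr & ~is_n).sum())
    non_n = total - total_n
    stats_out = {
        "total_bp": total,
        "masked_bp": masked_bp,
        "masked_fraction_incl_n": masked_bp / total if total else 0.0,
        "masked_fraction_excl_n": masked_non_n / non_n if non_n else 0.0,
    }
    return masked, stats_out


def window_density(hits: list[CopyHit],
                   genes: list[tuple[str, int, int, str]],
                   scaffold_lengths: dict[str, int],
                   window: int = 1_000_000,
                   step: int = 500_000) -> list[WindowDensity]:
    """Sliding-window counts of Copia/Gypsy/NA hits and genes per scaffold.

    A feature is counted in every window whose span contains its start.
    Terminal windows are shorter; densities are scaled by actual length.
    """
    if window < step:
        raise ValueError("window must be >= step")
    out: list[WindowDensity] = []
    for scaffold in sorted(scaffold_lengths):
        length = scaffold_lengths[scaffold]
        if length <= 0:
            continue
        starts = [h.start for h in hits if h.scaffold == scaffold]
        sfs = [h.superfamily for h in hits if h.scaffold == scaffold]
        gene_starts = [g[1] for g in genes if g[0] == scaffold]
        for wstart in range(0, length, step):
            wend = min(wstart + window, length)
            counts = {"Copia": 0, "Gypsy": 0, "NA": 0, "genes": 0}
            for s, sf in zip(starts, sfs):
                if wstart <= s < wend:
                    counts[sf if sf in counts else "NA"] += 1
            counts["genes"] = sum(1 for g in gene_starts if wstart <= g < wend)
            out.append(WindowDensity(scaffold, wstart, wend, counts))
            if wend >= length:
                break
    return out


def density_correlation(track_a: np.ndarray | list[float],
                        track_b: np.ndarray | list[float]
                        ) -> tuple[float, float]:
    """Pearson correlation of two window-density tracks with two-sided p."""
    a = np.asarray(track_a, dtype=float)
    b = np.asarray(track_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("tracks must have equal length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in a density track")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
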