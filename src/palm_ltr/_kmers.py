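"""Vectorised k-mer encoding and seed finding shared by the detector and scanners.

Sequences are encoded as uint8 arrays (A,C,G,T -> 0..3; anything else,
including N, -> 4).  k-mer codes are base-4 integers; any window touching a
non-ACGT base gets code -1 and is never used as a seed, so seeds never span N.
"""

from __future__ import annotations

import numpy as np

_LUT = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _LUT[ord(b)] = i
    _LUT[ord(b.lower())] = i

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
         "a": "t", "c": "g", "g": "c", "t": "a", "n": "n"}


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (non-ACGT -> 4)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return "".join(_COMP.get(c, "N") for c in reversed(seq))


def kmer_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """int64 code of every k-window; -1 where the window contains a non-ACGT base."""
    n = enc.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    e = enc.astype(np.int64)
    for j in range(k):
        col = e[j:j + n]
        codes = codes * 4 + np.where(col > 3, 0, col)
        bad |= col > 3
    codes[bad] = -1
    return codes


def kmer_index(enc: np.ndarray, k: int) -> dict[int, np.ndarray]:
    """Map k-mer code -> sorted positions. Windows containing N are skipped."""
    codes = kmer_codes(enc, k)
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    index: dict[int, np.ndarray] = {}
    boundaries = np.flatnonzero(np.diff(sorted_codes)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [sorted_codes.size]))
    for s, e in zip(starts, ends):
        code = int(sorted_codes[s])
        if code >= 0:
            index[code] = np.sort(order[s:e])
    return index


def shared_seed_hits(
    query_enc: np.ndarray,
    target_index: dict[int, np.ndarray],
    k: int,
    max_per_kmer: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """All (query_pos, target_pos) pairs of identical k-mers.

    k-mers occurring more than ``max_per_kmer`` times in the target are
    treated as repetitive noise and skipped.
    """
    codes = kmer_codes(query_enc, k)
    qpos_out: list[np.ndarray] = []
    tpos_out: list[np.ndarray] = []
    for qpos, code in enumerate(codes):
        if code < 0:
            continue
        hits = target_index.get(int(code))
        if hits is None or hits.size > max_per_kmer:
            continue
        qpos_out.append(np.full(hits.size, qpos, dtype=np.int64))
        tpos_out.append(hits.astype(np.int64))
    if not qpos_out:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(qpos_out), np.concatenate(tpos_out)


def direct_repeat_seeds(
    enc: np.ndarray, k: int, min_sep: int, max_sep: int, max_per_kmer: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Pairs (i, j), i < j, of identical k-mers with min_sep <= j-i <= max_sep.

    Used to seed direct-repeat (LTR pair) discovery on a single scaffold.
    """
    codes = kmer_codes(enc, k)
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    boundaries = np.flatnonzero(np.diff(sorted_codes)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [sorted_codes.size]))
    ii: list[np.ndarray] = []
    jj: list[np.ndarray] = []
    for s, e in zip(starts, ends):
        if int(sorted_codes[s]) < 0 or e - s < 2 or e - s > max_per_kmer:
            continue
        pos = np.sort(order[s:e])
        # pairs within the separation window; occurrence lists are short
        for a in range(pos.size - 1):
            sep = pos[a + 1:] - pos[a]
            keep = (sep >= min_sep) & (sep <= max_sep)
            if keep.any():
                sel = pos[a + 1:][keep]
                ii.append(np.full(sel.size, pos[a], dtype=np.int64))
                jj.append(sel.astype(np.int64))
    if not ii:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(ii), np.concatenate(jj)


def xdrop_extend(
    enc: np.ndarray,
    i0: int,
    j0: int,
    i1: int,
    j1: int,
    match: int = 1,
    mismatch: int = -2,
    xdrop: int = 15,
) -> tuple[int, int]:
    """Ungapped x-drop extension of an anchored repeat pair.

    The anchor copies are enc[i0:i1] and enc[j0:j1] (same length).  Returns
    (left_ext, right_ext): how far the repeat extends beyond the anchor on
    each side before the running score drops ``xdrop`` below its maximum.
    """
    # leftward
    best = cur = 0
    left_ext = 0
    step = 1
    while i0 - step >= 0 and j0 - step >= i1:
        a, b = enc[i0 - step], enc[j0 - step]
        cur += match if (a == b and a <= 3) else mismatch
        if cur > best:
            best, left_ext = cur, step
        if best - cur > xdrop:
            break
        step += 1
    # rightward
    best = cur = 0
    right_ext = 0
    step = 0
    n = enc.size
    while j1 + step < n and i1 + step < j0 - left_ext:
        a, b = enc[i1 + step], enc[j1 + step]
        cur += match if (a == b and a <= 3) else mismatch
        if cur > best:
            best, right_ext = cur, step + 1
        if best - cur > xdrop:
            break
        step += 1
    return left_ext, right_ext
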