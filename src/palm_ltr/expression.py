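"""Expression profiling of elements across tissues from short reads.

Reads are assigned to an element reference library by exact k-mer seeding
and ungapped extension on both strands; a read counts toward its
best-scoring element when the implied identity reaches ``min_identity``,
and ties among equally good elements are split fractionally (element
families are similar by construction, so winner-takes-all would bias the
family references).

Between-library scaling uses the trimmed mean of M-values (TMM): per
library, log2 ratios (M) against a reference library are trimmed (30 % of
M tails, 5 % of abundance tails), averaged with inverse-variance weights
and exponentiated; factors are rescaled to geometric mean 1.  Normalized
values are counts per million divided by the factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kmers import encode, kmer_index, revcomp


@dataclass
class CountMatrix:
    counts: pd.DataFrame                  # rows: elements, columns: tissues
    unassigned: dict[str, float] = field(default_factory=dict)
    factors: pd.Series | None = None

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def normalized(self) -> pd.DataFrame:
        """Counts per million scaled by the TMM factors."""
        if self.factors is None:
            self.factors = tmm_normalize(self.counts)
        cpm = self.counts / self.library_sizes * 1e6
        return cpm / self.factors


# ---------------------------------------------------------------------------
# read assignment


def _best_hit_identity(read_enc: np.ndarray, ref_enc: np.ndarray,
                       offsets: set[int]) -> float:
    """Best ungapped identity of the read against candidate alignment offsets."""
    best = 0.0
    L = read_enc.size
    for off in offsets:
        if off < 0 or off + L > ref_enc.size:
            continue
        seg = ref_enc[off:off + L]
        ident = float(np.mean((seg == read_enc) & (read_enc <= 3)))
        if ident > best:
            best = ident
    return best


def assign_reads(reads: list[tuple[str, str, str]],
                 library: dict[str, str],
                 min_identity: float = 0.95,
                 seed_k: int = 15) -> tuple[dict[str, float], float]:
    """Fractional per-element read counts plus the unassigned count."""
    if not library:
        raise ValueError("empty element library")
    ids = sorted(library)
    indexes = {}
    encs = {}
    for eid in ids:
        seq = library[eid].upper()
        encs[eid] = (encode(seq), encode(revcomp(seq)))
        indexes[eid] = (kmer_index(encs[eid][0], seed_k),
                        kmer_index(encs[eid][1], seed_k))
    counts = {eid: 0.0 for eid in ids}
    unassigned = 0.0
    for _, seq, _ in reads:
        if len(seq) < seed_k:
            unassigned += 1.0
            continue
        renc = encode(seq.upper())
        rcodes = _read_codes(renc, seed_k)
        scores: dict[str, float] = {}
        for eid in ids:
            best = 0.0
            for strand in (0, 1):
                offsets = set()
                for rpos, code in rcodes:
                    hits = indexes[eid][strand].get(code)
                    if hits is not None:
                        offsets.update(int(h) - rpos for h in hits[:10])
                if offsets:
                    best = max(best, _best_hit_identity(renc, encs[eid][strand],
                                                        offsets))
            if best >= min_identity:
                scores[eid] = best
        if not scores:
            unassigned += 1.0
            continue
        top = max(scores.values())
        winners = sorted(e for e, s in scores.items() if s == top)
        for w in winners:
            counts[w] += 1.0 / len(winners)
    return counts, unassigned


def _read_codes(renc: np.ndarray, k: int) -> list[tuple[int, int]]:
    from ._kmers import kmer_codes
    codes = kmer_codes(renc, k)
    # sparse sampling of seed positions keeps assignment fast
    step = max(1, k // 2)
    out = []
    for pos in range(0, codes.size, step):
        if codes[pos] >= 0:
            out.append((pos, int(codes[pos])))
    return out


def count_matrix(per_tissue_reads: dict[str, list[tuple[str, str, str]]],
                 library: dict[str, str],
                 min_identity: float = 0.95,
                 seed_k: int = 15) -> CountMatrix:
    """Assign every tissue's reads and assemble the element x tissue matrix."""
    tissues = sorted(per_tissue_reads)
    data = {}
    unassigned = {}
    for tissue in tissues:
        counts, un = assign_reads(per_tissue_reads[tissue], library,
                                  min_identity, seed_k)
        data[tissue] = counts
        unassigned[tissue] = un
    df = pd.DataFrame(data, index=sorted(library)).fillna(0.0)
    return CountMatrix(df, unassigned)


# ---------------------------------------------------------------------------
# TMM normalization


def _tmm_factor_pair(obs: np.ndarray, ref: np.ndarray,
                     logratio_trim: float = 0.30,
                     abundance_trim: float = 0.05) -> float:
    """TMM factor of one library against the reference library."""
    n_obs, n_ref = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        raise ValueError("library shares no expressed rows with the reference")
    o, r = obs[keep], ref[keep]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # asymptotic delta-method variance of M
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.allclose(m, m[0], atol=1e-10):
        return float(2.0 ** np.average(m, weights=1.0 / w))
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abundance_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & \
            (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        keep2 = np.ones_like(keep2)
    f = np.average(m[keep2], weights=1.0 / w[keep2])
    return float(2.0 ** f)


def tmm_normalize(counts: pd.DataFrame,
                  ref_column: str | None = None) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference library defaults to the column whose size is the median
    (lower median for even column counts).
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two libraries")
    sizes = counts.sum(axis=0)
    if (sizes <= 0).any():
        raise ValueError("every library must have positive total count")
    if ref_column is None:
        order = sizes.sort_values(kind="stable").index
        ref_column = order[(len(order) - 1) // 2]
    ref = counts[ref_column].to_numpy(dtype=float)
    factors = {}
    for col in counts.columns:
        if col == ref_column:
            factors[col] = 1.0
        else:
            factors[col] = _tmm_factor_pair(
                counts[col].to_numpy(dtype=float), ref)
    f = pd.Series(factors)[counts.columns]
    f /= np.exp(np.mean(np.log(f)))
    return f


# ---------------------------------------------------------------------------
# shares


def expressed_elements(normalized: pd.DataFrame,
                       min_cpm: float = 1.0) -> list[str]:
    """Elements with normalized expression above ``min_cpm`` in any tissue."""
    mask = (normalized > min_cpm).any(axis=1)
    return sorted(normalized.index[mask])


def expression_shares(normalized: pd.DataFrame,
                      classes: dict[str, str],
                      min_cpm: float = 1.0
                      ) -> tuple[pd.Series, pd.Series, list[str]]:
    """Percentage shares of total expression per class and per tissue.

    Restricted to elements expressed above ``min_cpm`` in at least one
    tissue.  Returns (class shares, tissue shares, expressed element ids).
    """
    missing = set(normalized.index) - set(classes)
    if missing:
        raise ValueError(f"elements without a class: {sorted(missing)[:5]}")
    expressed = expressed_elements(normalized, min_cpm)
    sub = normalized.loc[expressed]
    grand = float(sub.to_numpy().sum())
    if grand <= 0:
        raise ValueError("zero total expression")
    class_tot: dict[str, float] = {}
    for eid in expressed:
        cls = classes[eid]
        class_tot[cls] = class_tot.get(cls, 0.0) + float(sub.loc[eid].sum())
    class_shares = pd.Series(class_tot).sort_index() / grand * 100.0
    tissue_shares = sub.sum(axis=0) / grand * 100.0
    return class_shares, tissue_shares, expressed


def fold_change(normalized: pd.DataFrame, tissue_a: str, tissue_b: str,
                pseudo: float = 0.0) -> pd.Series:
    """Per-element ratio of normalized expression between two tissues."""
    return (normalized[tissue_b] + pseudo) / (normalized[tissue_a] + pseudo)
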