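"""Collection-level bookkeeping: the per-superfamily summary table.

Aggregates detection, classification, clustering and copy-number results
into the standard per-superfamily/lineage table: group and element counts,
LTR length statistics, mean LTR identity, genomic copy counts and coverage,
plus percentage shares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .clustering import Family
from .domains import ClassifiedElement
from .scan import CopyHit


def percentage_shares(counts: dict[str, int], decimals: int = 1
                      ) -> dict[str, float]:
    """Percentage of each category among the total, to ``decimals`` places.

    Shares are truncated (not rounded) toward zero, the convention common in
    TE collection tables; truncation also guarantees the shares never sum
    above 100.
    """
    total = sum(counts.values())
    if total == 0:
        return {k: 0.0 for k in counts}
    scale = 10.0 ** decimals
    return {k: math.floor(100.0 * v / total * scale + 1e-9) / scale
            for k, v in counts.items()}


def mapped_share(mapped: int, total: int, decimals: int = 1) -> float:
    """Share (%) of copies that could be mapped to a chromosome subset."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * mapped / total, decimals)


@dataclass
class CollectionSummary:
    table: pd.DataFrame
    shares: dict[str, float]
    totals: dict[str, float] = field(default_factory=dict)


def summarize_collection(
    classified: list[ClassifiedElement],
    families: list[Family],
    copies: list[CopyHit],
    genome_bp: int | None = None,
) -> CollectionSummary:
    """Build the per-superfamily summary table and overall shares."""
    rows = []
    sf_of = {ce.element_id: ce.superfamily for ce in classified}
    counts = {"RLC": 0, "RLG": 0, "RXX-NA": 0}
    for ce in classified:
        counts[ce.superfamily] = counts.get(ce.superfamily, 0) + 1
    fam_counts: dict[str, int] = {}
    for fam in families:
        sf = sf_of.get(fam.reference, fam.superfamily)
        fam_counts[sf] = fam_counts.get(sf, 0) + 1
    sf_label = {"Copia": "RLC", "Gypsy": "RLG", "NA": "RXX-NA"}
    copy_counts: dict[str, int] = {}
    copy_bp: dict[str, int] = {}
    for hit in copies:
        if not hit.complete:
            continue
        sf = sf_label.get(hit.superfamily, hit.superfamily)
        copy_counts[sf] = copy_counts.get(sf, 0) + 1
        copy_bp[sf] = copy_bp.get(sf, 0) + (hit.end - hit.start)
    for sf in ("RLC", "RLG", "RXX-NA"):
        members = [ce for ce in classified if ce.superfamily == sf]
        ltr_lens = []
        idents = []
        for ce in members:
            e = ce.element
            ltr_lens.append(e.ltr5[1] - e.ltr5[0])
            ltr_lens.append(e.ltr3[1] - e.ltr3[0])
            idents.append(e.identity)
        rows.append({
            "superfamily": sf,
            "groups": fam_counts.get(sf, 0),
            "elements": len(members),
            "ltr_mean_bp": round(sum(ltr_lens) / len(ltr_lens), 1)
                if ltr_lens else None,
            "ltr_min_bp": min(ltr_lens) if ltr_lens else None,
            "ltr_max_bp": max(ltr_lens) if ltr_lens else None,
            "ltr_mean_identity_pct": round(100.0 * sum(idents) / len(idents), 1)
                if idents else None,
            "copies": copy_counts.get(sf, 0),
            "coverage_pct": round(100.0 * copy_bp.get(sf, 0) / genome_bp, 2)
                if genome_bp else None,
        })
    table = pd.DataFrame(rows)
    totals = {
        "groups": int(table["groups"].sum()),
        "elements": int(table["elements"].sum()),
        "copies": int(table["copies"].sum()),
    }
    if genome_bp:
        totals["coverage_pct"] = round(
            100.0 * sum(copy_bp.values()) / genome_bp, 2)
    return CollectionSummary(table, percentage_shares(counts), totals)
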