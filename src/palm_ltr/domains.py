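"""Protein-domain annotation and RLC/RLG/RXX-NA superfamily classification.

Elements are translated in all six frames and scanned against a labelled
library of GAG/PR/INT/RT/RH amino-acid references by Smith-Waterman local
alignment (BLOSUM62, affine gaps).  E-values follow the Karlin-Altschul
extreme-value formula with the library residue count as database size.

Classification uses domain presence and order only: elements lacking all of
RT/INT/RH are putative non-autonomous retroelements (RXX-NA, covering
LARD/TRIM/TR-GAG-like structures with at most GAG and PR); otherwise the
superfamily is the majority label of the RT/INT/RH hits, with integrase
position (upstream of RT = Copia, downstream of RNaseH = Gypsy) breaking
ties.  Frameshift tolerance comes from merging same-kind hits in nearby
frames rather than from splice-aware alignment: the classification rule
needs presence and order, not intact ORFs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from ._kmers import revcomp
from .detector import LTRElement
from .io import DomainRef

DOMAIN_KINDS = ("GAG", "PR", "INT", "RT", "RH")
AUTONOMOUS_KINDS = {"RT", "INT", "RH"}
SUPERFAMILY_CODES = {"Copia": "RLC", "Gypsy": "RLG", "NA": "RXX-NA"}

# gapped Karlin-Altschul parameters for BLOSUM62 with 11/1 gap costs
_KA_LAMBDA = 0.267
_KA_K = 0.041

_IUPAC = set("ACGTRYSWKMBDHVN")


@dataclass
class DomainHit:
    kind: str
    frame: int                       # +1..+3 forward, -1..-3 reverse
    start: int                       # nucleotide interval on the element
    end: int
    score: float                     # raw Smith-Waterman score
    bit_score: float
    e_value: float
    ref_id: str
    superfamily: str
    lineage: str
    aa_query: tuple[int, int] = (0, 0)   # aa interval in the translated frame


@dataclass
class ClassifiedElement:
    element: LTRElement
    superfamily: str                 # RLC | RLG | RXX-NA
    lineage: str | None
    census: dict[str, DomainHit] = field(default_factory=dict)
    orientation: str = "unknown"     # forward | reverse | unknown

    @property
    def n_domains(self) -> int:
        return len(self.census)

    @property
    def element_id(self) -> str:
        return self.element.element_id


def translate_six_frames(sequence: str) -> dict[int, str]:
    """Standard-code translation of all six frames; stops '*', N -> 'X'."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC characters {sorted(bad)}")
    rc = revcomp(seq)
    frames: dict[int, str] = {}
    for f in (1, 2, 3):
        for sig, s in ((1, seq), (-1, rc)):
            sub = s[f - 1:]
            sub = sub[:len(sub) - len(sub) % 3]
            frames[sig * f] = str(Seq(sub).translate())
    return frames


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _evalue(score: float, m: int, n: int) -> tuple[float, float]:
    bits = (_KA_LAMBDA * score - math.log(_KA_K)) / math.log(2.0)
    return bits, m * n * 2.0 ** (-bits)


def _kmer_set(protein: str, k: int = 4) -> set[str]:
    return {protein[i:i + k] for i in range(len(protein) - k + 1)}


def _aa_to_nt(frame: int, aa_start: int, aa_end: int, nt_len: int
              ) -> tuple[int, int]:
    f = abs(frame)
    s = f - 1 + 3 * aa_start
    e = f - 1 + 3 * aa_end
    if frame > 0:
        return s, e
    return nt_len - e, nt_len - s


def scan_domains(sequence: str, library: list[DomainRef],
                 e_cutoff: float = 1e-4) -> list[DomainHit]:
    """All domain hits of the element against the labelled reference library.

    Overlapping hits of the same kind are reduced to the best scorer.
    Deterministic regardless of library order (ties broken by reference id).
    """
    if not library:
        raise ValueError("empty domain reference library")
    frames = translate_six_frames(sequence)
    db_size = sum(len(r.sequence) for r in library)
    aligner = _protein_aligner()
    refs = sorted(library, key=lambda r: r.ref_id)
    ref_kmers = {r.ref_id: _kmer_set(r.sequence) for r in refs}
    hits: list[DomainHit] = []
    for frame in sorted(frames):
        prot = frames[frame]
        if len(prot) < 10:
            continue
        frame_kmers = _kmer_set(prot)
        for ref in refs:
            if len(frame_kmers & ref_kmers[ref.ref_id]) < 2:
                continue
            alns = aligner.align(prot, ref.sequence)
            aln = alns[0]
            if aln.score <= 0:
                continue
            bits, ev = _evalue(aln.score, len(prot), db_size)
            if ev > e_cutoff:
                continue
            blocks = aln.aligned[0]
            aa_start, aa_end = int(blocks[0][0]), int(blocks[-1][1])
            nt_s, nt_e = _aa_to_nt(frame, aa_start, aa_end, len(sequence))
            hits.append(DomainHit(ref.kind, frame, nt_s, nt_e, float(aln.score),
                                  bits, ev, ref.ref_id, ref.superfamily,
                                  ref.lineage, (aa_start, aa_end)))
    hits.sort(key=lambda h: (-h.score, h.e_value, h.ref_id, h.start))
    # reduce overlapping same-kind hits to the best scorer
    kept: list[DomainHit] = []
    for hit in hits:
        clash = any(k.kind == hit.kind and k.start < hit.end and hit.start < k.end
                    for k in kept)
        if not clash:
            kept.append(hit)
    kept.sort(key=lambda h: (h.start, h.kind))
    return kept


def _merge_census(hits: list[DomainHit], merge_distance: int = 300
                  ) -> dict[str, DomainHit]:
    """Best hit per kind; nearby same-kind fragments (frameshifted pieces)
    count as one census entry represented by the strongest fragment."""
    census: dict[str, DomainHit] = {}
    for hit in sorted(hits, key=lambda h: (-h.score, h.e_value, h.ref_id)):
        cur = census.get(hit.kind)
        if cur is None:
            census[hit.kind] = hit
        elif (hit.start < cur.end + merge_distance
              and cur.start < hit.end + merge_distance):
            continue    # fragment of the already-counted domain
    return census


def classify_superfamily(hits: list[DomainHit],
                         element: LTRElement) -> ClassifiedElement:
    """Assign RLC/RLG/RXX-NA from domain presence, labels and order."""
    census = _merge_census(hits)
    core = [census[k] for k in sorted(AUTONOMOUS_KINDS & census.keys())]
    if not core:
        return ClassifiedElement(element, "RXX-NA", None, census,
                                 _orientation([census[k] for k in census]))
    votes: dict[str, int] = {}
    for hit in core:
        votes[hit.superfamily] = votes.get(hit.superfamily, 0) + 1
    best = max(votes.values())
    leaders = sorted(sf for sf, v in votes.items() if v == best)
    if len(leaders) == 1:
        superfamily = leaders[0]
    else:
        superfamily = _order_tiebreak(census)
    lineage = census["RT"].lineage if "RT" in census and \
        census["RT"].lineage not in ("", "-") else None
    return ClassifiedElement(element, SUPERFAMILY_CODES[superfamily], lineage,
                             census, _orientation(core))


def _order_tiebreak(census: dict[str, DomainHit]) -> str:
    intg = census.get("INT")
    if intg is not None:
        rt, rh = census.get("RT"), census.get("RH")
        if rt is not None and intg.start < rt.start:
            return "Copia"
        if rh is not None and intg.start > rh.start:
            return "Gypsy"
    return "Copia"    # deterministic fallback for unresolvable order


def _orientation(core: list[DomainHit]) -> str:
    fwd = sum(1 for h in core if h.frame > 0)
    rev = len(core) - fwd
    if fwd > rev:
        return "forward"
    if rev > fwd:
        return "reverse"
    return "unknown"


def summarize_domain_census(classified: list[ClassifiedElement]) -> dict:
    """Counts by n_domains (0-5) and per-kind frequencies, split by superfamily.

    Also reports the share of four-or-five-domain elements among RLC+RLG,
    and the five-domain share under both plausible denominators (RLC+RLG
    and the whole collection).
    """
    by_sf: dict[str, list[ClassifiedElement]] = {}
    for ce in classified:
        by_sf.setdefault(ce.superfamily, []).append(ce)
    table: dict[str, dict[int, int]] = {}
    kind_freq: dict[str, dict[str, int]] = {}
    for sf, members in sorted(by_sf.items()):
        table[sf] = {n: 0 for n in range(6)}
        kind_freq[sf] = {k: 0 for k in DOMAIN_KINDS}
        for ce in members:
            table[sf][ce.n_domains] += 1
            for kind in ce.census:
                kind_freq[sf][kind] += 1
    rlc_rlg = [ce for ce in classified if ce.superfamily in ("RLC", "RLG")]
    n_auto = len(rlc_rlg)
    n45 = sum(1 for ce in rlc_rlg if ce.n_domains in (4, 5))
    n5 = sum(1 for ce in rlc_rlg if ce.n_domains == 5)
    total = len(classified)
    return {
        "n_domains_by_superfamily": table,
        "kind_frequency": kind_freq,
        "four_or_five_share_pct": round(100.0 * n45 / n_auto, 1) if n_auto else None,
        "five_share_of_autonomous_pct":
            round(100.0 * n5 / n_auto, 1) if n_auto else None,
        "five_share_of_total_pct": round(100.0 * n5 / total, 1) if total else None,
    }


def classify_elements(genome: dict[str, str], elements: list[LTRElement],
                      library: list[DomainRef],
                      e_cutoff: float = 1e-4) -> list[ClassifiedElement]:
    """Scan and classify every detected element."""
    out = []
    for elem in elements:
        seq = genome[elem.scaffold][elem.start:elem.end]
        out.append(classify_superfamily(scan_domains(seq, library, e_cutoff),
                                        elem))
    return out
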