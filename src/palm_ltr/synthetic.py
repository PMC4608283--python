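"""Synthetic genomes with planted full-length LTR retrotransposons.

The generator emulates the statistical structure the annotation pipeline
assumes: multi-scaffold assemblies with i.i.d. background (optionally with
N runs), planted elements built as

    LTR5 + [offset + PBS + ORF(domains) + filler + PPT + offset] + LTR3

where the 3' LTR is the 5' LTR diverged under a Kimura two-parameter
substitution model by an expected K substitutions/site, every insertion
duplicates its target site (TSD) on both flanks, background "genes" follow
their own density gradient, and per-tissue read sets are drawn multinomially
from stated expression levels.

Element geometry defaults follow what is typical of plant LTR
retrotransposons (LTRs of a few hundred bp to a few kb, total length under
12 kb, TSDs of 4-6 bp, TG...CA termini).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .io import DomainRef, load_domain_library, load_trna_library
from .mutation import mutate, random_sequence
from ._kmers import revcomp

AUTONOMOUS_KINDS = {"RT", "INT", "RH"}

# canonical internal domain order per superfamily (integrase position is the
# structural discriminator: upstream of RT in Copia, downstream of RH in Gypsy)
DOMAIN_ORDER = {
    "Copia": ["GAG", "PR", "INT", "RT", "RH"],
    "Gypsy": ["GAG", "PR", "RT", "RH", "INT"],
    "NA": ["GAG", "PR"],
}

_CODONS: dict[str, list[str]] = {}
for codon, aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()


@dataclass
class ElementSpec:
    """Blueprint for one planted element."""

    superfamily: str = "Copia"          # Copia | Gypsy | NA
    lineage: str | None = None          # RT reference lineage (Copia/Gypsy only)
    ltr_length: int = 600
    internal_length: int = 4000
    domain_list: tuple[str, ...] | None = None   # default: full canonical order
    divergence_age: float = 0.05        # expected K between the LTR pair
    ts_tv_ratio: float = 2.0
    tsd_length: int = 5
    has_pbs: bool = True
    has_ppt: bool = True
    disrupt: bool = False
    tg_ca: bool = True                  # canonical TG...CA LTR termini

    def __post_init__(self) -> None:
        if self.superfamily not in DOMAIN_ORDER:
            raise ValueError(f"unknown superfamily {self.superfamily!r}")
        if self.domain_list is None:
            self.domain_list = tuple(DOMAIN_ORDER[self.superfamily])
        else:
            order = DOMAIN_ORDER["Copia" if self.superfamily == "NA"
                                 else self.superfamily]
            unknown = set(self.domain_list) - {"GAG", "PR", "INT", "RT", "RH"}
            if unknown:
                raise ValueError(f"unknown domain kinds {unknown}")
            self.domain_list = tuple(k for k in order if k in self.domain_list)
        if self.superfamily == "NA" and set(self.domain_list) & AUTONOMOUS_KINDS:
            raise ValueError("NA elements may carry only GAG/PR domains")
        if self.divergence_age < 0:
            raise ValueError("divergence_age must be >= 0")
        if not 4 <= self.tsd_length <= 6:
            raise ValueError("tsd_length must be 4-6 bp")
        if self.ltr_length < 50 or self.internal_length < 50:
            raise ValueError("ltr_length and internal_length must be >= 50 bp")

    @property
    def total_length(self) -> int:
        return 2 * self.ltr_length + self.internal_length

    @property
    def truth_superfamily(self) -> str:
        """Superfamily the classifier should recover: NA without RT/INT/RH."""
        if not set(self.domain_list) & AUTONOMOUS_KINDS:
            return "NA"
        return self.superfamily


@dataclass
class ElementTruth:
    """Coordinates (element-relative, 0-based half-open) of one built element."""

    spec: ElementSpec
    sequence: str
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    domains: list[tuple[str, int, int]]      # (kind, start, end) in frame +1 ORF
    pbs: tuple[int, int] | None
    ppt: tuple[int, int] | None
    lineage: str | None


@dataclass
class PlantedElement:
    """One planted element located on the assembled genome."""

    element_id: str
    scaffold: str
    start: int
    end: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    tsd: str
    superfamily: str
    lineage: str | None
    k: float
    family_id: str
    truth: ElementTruth


@dataclass
class SyntheticGenome:
    """Assembled genome plus full ground truth."""

    genome: dict[str, str]
    elements: list[PlantedElement]
    genes: list[tuple[str, int, int, str]]
    expression: dict[str, dict[str, float]] = field(default_factory=dict)

    def element_sequences(self) -> dict[str, str]:
        return {e.element_id: e.truth.sequence for e in self.elements}


def generate_background(length: int, gc: float = 0.45, n_run_fraction: float = 0.0,
                        seed: int | np.random.Generator = 0) -> str:
    """i.i.d. background sequence with N runs covering ~``n_run_fraction``."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= n_run_fraction < 1.0:
        raise ValueError("n_run_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    seq = list(random_sequence(length, gc, rng))
    n_target = int(round(length * n_run_fraction))
    placed = 0
    while placed < n_target:
        run = int(min(rng.integers(200, 2000), n_target - placed))
        start = int(rng.integers(0, max(1, length - run)))
        seq[start:start + run] = "N" * run
        placed += run
    return "".join(seq)


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(_CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in protein)


def _pick_domain_refs(spec: ElementSpec, library: list[DomainRef],
                      rng: np.random.Generator) -> tuple[list[DomainRef], str | None]:
    """Choose one labelled reference per requested domain kind."""
    sf = spec.superfamily if spec.superfamily != "NA" else \
        ("Copia" if rng.random() < 0.5 else "Gypsy")
    lineage = spec.lineage
    if lineage is None and spec.superfamily != "NA" and "RT" in spec.domain_list:
        choices = sorted({r.lineage for r in library
                          if r.kind == "RT" and r.superfamily == sf})
        lineage = choices[rng.integers(0, len(choices))]
    refs = []
    for kind in spec.domain_list:
        if kind == "RT":
            pool = [r for r in library if r.kind == "RT" and r.superfamily == sf
                    and r.lineage == lineage]
        else:
            pool = [r for r in library if r.kind == kind and r.superfamily == sf]
        if not pool:
            raise ValueError(f"no {kind} reference for {sf}/{lineage} in library")
        refs.append(pool[0])
    return refs, (lineage if spec.superfamily != "NA" else None)


def build_element(spec: ElementSpec, seed: int | np.random.Generator,
                  library: list[DomainRef] | None = None,
                  trna_lib: dict[str, str] | None = None) -> ElementTruth:
    """Build one element sequence and its ground-truth coordinates."""
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    if library is None:
        library = load_domain_library()
    if trna_lib is None:
        trna_lib = load_trna_library()

    ltr5 = random_sequence(spec.ltr_length, 0.45, rng)
    if spec.tg_ca:
        ltr5 = "TG" + ltr5[2:-2] + "CA"

    # --- internal region -------------------------------------------------
    L = spec.ltr_length
    pieces: list[str] = []
    pos = 0
    pbs_iv = ppt_iv = None
    if spec.has_pbs:
        trna_names = sorted(trna_lib)
        trna = trna_lib[trna_names[rng.integers(0, len(trna_names))]]
        pbs = revcomp(trna[-12:])            # complementary to the tRNA 3' end
        offset = int(rng.integers(1, 6))     # within 20 bp of the 5' LTR
        pieces.append(random_sequence(offset, 0.45, rng))
        pbs_iv = (offset, offset + len(pbs))
        pieces.append(pbs)
        pos = offset + len(pbs)

    refs, lineage = _pick_domain_refs(spec, library, rng) if spec.domain_list \
        else ([], None)
    domains: list[tuple[str, int, int]] = []
    if refs:
        gap = int(rng.integers(6, 30)) // 3 * 3
        pieces.append(random_sequence(gap, 0.45, rng))
        pos += gap
        orf_parts = ["ATG"]
        orf_pos = pos + 3
        for ref in refs:
            nt = _back_translate(ref.sequence, rng)
            domains.append((ref.kind, orf_pos, orf_pos + len(nt)))
            orf_parts.append(nt)
            linker = _back_translate(
                "".join(rng.choice(list("GASTLV"), size=4)), rng)
            orf_parts.append(linker)
            orf_pos += len(nt) + len(linker)
        orf = "".join(orf_parts)
        if spec.disrupt:
            orf = _disrupt_orf(orf, rng)
        pieces.append(orf)
        pos += len(orf)

    ppt = "".join(rng.choice(["A", "G"], size=15, p=[0.4, 0.6])) \
        if spec.has_ppt else ""
    tail = (len(ppt) + 3) if spec.has_ppt else 0
    filler = spec.internal_length - pos - tail
    if filler < 0:
        raise ValueError(
            f"domain_list needs {pos + tail} bp but internal_length is "
            f"{spec.internal_length}")
    pieces.append(random_sequence(filler, 0.45, rng) if filler else "")
    if spec.has_ppt:
        ppt_iv = (pos + filler, pos + filler + len(ppt))
        pieces.append(ppt)
        pieces.append(random_sequence(3, 0.45, rng))
    internal = "".join(pieces)
    assert len(internal) == spec.internal_length

    ltr3 = mutate(ltr5, spec.divergence_age, spec.ts_tv_ratio, rng)
    if spec.tg_ca:
        ltr3 = "TG" + ltr3[2:-2] + "CA"
    sequence = ltr5 + internal + ltr3

    shift = L
    return ElementTruth(
        spec=spec,
        sequence=sequence,
        ltr5=(0, L),
        ltr3=(L + spec.internal_length, len(sequence)),
        domains=[(k, s + shift, e + shift) for k, s, e in domains],
        pbs=(pbs_iv[0] + shift, pbs_iv[1] + shift) if pbs_iv else None,
        ppt=(ppt_iv[0] + shift, ppt_iv[1] + shift) if ppt_iv else None,
        lineage=lineage,
    )


def _disrupt_orf(orf: str, rng: np.random.Generator) -> str:
    """Inject one 1-bp insertion and one premature stop at in-frame positions."""
    n_codons = len(orf) // 3
    stop_at = int(rng.integers(n_codons // 2, n_codons - 1)) * 3
    orf = orf[:stop_at] + "TAA" + orf[stop_at + 3:]
    ins_at = int(rng.integers(1, n_codons // 2)) * 3
    orf = orf[:ins_at] + "ACGT"[rng.integers(0, 4)] + orf[ins_at:]
    return orf[:len(orf) - 1]    # keep internal length as budgeted


# ---------------------------------------------------------------------------
# planting


def _gradient_positions(n: int, length: int, slope: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Sample n positions with linear density 1 + slope*(2x/L - 1), slope in [-1,1]."""
    u = rng.random(n)
    if abs(slope) < 1e-9:
        return (u * length).astype(np.int64)
    # inverse CDF of f(x) = (1 + slope*(2x-1)) on [0,1]
    a, b = slope, 1.0 - slope
    x = (-b + np.sqrt(b * b + 4 * a * u)) / (2 * a)
    return (np.clip(x, 0, 1 - 1e-12) * length).astype(np.int64)


def _overlaps(start: int, end: int, occupied: list[tuple[int, int]]) -> bool:
    return any(s < end and start < e for s, e in occupied)


def plant_elements(
    background: dict[str, str],
    specs: list[ElementSpec],
    placement_bias: float = 0.0,
    seed: int | np.random.Generator = 0,
    n_genes: int = 0,
    gene_gradient: float = 0.8,
    gene_length: tuple[int, int] = (1000, 3000),
    library: list[DomainRef] | None = None,
    trna_lib: dict[str, str] | None = None,
    copies: dict[int, int] | None = None,
    copy_divergence: float = 0.08,
) -> SyntheticGenome:
    """Plant elements (with TSDs) and gene intervals into background scaffolds.

    ``placement_bias`` in [0, 1] makes Copia elements avoid the gene-dense
    end of each scaffold (genes follow a decreasing density gradient, Copia
    an increasing one), so TE-vs-gene density correlation tests have signal.
    ``copies`` maps spec index -> number of planted copies; extra copies are
    whole-element K2P-diverged duplicates sharing the founder's family id.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    if library is None:
        library = load_domain_library()
    if trna_lib is None:
        trna_lib = load_trna_library()

    scaffolds = sorted(background)
    lengths = {s: len(background[s]) for s in scaffolds}

    # genes first, on background coordinates, densest at scaffold start
    genes_bg: dict[str, list[tuple[int, int]]] = {s: [] for s in scaffolds}
    total_len = sum(lengths.values())
    for s in scaffolds:
        n_here = int(round(n_genes * lengths[s] / total_len))
        placed = 0
        attempts = 0
        while placed < n_here and attempts < 50 * n_here + 100:
            attempts += 1
            glen = int(rng.integers(gene_length[0], gene_length[1] + 1))
            pos = int(_gradient_positions(1, lengths[s] - glen, -gene_gradient,
                                          rng)[0])
            if not _overlaps(pos, pos + glen, genes_bg[s]):
                genes_bg[s].append((pos, pos + glen))
                placed += 1
        genes_bg[s].sort()

    # build element sequences
    built: list[tuple[int, ElementTruth, str]] = []   # (spec index, truth, family)
    for idx, spec in enumerate(specs):
        truth = build_element(spec, rng, library, trna_lib)
        family = f"FAM{idx:04d}"
        built.append((idx, truth, family))
        for _ in range((copies or {}).get(idx, 1) - 1):
            copy_truth = ElementTruth(
                spec=spec,
                sequence=mutate(truth.sequence, copy_divergence,
                                spec.ts_tv_ratio, rng),
                ltr5=truth.ltr5, ltr3=truth.ltr3, domains=truth.domains,
                pbs=truth.pbs, ppt=truth.ppt, lineage=truth.lineage)
            built.append((idx, copy_truth, family))

    # choose insertion points
    insertions: dict[str, list[tuple[int, ElementTruth, str]]] = \
        {s: [] for s in scaffolds}
    occupied: dict[str, list[tuple[int, int]]] = \
        {s: list(genes_bg[s]) for s in scaffolds}
    unplaced = []
    probs = np.array([lengths[s] for s in scaffolds], dtype=float)
    probs /= probs.sum()
    for idx, truth, family in built:
        spec = truth.spec
        slope = placement_bias if spec.truth_superfamily == "Copia" else 0.0
        placed = False
        for _ in range(500):
            s = scaffolds[rng.choice(len(scaffolds), p=probs)]
            span = len(truth.sequence) + spec.tsd_length
            if lengths[s] <= span + 200:
                continue
            pos = int(_gradient_positions(1, lengths[s] - span - 100, slope,
                                          rng)[0]) + 50
            if background[s][pos:pos + spec.tsd_length].count("N"):
                continue
            if not _overlaps(pos - 50, pos + span + 50, occupied[s]):
                occupied[s].append((pos - 50, pos + span + 50))
                insertions[s].append((pos, truth, family))
                placed = True
                break
        if not placed:
            unplaced.append(idx)
    if unplaced:
        raise ValueError(f"insufficient room to place specs at indices {unplaced}")

    # assemble scaffolds, shifting coordinates
    genome: dict[str, str] = {}
    planted: list[PlantedElement] = []
    genes_out: list[tuple[str, int, int, str]] = []
    eid = 0
    for s in scaffolds:
        bg = background[s]
        parts: list[str] = []
        cursor = 0
        shift = 0
        ins_sorted = sorted(insertions[s], key=lambda t: t[0])
        shifted_genes = list(genes_bg[s])
        shifts_at: list[tuple[int, int]] = []   # (bg position, cumulative shift)
        for pos, truth, family in ins_sorted:
            t = truth.spec.tsd_length
            tsd = bg[pos:pos + t]
            parts.append(bg[cursor:pos + t])
            parts.append(truth.sequence)
            cursor = pos
            start = pos + t + shift
            end = start + len(truth.sequence)
            planted.append(PlantedElement(
                element_id=f"ELEM{eid:04d}",
                scaffold=s,
                start=start, end=end,
                ltr5=(start + truth.ltr5[0], start + truth.ltr5[1]),
                ltr3=(start + truth.ltr3[0], start + truth.ltr3[1]),
                tsd=tsd,
                superfamily=truth.spec.truth_superfamily,
                lineage=truth.lineage,
                k=truth.spec.divergence_age,
                family_id=family,
                truth=truth,
            ))
            eid += 1
            shift += len(truth.sequence) + t
            shifts_at.append((pos, shift))
        parts.append(bg[cursor:])
        genome[s] = "".join(parts)
        for gi, (gs, ge) in enumerate(shifted_genes):
            gshift = 0
            for pos, cum in shifts_at:
                if pos <= gs:
                    gshift = cum
            genes_out.append((s, gs + gshift, ge + gshift, f"{s}_gene{gi:04d}"))
    return SyntheticGenome(genome=genome, elements=planted, genes=genes_out)


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    library: dict[str, str],
    levels: dict[str, float],
    read_length: int = 100,
    n_reads: int = 10_000,
    error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    tissue: str = "tissue",
) -> list[tuple[str, str, str]]:
    """Draw reads multinomially from elements proportional to their levels.

    Uniform start positions, substitution errors at ``error_rate``, constant
    Sanger qualities.  Returns (read id, sequence, quality) triples; read ids
    encode the true source element.
    """
    ids = sorted(k for k in levels if levels[k] > 0)
    if not ids:
        raise ValueError("zero total expression level")
    for k in ids:
        if levels[k] < 0:
            raise ValueError("expression levels must be >= 0")
        if read_length > len(library[k]):
            raise ValueError(f"read_length exceeds reference {k}")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    p = np.array([levels[k] for k in ids], dtype=float)
    p /= p.sum()
    counts = rng.multinomial(n_reads, p)
    qual = "I" * read_length
    reads: list[tuple[str, str, str]] = []
    rn = 0
    for elem, c in zip(ids, counts):
        seq = library[elem]
        starts = rng.integers(0, len(seq) - read_length + 1, size=c)
        for st in starts:
            r = seq[st:st + read_length]
            if error_rate > 0:
                r = _add_errors(r, error_rate, rng)
            reads.append((f"{tissue}_{rn:07d}_{elem}", r, qual))
            rn += 1
    return reads


def _add_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    arr = list(read)
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def generate_reads(
    library: dict[str, str],
    expression: dict[str, dict[str, float]],
    read_length: int = 100,
    n_reads: int = 10_000,
    error_rate: float = 0.005,
    seed: int = 0,
) -> dict[str, list[tuple[str, str, str]]]:
    """Per-tissue read sets from a {tissue: {element: level}} design."""
    root = np.random.default_rng(seed)
    out = {}
    for tissue in sorted(expression):
        sub = np.random.default_rng(root.integers(2**31))
        out[tissue] = simulate_reads(library, expression[tissue], read_length,
                                     n_reads, error_rate, sub, tissue)
    return out
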