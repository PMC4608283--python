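"""End-to-end orchestration: simulate -> detect -> classify -> lineages ->
cluster -> scan -> date -> express, with every stage's artifacts on disk.

All stage outputs are TSV/FASTA/GFF3 (one concept per file, diffable); all
randomness flows from the single config seed, from which per-stage seeds
are derived deterministically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dating, io
from .clustering import cluster_with_references
from .detector import DetectorParams, detect, element_sequences
from .domains import classify_elements, summarize_domain_census
from .expression import count_matrix, expression_shares
from .phylogeny import assign_lineages, extract_rt
from .scan import density_correlation, find_copies, mask_genome, window_density
from .summary import summarize_collection
from .synthetic import (ElementSpec, SyntheticGenome, generate_background,
                        generate_reads, plant_elements)

log = logging.getLogger("palm_ltr")

TISSUES = ("root", "leaf", "shoot_apex", "young_female_flower",
           "mature_female_flower", "pollen", "kernel", "mesocarp")


@dataclass
class RunConfig:
    """Every knob of the pipeline; YAML round-trippable."""

    seed: int = 0
    outdir: str = "palm_ltr_run"
    genome_fasta: str | None = None        # None -> simulate
    genes_bed: str | None = None

    # synthetic genome
    n_scaffolds: int = 3
    scaffold_length: int = 1_000_000
    n_elements: int = 30
    n_genes: int = 60
    placement_bias: float = 0.8
    n_run_fraction: float = 0.0
    max_divergence: float = 0.10
    family_copies: int = 1                 # planted copies per element spec
    copy_divergence: float = 0.08

    # detection / classification
    min_identity: float = 0.80
    max_element_length: int = 12_000
    strict: bool = False
    e_cutoff: float = 1e-4

    # clustering / copy scan
    cluster_min_id: float = 0.70
    cluster_min_cov: float = 0.70
    copy_min_id: float = 0.70
    copy_min_cov: float = 0.70
    mask_min_id: float = 0.80
    window: int = 1_000_000
    step: int = 500_000

    # dating
    substitution_rate: float = 1.3e-8

    # figures
    make_plots: bool = False

    # expression
    run_expression: bool = True
    n_reads: int = 5000
    read_length: int = 100
    error_rate: float = 0.005
    expressed_fraction: float = 0.4
    min_cpm: float = 1.0

    def __post_init__(self) -> None:
        for name in ("min_identity", "cluster_min_id", "cluster_min_cov",
                     "copy_min_id", "copy_min_cov", "mask_min_id"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [0, 1]")
        if self.window < self.step:
            raise ValueError("window must be >= step")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _stage_seed(config: RunConfig, stage: int) -> int:
    return int(np.random.SeedSequence([config.seed, stage])
               .generate_state(1)[0] % (2**31))


def default_specs(n: int, rng: np.random.Generator,
                  max_divergence: float = 0.10) -> list[ElementSpec]:
    """A realistic element mix: ~41 % Copia, ~26 % Gypsy, ~33 % NA."""
    specs = []
    for i in range(n):
        u = rng.random()
        sf = "Copia" if u < 0.41 else ("Gypsy" if u < 0.67 else "NA")
        domain_list = None if sf != "NA" else \
            (("GAG", "PR") if rng.random() < 0.5 else ("GAG",))
        specs.append(ElementSpec(
            superfamily=sf,
            domain_list=domain_list,
            ltr_length=int(rng.integers(200, 1500)),
            internal_length=int(rng.integers(3000, 5200)),
            divergence_age=float(rng.uniform(0.01, max_divergence)),
            tsd_length=int(rng.integers(4, 7)),
        ))
    return specs


def simulate(config: RunConfig) -> SyntheticGenome:
    """Build the synthetic study genome for this configuration."""
    rng = np.random.default_rng(_stage_seed(config, 0))
    background = {
        f"scaffold{i + 1:02d}": generate_background(
            config.scaffold_length, 0.45, config.n_run_fraction, rng)
        for i in range(config.n_scaffolds)}
    specs = default_specs(config.n_elements, rng, config.max_divergence)
    copies = {i: config.family_copies for i in range(len(specs))} \
        if config.family_copies > 1 else None
    sg = plant_elements(background, specs,
                        placement_bias=config.placement_bias, seed=rng,
                        n_genes=config.n_genes, copies=copies,
                        copy_divergence=config.copy_divergence)
    if config.run_expression:
        sg.expression = _expression_design(sg, config)
    return sg


def _expression_design(sg: SyntheticGenome,
                       config: RunConfig) -> dict[str, dict[str, float]]:
    """Per-tissue true expression levels; NA elements dominate activity."""
    rng = np.random.default_rng(_stage_seed(config, 1))
    ids = [e.element_id for e in sg.elements]
    sfs = {e.element_id: e.superfamily for e in sg.elements}
    n_expr = max(2, int(round(config.expressed_fraction * len(ids))))
    chosen = sorted(rng.choice(ids, size=n_expr, replace=False))
    base_level = {"NA": 6.0, "Copia": 2.0, "Gypsy": 2.0}
    design: dict[str, dict[str, float]] = {}
    for tissue in TISSUES:
        levels = {}
        for eid in chosen:
            on = rng.random() < 0.6
            levels[eid] = base_level[sfs[eid]] * rng.uniform(0.5, 2.0) \
                if on else 0.05
        design[tissue] = levels
    return design


@dataclass
class PipelineResult:
    config: RunConfig
    genome: dict[str, str]
    truth: SyntheticGenome | None
    elements: list
    classified: list
    lineages: list
    families: list
    copies: list
    densities: list
    correlation: tuple[float, float] | None
    estimates: list
    mask_stats: dict
    census: dict
    summary: object
    expression: dict = field(default_factory=dict)


def run_all(config: RunConfig) -> PipelineResult:
    """Run every stage and write all artifacts under ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    # --- inputs ----------------------------------------------------------
    truth: SyntheticGenome | None = None
    if config.genome_fasta is None:
        log.info("simulating genome")
        truth = simulate(config)
        genome = truth.genome
        genes = truth.genes
        io.write_fasta(out / "genome.fa", genome)
        _write_truth(out, truth)
    else:
        genome = io.read_fasta(config.genome_fasta)
        if not genome:
            raise ValueError(f"no records in {config.genome_fasta}")
        genes = io.read_bed(config.genes_bed) if config.genes_bed else []

    # --- detection -------------------------------------------------------
    params = DetectorParams(min_identity=config.min_identity,
                            max_element_length=config.max_element_length,
                            strict=config.strict)
    elements, report = detect(genome, params)
    log.info("detected %d elements (%d candidates)", len(elements),
             report.n_candidates)
    seqs = element_sequences(genome, elements)
    io.write_fasta(out / "elements.fa", seqs)
    _write_elements_gff3(out / "elements.gff3", elements)
    pd.DataFrame([{"scaffold": r.scaffold, "start": r.span[0],
                   "end": r.span[1], "reason": r.reason}
                  for r in report.rejections]).to_csv(
        out / "rejections.tsv", sep="\t", index=False)

    # --- classification --------------------------------------------------
    library = io.load_domain_library()
    classified = classify_elements(genome, elements, library, config.e_cutoff)
    census = summarize_domain_census(classified)
    _write_classification(out, classified, census)

    # --- lineages --------------------------------------------------------
    rts = {}
    for ce in classified:
        rt = extract_rt(ce, seqs[ce.element_id])
        if rt is not None:
            rts[ce.element_id] = rt
    lineages = assign_lineages(rts, library) if rts else []
    pd.DataFrame([{"element": a.element_id, "lineage": a.lineage,
                   "support": round(a.support, 4)} for a in lineages]
                 ).to_csv(out / "lineages.tsv", sep="\t", index=False)

    # --- clustering ------------------------------------------------------
    ltr_ident = {e.element_id: e.identity for e in elements}
    superfams = {ce.element_id: ce.superfamily for ce in classified}
    families = cluster_with_references(seqs, ltr_ident, superfams,
                                       config.cluster_min_id,
                                       config.cluster_min_cov)
    fam_rows = [{"family": f.family_id, "member": m,
                 "is_reference": m == f.reference}
                for f in families for m in f.members]
    pd.DataFrame(fam_rows).to_csv(out / "families.tsv", sep="\t", index=False)
    refs = {f.reference: seqs[f.reference] for f in families}
    io.write_fasta(out / "family_references.fa", refs)

    # --- genome scan -----------------------------------------------------
    sf_plain = {"RLC": "Copia", "RLG": "Gypsy", "RXX-NA": "NA"}
    ref_sf = {f.reference: sf_plain.get(superfams.get(f.reference, "NA"), "NA")
              for f in families}
    copies = find_copies(genome, refs, ref_sf, config.copy_min_id,
                         config.copy_min_cov)
    pd.DataFrame([{"ref": h.ref_id, "superfamily": h.superfamily,
                   "scaffold": h.scaffold, "start": h.start, "end": h.end,
                   "strand": h.strand, "identity": round(h.identity, 4),
                   "coverage": round(h.coverage, 4), "complete": h.complete}
                  for h in copies]).to_csv(out / "copies.tsv", sep="\t",
                                           index=False)
    _, mask_stats = mask_genome(genome, refs, config.mask_min_id)
    lengths = {s: len(genome[s]) for s in genome}
    densities = window_density([h for h in copies if h.complete], genes,
                               lengths, config.window, config.step)
    dens_rows = [{"scaffold": w.scaffold, "start": w.start, "end": w.end,
                  **w.counts} for w in densities]
    pd.DataFrame(dens_rows).to_csv(out / "window_density.tsv", sep="\t",
                                   index=False)
    correlation = None
    copia = np.array([w.density("Copia") for w in densities])
    gene_track = np.array([w.density("genes") for w in densities])
    if len(densities) >= 3 and np.ptp(copia) > 0 and np.ptp(gene_track) > 0:
        correlation = density_correlation(copia, gene_track)

    # --- dating ----------------------------------------------------------
    pairs = [(e.element_id,
              genome[e.scaffold][e.ltr5[0]:e.ltr5[1]],
              genome[e.scaffold][e.ltr3[0]:e.ltr3[1]]) for e in elements]
    estimates = dating.date_elements(pairs, config.substitution_rate)
    pd.DataFrame([{"element": d.element_id, "aligned_len": d.aligned_length,
                   "P": round(d.p, 5), "Q": round(d.q, 5),
                   "K": round(d.k, 5), "T_years": round(d.t_years, 1),
                   "status": d.status} if d.status == "ok" else
                  {"element": d.element_id, "status": d.status}
                  for d in estimates]).to_csv(out / "insertion_times.tsv",
                                              sep="\t", index=False)

    # --- expression ------------------------------------------------------
    expression: dict = {}
    if config.run_expression and truth is not None and truth.expression:
        reads = generate_reads(truth.element_sequences(), truth.expression,
                               config.read_length, config.n_reads,
                               config.error_rate, _stage_seed(config, 2))
        # quantify against the detected-element library
        cm = count_matrix(reads, seqs)
        cm.counts.to_csv(out / "counts.tsv", sep="\t")
        norm = cm.normalized()
        norm.round(3).to_csv(out / "normalized.tsv", sep="\t")
        classes = {eid: superfams.get(eid, "RXX-NA") for eid in norm.index}
        try:
            cls_shares, tis_shares, expressed = expression_shares(
                norm, classes, config.min_cpm)
            expression = {"class_shares": cls_shares.to_dict(),
                          "tissue_shares": tis_shares.to_dict(),
                          "expressed": expressed}
            cls_shares.round(1).to_csv(out / "class_shares.tsv", sep="\t",
                                       header=["share_pct"])
            tis_shares.round(1).to_csv(out / "tissue_shares.tsv", sep="\t",
                                       header=["share_pct"])
        except ValueError:
            expression = {}

    # --- figures ---------------------------------------------------------
    if config.make_plots:
        from . import plotting
        superfams_of = {e.element_id: superfams.get(e.element_id, "RXX-NA")
                        for e in elements}
        hists, edges, _ = dating.divergence_profile(estimates, superfams_of)
        if hists:
            plotting.plot_divergence_profile(hists, edges,
                                             out / "divergence_profile.png")
        if densities:
            plotting.plot_density_tracks(densities,
                                         out / "density_tracks.png")
        if config.run_expression and truth is not None and expression:
            norm = pd.read_csv(out / "normalized.tsv", sep="\t", index_col=0)
            plotting.plot_expression_heatmap(norm,
                                             out / "expression_heatmap.png")

    # --- summary ---------------------------------------------------------
    summary = summarize_collection(classified, families, copies,
                                   genome_bp=sum(lengths.values()))
    summary.table.to_csv(out / "summary.tsv", sep="\t", index=False)
    run_log = {
        "seed": config.seed,
        "n_elements": len(elements),
        "n_families": len(families),
        "n_complete_copies": sum(1 for h in copies if h.complete),
        "superfamily_shares_pct": summary.shares,
        "correlation_copia_genes": correlation,
        "mask_stats": mask_stats,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, default=str)

    return PipelineResult(config, genome, truth, elements, classified,
                          lineages, families, copies, densities, correlation,
                          estimates, mask_stats, census, summary, expression)


def _write_truth(out: Path, truth: SyntheticGenome) -> None:
    feats = []
    for e in truth.elements:
        feats.append((e.scaffold, "synthetic", "LTR_retrotransposon",
                      e.start, e.end, ".", "+",
                      {"ID": e.element_id, "superfamily": e.superfamily,
                       "lineage": e.lineage or "NA", "K": e.k,
                       "family": e.family_id, "tsd": e.tsd}))
        feats.append((e.scaffold, "synthetic", "long_terminal_repeat",
                      e.ltr5[0], e.ltr5[1], ".", "+",
                      {"Parent": e.element_id}))
        feats.append((e.scaffold, "synthetic", "long_terminal_repeat",
                      e.ltr3[0], e.ltr3[1], ".", "+",
                      {"Parent": e.element_id}))
    io.write_gff3(out / "truth.gff3", feats)
    io.write_bed(out / "genes.bed", truth.genes)
    rows = [{"element": e.element_id, "scaffold": e.scaffold,
             "start": e.start, "end": e.end, "superfamily": e.superfamily,
             "lineage": e.lineage or "", "K": e.k, "family": e.family_id}
            for e in truth.elements]
    pd.DataFrame(rows).to_csv(out / "truth.tsv", sep="\t", index=False)


def _write_elements_gff3(path: Path, elements: list) -> None:
    feats = []
    for e in elements:
        attrs = {"ID": e.element_id, "ltr_identity": round(e.identity, 4)}
        if e.tsd:
            attrs["tsd"] = e.tsd
        if e.pbs:
            attrs["pbs"] = f"{e.pbs.trna_id}:{e.pbs.match_length}"
        if e.ppt:
            attrs["ppt"] = f"{e.ppt.purine_fraction:.2f}"
        feats.append((e.scaffold, "palm_ltr", "LTR_retrotransposon",
                      e.start, e.end, e.identity, "+", attrs))
        feats.append((e.scaffold, "palm_ltr", "long_terminal_repeat",
                      e.ltr5[0], e.ltr5[1], ".", "+", {"Parent": e.element_id}))
        feats.append((e.scaffold, "palm_ltr", "long_terminal_repeat",
                      e.ltr3[0], e.ltr3[1], ".", "+", {"Parent": e.element_id}))
    io.write_gff3(path, feats)


def _write_classification(out: Path, classified: list, census: dict) -> None:
    rows = []
    hit_rows = []
    for ce in classified:
        rows.append({"element": ce.element_id, "superfamily": ce.superfamily,
                     "lineage": ce.lineage or "", "n_domains": ce.n_domains,
                     "orientation": ce.orientation})
        for kind, h in sorted(ce.census.items()):
            hit_rows.append({"element": ce.element_id, "kind": kind,
                             "frame": h.frame, "start": h.start, "end": h.end,
                             "score": h.score, "e_value": f"{h.e_value:.2e}",
                             "ref": h.ref_id})
    pd.DataFrame(rows).to_csv(out / "classification.tsv", sep="\t", index=False)
    pd.DataFrame(hit_rows).to_csv(out / "domain_hits.tsv", sep="\t", index=False)
    with open(out / "domain_census.json", "w") as fh:
        json.dump(census, fh, indent=2, default=str)
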