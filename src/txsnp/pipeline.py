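"""End-to-end orchestration: filter -> select -> assign -> classify ->
NTU -> statistics, with TSV outputs and a machine-readable manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import io as tio
from .effects import (
    ClassificationResult,
    classify_all,
    strain_specific,
    strain_specific_percentages,
    summarize_effects,
)
from .filtering import FilterCriteria, FilteredCallset, apply_quality_filters, unique_polymorphic_sites
from .models import CoverageTrack, GeneExpression, GeneModel, Genome
from .ntu import (
    NTURecord,
    WindowThresholds,
    bin_by_fpkm,
    classify_ntus,
    read_ntu_gtf,
    window_histogram,
)
from .selection import (
    SelectionCriteria,
    SNPGeneSet,
    assign_sites_to_genes,
    gene_coverage,
    select_snp_genes,
)
from . import stats as tstats

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run (defaults are the study's)."""

    strains: Tuple[str, ...]
    genome: str = "genome.fasta"
    annotation: str = "annotation.gtf"
    variants: str = "variants.vcf"
    depth_template: str = "depth_{strain}.tsv"
    fpkm: str = "fpkm.tsv"
    ntus: str = "ntus.gtf"
    ntu_fpkm: str = "ntu_fpkm.tsv"
    outdir: str = "txsnp_out"
    min_qual: float = 40.0
    min_qa: float = 40.0
    min_dp: int = 3
    min_ao: int = 2
    min_base_depth: int = 3
    min_coverage_fraction: float = 0.90
    min_fpkm: float = 15.0
    near_window: int = 1_000
    far_window: int = 10_000
    alpha: float = 0.01

    def __post_init__(self) -> None:
        if len(self.strains) < 2:
            raise ValueError("need at least 2 strains")

    def filter_criteria(self) -> FilterCriteria:
        return FilterCriteria(self.min_qual, self.min_qa, self.min_dp, self.min_ao)

    def selection_criteria(self) -> SelectionCriteria:
        return SelectionCriteria(
            self.min_coverage_fraction, self.min_base_depth, self.min_fpkm
        )

    def window_thresholds(self) -> WindowThresholds:
        return WindowThresholds(self.near_window, self.far_window)


@dataclass
class PipelineReport:
    """All stage outputs of one run, in memory."""

    callset: FilteredCallset
    unique_sites: Set[Tuple[str, int]]
    snp_gene_set: SNPGeneSet
    assignment: Dict[str, List[Tuple[str, int]]]
    classification: ClassificationResult
    effect_summary: pd.DataFrame
    strain_specific_pct: Dict[str, float]
    ntu_records: List[NTURecord]
    ntu_window_hist: pd.DataFrame
    ntu_fpkm_bins: pd.DataFrame
    density: pd.DataFrame
    strain_density: Dict[str, float]
    comparisons: List[tstats.StrainComparisonResult]
    gene_count_r2: float
    fpkm_association: Dict[str, Tuple[float, float]]
    zero_polymorphism: List[str]
    n_ref_mismatch: int = 0
    n_skipped_non_snv: int = 0


def run_stages(
    genome: Genome,
    genes: Sequence[GeneModel],
    sites,
    tracks: Mapping[str, CoverageTrack],
    expression: GeneExpression,
    ntus,
    ntu_fpkm: Mapping[str, Mapping[str, float]],
    config: PipelineConfig,
    n_skipped_non_snv: int = 0,
) -> PipelineReport:
    """Run the analysis on in-memory inputs (the composition the CLI and
    run_all wrap with file I/O)."""
    strains = list(config.strains)

    sites, n_mismatch, _ = tio.cross_check_ref(sites, genome)
    callset = apply_quality_filters(sites, config.filter_criteria(), strains)
    unique = unique_polymorphic_sites(callset)

    cov_records = [
        gene_coverage(tracks[s], g, config.min_base_depth)
        for g in genes
        for s in strains
    ]
    snp_set = select_snp_genes(
        cov_records, expression, strains, config.selection_criteria()
    )
    assignment = assign_sites_to_genes(unique, genes, snp_set.snp_genes)

    classification = classify_all(callset, genes, genome, snp_set.snp_genes)
    specific = strain_specific(callset)
    summary = summarize_effects(classification.records, callset, specific)
    spec_pct = strain_specific_percentages(summary)

    ntu_records = classify_ntus(
        ntus, genes, ntu_fpkm, config.window_thresholds()
    )
    hist = window_histogram(ntu_records)
    bins = bin_by_fpkm(ntu_records, strains)

    # densities over SNP-genes, per gene / supercontig / strain
    gene_lengths = {
        g.gene_id: g.exon_union_length
        for g in genes
        if g.gene_id in snp_set.snp_genes
    }
    loc_to_genes: Dict[Tuple[str, int], List[str]] = {}
    for gid, locs in assignment.items():
        for loc in locs:
            loc_to_genes.setdefault(loc, []).append(gid)
    per_strain_locs = {
        s: {loc for loc in callset.retained_locations(s) if loc in loc_to_genes}
        for s in strains
    }
    gene_density = tstats.ps_density(
        per_strain_locs, gene_lengths, loc_to_genes, scope="gene"
    )
    by_contig_len: Dict[str, int] = {}
    gene_contig = {g.gene_id: g.contig_id for g in genes}
    for gid, L in gene_lengths.items():
        by_contig_len[gene_contig[gid]] = by_contig_len.get(gene_contig[gid], 0) + L
    loc_to_contig = {
        loc: [loc[0]] if loc[0] in by_contig_len else []
        for loc in loc_to_genes
    }
    sc_density = tstats.ps_density(
        per_strain_locs, by_contig_len, loc_to_contig,
        strain_scope=False, scope="supercontig",
    )
    density_df = tstats.density_table(gene_density + sc_density)
    strain_density = {
        r.unit_id: r.ps_per_kb for r in gene_density if r.scope == "strain"
    }

    comparisons = []
    sc_map: Dict[str, Dict[str, float]] = {s: {} for s in strains}
    for r in sc_density:
        if r.scope == "supercontig":
            sc_map[r.strain][r.unit_id] = r.ps_per_kb
    for i, a in enumerate(strains):
        for b in strains[i + 1 :]:
            try:
                comparisons.append(
                    tstats.compare_density_distributions(
                        sc_map[a], sc_map[b], a, b, alpha=config.alpha
                    )
                )
            except ValueError as exc:
                log.warning("skipping %s vs %s: %s", a, b, exc)

    annotated_counts: Dict[str, int] = {}
    snp_counts: Dict[str, int] = {}
    for g in genes:
        annotated_counts[g.contig_id] = annotated_counts.get(g.contig_id, 0) + 1
        if g.gene_id in snp_set.snp_genes:
            snp_counts[g.contig_id] = snp_counts.get(g.contig_id, 0) + 1
    try:
        r2 = tstats.gene_count_correlation(annotated_counts, snp_counts)
    except ValueError:
        r2 = float("nan")

    fpkm_assoc: Dict[str, Tuple[float, float]] = {}
    for s in strains:
        dens = {
            r.unit_id: r.ps_per_kb
            for r in gene_density
            if r.scope == "gene" and r.strain == s
        }
        fp = {gid: expression.get(gid, s) for gid in gene_lengths}
        try:
            fpkm_assoc[s] = tstats.density_fpkm_association(dens, fp)
        except ValueError:
            fpkm_assoc[s] = (float("nan"), float("nan"))

    zero_genes = tstats.zero_polymorphism_genes(snp_set.snp_genes, assignment)

    return PipelineReport(
        callset=callset,
        unique_sites=unique,
        snp_gene_set=snp_set,
        assignment=assignment,
        classification=classification,
        effect_summary=summary,
        strain_specific_pct=spec_pct,
        ntu_records=ntu_records,
        ntu_window_hist=hist,
        ntu_fpkm_bins=bins,
        density=density_df,
        strain_density=strain_density,
        comparisons=comparisons,
        gene_count_r2=r2,
        fpkm_association=fpkm_assoc,
        zero_polymorphism=zero_genes,
        n_ref_mismatch=n_mismatch,
        n_skipped_non_snv=n_skipped_non_snv,
    )


def run_all(config: PipelineConfig, indir=".") -> PipelineReport:
    """Load all inputs from files, run the stages, write the report."""
    indir = Path(indir)

    def _p(name: str) -> Path:
        p = indir / name
        if not p.exists():
            raise FileNotFoundError(f"required input missing: {p}")
        return p

    strains = list(config.strains)
    genome = tio.read_genome(_p(config.genome))
    genes = tio.read_annotation(_p(config.annotation), genome)
    vres = tio.read_variants(_p(config.variants), strains)
    tracks = {
        s: tio.read_coverage(_p(config.depth_template.format(strain=s)), s, genome)
        for s in strains
    }
    expression = tio.read_expression(_p(config.fpkm), strains)
    ntus = read_ntu_gtf(_p(config.ntus))
    ntu_expr = tio.read_expression(_p(config.ntu_fpkm), strains)
    ntu_fpkm = {nid: {s: ntu_expr.get(nid, s) for s in strains} for nid, _, _ in ntus}

    report = run_stages(
        genome, genes, vres.sites, tracks, expression, ntus, ntu_fpkm,
        config, n_skipped_non_snv=vres.n_skipped_non_snv,
    )
    write_report(report, config)
    return report


def _provenance(config: PipelineConfig) -> str:
    cfg = asdict(config)
    keys = (
        "strains min_qual min_qa min_dp min_ao min_base_depth "
        "min_coverage_fraction min_fpkm near_window far_window alpha"
    ).split()
    analysis = {k: cfg[k] for k in keys}  # not paths: same analysis, same hash
    digest = hashlib.sha256(
        json.dumps(analysis, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    parts = " ".join(f"{k}={cfg[k]}" for k in keys[1:])
    return f"# txsnp config_hash={digest} {parts}\n"


def write_report(report: PipelineReport, config: PipelineConfig) -> Dict[str, Path]:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    paths: Dict[str, Path] = {}

    def _tsv(name: str, df: pd.DataFrame, index: bool = False) -> None:
        p = outdir / name
        with open(p, "w") as fh:
            fh.write(prov)
            df.to_csv(fh, sep="\t", index=index, float_format="%.6g")
        paths[name] = p

    strains = list(config.strains)
    _tsv(
        "filter_summary.tsv",
        pd.DataFrame(
            [
                {
                    "strain": s,
                    "n_input": report.callset.n_input[s],
                    "n_retained": report.callset.n_retained(s),
                    **{
                        f"removed_{reason}": n
                        for reason, n in sorted(report.callset.n_removed[s].items())
                    },
                }
                for s in strains
            ]
        ).fillna(0),
    )
    _tsv(
        "snp_genes.tsv",
        pd.DataFrame({"gene_id": sorted(report.snp_gene_set.snp_genes)}),
    )
    _tsv(
        "venn.tsv",
        pd.DataFrame(
            [
                {"strains": "&".join(k), "n_genes": v}
                for k, v in report.snp_gene_set.venn.items()
            ]
        ),
    )
    _tsv("effect_summary.tsv", report.effect_summary, index=True)
    _tsv(
        "effect_records.tsv",
        pd.DataFrame(
            [
                {
                    "contig": r.contig_id,
                    "pos": r.pos0 + 1,
                    "ref": r.ref_allele,
                    "alt": r.alt_allele,
                    "gene_id": r.gene_id,
                    "transcript_id": r.transcript_id,
                    "effect_class": r.effect_class.value,
                }
                for r in report.classification.records
            ]
        ),
    )
    _tsv("ntu_windows.tsv", report.ntu_window_hist, index=True)
    _tsv("ntu_fpkm_bins.tsv", report.ntu_fpkm_bins, index=True)
    _tsv(
        "ntu_records.tsv",
        pd.DataFrame(
            [
                {
                    "ntu_id": r.ntu_id,
                    "contig": r.contig_id,
                    "start": r.interval[0] + 1,
                    "end": r.interval[1],
                    "min_distance": r.min_distance,
                    "window": r.window.value,
                    "empty_supercontig": r.empty_supercontig,
                    "cumulative_bin": r.cumulative_bin.value,
                }
                for r in report.ntu_records
            ]
        ),
    )
    _tsv("density.tsv", report.density)
    _tsv(
        "comparisons.tsv",
        pd.DataFrame(
            [
                {
                    "strain_a": c.strain_a,
                    "strain_b": c.strain_b,
                    "test": c.test_name,
                    "statistic": c.statistic,
                    "p_value": c.p_value,
                    "n_pairs": c.n_pairs,
                    "significant": c.significant,
                    "alpha": c.alpha,
                }
                for c in report.comparisons
            ]
        ),
    )
    _tsv(
        "diagnostics.tsv",
        pd.DataFrame(
            [
                {
                    "metric": "gene_count_r2",
                    "strain": "",
                    "value": report.gene_count_r2,
                    "p_value": float("nan"),
                }
            ]
            + [
                {
                    "metric": "density_fpkm_spearman",
                    "strain": s,
                    "value": rho,
                    "p_value": p,
                }
                for s, (rho, p) in report.fpkm_association.items()
            ]
        ),
    )
    _tsv(
        "zero_polymorphism_genes.tsv",
        pd.DataFrame({"gene_id": report.zero_polymorphism}),
    )
    _tsv(
        "headline.tsv",
        pd.DataFrame(
            [
                {"quantity": "unique_polymorphic_sites", "value": len(report.unique_sites)},
                {"quantity": "snp_genes", "value": len(report.snp_gene_set.snp_genes)},
                *(
                    {"quantity": f"retained_sites_{s}", "value": report.callset.n_retained(s)}
                    for s in strains
                ),
                *(
                    {"quantity": f"ps_per_kb_{s}",
                     "value": round(report.strain_density.get(s, float("nan")), 6)}
                    for s in strains
                ),
                *(
                    {"quantity": f"strain_specific_pct_{s}",
                     "value": round(report.strain_specific_pct[s], 6)}
                    for s in strains
                ),
            ]
        ),
    )

    manifest = {
        "outputs": {
            name: hashlib.sha256(p.read_bytes()).hexdigest() for name, p in paths.items()
        },
        "stages_completed": [
            "filter", "select", "assign", "classify", "ntu", "stats",
        ],
    }
    with open(outdir / "MANIFEST.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths
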