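"""End-to-end convenience: counts -> filters -> peaks -> calls -> GWAS.

Chains the module-level operations in the canonical order used for one
cell type: qualify SNPs, clean the peak set, restrict SNPs to open
chromatin, run the binomial/BH ASoC caller, annotate TSS distance, and
intersect the calls with GWAS loci and enhancer-gene links.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .context import annotate_tss_distance, clean_peaks, snps_in_peaks
from .core import call_asoc, reference_bias_qc
from .counts_io import FilterParams, FilterReport, apply_qualification_filters
from .gwas import ColocReport, assign_target_genes, colocalize, expand_ld_proxies

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """All intermediate and final tables of one cell-type analysis."""

    filter_report: FilterReport
    results: pd.DataFrame  # per-SNP test results (open-chromatin SNPs)
    asoc: pd.DataFrame  # the is_asoc subset
    tss_annotation: pd.DataFrame | None
    coloc: ColocReport | None
    target_genes: pd.DataFrame | None
    qc: object


def run_pipeline(
    counts: pd.DataFrame,
    peaks: pd.DataFrame | None = None,
    blacklist: pd.DataFrame | None = None,
    tss: pd.DataFrame | None = None,
    gwas: pd.DataFrame | None = None,
    ld: pd.DataFrame | None = None,
    abc: pd.DataFrame | None = None,
    filter_params: FilterParams | None = None,
    fdr_threshold: float = 0.05,
    r2_threshold: float = 0.8,
) -> PipelineResult:
    """Run the full ASoC analysis for one cell type.

    Only the count table is mandatory; each optional input enables the
    corresponding downstream step.  The BH adjustment is computed over
    the qualified SNPs that lie in cleaned open-chromatin peaks —
    exactly the set being tested.  Colocalization and target-gene
    assignment use the ASoC calls (``is_asoc`` true).
    """
    qualified, report = apply_qualification_filters(counts, filter_params)
    if peaks is not None:
        cleaned = clean_peaks(peaks, blacklist)
        tested = snps_in_peaks(qualified, cleaned)
    else:
        tested = qualified
    results = call_asoc(tested, fdr_threshold)
    asoc = results[results["is_asoc"]].reset_index(drop=True)
    qc = reference_bias_qc(results) if len(results) else None

    tss_annotation = annotate_tss_distance(asoc, tss) if tss is not None and len(asoc) else None
    coloc = None
    if gwas is not None and ld is not None:
        loci = expand_ld_proxies(gwas, ld, r2_threshold)
        coloc = colocalize(asoc["snp_id"], loci)
    target_genes = assign_target_genes(asoc, abc) if abc is not None else None
    return PipelineResult(
        filter_report=report,
        results=results,
        asoc=asoc,
        tss_annotation=tss_annotation,
        coloc=coloc,
        target_genes=target_genes,
        qc=qc,
    )
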