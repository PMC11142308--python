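"""GWAS colocalization, LD-proxy expansion, target genes, enrichment.

A GWAS risk locus is taken as one row of an index-SNP table; its proxy
set is the index SNP itself plus every SNP whose linkage-disequilibrium
r-squared with the index reaches the threshold (inclusive, default
r2 >= 0.8).  A locus is "hit" by the ASoC map when at least one member
of its proxy set is an ASoC SNP.  Target genes are assigned by a
point-in-interval join of SNP positions against ABC-style
enhancer-gene links.  ``set_enrichment`` is deliberately plain set
arithmetic — a fold ratio with a Fisher exact or permutation p-value —
for transparent sanity checks of annotation overlap.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import fisher_exact

from .core import bh_adjust
from .errors import SchemaError
from .utils import normalize_chrom

__all__ = [
    "GwasLocus",
    "ColocReport",
    "EnrichmentResult",
    "read_gwas",
    "read_ld",
    "read_abc",
    "expand_ld_proxies",
    "colocalize",
    "assign_target_genes",
    "set_enrichment",
    "adjust_enrichment_pvalues",
]


@dataclass
class GwasLocus:
    """One GWAS risk locus: index SNP plus its LD-proxy set."""

    locus_id: str
    index_snp_id: str
    chrom: str
    pos: int
    gwas_p: float
    proxy_set: dict[str, float] = field(default_factory=dict)  # snp_id -> r2

    def __post_init__(self) -> None:
        self.proxy_set.setdefault(self.index_snp_id, 1.0)


@dataclass
class ColocReport:
    """Colocalization of an ASoC SNP set with GWAS risk loci.

    ``fraction_loci_hit`` is None (not 0) when there are no loci.
    ``per_locus`` maps each hit locus to the ASoC SNP ids in its proxy
    set; an ASoC SNP proxying several loci appears under each of them.
    """

    n_loci_total: int
    n_loci_with_asoc: int
    per_locus: dict[str, list[str]]
    fraction_loci_hit: float | None

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_loci_total": self.n_loci_total,
                "n_loci_with_asoc": self.n_loci_with_asoc,
                "fraction_loci_hit": self.fraction_loci_hit,
                "per_locus": self.per_locus,
            },
            indent=2,
        )


def read_gwas(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ("locus_id", "index_snp_id", "chrom", "pos", "p_value") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing GWAS column(s) {missing}")
    return df


def read_ld(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ("snp_a", "snp_b", "r2") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing LD column(s) {missing}")
    return df


def read_abc(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ("chrom", "start", "end", "target_gene", "abc_score") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing ABC column(s) {missing}")
    return df


def expand_ld_proxies(
    index_snps: pd.DataFrame, ld_table: pd.DataFrame, r2_threshold: float = 0.8
) -> list[GwasLocus]:
    """Expand each GWAS index SNP into its LD-proxy set.

    The LD table is symmetrized on load, so pairs may be given in
    either orientation.  The proxy set is ``{index} ∪ {s : r2(index, s)
    >= r2_threshold}`` (inclusive).  An index SNP absent from the LD
    table keeps a singleton proxy set and triggers a warning.
    """
    if not 0.0 <= r2_threshold <= 1.0:
        raise ValueError("r2_threshold must lie in [0, 1]")
    if np.any((ld_table["r2"] < 0) | (ld_table["r2"] > 1)):
        raise ValueError("LD r2 values must lie in [0, 1]")
    # symmetrize: best r2 per unordered pair, indexable from either end
    pairs: dict[str, dict[str, float]] = {}
    for a, b, r2 in zip(ld_table["snp_a"], ld_table["snp_b"], ld_table["r2"]):
        r2 = float(r2)
        for x, y in ((str(a), str(b)), (str(b), str(a))):
            d = pairs.setdefault(x, {})
            if r2 > d.get(y, -1.0):
                d[y] = r2
    loci = []
    for row in index_snps.itertuples(index=False):
        idx = str(row.index_snp_id)
        neighbours = pairs.get(idx)
        if neighbours is None:
            warnings.warn(f"index SNP {idx} absent from the LD table; proxy set is itself only")
            neighbours = {}
        proxy = {s: r2 for s, r2 in neighbours.items() if r2 >= r2_threshold and s != idx}
        proxy[idx] = 1.0
        loci.append(
            GwasLocus(
                locus_id=str(row.locus_id),
                index_snp_id=idx,
                chrom=str(row.chrom),
                pos=int(row.pos),
                gwas_p=float(row.p_value),
                proxy_set=proxy,
            )
        )
    return loci


def colocalize(asoc_snp_ids: Iterable[str], loci: Sequence[GwasLocus]) -> ColocReport:
    """Intersect an ASoC SNP id set with GWAS locus proxy sets.

    The caller chooses (and should log) which set is passed — typically
    the SNPs called ASoC within open chromatin.  Results are invariant
    to the input order of loci and of SNP ids.
    """
    asoc = set(map(str, asoc_snp_ids))
    per_locus: dict[str, list[str]] = {}
    for locus in loci:
        hits = sorted(asoc.intersection(locus.proxy_set))
        if hits:
            per_locus[locus.locus_id] = hits
    n = len(loci)
    n_hit = len(per_locus)
    return ColocReport(
        n_loci_total=n,
        n_loci_with_asoc=n_hit,
        per_locus=per_locus,
        fraction_loci_hit=(n_hit / n) if n > 0 else None,
    )


def assign_target_genes(snps: pd.DataFrame, abc: pd.DataFrame) -> pd.DataFrame:
    """Assign target genes to SNPs inside linked enhancers.

    A SNP (1-based position) is assigned gene G iff it lies inside an
    enhancer (half-open interval) linked to G; one output row per
    (SNP, link), so a SNP in an enhancer linked to several genes yields
    several rows and a SNP outside all enhancers yields none.

    Returns columns snp_id, target_gene, abc_score.
    """
    if len(snps) == 0 or len(abc) == 0:
        return pd.DataFrame(columns=["snp_id", "target_gene", "abc_score"])
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in abc.groupby(abc["chrom"].map(normalize_chrom)):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), (g, float(sc)))
            for s, e, g, sc in zip(grp["start"], grp["end"], grp["target_gene"], grp["abc_score"])
        )
    rows = []
    for r in snps.itertuples(index=False):
        tree = trees.get(normalize_chrom(r.chrom))
        if tree is None:
            continue
        for iv in sorted(tree[int(r.pos) - 1], key=lambda iv: (iv.begin, iv.end, iv.data)):
            rows.append((r.snp_id, iv.data[0], iv.data[1]))
    return pd.DataFrame(rows, columns=["snp_id", "target_gene", "abc_score"])


@dataclass
class EnrichmentResult:
    """Fold enrichment of an annotation within a SNP set, with p-value."""

    fold: float
    p_value: float
    method: str
    n_overlap: int
    n_set: int
    n_annotation: int
    n_universe: int


def set_enrichment(
    asoc_set: Iterable[str],
    annotation_set: Iterable[str],
    universe: Iterable[str],
    method: str = "fisher",
    n_perm: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Fold enrichment of ``annotation_set`` among ``asoc_set``.

    fold = (|A ∩ B| / |A|) / (|B| / |U|).  The p-value is one-sided for
    over-representation: Fisher's exact test on the 2x2 table, or a
    permutation test resampling |A|-sized sets from the universe with a
    fixed seed.  This is transparent plumbing for sanity checks, not a
    heritability- or LD-aware enrichment model.
    """
    U = set(map(str, universe))
    A = set(map(str, asoc_set))
    B = set(map(str, annotation_set))
    if not U:
        raise ValueError("universe must be non-empty")
    if not A:
        raise ValueError("asoc_set must be non-empty")
    if not A <= U or not B <= U:
        raise ValueError("asoc_set and annotation_set must be subsets of the universe")
    k = len(A & B)
    fold_denom = len(B) / len(U)
    fold = (k / len(A)) / fold_denom if fold_denom > 0 else float("nan")
    if method == "fisher":
        table = [[k, len(A) - k], [len(B) - k, len(U) - len(A) - len(B) + k]]
        _, p = fisher_exact(table, alternative="greater")
        p = float(p)
    elif method == "permutation":
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        # overlap of a uniformly resampled |A|-set with B is hypergeometric
        draws = rng.hypergeometric(len(B), len(U) - len(B), len(A), size=n_perm)
        p = float((1 + np.sum(draws >= k)) / (n_perm + 1))
    else:
        raise ValueError(f"unknown enrichment method {method!r}")
    return EnrichmentResult(
        fold=float(fold),
        p_value=p,
        method=method,
        n_overlap=k,
        n_set=len(A),
        n_annotation=len(B),
        n_universe=len(U),
    )


def adjust_enrichment_pvalues(results: Sequence[EnrichmentResult]) -> np.ndarray:
    """BH-adjust the p-values of several enrichment tests."""
    return bh_adjust([r.p_value for r in results])
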