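"""Open-chromatin context: peak cleaning, SNP restriction, TSS distance.

Intervals are half-open, zero-based ``[start, end)`` BED conventions;
SNP positions are 1-based, so a SNP at position ``p`` lies inside a peak
``[s, e)`` iff ``s <= p - 1 < e``.

Peak cleaning mirrors standard ATAC-seq post-processing: peaks that
overlap a blacklisted region by at least one base are dropped whole
(never trimmed, keeping peak identity stable), and peaks on the sex
chromosomes, the mitochondrial genome and decoy contigs are removed.

TSS annotation is a strand-agnostic point distance to the nearest
transcription start site on the same chromosome, binned into
``promoter_proximal`` (<= 5 kb), ``intermediate``, and ``distal``
(> 50 kb); both cutoffs are configurable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ParseError, SchemaError
from .utils import CANONICAL, normalize_chrom

__all__ = [
    "read_bed",
    "write_bed",
    "read_tss",
    "write_tss",
    "clean_peaks",
    "snps_in_peaks",
    "annotate_tss_distance",
]

BED_COLUMNS = ["chrom", "start", "end", "name"]
TSS_COLUMNS = ["chrom", "tss_pos", "gene", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3+ / narrowPeak; keeps chrom, start, end, name.

    Extra columns (score, signal, summit offset...) are ignored.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("BED line needs >= 3 fields", path, lineno)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError("non-integer BED coordinates", path, lineno) from None
            if start < 0 or start >= end:
                raise ParseError(f"invalid interval [{start}, {end})", path, lineno)
            name = parts[3] if len(parts) > 3 else f"interval{lineno}"
            rows.append((parts[0], start, end, name))
    df = pd.DataFrame(rows, columns=BED_COLUMNS)
    if len(df) == 0:
        return df.astype({"start": np.int64, "end": np.int64})
    return df.astype({"start": np.int64, "end": np.int64})


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_tss(path: str | Path) -> pd.DataFrame:
    """Read a TSS table (TSV: chrom, tss_pos 1-based, gene, strand)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ("chrom", "tss_pos", "gene") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing TSS column(s) {missing}")
    if "strand" not in df.columns:
        df["strand"] = "+"
    return df.astype({"tss_pos": np.int64})


def write_tss(df: pd.DataFrame, path: str | Path) -> None:
    df[TSS_COLUMNS].to_csv(path, sep="\t", index=False)


def _build_trees(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in intervals.groupby(intervals["chrom"].map(normalize_chrom)):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(grp["start"], grp["end"])
        )
    return trees


def clean_peaks(
    peaks: pd.DataFrame,
    blacklist: pd.DataFrame | None = None,
    excluded_chroms: frozenset[str] | set[str] = frozenset({"X", "Y", "MT"}),
    exclude_noncanonical: bool = True,
) -> pd.DataFrame:
    """Drop blacklisted and excluded-chromosome peaks.

    A peak overlapping any blacklist interval by >= 1 bp is removed
    entirely.  Output is sorted by (chrom, start).  Idempotent.
    """
    df = peaks.copy()
    excluded = {normalize_chrom(c) for c in excluded_chroms}
    norm = df["chrom"].map(normalize_chrom)
    keep = ~norm.isin(excluded)
    if exclude_noncanonical:
        keep &= norm.isin(CANONICAL)
    if blacklist is not None and len(blacklist):
        trees = _build_trees(blacklist)
        overlaps = np.array(
            [
                bool(trees.get(c, IntervalTree()).overlap(int(s), int(e)))
                for c, s, e in zip(norm, df["start"], df["end"])
            ]
        )
        keep &= ~overlaps
    out = df.loc[keep].sort_values(["chrom", "start"], kind="mergesort")
    return out.reset_index(drop=True)


def snps_in_peaks(snps: pd.DataFrame, peaks: pd.DataFrame) -> pd.DataFrame:
    """Restrict SNPs to those inside a peak; adds a ``peak_id`` column.

    SNP positions are 1-based, peaks half-open 0-based; a SNP at ``p``
    is inside ``[s, e)`` iff ``s <= p - 1 < e``.  When peaks are nested
    or duplicated, the first containing peak in (chrom, start, end)
    sort order is assigned.
    """
    if len(snps) == 0 or len(peaks) == 0:
        out = snps.iloc[0:0].copy()
        out["peak_id"] = pd.Series(dtype=object)
        return out
    pk = peaks.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    if "name" not in pk.columns:
        pk = pk.assign(name=[f"peak{i}" for i in range(len(pk))])
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in pk.groupby(pk["chrom"].map(normalize_chrom)):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), (int(s), int(e), nm))
            for s, e, nm in zip(grp["start"], grp["end"], grp["name"])
        )
    peak_ids = []
    hit_rows = []
    for i, (c, p) in enumerate(zip(snps["chrom"].map(normalize_chrom), snps["pos"])):
        tree = trees.get(c)
        if tree is None:
            continue
        hits = tree[int(p) - 1]
        if not hits:
            continue
        best = min(hits, key=lambda iv: (iv.data[0], iv.data[1], iv.data[2]))
        hit_rows.append(i)
        peak_ids.append(best.data[2])
    out = snps.iloc[hit_rows].copy()
    out["peak_id"] = peak_ids
    return out.reset_index(drop=True)


def annotate_tss_distance(
    snps: pd.DataFrame,
    tss: pd.DataFrame,
    promoter_cutoff: int = 5_000,
    distal_cutoff: int = 50_000,
) -> pd.DataFrame:
    """Annotate each SNP with its nearest TSS and a distance category.

    Distance is ``|snp_pos - tss_pos|`` to the nearest TSS on the same
    chromosome, strand-agnostic.  Categories: ``promoter_proximal``
    (distance <= promoter_cutoff, inclusive), ``distal`` (strictly >
    distal_cutoff), ``intermediate`` otherwise.  SNPs on chromosomes
    without any TSS are marked ``unannotated`` with missing gene and
    distance.
    """
    if promoter_cutoff < 0 or distal_cutoff < promoter_cutoff:
        raise ValueError("need 0 <= promoter_cutoff <= distal_cutoff")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in tss.groupby(tss["chrom"].map(normalize_chrom)):
        order = np.argsort(grp["tss_pos"].to_numpy(), kind="mergesort")
        by_chrom[chrom] = (
            grp["tss_pos"].to_numpy()[order],
            grp["gene"].to_numpy()[order],
        )
    genes: list[object] = []
    dists: list[float] = []
    cats: list[str] = []
    for c, p in zip(snps["chrom"].map(normalize_chrom), snps["pos"]):
        entry = by_chrom.get(c)
        if entry is None:
            genes.append(None)
            dists.append(np.nan)
            cats.append("unannotated")
            continue
        positions, names = entry
        j = int(np.searchsorted(positions, p))
        cand = [k for k in (j - 1, j) if 0 <= k < len(positions)]
        best = min(cand, key=lambda k: (abs(int(positions[k]) - int(p)), k))
        d = abs(int(positions[best]) - int(p))
        genes.append(names[best])
        dists.append(float(d))
        if d <= promoter_cutoff:
            cats.append("promoter_proximal")
        elif d > distal_cutoff:
            cats.append("distal")
        else:
            cats.append("intermediate")
    return pd.DataFrame(
        {
            "snp_id": snps["snp_id"].to_numpy(),
            "nearest_gene": genes,
            "distance_bp": dists,
            "category": cats,
        }
    )
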