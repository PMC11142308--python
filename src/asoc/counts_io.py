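"""Reading, writing and qualifying heterozygous-SNP allelic count tables.

Counts arrive either as a tab-separated table (columns chrom, pos,
snp_id, ref, alt, ref_count, alt_count, genotype, optionally in_dbsnp)
or as a minimal single-sample VCF whose FORMAT carries GT and AD; the
reference and alternative read counts are taken from the two AD fields.
Positions are 1-based throughout.

Qualification follows the standard ASoC protocol: keep biallelic
heterozygous sites (GT 0/1) on autosomes, with a dbSNP record, total
depth (DP = ref_count + alt_count) >= 20 and both allele counts >= 2.
DP is deliberately the sum of the two allelic counts, not the aligner's
total over all bases, because the binomial test consumes exactly these
two counts.  Each rejected SNP is charged to the FIRST failing rule in
the fixed order genotype -> chromosome -> dbSNP -> depth -> allele
count, which makes the :class:`FilterReport` deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError
from .utils import is_canonical_autosome, normalize_chrom

__all__ = [
    "read_counts",
    "write_counts",
    "write_vcf",
    "FilterParams",
    "FilterReport",
    "apply_qualification_filters",
    "COUNT_COLUMNS",
]

COUNT_COLUMNS = [
    "chrom",
    "pos",
    "snp_id",
    "ref",
    "alt",
    "ref_count",
    "alt_count",
    "genotype",
    "in_dbsnp",
]

_REQUIRED = COUNT_COLUMNS[:-1]  # in_dbsnp optional, defaults to True

#: rejection rules in charging order
FILTER_RULES = ("non_het", "excluded_chrom", "not_in_dbsnp", "low_depth", "low_allele_count")

_VALID_BASES = frozenset("ACGT")


def _detect_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in {"tsv", "vcf"}:
            raise ValueError(f"unknown counts format {fmt!r}")
        return fmt
    return "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv"


def read_counts(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read an allelic count table from TSV or minimal VCF.

    Raises :class:`~asoc.errors.ParseError` (with the line number) on a
    malformed row and :class:`~asoc.errors.SchemaError` when required
    columns are missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _detect_format(path, format) == "vcf":
        return _read_vcf(path)
    return _read_tsv(path)


def _read_tsv(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        lines = fh.read().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        if line and not line.startswith("#"):
            header_idx = i
            break
    if header_idx is None:
        raise SchemaError(f"{path}: empty file, no header")
    header = lines[header_idx].split("\t")
    missing = [c for c in _REQUIRED if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    col = {c: header.index(c) for c in header}
    rows = []
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ParseError(
                f"expected {len(header)} fields, got {len(parts)}", path, lineno
            )
        try:
            pos = int(parts[col["pos"]])
            ref_count = int(parts[col["ref_count"]])
            alt_count = int(parts[col["alt_count"]])
        except ValueError as exc:
            raise ParseError(f"non-integer count field ({exc})", path, lineno) from None
        if pos < 1 or ref_count < 0 or alt_count < 0:
            raise ParseError("pos must be >= 1 and counts >= 0", path, lineno)
        in_dbsnp = True
        if "in_dbsnp" in col:
            tok = parts[col["in_dbsnp"]].strip().lower()
            if tok not in {"true", "false", "1", "0"}:
                raise ParseError(f"bad in_dbsnp flag {tok!r}", path, lineno)
            in_dbsnp = tok in {"true", "1"}
        rows.append(
            (
                parts[col["chrom"]],
                pos,
                parts[col["snp_id"]],
                parts[col["ref"]].upper(),
                parts[col["alt"]].upper(),
                ref_count,
                alt_count,
                parts[col["genotype"]],
                in_dbsnp,
            )
        )
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    return df.astype({"pos": np.int64, "ref_count": np.int64, "alt_count": np.int64})


def _read_vcf(path: Path) -> pd.DataFrame:
    """Read a minimal single-sample VCF with GT and AD FORMAT fields."""
    from cyvcf2 import VCF

    rows = []
    vcf = VCF(str(path))
    try:
        if len(vcf.samples) != 1:
            raise SchemaError(f"{path}: expected a single-sample VCF, got {len(vcf.samples)}")
        for var in vcf:
            if len(var.ALT) != 1:
                continue  # counts are defined for biallelic records only
            ad = var.format("AD")
            if ad is None:
                raise SchemaError(f"{path}: VCF lacks the AD FORMAT field")
            gt = var.genotypes[0]
            genotype = f"{gt[0]}{'|' if gt[2] else '/'}{gt[1]}"
            rows.append(
                (
                    var.CHROM,
                    var.POS,
                    var.ID or f"{var.CHROM}:{var.POS}",
                    var.REF,
                    var.ALT[0],
                    int(ad[0][0]),
                    int(ad[0][1]),
                    genotype,
                    var.ID is not None and str(var.ID).startswith("rs"),
                )
            )
    finally:
        vcf.close()
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    if len(df) == 0:
        return df.astype(
            {"pos": np.int64, "ref_count": np.int64, "alt_count": np.int64, "in_dbsnp": bool}
        )
    return df.astype({"pos": np.int64, "ref_count": np.int64, "alt_count": np.int64})


def write_counts(
    df: pd.DataFrame, path: str | Path, header_comments: list[str] | None = None
) -> None:
    """Write a count table as TSV; optional ``#``-prefixed header lines."""
    out = df.copy()
    if "in_dbsnp" not in out.columns:
        out["in_dbsnp"] = True
    out = out[COUNT_COLUMNS]
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index=False)


def write_vcf(df: pd.DataFrame, path: str | Path, sample: str = "sample1") -> None:
    """Write counts as a minimal single-sample VCF with GT:AD:DP."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(df["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for r in df.itertuples(index=False):
            dp = int(r.ref_count) + int(r.alt_count)
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.snp_id}\t{r.ref}\t{r.alt}\t.\tPASS\t.\t"
                f"GT:AD:DP\t{r.genotype}:{r.ref_count},{r.alt_count}:{dp}\n"
            )


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the SNP qualification filters."""

    min_depth: int = 20
    min_allele_count: int = 2
    require_dbsnp: bool = True
    excluded_chromosomes: frozenset[str] = frozenset({"X", "Y", "MT"})
    exclude_noncanonical: bool = True  # decoy/unplaced contigs

    def validate(self) -> None:
        if self.min_depth < 0 or self.min_allele_count < 0:
            raise ValueError("filter thresholds must be non-negative")


@dataclass
class FilterReport:
    """Per-rule rejection accounting for one filtering pass.

    ``n_input == n_pass + sum(rejections.values())``: every SNP is
    charged to exactly one rule (the first failing one).
    """

    n_input: int
    n_pass: int
    rejections: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"n_input": self.n_input, "n_pass": self.n_pass, "rejections": self.rejections},
            indent=2,
        )

    def log_lines(self) -> list[str]:
        lines = [f"input SNPs: {self.n_input}", f"qualified SNPs: {self.n_pass}"]
        lines += [f"rejected ({rule}): {n}" for rule, n in self.rejections.items()]
        return lines


def apply_qualification_filters(
    counts: pd.DataFrame, params: FilterParams | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the SNP qualification filters; returns (retained, report).

    Rules, in charging order: heterozygous biallelic genotype (0/1),
    chromosome not excluded (sex chromosomes, mitochondrion, decoys),
    dbSNP membership, depth >= ``min_depth``, and both allele counts
    >= ``min_allele_count``.  Row order is preserved; the operation is
    idempotent.
    """
    if params is None:
        params = FilterParams()
    params.validate()
    df = counts.reset_index(drop=True)
    n = len(df)
    if n == 0:
        return df.copy(), FilterReport(0, 0, {r: 0 for r in FILTER_RULES})

    gt = df["genotype"].astype(str).str.replace("|", "/", regex=False)
    het = gt.isin(["0/1", "1/0"]).to_numpy()

    norm = df["chrom"].map(normalize_chrom)
    excluded = {normalize_chrom(c) for c in params.excluded_chromosomes}
    bad_chrom = norm.isin(excluded).to_numpy()
    if params.exclude_noncanonical:
        bad_chrom |= ~df["chrom"].map(is_canonical_autosome).to_numpy() & ~bad_chrom

    in_dbsnp = (
        df["in_dbsnp"].to_numpy(dtype=bool)
        if "in_dbsnp" in df.columns
        else np.ones(n, dtype=bool)
    )
    ref = df["ref_count"].to_numpy()
    alt = df["alt_count"].to_numpy()
    depth_ok = (ref + alt) >= params.min_depth
    allele_ok = np.minimum(ref, alt) >= params.min_allele_count

    fail = {
        "non_het": ~het,
        "excluded_chrom": bad_chrom,
        "not_in_dbsnp": ~in_dbsnp if params.require_dbsnp else np.zeros(n, dtype=bool),
        "low_depth": ~depth_ok,
        "low_allele_count": ~allele_ok,
    }
    charged = np.zeros(n, dtype=bool)
    rejections: dict[str, int] = {}
    for rule in FILTER_RULES:
        hit = fail[rule] & ~charged
        rejections[rule] = int(hit.sum())
        charged |= hit
    retained = df.loc[~charged].reset_index(drop=True)
    return retained, FilterReport(n, int((~charged).sum()), rejections)
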