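"""Synthetic allelic-count data with planted ground truth.

This module generates datasets with the statistical structure the ASoC
analysis assumes, so that the caller, filters and downstream integration
can be validated against known truth:

* heterozygous biallelic SNPs with total read depth drawn from a stated
  depth model (default: 20 + Poisson(40), so every SNP clears the
  default DP >= 20 qualification filter and filtering and power can be
  probed independently);
* a null allelic fraction of 0.5 with optional beta-binomial
  overdispersion ``rho`` (rho = 0 is a pure binomial);
* a planted fraction ``pi_asoc`` of true-ASoC SNPs whose alternative
  allele is sampled with fraction ``theta_asoc``;
* an optional multiplicative reference-mapping bias ``ref_bias``
  (effective alternative fraction theta' = theta / (theta + (1-theta) *
  ref_bias); ref_bias = 1 is unbiased);
* SNP placement inside/outside open-chromatin peaks, GWAS loci with LD
  proxies, and enhancer-gene (ABC-style) link tables, each with planted
  coincidences for end-to-end recovery tests.

Beta-binomial draws use the mean/overdispersion parameterization with
shape parameters a = theta*(1-rho)/rho and b = (1-theta)*(1-rho)/rho,
the standard allele-specific-expression noise model: one interpretable
knob, with the binomial recovered as rho -> 0.

All randomness flows through a single seeded :class:`numpy.random.Generator`,
so identical (config, seed) pairs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import binomial_two_sided_p
from .errors import ConfigError, GenerationError

__all__ = [
    "DepthModel",
    "SimConfig",
    "simulate_allelic_counts",
    "simulate_genome_annotation",
    "simulate_gwas_and_ld",
    "simulate_abc_links",
    "simulate_study",
    "StudyData",
]

_BASES = np.array(list("ACGT"))

DEFAULT_CHROM_LENGTHS = {"chr1": 10_000_000, "chr2": 8_000_000}


@dataclass(frozen=True)
class DepthModel:
    """Total read depth distribution at a SNP.

    ``shifted_poisson`` draws ``shift + Poisson(mean - shift)``;
    ``fixed`` returns ``depth`` everywhere.  Depths are clamped to >= 1.
    """

    family: str = "shifted_poisson"
    shift: int = 20
    mean: float = 60.0
    depth: int = 20

    def validate(self) -> None:
        if self.family == "shifted_poisson":
            if self.shift < 0 or self.mean <= self.shift:
                raise ConfigError(
                    "shifted_poisson needs shift >= 0 and mean > shift "
                    f"(got shift={self.shift}, mean={self.mean})"
                )
        elif self.family == "fixed":
            if self.depth < 1:
                raise ConfigError("fixed depth must be >= 1")
        else:
            raise ConfigError(f"unknown depth model family {self.family!r}")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        self.validate()
        if self.family == "fixed":
            d = np.full(n, self.depth, dtype=np.int64)
        else:
            d = self.shift + rng.poisson(self.mean - self.shift, size=n)
        return np.maximum(d, 1)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated allelic-count dataset.

    Parameters
    ----------
    n_snps : number of heterozygous SNPs.
    depth : total-depth model (default 20 + Poisson(40), mean 60).
    pi_asoc : fraction of true-ASoC SNPs, in [0, 1].
    theta_asoc : alternative-allele fraction of ASoC SNPs; a scalar in
        (0, 1] \\ {0.5}, or a (low, high) interval sampled uniformly.
    rho : beta-binomial overdispersion in [0, 1); 0 is pure binomial.
    ref_bias : multiplicative capture bias toward the reference allele
        (> 0; 1 = unbiased).
    frac_in_peaks : fraction of SNPs placed inside peaks when a peak set
        is supplied to :func:`simulate_allelic_counts`.
    frac_dbsnp : fraction of SNPs flagged as known dbSNP records.
    chrom_lengths : chromosome name -> length in bp.
    seed : RNG seed; the same (config, seed) is byte-reproducible.
    """

    n_snps: int = 10_000
    depth: DepthModel = field(default_factory=DepthModel)
    pi_asoc: float = 0.0
    theta_asoc: float | tuple[float, float] = 0.75
    rho: float = 0.0
    ref_bias: float = 1.0
    frac_in_peaks: float = 1.0
    frac_dbsnp: float = 1.0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 0:
            raise ConfigError("n_snps must be >= 0")
        self.depth.validate()
        if not 0.0 <= self.pi_asoc <= 1.0:
            raise ConfigError("pi_asoc must lie in [0, 1]")
        if not 0.0 <= self.rho < 1.0:
            raise ConfigError("rho must lie in [0, 1)")
        if self.ref_bias <= 0:
            raise ConfigError("ref_bias must be > 0")
        if not 0.0 <= self.frac_in_peaks <= 1.0:
            raise ConfigError("frac_in_peaks must lie in [0, 1]")
        if not 0.0 <= self.frac_dbsnp <= 1.0:
            raise ConfigError("frac_dbsnp must lie in [0, 1]")
        lo, hi = self._theta_bounds()
        if not (0.0 < lo <= hi <= 1.0) or (lo == hi == 0.5):
            raise ConfigError("theta_asoc must lie in (0, 1] and differ from 0.5")
        if not self.chrom_lengths:
            raise ConfigError("chrom_lengths must be non-empty")

    def _theta_bounds(self) -> tuple[float, float]:
        if isinstance(self.theta_asoc, (tuple, list)):
            lo, hi = float(self.theta_asoc[0]), float(self.theta_asoc[1])
            return (lo, hi)
        t = float(self.theta_asoc)
        return (t, t)

    def draw_theta(self, rng: np.random.Generator, n: int) -> np.ndarray:
        lo, hi = self._theta_bounds()
        if lo == hi:
            return np.full(n, lo)
        return rng.uniform(lo, hi, size=n)


def _effective_theta(theta: np.ndarray, ref_bias: float) -> np.ndarray:
    """Alternative fraction after multiplicative reference capture bias."""
    return theta / (theta + (1.0 - theta) * ref_bias)


def _beta_binomial(
    rng: np.random.Generator, n: np.ndarray, theta: np.ndarray, rho: float
) -> np.ndarray:
    """Draw alt counts ~ BetaBinomial(n, mean theta, overdispersion rho)."""
    if rho == 0.0:
        return rng.binomial(n, theta)
    a = theta * (1.0 - rho) / rho
    b = (1.0 - theta) * (1.0 - rho) / rho
    # degenerate means stay degenerate under any rho
    p = np.where(
        (theta <= 0.0) | (theta >= 1.0),
        theta,
        rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12)),
    )
    return rng.binomial(n, p)


def _draw_positions(
    rng: np.random.Generator,
    n: int,
    chrom_lengths: dict[str, int],
    peaks: pd.DataFrame | None,
    frac_in_peaks: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample n distinct (chrom, pos 1-based) sites plus in_peak flags."""
    chroms = np.array(list(chrom_lengths))
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    p_chrom = lengths / lengths.sum()

    if peaks is None or len(peaks) == 0:
        in_peak = np.zeros(n, dtype=bool)
        widths = starts = ends = pk_chroms = None
        by_chrom: dict[str, np.ndarray] = {}
    else:
        in_peak = rng.random(n) < frac_in_peaks
        widths = (peaks["end"] - peaks["start"]).to_numpy(dtype=float)
        starts = peaks["start"].to_numpy()
        ends = peaks["end"].to_numpy()
        pk_chroms = peaks["chrom"].to_numpy()
        by_chrom = {c: g[["start", "end"]].to_numpy() for c, g in peaks.groupby("chrom")}

    p_peak = widths / widths.sum() if widths is not None else None
    chrom_out = np.empty(n, dtype=object)
    pos_out = np.zeros(n, dtype=np.int64)
    taken: set[tuple[str, int]] = set()
    todo = np.arange(n)
    guard = 0
    while todo.size:
        guard += 1
        if guard > 1000:
            raise GenerationError("cannot place distinct SNP sites; region too dense")
        k = todo.size
        mask_in = in_peak[todo]
        cand_c = np.empty(k, dtype=object)
        cand_p = np.empty(k, dtype=np.int64)
        n_in = int(mask_in.sum())
        if n_in:
            j = rng.choice(len(p_peak), size=n_in, p=p_peak)
            cand_c[mask_in] = pk_chroms[j]
            cand_p[mask_in] = rng.integers(starts[j], ends[j]) + 1
        n_out = k - n_in
        if n_out:
            ci = rng.choice(len(chroms), size=n_out, p=p_chrom)
            cand_c[~mask_in] = chroms[ci]
            cand_p[~mask_in] = rng.integers(1, lengths[ci].astype(np.int64) + 1)
        for t, c, p in zip(todo, cand_c, cand_p):
            p = int(p)
            if not in_peak[t]:
                iv = by_chrom.get(c)
                if iv is not None and np.any((iv[:, 0] <= p - 1) & (p - 1 < iv[:, 1])):
                    continue  # landed inside a peak; retry next round
            if (c, p) in taken:
                continue  # distinct sites required
            taken.add((c, p))
            chrom_out[t] = c
            pos_out[t] = p
        todo = np.flatnonzero(pos_out == 0)
    return chrom_out, pos_out, in_peak


def simulate_allelic_counts(
    config: SimConfig, peaks: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-SNP allelic read counts plus a ground-truth table.

    Returns
    -------
    counts : DataFrame with columns chrom, pos (1-based), snp_id, ref,
        alt, ref_count, alt_count, genotype, in_dbsnp — all genotypes
        heterozygous (0/1).
    truth : DataFrame with columns snp_id, is_asoc, theta_true (the
        pre-bias alternative fraction used), in_peak, aligned row-by-row
        with ``counts``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_snps

    chrom, pos, in_peak = _draw_positions(
        rng, n, config.chrom_lengths, peaks, config.frac_in_peaks
    )
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4

    depth = config.depth.draw(rng, n)
    is_asoc = rng.random(n) < config.pi_asoc
    theta_true = np.full(n, 0.5)
    if is_asoc.any():
        theta_true[is_asoc] = config.draw_theta(rng, int(is_asoc.sum()))
    theta_eff = _effective_theta(theta_true, config.ref_bias)
    alt_count = _beta_binomial(rng, depth, theta_eff, config.rho)
    ref_count = depth - alt_count
    in_dbsnp = rng.random(n) < config.frac_dbsnp

    ids = np.array([f"snp{i:07d}" for i in range(n)])
    counts = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "snp_id": ids,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "ref_count": ref_count.astype(np.int64),
            "alt_count": alt_count.astype(np.int64),
            "genotype": "0/1",
            "in_dbsnp": in_dbsnp,
        }
    )
    truth = pd.DataFrame(
        {
            "snp_id": ids,
            "is_asoc": is_asoc,
            "theta_true": theta_true,
            "in_peak": in_peak,
        }
    )
    return counts, truth


def _allocate(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of `total` items by weight."""
    share = weights / weights.sum() * total
    base = np.floor(share).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(share - base), kind="mergesort")
    base[order[:rem]] += 1
    return base


def simulate_genome_annotation(
    chrom_lengths: dict[str, int] | None = None,
    n_peaks: int = 200,
    peak_width: int = 500,
    blacklist_frac: float = 0.0,
    n_genes: int = 50,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate non-overlapping peaks, a blacklist, and a TSS table.

    Peaks are disjoint half-open zero-based intervals of fixed width.
    ``blacklist_frac`` of the peaks (rounded) receive a planted
    blacklist interval strictly inside them, so the planted overlap
    count is exact.  TSS rows carry 1-based positions.

    Returns (peaks, blacklist, tss).
    """
    if chrom_lengths is None:
        chrom_lengths = dict(DEFAULT_CHROM_LENGTHS)
    if not 0.0 <= blacklist_frac <= 1.0:
        raise ConfigError("blacklist_frac must lie in [0, 1]")
    if n_peaks < 0 or peak_width < 2 or n_genes < 0:
        raise ConfigError("n_peaks, n_genes >= 0 and peak_width >= 2 required")
    if rng is None:
        rng = np.random.default_rng(seed)

    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    per_chrom = _allocate(n_peaks, lengths) if n_peaks else np.zeros(len(chroms), int)

    rows = []
    for c, L, k in zip(chroms, lengths.astype(int), per_chrom):
        if k == 0:
            continue
        free = L - k * peak_width
        if free < 0:
            raise GenerationError(
                f"{k} peaks of width {peak_width} do not fit on {c} (length {L})"
            )
        gaps = np.sort(rng.integers(0, free + 1, size=k))
        starts = gaps + np.arange(k) * peak_width
        for s in starts:
            rows.append((c, int(s), int(s + peak_width)))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    peaks = peaks.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    peaks["name"] = [f"peak{i:05d}" for i in range(len(peaks))]

    n_black = int(round(blacklist_frac * len(peaks)))
    bl_rows = []
    if n_black:
        chosen = np.sort(rng.choice(len(peaks), size=n_black, replace=False))
        for i in chosen:
            s, e = int(peaks.at[i, "start"]), int(peaks.at[i, "end"])
            w = e - s
            bl_rows.append((peaks.at[i, "chrom"], s + w // 4, s + w // 2))
    blacklist = pd.DataFrame(bl_rows, columns=["chrom", "start", "end"])
    blacklist["name"] = [f"blacklist{i:04d}" for i in range(len(blacklist))]

    per_chrom_g = _allocate(n_genes, lengths) if n_genes else np.zeros(len(chroms), int)
    g_rows = []
    gi = 0
    for c, L, k in zip(chroms, lengths.astype(int), per_chrom_g):
        for p in np.sort(rng.integers(1, L + 1, size=k)):
            g_rows.append((c, int(p), f"gene{gi:04d}", rng.choice(["+", "-"])))
            gi += 1
    tss = pd.DataFrame(g_rows, columns=["chrom", "tss_pos", "gene", "strand"])
    return peaks, blacklist, tss


def simulate_gwas_and_ld(
    n_loci: int,
    proxies_per_locus: int,
    r2_distribution: float | tuple[float, float] = (0.8, 1.0),
    seed: int = 0,
    chrom_lengths: dict[str, int] | None = None,
    planted_proxy_ids: Sequence[str] = (),
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a GWAS index-SNP table and an LD pair table.

    Each locus gets one index SNP and ``proxies_per_locus`` proxies with
    r-squared drawn from ``r2_distribution`` (a constant or a uniform
    (low, high) interval).  The first ``len(planted_proxy_ids)`` loci
    each have one proxy id replaced by the given id, planting a known
    coincidence with simulated ASoC SNPs for end-to-end recovery tests.

    Returns (gwas table: locus_id, index_snp_id, chrom, pos, p_value;
    LD table: snp_a, snp_b, r2).
    """
    if n_loci < 0 or proxies_per_locus < 0:
        raise ConfigError("n_loci and proxies_per_locus must be >= 0")
    if len(planted_proxy_ids) > n_loci:
        raise ConfigError("more planted proxy ids than loci")
    if len(planted_proxy_ids) > 0 and proxies_per_locus < 1:
        raise ConfigError("planting requires proxies_per_locus >= 1")
    if chrom_lengths is None:
        chrom_lengths = dict(DEFAULT_CHROM_LENGTHS)
    if rng is None:
        rng = np.random.default_rng(seed)

    def draw_r2(m: int) -> np.ndarray:
        if isinstance(r2_distribution, (int, float)):
            v = float(r2_distribution)
            if not 0.0 <= v <= 1.0:
                raise ConfigError("r2 must lie in [0, 1]")
            return np.full(m, v)
        lo, hi = map(float, r2_distribution)
        if not 0.0 <= lo <= hi <= 1.0:
            raise ConfigError("r2 interval must lie in [0, 1]")
        return rng.uniform(lo, hi, size=m)

    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    g_rows, ld_rows = [], []
    for li in range(n_loci):
        ci = rng.choice(len(chroms), p=lengths / lengths.sum())
        pos = int(rng.integers(1, int(lengths[ci]) + 1))
        index_id = f"locus{li:03d}_index"
        gwas_p = float(10.0 ** -rng.uniform(8.0, 30.0))
        g_rows.append((f"locus{li:03d}", index_id, chroms[ci], pos, gwas_p))
        r2 = draw_r2(proxies_per_locus)
        for pj in range(proxies_per_locus):
            if pj == 0 and li < len(planted_proxy_ids):
                proxy_id = planted_proxy_ids[li]
            else:
                proxy_id = f"locus{li:03d}_proxy{pj}"
            ld_rows.append((index_id, proxy_id, float(r2[pj])))
    gwas = pd.DataFrame(
        g_rows, columns=["locus_id", "index_snp_id", "chrom", "pos", "p_value"]
    )
    ld = pd.DataFrame(ld_rows, columns=["snp_a", "snp_b", "r2"])
    return gwas, ld


def simulate_abc_links(
    planted_snps: pd.DataFrame,
    n_background: int = 20,
    enhancer_width: int = 500,
    chrom_lengths: dict[str, int] | None = None,
    avoid: pd.DataFrame | None = None,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate an ABC-style enhancer-gene link table.

    Every row of ``planted_snps`` (columns chrom, pos, snp_id, and
    optionally target_gene) gets one enhancer containing its position,
    linked to a gene — the planted SNP-to-gene assignments.  All
    enhancers, planted and background, are placed so that they contain
    no position from ``avoid`` other than their own planted SNP (pass
    the full SNP table to make the planted assignments the only ones).

    Returns a table with columns chrom, start, end, target_gene,
    abc_score.
    """
    if chrom_lengths is None:
        chrom_lengths = dict(DEFAULT_CHROM_LENGTHS)
    if rng is None:
        rng = np.random.default_rng(seed)
    avoid_by_chrom: dict[str, np.ndarray] = {}
    if avoid is not None and len(avoid):
        avoid_by_chrom = {
            c: np.sort(g["pos"].to_numpy(dtype=np.int64) - 1)
            for c, g in avoid.groupby("chrom")
        }
    rows = []
    for i, r in enumerate(planted_snps.itertuples(index=False)):
        p0 = int(r.pos) - 1  # 0-based position of the SNP
        # clip the enhancer between the neighbouring avoided positions so
        # it contains the planted SNP and nothing else from `avoid`
        pts = avoid_by_chrom.get(r.chrom, np.empty(0, dtype=np.int64))
        others = pts[pts != p0]
        left = int(others[others < p0].max()) if np.any(others < p0) else -1
        right = int(others[others > p0].min()) if np.any(others > p0) else np.iinfo(np.int64).max
        lo = max(0, p0 - enhancer_width + 1, left + 1)
        start = int(rng.integers(lo, p0 + 1))
        end = int(min(start + enhancer_width, right))
        gene = getattr(r, "target_gene", None) or f"targetgene{i:03d}"
        rows.append((r.chrom, start, end, gene,
                     float(np.round(rng.uniform(0.02, 0.5), 4))))
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    placed, guard = 0, 0
    while placed < n_background:
        guard += 1
        if guard > 100 * max(1, n_background):
            raise GenerationError("cannot place background enhancers clear of SNPs")
        ci = rng.choice(len(chroms), p=lengths / lengths.sum())
        start = int(rng.integers(0, int(lengths[ci]) - enhancer_width))
        pts = avoid_by_chrom.get(chroms[ci])
        if pts is not None and np.any((start <= pts) & (pts < start + enhancer_width)):
            continue
        rows.append((chroms[ci], start, start + enhancer_width,
                     f"bggene{placed:03d}", float(np.round(rng.uniform(0.02, 0.5), 4))))
        placed += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "target_gene", "abc_score"])


@dataclass
class StudyData:
    """One fully seeded synthetic study: inputs plus planted truth."""

    counts: pd.DataFrame
    truth: pd.DataFrame
    peaks: pd.DataFrame
    blacklist: pd.DataFrame
    tss: pd.DataFrame
    gwas: pd.DataFrame
    ld: pd.DataFrame
    abc: pd.DataFrame
    planted_locus_ids: list[str]
    planted_assignments: pd.DataFrame  # snp_id, target_gene


def simulate_study(
    config: SimConfig,
    n_peaks: int = 400,
    peak_width: int = 500,
    blacklist_frac: float = 0.05,
    n_genes: int = 100,
    n_loci: int = 12,
    proxies_per_locus: int = 5,
    n_planted_loci: int = 3,
    n_planted_abc: int = 5,
    n_background_enhancers: int = 20,
) -> StudyData:
    """Generate a complete synthetic study with planted coincidences.

    GWAS proxies and ABC enhancers are planted on simulated SNPs whose
    emitted counts carry allelic imbalance strong enough that the
    binomial/BH caller is guaranteed to flag them at FDR 0.05
    (two-sided p <= 0.05 / n_snps, a Bonferroni-level bar that implies a
    BH discovery), so end-to-end recovery of the planted loci and
    SNP-to-gene assignments is exact and deterministic for a given seed.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7_919]))
    peaks, blacklist, tss = simulate_genome_annotation(
        config.chrom_lengths, n_peaks, peak_width, blacklist_frac, n_genes, rng=rng
    )
    counts, truth = simulate_allelic_counts(config, peaks=peaks)

    # SNPs whose observed counts both survive the default qualification
    # filters and guarantee an ASoC call at FDR 0.05 (Bonferroni bound)
    ref = counts["ref_count"].to_numpy()
    alt = counts["alt_count"].to_numpy()
    p = binomial_two_sided_p(ref, alt)
    callable_mask = (
        (p * len(counts) < 0.05)
        & (ref + alt >= 20)
        & (np.minimum(ref, alt) >= 2)
        & truth["is_asoc"].to_numpy()
        & truth["in_peak"].to_numpy()
        & counts["in_dbsnp"].to_numpy()
    )
    # exclude SNPs sitting in peaks that blacklist-cleaning will remove
    if len(blacklist):
        bad = peaks.merge(blacklist, on="chrom", suffixes=("", "_bl"))
        bad = bad[(bad["start"] < bad["end_bl"]) & (bad["start_bl"] < bad["end"])]
        pos0 = counts["pos"].to_numpy() - 1
        chrom_arr = counts["chrom"].to_numpy()
        in_removed = np.zeros(len(counts), dtype=bool)
        for bp in bad.itertuples(index=False):
            in_removed |= (chrom_arr == bp.chrom) & (bp.start <= pos0) & (pos0 < bp.end)
        callable_mask &= ~in_removed
    need = n_planted_loci + n_planted_abc
    pool = counts.loc[callable_mask, ["chrom", "pos", "snp_id"]].reset_index(drop=True)
    if len(pool) < need:
        raise GenerationError(
            f"only {len(pool)} strongly imbalanced ASoC SNPs available; "
            f"{need} needed for planting — increase n_snps or pi_asoc"
        )
    picked = pool.iloc[rng.choice(len(pool), size=need, replace=False)]
    proxy_snps = picked.iloc[:n_planted_loci]
    abc_snps = picked.iloc[n_planted_loci:].reset_index(drop=True)

    gwas, ld = simulate_gwas_and_ld(
        n_loci,
        proxies_per_locus,
        (0.8, 1.0),
        chrom_lengths=config.chrom_lengths,
        planted_proxy_ids=list(proxy_snps["snp_id"]),
        rng=rng,
    )
    abc = simulate_abc_links(
        abc_snps,
        n_background=n_background_enhancers,
        chrom_lengths=config.chrom_lengths,
        avoid=counts[["chrom", "pos"]],
        rng=rng,
    )
    planted_assignments = pd.DataFrame(
        {
            "snp_id": abc_snps["snp_id"].to_numpy(),
            "target_gene": [f"targetgene{i:03d}" for i in range(len(abc_snps))],
        }
    )
    return StudyData(
        counts=counts,
        truth=truth,
        peaks=peaks,
        blacklist=blacklist,
        tss=tss,
        gwas=gwas,
        ld=ld,
        abc=abc,
        planted_locus_ids=list(gwas["locus_id"].iloc[: len(proxy_snps)]),
        planted_assignments=planted_assignments,
    )
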