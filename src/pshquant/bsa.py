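"""Bulk-segregant analysis with the smoothed-G statistic.

Two pools of phenotypically extreme segregants are sequenced; at every SNP
the allele-by-bulk read-count table is scored with the likelihood-ratio
G statistic, G values are smoothed along each chromosome with a tricube
kernel (G'), a log-normal null is fitted robustly to the genome-wide G'
distribution, and Benjamini-Hochberg-adjusted significant regions are
reported as peaks.

The module also ships a forward simulator of an F5 mapping population with
planted QTL, producing allele-depth tables of the same shape the real
pipeline consumes from a VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: canonical column order of a SNP allele-depth table
SNP_COLUMNS = ["chrom", "pos", "ref_high", "alt_high", "ref_low", "alt_low", "qual"]


@dataclass
class GScanParams:
    """Tuning knobs of the smoothed-G scan.

    window
        Full width of the tricube smoothing window in bp; SNPs within
        ``window / 2`` of the focal SNP contribute to its G'.
    fdr_q
        Benjamini-Hochberg q-value threshold for calling a SNP significant.
    filter_min_depth / filter_max_depth
        Per-bulk read-depth bounds applied before the scan.
    filter_min_quality
        Minimum site quality.
    outlier_cutoff_mads
        Hampel multiplier: ln G' values above median + k*MAD are treated as
        putative QTL and excluded before the null is refitted.
    """

    window: int = 60_000
    fdr_q: float = 0.01
    filter_min_depth: int = 10
    filter_max_depth: int = 220
    filter_min_quality: float = 20.0
    outlier_cutoff_mads: float = 5.2

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not 0.0 < self.fdr_q < 1.0:
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.filter_min_depth > self.filter_max_depth:
            raise ValueError("filter_min_depth exceeds filter_max_depth")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_snp_table(path, fmt: str = "auto", high_sample: str | None = None,
                   low_sample: str | None = None) -> pd.DataFrame:
    """Read a two-bulk SNP allele-depth table from VCF or TSV.

    Only biallelic SNPs are kept; multiallelic sites and indels are skipped
    with a counted log message.  Rows are returned sorted by (chrom, pos).
    """
    path = str(path)
    if fmt == "auto":
        fmt = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#")
        missing = [c for c in SNP_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"TSV is missing columns {missing}")
        df = df[SNP_COLUMNS]
    elif fmt == "vcf":
        df = _read_vcf(path, high_sample, low_sample)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if (df["pos"] < 1).any():
        raise ValueError("positions must be 1-based (>= 1)")
    return df


def _read_vcf(path: str, high_sample: str | None, low_sample: str | None) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    if len(samples) < 2:
        raise ValueError(f"VCF must carry two bulk samples, found {samples}")
    high = high_sample or samples[0]
    low = low_sample or samples[1]
    for name in (high, low):
        if name not in samples:
            raise ValueError(f"sample {name!r} not in VCF (has {samples})")
    ih, il = samples.index(high), samples.index(low)

    rows = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        ad = var.format("AD")
        if ad is None:
            raise ValueError(
                f"record {var.CHROM}:{var.POS} lacks the per-sample AD field")
        rows.append((var.CHROM, var.POS,
                     int(ad[ih][0]), int(ad[ih][1]),
                     int(ad[il][0]), int(ad[il][1]),
                     float(var.QUAL if var.QUAL is not None else 0.0)))
    if n_skipped:
        logger.info("skipped %d multiallelic/indel records", n_skipped)
    return pd.DataFrame(rows, columns=SNP_COLUMNS)


def write_snp_table(df: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    """Write a SNP table as TSV, optionally with ``#``-prefixed header lines."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_vcf(df: pd.DataFrame, path, genome: list[tuple[str, int]] | None = None,
              high_name: str = "HIGH", low_name: str = "LOW") -> None:
    """Write a two-bulk allele-depth table as a minimal uncompressed VCF.

    Alleles are written as placeholder A/T bases: the scan only consumes the
    per-sample allele depths (AD), never the base identities.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pshquant\n")
        if genome:
            for chrom, length in genome:
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        else:
            for chrom in pd.unique(df["chrom"]):
                sub = df[df["chrom"] == chrom]
                fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths for the ref and alt alleles">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{high_name}\t{low_name}\n")
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{int(row.pos)}\t.\tA\tT\t{row.qual:g}\t.\t.\t"
                     f"GT:AD\t./.:{int(row.ref_high)},{int(row.alt_high)}\t"
                     f"./.:{int(row.ref_low)},{int(row.alt_low)}\n")


# ---------------------------------------------------------------------------
# per-SNP statistics
# ---------------------------------------------------------------------------

def filter_snps(df: pd.DataFrame, params: GScanParams) -> pd.DataFrame:
    """Quality/coverage filter: keep sites with quality >= min and both bulk
    depths inside [min_depth, max_depth].  Removal counts are logged."""
    depth_high = df["ref_high"] + df["alt_high"]
    depth_low = df["ref_low"] + df["alt_low"]
    ok_qual = df["qual"] >= params.filter_min_quality
    ok_depth = (
        (depth_high >= params.filter_min_depth)
        & (depth_high <= params.filter_max_depth)
        & (depth_low >= params.filter_min_depth)
        & (depth_low <= params.filter_max_depth)
    )
    n_qual = int((~ok_qual).sum())
    n_depth = int((ok_qual & ~ok_depth).sum())
    if n_qual or n_depth:
        logger.info("filtered %d SNPs on quality, %d on depth", n_qual, n_depth)
    out = df[ok_qual & ok_depth].reset_index(drop=True)
    if out.empty:
        logger.warning("all SNPs removed by filtering")
    return out


def g_statistic(ref_high, alt_high, ref_low, alt_low):
    """Likelihood-ratio G on the 2x2 allele-by-bulk read-count table.

    G = 2 * sum_ij n_ij * ln(n_ij / nhat_ij) with expected counts
    nhat_ij = (row total * column total) / grand total and 0*ln 0 = 0.
    Accepts scalars or arrays; returns the same shape.
    """
    n = np.stack([np.asarray(x, dtype=float) for x in
                  (ref_high, alt_high, ref_low, alt_low)], axis=-1)
    if np.any(n < 0):
        raise ValueError("negative read counts")
    total = n.sum(axis=-1)
    if np.any(total <= 0):
        raise ValueError("all-zero count table")
    row_high = n[..., 0] + n[..., 1]
    row_low = n[..., 2] + n[..., 3]
    col_ref = n[..., 0] + n[..., 2]
    col_alt = n[..., 1] + n[..., 3]
    expected = np.stack([row_high * col_ref, row_high * col_alt,
                         row_low * col_ref, row_low * col_alt],
                        axis=-1) / total[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > 0, n * np.log(n / expected), 0.0)
    g = 2.0 * terms.sum(axis=-1)
    g = np.maximum(g, 0.0)  # clip -0.0 / rounding slop at independence
    return float(g) if g.ndim == 0 else g


def delta_snp_index(ref_high, alt_high, ref_low, alt_low):
    """Alt-allele frequency difference, high bulk minus low bulk, in [-1, 1].

    A bulk with zero depth yields a missing value (NaN).
    """
    rh, ah = np.asarray(ref_high, float), np.asarray(alt_high, float)
    rl, al = np.asarray(ref_low, float), np.asarray(alt_low, float)
    dh, dl = rh + ah, rl + al
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where((dh > 0) & (dl > 0), ah / dh - al / dl, np.nan)
    return float(delta) if delta.ndim == 0 else delta


def smooth_g(chrom, pos, g, window: int) -> np.ndarray:
    """Tricube-smoothed G' per SNP.

    For the focal SNP at p0, neighbours on the same chromosome with
    |p - p0| <= window/2 receive weight (1 - (|p - p0| / (window/2))^3)^3,
    normalised to sum to one; windows truncate at chromosome ends.
    Input must be position-sorted within each chromosome.
    """
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=np.int64)
    g = np.asarray(g, dtype=float)
    half = window / 2.0
    out = np.empty_like(g)
    for c in pd.unique(chrom):
        idx = np.nonzero(chrom == c)[0]
        p = pos[idx]
        if np.any(np.diff(p) < 0):
            raise ValueError(f"positions unsorted on chromosome {c}")
        gv = g[idx]
        lo = np.searchsorted(p, p - half, side="left")
        hi = np.searchsorted(p, p + half, side="right")
        for j in range(len(idx)):
            d = np.abs(p[lo[j]:hi[j]] - p[j]) / half
            w = (1.0 - d ** 3) ** 3
            out[idx[j]] = np.dot(w, gv[lo[j]:hi[j]]) / w.sum()
    return out


def null_pvalues(g_prime, outlier_cutoff_mads: float = 5.2,
                 min_snps: int = 50) -> np.ndarray:
    """Upper-tail p-values from a robustly fitted log-normal null on G'.

    Fits median/MAD to y = ln G', discards y above median + k*MAD (putative
    QTL), refits on the remainder and returns Normal(m, MAD^2) upper-tail
    probabilities at each y.  MAD is scaled by 1.4826 for sd-consistency.
    """
    gp = np.asarray(g_prime, dtype=float)
    if gp.size < min_snps:
        raise ValueError(
            f"need at least {min_snps} SNPs to fit the null, got {gp.size}")
    positive = gp > 0
    y = np.where(positive, np.log(np.where(positive, gp, 1.0)), -np.inf)
    yf = y[positive]
    if yf.size < min_snps:
        raise ValueError("too few positive G' values to fit the null")

    def _fit(v):
        m = np.median(v)
        mad = 1.4826 * np.median(np.abs(v - m))
        return m, mad

    m, mad = _fit(yf)
    if mad > 0:
        keep = yf <= m + outlier_cutoff_mads * mad
        if keep.sum() >= min_snps:
            m, mad = _fit(yf[keep])
    if mad <= 0:
        raise ValueError("degenerate G' distribution (zero spread)")
    p = stats.norm.sf(y, loc=m, scale=mad)
    return np.clip(p, 1e-300, 1.0 - 1e-16)


def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_peaks(df: pd.DataFrame, params: GScanParams) -> pd.DataFrame:
    """Merge runs of significant SNPs (q <= fdr_q) into peaks.

    Within a chromosome, maximal consecutive runs of significant SNPs are
    found; runs whose gap is smaller than window/2 bp are merged.  Each peak
    reports its span, SNP count and the position of the maximum G'.
    """
    merge_gap = params.window / 2.0
    peaks = []
    for c, sub in df.groupby("chrom", sort=False):
        sub = sub.reset_index(drop=True)
        if np.any(np.diff(sub["pos"].to_numpy()) < 0):
            raise ValueError(f"positions unsorted on chromosome {c}")
        sig = np.nonzero((sub["q"] <= params.fdr_q).to_numpy())[0]
        if sig.size == 0:
            continue
        # maximal runs of consecutive significant SNP indices
        breaks = np.nonzero(np.diff(sig) > 1)[0]
        runs = np.split(sig, breaks + 1)
        spans = [(sub["pos"].iloc[r[0]], sub["pos"].iloc[r[-1]], r) for r in runs]
        merged = [spans[0]]
        for start, end, r in spans[1:]:
            pstart, pend, pr = merged[-1]
            if start - pend < merge_gap:
                merged[-1] = (pstart, end, np.concatenate([pr, r]))
            else:
                merged.append((start, end, r))
        for start, end, r in merged:
            gp = sub["G_prime"].iloc[r]
            imax = gp.idxmax()
            peaks.append({
                "chrom": c, "start": int(start), "end": int(end),
                "n_snps": int(len(r)),
                "max_gprime_pos": int(sub["pos"].loc[imax]),
                "max_gprime": float(gp.max()),
            })
    return pd.DataFrame(
        peaks, columns=["chrom", "start", "end", "n_snps",
                        "max_gprime_pos", "max_gprime"])


def write_peaks_bed(peaks: pd.DataFrame, path,
                    header_lines: list[str] | None = None) -> None:
    """Write peaks as BED (0-based half-open) with the max-G' score."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        for row in peaks.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t"
                     f"peak_{row.chrom}_{row.max_gprime_pos}\t"
                     f"{row.max_gprime:.4f}\n")


# ---------------------------------------------------------------------------
# model-style front end
# ---------------------------------------------------------------------------

class GPrimeScan:
    """Smoothed-G bulk-segregant scan over a two-bulk SNP table.

    Parameters
    ----------
    snps : pandas.DataFrame
        Allele-depth table with columns ``chrom, pos, ref_high, alt_high,
        ref_low, alt_low, qual`` (see :data:`SNP_COLUMNS`); one row per
        biallelic SNP.
    params : GScanParams, optional
        Window width, FDR threshold and filter settings.
    apply_filters : bool
        Whether to run the quality/coverage filter before scanning.

    Examples
    --------
    >>> result = GPrimeScan(snps, GScanParams(window=20_000)).fit()
    >>> result.peaks          # doctest: +SKIP
    """

    def __init__(self, snps: pd.DataFrame, params: GScanParams | None = None,
                 apply_filters: bool = True):
        missing = [c for c in SNP_COLUMNS if c not in snps.columns]
        if missing:
            raise ValueError(f"SNP table is missing columns {missing}")
        self.snps = snps.sort_values(["chrom", "pos"],
                                     kind="mergesort").reset_index(drop=True)
        self.params = params or GScanParams()
        self.apply_filters = apply_filters

    @classmethod
    def from_vcf(cls, path, params: GScanParams | None = None,
                 high_sample: str | None = None, low_sample: str | None = None,
                 **kwargs) -> "GPrimeScan":
        snps = read_snp_table(path, fmt="vcf", high_sample=high_sample,
                              low_sample=low_sample)
        return cls(snps, params, **kwargs)

    def fit(self) -> "GScanResult":
        df = self.snps
        n_input = len(df)
        if self.apply_filters:
            df = filter_snps(df, self.params)
        df = df.copy()
        df["G"] = g_statistic(df["ref_high"], df["alt_high"],
                              df["ref_low"], df["alt_low"])
        df["G_prime"] = smooth_g(df["chrom"].to_numpy(), df["pos"].to_numpy(),
                                 df["G"].to_numpy(), self.params.window)
        df["delta_snp"] = delta_snp_index(df["ref_high"], df["alt_high"],
                                          df["ref_low"], df["alt_low"])
        df["p"] = null_pvalues(df["G_prime"].to_numpy(),
                               self.params.outlier_cutoff_mads)
        df["q"] = fdr_adjust(df["p"].to_numpy())
        peaks = call_peaks(df, self.params)
        return GScanResult(df, peaks, self.params, n_input)


@dataclass
class GScanResult:
    """Fitted smoothed-G scan: per-SNP table, called peaks and settings."""

    snps: pd.DataFrame
    peaks: pd.DataFrame
    params: GScanParams
    n_input: int

    @property
    def n_significant(self) -> int:
        return int((self.snps["q"] <= self.params.fdr_q).sum())

    def summary(self) -> str:
        lines = [
            "Smoothed-G bulk segregant scan",
            "=" * 46,
            f"SNPs in input            {self.n_input:>10d}",
            f"SNPs after filtering     {len(self.snps):>10d}",
            f"window (bp)              {self.params.window:>10d}",
            f"FDR threshold            {self.params.fdr_q:>10.3g}",
            f"significant SNPs         {self.n_significant:>10d}",
            f"peaks called             {len(self.peaks):>10d}",
        ]
        if len(self.peaks):
            lines.append("-" * 46)
            lines.append("chrom      start        end   n_snps   maxG'@")
            for r in self.peaks.itertuples(index=False):
                lines.append(f"{r.chrom:<8} {r.start:>9d} {r.end:>10d} "
                             f"{r.n_snps:>8d} {r.max_gprime_pos:>8d}")
        return "\n".join(lines)

    def write(self, scan_path, peaks_path=None,
              header_lines: list[str] | None = None) -> None:
        write_snp_table(self.snps, scan_path, header_lines)
        if peaks_path is not None:
            write_peaks_bed(self.peaks, peaks_path, header_lines)


# ---------------------------------------------------------------------------
# F5 pool simulator
# ---------------------------------------------------------------------------

# 16 chromosomes at budding-yeast scale (~12 Mb total)
DEFAULT_GENOME: list[tuple[str, int]] = [
    (f"chr{i + 1:02d}", length * 1000) for i, length in enumerate(
        [230, 813, 317, 1532, 577, 270, 1091, 563,
         440, 746, 667, 1078, 924, 784, 1091, 948])
]


@dataclass
class PoolTruth:
    """Ground truth of one simulated pool-sequencing experiment."""

    qtls: list[dict]
    n_segregants: int
    k_per_pool: int
    mean_depth: float
    snp_spacing: int
    map_density: float
    map_expansion: float
    noise_sd: float
    seed: int
    high_pool_mean: float = 0.0
    low_pool_mean: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_pools(genome: list[tuple[str, int]] | None = None,
                   qtls: list[tuple[str, int, float]] | None = None,
                   n_segregants: int = 360, k_per_pool: int = 22,
                   mean_depth: float = 55.0, snp_spacing: int = 500,
                   map_density: float = 2_000.0, map_expansion: float = 2.0,
                   noise_sd: float = 1.0, site_quality: float = 60.0,
                   seed: int = 0) -> tuple[pd.DataFrame, PoolTruth]:
    """Simulate pooled sequencing of extreme F5 segregants with planted QTL.

    Each segregant's genotype along a chromosome is a two-state Markov chain
    over the SNP grid: the recombination fraction of an interval of ``d`` bp
    comes from the Haldane map function on ``d / map_density`` cM, with map
    distance multiplied by ``map_expansion`` to emulate the extra meioses of
    an F5 design.  Phenotype = sum of QTL effects carried + Normal(0,
    noise_sd^2); the top/bottom ``k_per_pool`` segregants by phenotype form
    the bulks.  Per SNP and bulk, depth ~ Poisson(mean_depth) and alt reads
    ~ Binomial(depth, pool alt-allele frequency); the alt allele is the one
    whose QTL effects raise the phenotype.

    Parameters are bp-scale throughout; ``map_density`` is bp per cM.
    Returns the SNP table (see :data:`SNP_COLUMNS`) and a :class:`PoolTruth`
    holding QTL positions and realised pool allele frequencies.
    """
    genome = genome if genome is not None else DEFAULT_GENOME
    qtls = qtls or []
    if 2 * k_per_pool > n_segregants:
        raise ValueError("2*k_per_pool exceeds n_segregants")
    chrom_names = [c for c, _ in genome]
    for chrom, qpos, _ in qtls:
        if chrom not in chrom_names:
            raise ValueError(f"QTL chromosome {chrom!r} not in genome")
        length = dict(genome)[chrom]
        if not 1 <= qpos <= length:
            raise ValueError(f"QTL position {qpos} outside {chrom} (1..{length})")

    rng = np.random.default_rng(seed)
    chroms, positions, genotypes = [], [], []
    for chrom, length in genome:
        pos = np.arange(snp_spacing, length + 1, snp_spacing, dtype=np.int64)
        if pos.size == 0:
            raise ValueError(f"chromosome {chrom} shorter than snp_spacing")
        d_morgan = np.diff(pos) / map_density * map_expansion / 100.0
        r = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))  # Haldane
        start = rng.integers(0, 2, size=n_segregants)
        switches = rng.random((n_segregants, r.size)) < r
        g = np.empty((n_segregants, pos.size), dtype=np.int8)
        g[:, 0] = start
        g[:, 1:] = (start[:, None] + np.cumsum(switches, axis=1)) % 2
        chroms.append(np.repeat(chrom, pos.size))
        positions.append(pos)
        genotypes.append(g)
    chrom_arr = np.concatenate(chroms)
    pos_arr = np.concatenate(positions)
    geno = np.concatenate(genotypes, axis=1)  # (n_segregants, n_snps)

    phenotype = rng.normal(0.0, noise_sd, size=n_segregants)
    truth_qtls = []
    for chrom, qpos, effect in qtls:
        on_chrom = np.nonzero(chrom_arr == chrom)[0]
        snp_idx = on_chrom[np.argmin(np.abs(pos_arr[on_chrom] - qpos))]
        phenotype += effect * geno[:, snp_idx]
        truth_qtls.append({"chrom": chrom, "pos": int(qpos), "effect": effect,
                           "snp_pos": int(pos_arr[snp_idx]),
                           "snp_index": int(snp_idx)})

    order = np.argsort(phenotype, kind="stable")
    low_ids = order[:k_per_pool]
    high_ids = order[-k_per_pool:]
    freq_high = geno[high_ids].mean(axis=0)
    freq_low = geno[low_ids].mean(axis=0)

    depth_high = rng.poisson(mean_depth, size=pos_arr.size)
    depth_low = rng.poisson(mean_depth, size=pos_arr.size)
    alt_high = rng.binomial(depth_high, freq_high)
    alt_low = rng.binomial(depth_low, freq_low)

    df = pd.DataFrame({
        "chrom": chrom_arr, "pos": pos_arr,
        "ref_high": depth_high - alt_high, "alt_high": alt_high,
        "ref_low": depth_low - alt_low, "alt_low": alt_low,
        "qual": np.full(pos_arr.size, float(site_quality)),
    })
    for q in truth_qtls:
        q["freq_high"] = float(freq_high[q["snp_index"]])
        q["freq_low"] = float(freq_low[q["snp_index"]])
    truth = PoolTruth(
        qtls=truth_qtls, n_segregants=n_segregants, k_per_pool=k_per_pool,
        mean_depth=mean_depth, snp_spacing=snp_spacing,
        map_density=map_density, map_expansion=map_expansion,
        noise_sd=noise_sd, seed=seed,
        high_pool_mean=float(phenotype[high_ids].mean()),
        low_pool_mean=float(phenotype[low_ids].mean()),
    )
    return df, truth
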