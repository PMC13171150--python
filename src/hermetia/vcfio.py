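"""VCF and population-map I/O, site/sample filtering, and LD pruning.

The central container is :class:`GenotypeMatrix`: an unphased diploid
dosage matrix (samples x sites, values 0/1/2 with -1 for missing) plus
per-site metadata (chrom, 1-based pos, ref, alt, QUAL) and, when the VCF
carries them, per-genotype read depth (DP) and allele depths (AD).

Filtering follows standard short-read SNP practice: genotypes with depth
outside the accepted range are set missing first, then site-level rules
(QUAL, missingness, optional MAF, biallelic-only) are applied. Defaults
are QUAL > 75, depth 10-34x, missingness <= 15%, MAF filter off (0.1 when
enabled).

LD pruning mirrors plink's ``--indep-pairwise 50 10 0.1``: greedy removal
of one SNP from every pair with genotypic r^2 above the threshold inside a
sliding 50-SNP window advanced by 10 SNPs.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

MISSING = -1

# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x sites dosage matrix with site metadata.

    Attributes
    ----------
    samples : list of sample IDs, order fixes the row order of ``dosage``.
    sites : DataFrame with columns chrom, pos (1-based), ref, alt, qual,
        strictly sorted by (chrom, pos).
    dosage : int8 array (n_samples, n_sites); 0/1/2 alt-allele dosage,
        -1 = missing.
    dp : optional int32 array (n_samples, n_sites), -1 = missing.
    ad : optional int32 array (n_samples, n_sites, 2) of (ref, alt) read
        counts, -1 = missing.
    """

    samples: List[str]
    sites: pd.DataFrame
    dosage: np.ndarray
    dp: Optional[np.ndarray] = None
    ad: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        self.sites = self.sites.reset_index(drop=True)
        self._check_sorted()

    def _check_sorted(self) -> None:
        chrom = self.sites["chrom"].to_numpy()
        pos = self.sites["pos"].to_numpy()
        for i in range(1, len(pos)):
            if chrom[i] == chrom[i - 1] and pos[i] <= pos[i - 1]:
                raise ValueError(
                    f"sites not strictly sorted: {chrom[i]}:{pos[i]} "
                    f"follows {chrom[i - 1]}:{pos[i - 1]}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def take_sites(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx].copy(),
            dp=None if self.dp is None else self.dp[:, idx].copy(),
            ad=None if self.ad is None else self.ad[:, idx].copy(),
        )

    def take_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        rows = [self.sample_index(s) for s in samples]
        return GenotypeMatrix(
            samples=list(samples),
            sites=self.sites.copy(),
            dosage=self.dosage[rows].copy(),
            dp=None if self.dp is None else self.dp[rows].copy(),
            ad=None if self.ad is None else self.ad[rows].copy(),
        )

    def alt_freq(self, rows: Optional[Sequence[int]] = None) -> np.ndarray:
        """Per-site alt allele frequency over non-missing genotypes of the
        given sample rows (all samples by default); NaN where no calls."""
        d = self.dosage if rows is None else self.dosage[np.asarray(rows)]
        called = d >= 0
        n_copies = 2 * called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_copies > 0, alt / np.maximum(n_copies, 1), np.nan)


@dataclass
class PopulationMap:
    """Sample -> (population, captivity status, lineage)."""

    population: Dict[str, str]
    status: Dict[str, str]
    lineage: Dict[str, str]

    def __post_init__(self) -> None:
        bad = {s for s, v in self.status.items() if v not in ("wild", "captive")}
        if bad:
            raise ValueError(f"status must be 'wild' or 'captive'; bad samples: {sorted(bad)}")

    @property
    def samples(self) -> List[str]:
        return list(self.population)

    def members(self, population: str) -> List[str]:
        out = [s for s, p in self.population.items() if p == population]
        if not out:
            raise KeyError(f"no samples in population {population!r}")
        return out

    def by_status(self, status: str) -> List[str]:
        return [s for s, v in self.status.items() if v == status]

    def by_lineage(self, lineage: str) -> List[str]:
        return [s for s, v in self.lineage.items() if v == lineage]

    def populations(self) -> List[str]:
        seen: List[str] = []
        for p in self.population.values():
            if p not in seen:
                seen.append(p)
        return seen

    def validate_against(self, gm: GenotypeMatrix) -> None:
        missing = [s for s in gm.samples if s not in self.population]
        if missing:
            raise ValueError(f"samples missing from population map: {missing}")


@dataclass
class FilterConfig:
    """Site/genotype filter thresholds (study defaults)."""

    min_qual: float = 75.0
    min_dp: int = 10
    max_dp: int = 34
    max_missing: float = 0.15
    maf: Optional[float] = None  # study used 0.1 for the RoH dataset
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must be in [0, 1]")
        if self.min_dp > self.max_dp:
            raise ValueError("min_dp must be <= max_dp")


# ---------------------------------------------------------------------------
# VCF and TSV I/O
# ---------------------------------------------------------------------------


def read_vcf(
    path: str,
    samples: Optional[Sequence[str]] = None,
    biallelic_only: bool = True,
) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix` via cyvcf2.

    Multiallelic records are dropped when ``biallelic_only`` (default) and
    rejected otherwise. Unsorted input raises, naming the first offending
    record; an unknown name in ``samples`` raises KeyError.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    all_samples = list(vcf.samples)
    if samples is not None:
        unknown = [s for s in samples if s not in all_samples]
        if unknown:
            raise KeyError(f"samples not in VCF: {unknown}")
        keep = [s for s in all_samples if s in set(samples)]
        vcf = VCF(path, gts012=True, samples=keep)
        all_samples = list(vcf.samples)

    chroms: List[str] = []
    poss: List[int] = []
    refs: List[str] = []
    alts: List[str] = []
    quals: List[float] = []
    dosage_rows: List[np.ndarray] = []
    dp_rows: List[np.ndarray] = []
    ad_rows: List[np.ndarray] = []
    have_dp = have_ad = True
    last: Optional[Tuple[str, int]] = None
    seen_chroms: set = set()

    for rec in vcf:
        if len(rec.ALT) != 1:
            if not biallelic_only:
                raise ValueError(
                    f"multiallelic record at {rec.CHROM}:{rec.POS} with biallelic_only off"
                )
            continue
        if last is not None:
            if rec.CHROM == last[0] and rec.POS <= last[1]:
                raise ValueError(
                    f"VCF not sorted: {rec.CHROM}:{rec.POS} follows {last[0]}:{last[1]}"
                )
            if rec.CHROM != last[0] and rec.CHROM in seen_chroms:
                raise ValueError(f"VCF not sorted: chromosome {rec.CHROM} appears twice")
        seen_chroms.add(rec.CHROM)
        last = (rec.CHROM, rec.POS)

        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        quals.append(np.nan if rec.QUAL is None else float(rec.QUAL))
        gt = rec.gt_types.astype(np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt[gt == 3] = MISSING
        dosage_rows.append(gt)

        if have_dp:
            try:
                dp = rec.format("DP")
            except KeyError:
                dp = None
            if dp is None:
                have_dp = False
            else:
                dp = dp.astype(np.int32).reshape(-1)
                dp[dp < 0] = MISSING
                dp_rows.append(dp)
        if have_ad:
            try:
                ad = rec.format("AD")
            except KeyError:
                ad = None
            if ad is None or ad.shape[1] < 2:
                have_ad = False
            else:
                ad = ad[:, :2].astype(np.int32)
                ad[ad < 0] = MISSING
                ad_rows.append(ad)

    sites = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts, "qual": quals}
    )
    n_sites = len(sites)
    dosage = (
        np.stack(dosage_rows, axis=1)
        if n_sites
        else np.zeros((len(all_samples), 0), dtype=np.int8)
    )
    dp = np.stack(dp_rows, axis=1) if (have_dp and dp_rows) else None
    ad = np.stack(ad_rows, axis=1) if (have_ad and ad_rows) else None
    return GenotypeMatrix(samples=all_samples, sites=sites, dosage=dosage, dp=dp, ad=ad)


def write_vcf(gm: GenotypeMatrix, path: str, contig_lengths: Optional[Dict[str, int]] = None) -> None:
    """Write a VCF 4.2 text file (FORMAT GT:DP:AD, or GT when depths absent).

    Output is deterministic: no timestamps, fixed field formatting.
    """
    gt_codes = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hermetia\n")
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        else:
            for chrom in dict.fromkeys(gm.sites["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        has_depth = gm.dp is not None and gm.ad is not None
        if has_depth:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        fmt = "GT:DP:AD" if has_depth else "GT"
        chrom_a = gm.sites["chrom"].to_numpy()
        pos_a = gm.sites["pos"].to_numpy()
        ref_a = gm.sites["ref"].to_numpy()
        alt_a = gm.sites["alt"].to_numpy()
        qual_a = gm.sites["qual"].to_numpy()
        for j in range(gm.n_sites):
            qual = "." if np.isnan(qual_a[j]) else f"{qual_a[j]:g}"
            fields = [
                str(chrom_a[j]), str(pos_a[j]), ".", str(ref_a[j]), str(alt_a[j]),
                qual, ".", ".", fmt,
            ]
            for i in range(gm.n_samples):
                gt = gt_codes[int(gm.dosage[i, j])]
                if has_depth:
                    dp = int(gm.dp[i, j])
                    adr, ada = int(gm.ad[i, j, 0]), int(gm.ad[i, j, 1])
                    dp_s = "." if dp < 0 else str(dp)
                    ad_s = ".,." if adr < 0 else f"{adr},{ada}"
                    fields.append(f"{gt}:{dp_s}:{ad_s}")
                else:
                    fields.append(gt)
            fh.write("\t".join(fields) + "\n")


def read_population_map(path: str) -> PopulationMap:
    """Read a 4-column TSV: sample, population, status, lineage (no header,
    or a header line starting with 'sample')."""
    pop: Dict[str, str] = {}
    status: Dict[str, str] = {}
    lineage: Dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if ln == 1 and parts[0].lower() == "sample":
                continue
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 tab-separated fields")
            s, p, st, li = parts
            pop[s], status[s], lineage[s] = p, st, li
    return PopulationMap(population=pop, status=status, lineage=lineage)


def write_population_map(pm: PopulationMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\tstatus\tlineage\n")
        for s in pm.samples:
            fh.write(f"{s}\t{pm.population[s]}\t{pm.status[s]}\t{pm.lineage[s]}\n")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    """Per-rule attrition counts from :func:`filter_sites`."""

    n_input: int = 0
    n_genotypes_depth_masked: int = 0
    n_removed_qual: int = 0
    n_removed_missingness: int = 0
    n_removed_maf: int = 0
    n_output: int = 0

    def as_dict(self) -> Dict[str, int]:
        return dataclasses.asdict(self)


def filter_sites(
    gm: GenotypeMatrix, cfg: FilterConfig = FilterConfig()
) -> Tuple[GenotypeMatrix, FilterReport]:
    """Apply genotype-depth masking, then site-level QUAL / missingness /
    MAF filters. Returns the filtered matrix and an attrition report.

    Masking happens before missingness is computed, so a site whose
    genotypes all fail the depth range is removed as fully missing (never
    a divide-by-zero in the MAF rule).
    """
    report = FilterReport(n_input=gm.n_sites)
    dosage = gm.dosage.copy()
    dp = None if gm.dp is None else gm.dp.copy()
    ad = None if gm.ad is None else gm.ad.copy()

    if dp is not None:
        bad = (dp >= 0) & ((dp < cfg.min_dp) | (dp > cfg.max_dp)) & (dosage >= 0)
        report.n_genotypes_depth_masked = int(bad.sum())
        dosage[bad] = MISSING

    called = dosage >= 0
    n_called = called.sum(axis=0)
    miss_frac = 1.0 - n_called / gm.n_samples

    qual = gm.sites["qual"].to_numpy()
    fail_qual = ~(qual > cfg.min_qual)  # NaN QUAL fails
    fail_miss = miss_frac > cfg.max_missing

    fail_maf = np.zeros(gm.n_sites, dtype=bool)
    if cfg.maf is not None:
        alt = np.where(called, dosage, 0).sum(axis=0)
        n_copies = 2 * n_called
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_copies > 0, alt / np.maximum(n_copies, 1), 0.0)
        maf = np.minimum(p, 1.0 - p)
        fail_maf = (maf < cfg.maf) & (n_copies > 0)

    # attrition accounting: each removed site counted under the first rule
    # (QUAL, then missingness, then MAF) that rejects it
    report.n_removed_qual = int(fail_qual.sum())
    report.n_removed_missingness = int((fail_miss & ~fail_qual).sum())
    report.n_removed_maf = int((fail_maf & ~fail_qual & ~fail_miss).sum())

    keep = ~(fail_qual | fail_miss | fail_maf)
    idx = np.flatnonzero(keep)
    report.n_output = len(idx)
    out = GenotypeMatrix(
        samples=list(gm.samples),
        sites=gm.sites.iloc[idx].reset_index(drop=True),
        dosage=dosage[:, idx],
        dp=None if dp is None else dp[:, idx],
        ad=None if ad is None else ad[:, idx],
    )
    return out, report


def allelic_balance_flags(
    gm: GenotypeMatrix, min_mean_balance: float = 0.25
) -> pd.DataFrame:
    """Mean minor-read fraction over heterozygous genotypes, per sample.

    Low mean balance at het calls is the classic signature of cross-sample
    contamination or severe reference bias. Samples below the threshold
    are flagged; samples with no het calls get balance NaN and flag 'NA'.
    Report only — nothing is removed.
    """
    if gm.ad is None:
        raise ValueError("AD field required for allelic balance")
    rows = []
    for i, sample in enumerate(gm.samples):
        het = gm.dosage[i] == 1
        ad = gm.ad[i][het]
        valid = (ad[:, 0] >= 0) & (ad[:, 1] >= 0) & (ad.sum(axis=1) > 0)
        ad = ad[valid]
        if len(ad) == 0:
            rows.append((sample, 0, np.nan, "NA"))
            continue
        balance = np.minimum(ad[:, 0], ad[:, 1]) / ad.sum(axis=1)
        mean_b = float(balance.mean())
        flag = "flagged" if mean_b < min_mean_balance else "ok"
        rows.append((sample, len(ad), mean_b, flag))
    return pd.DataFrame(rows, columns=["sample", "n_het", "mean_balance", "flag"])


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over jointly
    non-missing samples; 0.0 if either is monomorphic there (undefined)."""
    ok = (x >= 0) & (y >= 0)
    if ok.sum() < 2:
        return 0.0
    xs = x[ok].astype(float)
    ys = y[ok].astype(float)
    vx = xs.var()
    vy = ys.var()
    if vx == 0.0 or vy == 0.0:
        return 0.0
    cov = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return float(cov * cov / (vx * vy))


def ld_prune(
    gm: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 10,
    r2_max: float = 0.1,
) -> np.ndarray:
    """plink-style ``--indep-pairwise`` pruning; returns the sorted indices
    of retained sites.

    Within each window of ``window_snps`` consecutive input SNPs (advanced
    by ``step_snps``), every retained pair with r^2 > ``r2_max`` loses its
    later member (larger position) — a deterministic greedy sweep.
    Monomorphic SNPs have undefined r^2, treated as 0 (never pruned).
    """
    chrom = gm.sites["chrom"].to_numpy()
    retained = np.ones(gm.n_sites, dtype=bool)
    for c in dict.fromkeys(chrom):
        idx = np.flatnonzero(chrom == c)
        n = len(idx)
        start = 0
        while start < n:
            win = idx[start : start + window_snps]
            for a_i in range(len(win)):
                ia = win[a_i]
                if not retained[ia]:
                    continue
                for b_i in range(a_i + 1, len(win)):
                    ib = win[b_i]
                    if not retained[ib]:
                        continue
                    if genotype_r2(gm.dosage[:, ia], gm.dosage[:, ib]) > r2_max:
                        retained[ib] = False
            if start + window_snps >= n:
                break
            start += step_snps
    return np.flatnonzero(retained)


def region_to_bed(chrom: str, start_1based: int, end_1based: int) -> Tuple[str, int, int]:
    """1-based inclusive region (VCF/samtools style) -> 0-based half-open."""
    if start_1based < 1 or end_1based < start_1based:
        raise ValueError(f"bad region {chrom}:{start_1based}-{end_1based}")
    return chrom, start_1based - 1, end_1based


def bed_to_region(chrom: str, start: int, end: int) -> Tuple[str, int, int]:
    """0-based half-open interval -> 1-based inclusive region bounds."""
    if start < 0 or end <= start:
        raise ValueError(f"bad interval {chrom}:{start}-{end}")
    return chrom, start + 1, end


def write_filter_report(report: FilterReport, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("rule\tcount\n")
        for k, v in report.as_dict().items():
            fh.write(f"{k}\t{v}\n")
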