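"""Genotype containers, VCF/TSV I/O, QC filtering and LD pruning.

The central containers are :class:`GenotypeMatrix` (diploid alt-allele
dosages in {0,1,2} with explicit missingness) and :class:`HaplotypeMatrix`
(phased 0/1 alleles, two haplotypes per diploid sample).  Coordinates are
1-based inclusive throughout (VCF convention); BED output converts to
0-based half-open at the writer boundary only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1  # dosage sentinel; never encoded as 0

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


class VcfFormatError(ValueError):
    """Raised for malformed VCF input, carrying the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message}" + (f" (line {line})" if line else ""))


def _as_variant_table(variants: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table lacks columns {missing}")
    vt = variants.reset_index(drop=True)
    for chrom, grp in vt.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on {chrom}")
    return vt


@dataclass
class GenotypeMatrix:
    """Diploid alt-allele dosages, samples x variants, missing = -1."""

    dosage: np.ndarray                       # int8 (n_samples, n_variants)
    variants: pd.DataFrame                   # chrom, pos, id, ref, alt
    samples: pd.DataFrame                    # sample_id, population

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.variants = _as_variant_table(self.variants)
        self.samples = self.samples.reset_index(drop=True)
        n, m = self.dosage.shape
        if len(self.samples) != n or len(self.variants) != m:
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 (missing)")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    @property
    def is_missing(self) -> np.ndarray:
        return self.dosage == MISSING

    @property
    def populations(self) -> np.ndarray:
        return self.samples["population"].to_numpy()

    def take_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosage[:, idx],
            self.variants.iloc[idx].reset_index(drop=True),
            self.samples,
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosage[idx],
            self.variants,
            self.samples.iloc[idx].reset_index(drop=True),
        )

    def alt_freq(self) -> np.ndarray:
        """Per-variant alt-allele frequency over observed genotypes."""
        obs = self.dosage != MISSING
        n_alleles = 2 * obs.sum(axis=0)
        alt = np.where(obs, self.dosage, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / n_alleles, np.nan)


@dataclass
class HaplotypeMatrix:
    """Phased alleles in {0,1}, haplotypes x variants; 2 per diploid sample.

    Haplotype ``2*i`` and ``2*i + 1`` belong to sample ``i`` (stable order).
    Phased input is required, so there is no missingness.
    """

    alleles: np.ndarray                      # uint8 (n_haplotypes, n_variants)
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.variants = _as_variant_table(self.variants)
        self.samples = self.samples.reset_index(drop=True)
        if self.alleles.shape[0] != 2 * len(self.samples):
            raise ValueError("need exactly 2 haplotypes per sample")
        if self.alleles.shape[1] != len(self.variants):
            raise ValueError("allele matrix does not match variant table")
        if not np.isin(self.alleles, [0, 1]).all():
            raise ValueError("haplotype alleles must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return self.variants["pos"].to_numpy()

    @property
    def haplotype_populations(self) -> np.ndarray:
        return np.repeat(self.samples["population"].to_numpy(), 2)

    def to_genotypes(self) -> GenotypeMatrix:
        dos = (self.alleles[0::2].astype(np.int8) + self.alleles[1::2])
        return GenotypeMatrix(dos, self.variants, self.samples)

    def subset_population(self, population: str) -> "HaplotypeMatrix":
        keep = np.flatnonzero(self.samples["population"].to_numpy() == population)
        if keep.size == 0:
            raise ValueError(f"no samples with population label {population!r}")
        hap_idx = np.column_stack([2 * keep, 2 * keep + 1]).ravel()
        return HaplotypeMatrix(
            self.alleles[hap_idx],
            self.variants,
            self.samples.iloc[keep].reset_index(drop=True),
        )


@dataclass
class QcReport:
    """Per-rule removal counts for a QC pass; removed + retained = input."""

    n_samples_in: int
    n_variants_in: int
    samples_removed_missing: int
    variants_removed_missing: int
    variants_removed_maf: int
    variants_removed_hwe: int
    thresholds: dict = field(default_factory=dict)

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - self.samples_removed_missing

    @property
    def n_variants_out(self) -> int:
        return (self.n_variants_in - self.variants_removed_missing
                - self.variants_removed_maf - self.variants_removed_hwe)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("samples_in", self.n_samples_in),
            ("samples_removed_missingness", self.samples_removed_missing),
            ("samples_out", self.n_samples_out),
            ("variants_in", self.n_variants_in),
            ("variants_removed_missingness", self.variants_removed_missing),
            ("variants_removed_maf", self.variants_removed_maf),
            ("variants_removed_hwe", self.variants_removed_hwe),
            ("variants_out", self.n_variants_out),
        ]
        return pd.DataFrame(rows, columns=["rule", "count"])


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

def _validate_vcf_header(path: str | Path) -> None:
    """Cheap structural check so header errors carry a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 and not line.startswith("##fileformat="):
                raise VcfFormatError("first line must be ##fileformat=", lineno)
            if line.startswith("#CHROM"):
                cols = line.rstrip("\n").split("\t")
                if cols[:9] != ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL",
                                "FILTER", "INFO", "FORMAT"]:
                    raise VcfFormatError("malformed #CHROM header line", lineno)
                return
            if not line.startswith("##"):
                raise VcfFormatError("data line before #CHROM header", lineno)
    raise VcfFormatError("no #CHROM header line found", None)


def read_vcf(path, populations=None, multiallelic: str = "error",
             require_phased: bool = False):
    """Read a VCF into a :class:`GenotypeMatrix` (and haplotypes if phased).

    Parameters
    ----------
    path
        VCF file (v4.2 dialect, GT genotypes).
    populations
        Optional ``{sample_id: population}`` mapping or a TSV path with
        columns ``sample_id`` and ``population``; unlabelled samples get
        population ``"NA"``.
    multiallelic
        ``"error"`` rejects multi-allelic records, ``"drop"`` silently skips
        them.
    require_phased
        If True, an unphased genotype raises instead of returning
        ``haplotypes=None``.

    Returns
    -------
    (GenotypeMatrix, HaplotypeMatrix | None)
        Haplotypes are returned only when every genotype is phased and
        called.
    """
    from cyvcf2 import VCF

    _validate_vcf_header(path)
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)

    rows = []
    dosages = []
    haps = []
    all_phased = True
    for rec in vcf:
        if len(rec.ALT) != 1:
            if multiallelic == "drop":
                continue
            raise VcfFormatError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS}; "
                "pass multiallelic='drop' to skip"
            )
        rows.append((rec.CHROM, rec.POS, rec.ID or ".", rec.REF, rec.ALT[0]))
        gt = np.array(rec.genotypes, dtype=object)  # [allele0, allele1, phased]
        a0 = np.array([g[0] for g in gt], dtype=np.int16)
        a1 = np.array([g[1] for g in gt], dtype=np.int16)
        phased = np.array([bool(g[2]) for g in gt])
        miss = (a0 < 0) | (a1 < 0)
        dos = np.where(miss, MISSING, a0 + a1).astype(np.int8)
        dosages.append(dos)
        if miss.any() or not phased.all():
            all_phased = False
        haps.append(np.column_stack([a0, a1]))
    vcf.close()

    if not rows:
        raise VcfFormatError("VCF contains no usable biallelic records")
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosage = np.column_stack(dosages).astype(np.int8)
    dosage = dosage.reshape(len(sample_ids), len(rows))

    pops = _resolve_populations(sample_ids, populations)
    samples = pd.DataFrame({"sample_id": sample_ids, "population": pops})
    gm = GenotypeMatrix(dosage, variants, samples)

    if require_phased and not all_phased:
        raise VcfFormatError("haplotypes requested but VCF is not fully phased")
    hm = None
    if all_phased:
        allele_mat = np.empty((2 * len(sample_ids), len(rows)), dtype=np.uint8)
        for j, h in enumerate(haps):
            allele_mat[0::2, j] = h[:, 0]
            allele_mat[1::2, j] = h[:, 1]
        hm = HaplotypeMatrix(allele_mat, variants, samples)
    return gm, hm


def _resolve_populations(sample_ids, populations):
    if populations is None:
        return ["NA"] * len(sample_ids)
    if isinstance(populations, (str, Path)):
        df = pd.read_csv(populations, sep="\t", dtype=str)
        populations = dict(zip(df["sample_id"], df["population"]))
    return [populations.get(s, "NA") for s in sample_ids]


def write_vcf(path, gm: GenotypeMatrix, hm: HaplotypeMatrix | None = None) -> None:
    """Write a minimal VCF v4.2 with GT fields; phased "a|b" if ``hm`` given.

    The dialect is intentionally narrow (biallelic, GT only) so that
    ``write_vcf`` → ``read_vcf`` → ``write_vcf`` is byte-identical.
    """
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                  + "\t".join(gm.samples["sample_id"]) + "\n")
        var = gm.variants
        for j in range(gm.n_variants):
            fields = [str(var.at[j, "chrom"]), str(var.at[j, "pos"]),
                      str(var.at[j, "id"]), str(var.at[j, "ref"]),
                      str(var.at[j, "alt"]), ".", ".", ".", "GT"]
            if hm is not None:
                col = hm.alleles[:, j]
                gts = [f"{col[2 * i]}|{col[2 * i + 1]}"
                       for i in range(gm.n_samples)]
            else:
                lut = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
                gts = [lut[int(d)] for d in gm.dosage[:, j]]
            out.write("\t".join(fields + gts) + "\n")


def write_population_tsv(path, samples: pd.DataFrame) -> None:
    samples[["sample_id", "population"]].to_csv(path, sep="\t", index=False)


def write_bed(path, regions) -> None:
    """Write regions (1-based inclusive) as 0-based half-open BED lines."""
    with open(path, "w") as out:
        for r in regions:
            name = getattr(r, "label", None) or getattr(r, "name", ".") or "."
            out.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\n")


def read_bed(path) -> pd.DataFrame:
    """Read a BED file into 1-based inclusive intervals (chrom, start, end, name)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {lineno}: need >=3 columns")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"malformed BED line {lineno}: non-integer coordinates")
            if end0 <= start0:
                raise ValueError(f"malformed BED line {lineno}: end <= start")
            name = parts[3] if len(parts) > 3 else "."
            rows.append((parts[0], start0 + 1, end0, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional test for Hardy-Weinberg proportions.

    Conditions on the observed minor-allele count and sums the probability
    of every heterozygote count whose conditional probability does not
    exceed that of the observed one (plain two-sided exact test, not
    mid-p).  Monomorphic sites return 1.0.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_aa + n_Aa          # minor-ish allele count
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0
    probs = _hwe_het_probabilities(n, rare)
    obs = probs[n_Aa]
    p = probs[probs <= obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def _hwe_het_probabilities(n: int, rare: int) -> np.ndarray:
    """P(het count | n diploids, rare allele count), indexed 0..rare.

    Recurrence of the conditional distribution; heterozygote count has the
    same parity as the rare-allele count, other entries are exactly 0.
    """
    probs = np.zeros(rare + 1)
    het = rare % 2
    # log probability at the lowest admissible het count via log-gammas
    common = 2 * n - rare
    logp = (
        math.lgamma(n + 1)
        - math.lgamma((rare - het) // 2 + 1)
        - math.lgamma(het + 1)
        - math.lgamma((common - het) // 2 + 1)
        + het * math.log(2)
        + math.lgamma(rare + 1) + math.lgamma(common + 1) - math.lgamma(2 * n + 1)
    )
    vals = {}
    vals[het] = logp
    h = het
    while h + 2 <= rare:
        # P(h+2)/P(h) = 4 * n_hom_rare * n_hom_common / ((h+2)(h+1))
        hom_r = (rare - h) // 2
        hom_c = (common - h) // 2
        logp = logp + math.log(4.0 * hom_r * hom_c) - math.log((h + 2) * (h + 1))
        h += 2
        vals[h] = logp
    mx = max(vals.values())
    total = sum(math.exp(v - mx) for v in vals.values())
    for h, v in vals.items():
        probs[h] = math.exp(v - mx) / total
    return probs


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

def qc_filter(gm: GenotypeMatrix, max_missing_sample: float = 0.10,
              max_missing_snp: float = 0.10, min_maf: float = 0.01,
              hwe_alpha: float = 1e-4, hwe_stratify: bool = False):
    """Apply the QC cascade: sample missingness, SNP missingness, MAF, HWE.

    Filters are applied in that order; MAF and HWE are computed on the
    sample set retained after the sample-missingness step.  Samples or SNPs
    with missingness strictly above the threshold are removed; SNPs with
    MAF strictly below ``min_maf`` or HWE exact p strictly below
    ``hwe_alpha`` are removed.  By default the HWE test pools all samples;
    ``hwe_stratify=True`` tests within each population and removes a SNP
    failing in any of them.

    Returns ``(filtered GenotypeMatrix, QcReport)``; raises if no variant
    survives.
    """
    if gm.n_variants == 0 or gm.n_samples == 0:
        raise ValueError("empty genotype matrix")

    miss = gm.is_missing
    sample_missing = miss.mean(axis=1)
    keep_samples = np.flatnonzero(sample_missing <= max_missing_sample)
    n_samples_removed = gm.n_samples - keep_samples.size
    if keep_samples.size == 0:
        raise ValueError("all samples removed by missingness filter")
    g = gm.take_samples(keep_samples)

    miss = g.is_missing
    snp_missing = miss.mean(axis=0)
    pass_missing = snp_missing <= max_missing_snp
    n_var_missing = int((~pass_missing).sum())

    freq = g.alt_freq()
    maf = np.minimum(freq, 1 - freq)
    pass_maf = pass_missing & ~np.isnan(maf) & (maf >= min_maf)
    n_var_maf = int((pass_missing & ~pass_maf).sum())

    pass_hwe = pass_maf.copy()
    cand = np.flatnonzero(pass_maf)
    groups = ([np.arange(g.n_samples)] if not hwe_stratify else
              [np.flatnonzero(g.populations == p)
               for p in pd.unique(g.populations)])
    for j in cand:
        col = g.dosage[:, j]
        for idx in groups:
            sub = col[idx]
            sub = sub[sub != MISSING]
            p = hwe_exact_test(int((sub == 0).sum()), int((sub == 1).sum()),
                               int((sub == 2).sum()))
            if p < hwe_alpha:
                pass_hwe[j] = False
                break
    n_var_hwe = int((pass_maf & ~pass_hwe).sum())

    keep = np.flatnonzero(pass_hwe)
    if keep.size == 0:
        raise ValueError("all variants removed by QC; check thresholds")
    report = QcReport(
        n_samples_in=gm.n_samples, n_variants_in=gm.n_variants,
        samples_removed_missing=n_samples_removed,
        variants_removed_missing=n_var_missing,
        variants_removed_maf=n_var_maf, variants_removed_hwe=n_var_hwe,
        thresholds=dict(max_missing_sample=max_missing_sample,
                        max_missing_snp=max_missing_snp, min_maf=min_maf,
                        hwe_alpha=hwe_alpha, hwe_stratify=hwe_stratify),
    )
    return g.take_variants(keep), report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, pairwise-complete."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    sx = xv.std()
    sy = yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy)
    return float(r * r)


def ld_prune(gm: GenotypeMatrix, window_snps: int = 50, step: int = 5,
             r2_max: float = 0.5) -> np.ndarray:
    """Greedy within-window LD pruning on genotype-dosage correlation.

    Mirrors the plink ``--indep-pairwise`` procedure: within each window of
    ``window_snps`` consecutive SNPs (advancing by ``step``, per
    chromosome), while any retained pair has r^2 > ``r2_max`` the
    lower-MAF member of the worst pair is dropped (tie: the
    later-positioned one).  r^2 is the squared Pearson correlation of
    dosages over pairwise-complete samples (composite LD).

    Returns the sorted indices of retained variants.
    """
    keep = np.ones(gm.n_variants, dtype=bool)
    freq = gm.alt_freq()
    maf = np.minimum(freq, 1 - freq)
    chroms = gm.variants["chrom"].to_numpy()
    any_missing = bool(gm.is_missing.any())
    for chrom in pd.unique(chroms):
        cidx = np.flatnonzero(chroms == chrom)
        start = 0
        while start < cidx.size:
            win = cidx[start:start + window_snps]
            active = [j for j in win if keep[j]]
            while len(active) > 1:
                if any_missing:
                    r2 = np.array([[_pairwise_r2(gm.dosage[:, a],
                                                 gm.dosage[:, b])
                                    for b in active] for a in active])
                else:
                    with np.errstate(invalid="ignore"):
                        r2 = np.corrcoef(gm.dosage[:, active].astype(float),
                                         rowvar=False) ** 2
                    r2 = np.nan_to_num(r2)
                np.fill_diagonal(r2, 0.0)
                ii, jj = np.unravel_index(np.argmax(r2), r2.shape)
                if r2[ii, jj] <= r2_max:
                    break
                a, b = active[min(ii, jj)], active[max(ii, jj)]
                drop = a if maf[a] < maf[b] else b  # tie: later position
                keep[drop] = False
                active.remove(drop)
            if start + window_snps >= cidx.size:
                break
            start += step
    return np.flatnonzero(keep)
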