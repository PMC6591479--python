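"""Selection-scan statistics: Weir-Cockerham F_ST, EHH/iHH/XP-EHH, Tajima's D.

Per-SNP F_ST uses the Weir & Cockerham (1984) variance components a/b/c
with per-SNP observed sample sizes; pairwise population means are
ratio-of-sums, never means of per-SNP ratios.  XP-EHH integrates the EHH
decay curve over physical distance (bp), with the integration boundary
set by the *pooled* two-population EHH so both populations integrate over
identical intervals; raw scores ln(iHH_A/iHH_B) are standardized
genome-wide.  Tajima's D follows the 1989 formulation over sliding
windows (default 100 kb advancing by 10 kb), skipping windows that
contain missing genotype calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .genotype_io import MISSING, GenotypeMatrix, HaplotypeMatrix

EHH_CUTOFF = 0.05
MAX_EXTENSION_BP = 1_000_000
MAX_GAP_BP = 200_000


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    """Per-SNP W&C variance components and the pairwise mean estimate."""

    table: pd.DataFrame          # chrom, pos, id, a, b, c, theta, theta_clamped
    pop_a: str
    pop_b: str
    mean_fst: float              # ratio of sums: sum(a) / sum(a+b+c)


def _pop_counts(gm: GenotypeMatrix, pop: str):
    idx = np.flatnonzero(gm.populations == pop)
    if idx.size < 2:
        raise ValueError(f"population {pop!r} needs >= 2 samples")
    d = gm.dosage[idx]
    obs = d != MISSING
    n = obs.sum(axis=0).astype(float)                # diploids observed
    alt = np.where(obs, d, 0).sum(axis=0).astype(float)
    het = np.where(obs, d == 1, False).sum(axis=0).astype(float)
    return n, alt, het


def wc_fst_components(n1, p1, h1, n2, p2, h2):
    """Weir & Cockerham (1984) a, b, c for two populations, vectorized.

    ``n`` are per-SNP diploid sample sizes, ``p`` alt-allele frequencies
    and ``h`` observed heterozygote proportions.
    """
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r
                             - hbar / 4.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 * (r - 1.0) / r
                                 - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar))
    c = hbar / 2.0
    return a, b, c


def wc_fst_per_snp(gm: GenotypeMatrix, pop_a: str, pop_b: str) -> FstResult:
    """Per-SNP Weir-Cockerham F_ST between two labeled populations.

    Missing genotypes are excluded per SNP, so sample sizes vary along the
    genome.  Per-SNP estimates theta = a/(a+b+c) are clamped to zero for
    reporting when negative; the unclamped components feed the
    ratio-of-sums mean.  SNPs monomorphic across both populations have
    undefined theta and are excluded from the mean.
    """
    na, alt_a, het_a = _pop_counts(gm, pop_a)
    nb, alt_b, het_b = _pop_counts(gm, pop_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = alt_a / (2 * na)
        p2 = alt_b / (2 * nb)
        h1 = het_a / na
        h2 = het_b / nb
        a, b, c = wc_fst_components(na, p1, h1, nb, p2, h2)
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)
    defined = np.isfinite(theta) & (denom != 0)
    theta_clamped = np.where(defined, np.clip(theta, 0.0, None), np.nan)

    table = gm.variants[["chrom", "pos", "id"]].copy()
    table["a"] = a
    table["b"] = b
    table["c"] = c
    table["theta"] = theta
    table["theta_clamped"] = theta_clamped
    mean_fst = float(a[defined].sum() / denom[defined].sum())
    return FstResult(table, pop_a, pop_b, mean_fst)


def pairwise_mean_fst(gm: GenotypeMatrix, labels=None) -> pd.DataFrame:
    """Symmetric matrix of ratio-of-sums mean F_ST over population pairs."""
    if labels is not None:
        gm = GenotypeMatrix(gm.dosage, gm.variants,
                            gm.samples.assign(population=np.asarray(labels)))
    pops = list(pd.unique(gm.populations))
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    m = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, pa in enumerate(pops):
        for pb in pops[i + 1:]:
            fst = wc_fst_per_snp(gm, pa, pb).mean_fst
            m.loc[pa, pb] = m.loc[pb, pa] = fst
    return m


# ---------------------------------------------------------------------------
# EHH / iHH
# ---------------------------------------------------------------------------

@dataclass
class EhhProfile:
    """EHH decay away from a core SNP in one direction."""

    core_index: int
    direction: str                   # "left" or "right"
    positions: np.ndarray            # bp, starting at the core
    ehh: np.ndarray                  # starts at 1.0, non-increasing
    ihh: float                       # trapezoid integral over bp
    defined: bool = True
    flags: list = field(default_factory=list)


def ehh_profile(hm: HaplotypeMatrix, core_index: int, haplotype_subset=None,
                direction: str = "right", cutoff: float = EHH_CUTOFF,
                max_extension_bp: int = MAX_EXTENSION_BP,
                max_gap_bp: int = MAX_GAP_BP) -> EhhProfile:
    """EHH decay curve from a core SNP over a haplotype set.

    At distance d, EHH is the probability that two randomly drawn
    haplotypes from the set are identical at every SNP between the core
    (exclusive) and d (inclusive): sum over identity groups g of
    C(k_g, 2) / C(n, 2).  EHH at the core itself is 1 by definition.
    Extension stops when EHH drops below ``cutoff``, at
    ``max_extension_bp`` from the core, at a gap larger than
    ``max_gap_bp``, or at the chromosome edge.  iHH is the trapezoid
    integral of the curve over physical distance.
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    alleles = hm.alleles
    if haplotype_subset is not None:
        alleles = alleles[np.asarray(haplotype_subset)]
    n = alleles.shape[0]
    pos = hm.positions
    flags = []
    if n < 2:
        return EhhProfile(core_index, direction, pos[[core_index]],
                          np.array([1.0]), 0.0, defined=False,
                          flags=["subset_too_small"])
    col = alleles[:, core_index]
    if (col == col[0]).all():
        flags.append("core_monomorphic_in_subset")

    step = 1 if direction == "right" else -1
    denom = n * (n - 1) / 2.0
    labels = np.zeros(n, dtype=np.int64)
    out_pos = [pos[core_index]]
    out_ehh = [1.0]
    ihh = 0.0
    j = core_index + step
    prev_pos = pos[core_index]
    prev_ehh = 1.0
    while 0 <= j < hm.n_variants:
        if abs(int(pos[j]) - int(pos[core_index])) > max_extension_bp:
            break
        if abs(int(pos[j]) - int(prev_pos)) > max_gap_bp:
            flags.append("gap")
            break
        _, labels = np.unique(labels * 2 + alleles[:, j], return_inverse=True)
        counts = np.bincount(labels)
        e = float((counts * (counts - 1)).sum() / 2.0 / denom)
        d = abs(int(pos[j]) - int(prev_pos))
        ihh += 0.5 * (prev_ehh + e) * d
        out_pos.append(pos[j])
        out_ehh.append(e)
        prev_pos, prev_ehh = pos[j], e
        if e < cutoff:
            break
        j += step
    return EhhProfile(core_index, direction, np.array(out_pos),
                      np.array(out_ehh), ihh, defined=True, flags=flags)


@njit(cache=True)
def _xpehh_one_side(alleles, n_a, positions, core, step, cutoff,
                    max_extension, max_gap, labels, new_labels, keymap,
                    cnt_a, cnt_b):
    """Integrate per-population EHH outward until the pooled EHH dies.

    ``alleles`` holds population A's haplotypes in the first ``n_a`` rows.
    Returns (iHH_A, iHH_B) for one direction; the partition over the
    pooled haplotype set is refined SNP by SNP (counting relabel in
    first-occurrence order) and per-population EHH is read off the
    within-population group counts, so both populations stop at the same
    boundary.  The last five arguments are caller-owned scratch buffers.
    """
    n, L = alleles.shape
    n_b = n - n_a
    denom_a = n_a * (n_a - 1) / 2.0
    denom_b = n_b * (n_b - 1) / 2.0
    denom_p = n * (n - 1) / 2.0

    labels[:] = 0
    n_groups = 1
    ihh_a = 0.0
    ihh_b = 0.0
    ehh_a = 1.0
    ehh_b = 1.0
    prev_pos = positions[core]
    core_pos = positions[core]
    j = core + step
    while j >= 0 and j < L:
        if abs(positions[j] - core_pos) > max_extension:
            break
        if abs(positions[j] - prev_pos) > max_gap:
            break
        for k in range(2 * n_groups):
            keymap[k] = -1
        cur = 0
        for r in range(n):
            k = labels[r] * 2 + alleles[r, j]
            m = keymap[k]
            if m == -1:
                keymap[k] = cur
                m = cur
                cur += 1
            new_labels[r] = m
        n_groups = cur
        for g in range(n_groups):
            cnt_a[g] = 0
            cnt_b[g] = 0
        for r in range(n):
            labels[r] = new_labels[r]
            if r < n_a:
                cnt_a[labels[r]] += 1
            else:
                cnt_b[labels[r]] += 1
        s_a = 0.0
        s_b = 0.0
        s_p = 0.0
        for g in range(n_groups):
            ka = cnt_a[g]
            kb = cnt_b[g]
            s_a += ka * (ka - 1) / 2.0
            s_b += kb * (kb - 1) / 2.0
            s_p += (ka + kb) * (ka + kb - 1) / 2.0
        e_a = s_a / denom_a
        e_b = s_b / denom_b
        e_p = s_p / denom_p
        d = abs(positions[j] - prev_pos)
        ihh_a += 0.5 * (ehh_a + e_a) * d
        ihh_b += 0.5 * (ehh_b + e_b) * d
        ehh_a = e_a
        ehh_b = e_b
        prev_pos = positions[j]
        if e_p < cutoff:
            break
        j += step
    return ihh_a, ihh_b


@njit(cache=True)
def _xpehh_all_cores(alleles, n_a, positions, cutoff, max_extension, max_gap):
    n, L = alleles.shape
    ihh_a = np.zeros(L)
    ihh_b = np.zeros(L)
    labels = np.empty(n, dtype=np.int64)
    new_labels = np.empty(n, dtype=np.int64)
    keymap = np.empty(2 * n + 2, dtype=np.int64)
    cnt_a = np.empty(n, dtype=np.int64)
    cnt_b = np.empty(n, dtype=np.int64)
    for core in range(L):
        la, lb = _xpehh_one_side(alleles, n_a, positions, core, -1, cutoff,
                                 max_extension, max_gap, labels, new_labels,
                                 keymap, cnt_a, cnt_b)
        ra, rb = _xpehh_one_side(alleles, n_a, positions, core, 1, cutoff,
                                 max_extension, max_gap, labels, new_labels,
                                 keymap, cnt_a, cnt_b)
        ihh_a[core] = la + ra
        ihh_b[core] = lb + rb
    return ihh_a, ihh_b


@dataclass
class XpehhTrack:
    """Per-SNP XP-EHH scores between two phased populations."""

    table: pd.DataFrame      # chrom, pos, id, ihh_a, ihh_b, raw, std, defined
    pop_a: str
    pop_b: str


def xpehh_scan(hm_a: HaplotypeMatrix, hm_b: HaplotypeMatrix,
               cutoff: float = EHH_CUTOFF,
               max_extension_bp: int = MAX_EXTENSION_BP,
               max_gap_bp: int = MAX_GAP_BP) -> XpehhTrack:
    """XP-EHH scan over every SNP shared by two phased populations.

    For each core SNP, iHH is computed per population over all of that
    population's haplotypes (no core-allele partition), integrating EHH by
    trapezoid over physical distance between the bounds where the pooled
    two-population EHH falls below ``cutoff``.  Raw score =
    ln(iHH_A / iHH_B); positive values mean longer haplotypes (a selection
    signal) in population A.  Scores are standardized genome-wide; cores
    with zero iHH in either population are flagged undefined and excluded
    from standardization.
    """
    if not hm_a.variants["pos"].equals(hm_b.variants["pos"]):
        raise ValueError("populations must be phased on the same variant set")
    pop_a = str(hm_a.samples["population"].iloc[0])
    pop_b = str(hm_b.samples["population"].iloc[0])
    alleles = np.vstack([hm_a.alleles, hm_b.alleles])
    positions = hm_a.positions.astype(np.int64)

    ihh_a, ihh_b = _xpehh_all_cores(alleles, hm_a.n_haplotypes, positions,
                                    cutoff, float(max_extension_bp),
                                    float(max_gap_bp))
    defined = (ihh_a > 0) & (ihh_b > 0)
    raw = np.full(len(positions), np.nan)
    raw[defined] = np.log(ihh_a[defined] / ihh_b[defined])
    std = np.full(len(positions), np.nan)
    if defined.sum() >= 2 and np.std(raw[defined]) > 0:
        std[defined] = (raw[defined] - raw[defined].mean()) / raw[defined].std()

    table = hm_a.variants[["chrom", "pos", "id"]].copy()
    table["ihh_a"] = ihh_a
    table["ihh_b"] = ihh_b
    table["raw"] = raw
    table["std"] = std
    table["defined"] = defined
    return XpehhTrack(table, pop_a, pop_b)


# ---------------------------------------------------------------------------
# Tajima's D sliding windows
# ---------------------------------------------------------------------------

def tajima_constants(n: int):
    """Tajima (1989) normalizing constants for n sequences."""
    i = np.arange(1, n)
    a1 = (1.0 / i).sum()
    a2 = (1.0 / i ** 2).sum()
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n ** 2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return a1, a2, b1, b2, c1, c2, e1, e2


def tajima_d(n: int, S: int, pi: float) -> float:
    """Tajima's D from n sequences, S segregating sites, pairwise pi."""
    if S < 2:
        raise ValueError("D undefined for S < 2")
    a1, _, _, _, _, _, e1, e2 = tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1.0)
    if var <= 0:
        raise ValueError("zero variance")
    return float((pi - S / a1) / np.sqrt(var))


def tajima_d_windows(data, window: int = 100_000, step: int = 10_000,
                     origin: int = 1) -> pd.DataFrame:
    """Tajima's D over sliding windows (1-based inclusive coordinates).

    ``data`` may be a :class:`HaplotypeMatrix` (pi from haplotypes) or a
    :class:`GenotypeMatrix` (pi from allele counts with the unbiased
    n/(n-1) pairwise formula).  Windows of ``window`` bp advance by
    ``step`` bp from ``origin`` along each chromosome.  A window is
    skipped (with a reason) when it contains a missing genotype call, has
    S < 2, or zero variance.  Returns a DataFrame with columns chrom,
    start, end, n_snps, S, pi, theta_w, D, skipped, reason.
    """
    if isinstance(data, HaplotypeMatrix):
        n_seq = data.n_haplotypes
        derived = data.alleles.sum(axis=0).astype(float)
        has_missing = np.zeros(data.n_variants, dtype=bool)
        variants = data.variants
    elif isinstance(data, GenotypeMatrix):
        obs = data.dosage != MISSING
        n_seq = 2 * data.n_samples
        derived = np.where(obs, data.dosage, 0).sum(axis=0).astype(float)
        has_missing = (~obs).any(axis=0)
        variants = data.variants
    else:
        raise TypeError("expected HaplotypeMatrix or GenotypeMatrix")

    rows = []
    chroms = variants["chrom"].to_numpy()
    positions = variants["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        cmask = chroms == chrom
        pos = positions[cmask]
        der = derived[cmask]
        hmiss = has_missing[cmask]
        last = int(pos.max())
        start = origin
        while start <= last:
            end = start + window - 1
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            rec = dict(chrom=chrom, start=start, end=end,
                       n_snps=int(hi - lo), S=0, pi=np.nan,
                       theta_w=np.nan, D=np.nan, skipped=True, reason="")
            if hi == lo:
                rec["reason"] = "no_variants"
            elif hmiss[lo:hi].any():
                rec["reason"] = "missing_genotypes"
            else:
                k = der[lo:hi]
                seg = (k > 0) & (k < n_seq)
                S = int(seg.sum())
                rec["S"] = S
                if S < 2:
                    rec["reason"] = "fewer_than_2_segregating_sites"
                else:
                    ks = k[seg]
                    pi = float((2.0 * ks * (n_seq - ks)
                                / (n_seq * (n_seq - 1.0))).sum())
                    a1 = tajima_constants(n_seq)[0]
                    rec["pi"] = pi
                    rec["theta_w"] = S / a1
                    try:
                        rec["D"] = tajima_d(n_seq, S, pi)
                        rec["skipped"] = False
                    except ValueError:
                        rec["reason"] = "zero_variance"
            rows.append(rec)
            start += step
    return pd.DataFrame(rows)
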