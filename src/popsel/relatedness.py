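"""Duplicate/relative detection and inbreeding screening.

Implements the KING-robust between-family kinship estimator and the
method-of-moments inbreeding coefficient (observed vs expected homozygote
counts), with the sample-cleaning rule built on top: one member of each
related pair and every inbred individual is excluded.

Default thresholds follow the source study's printed cutoffs: kinship
phi > 0.0084 and inbreeding F >= 0.0156 (= 1/64, the expected F of a
second-cousin mating's offspring).  Note 0.0084 matches neither the
expected second-degree kinship (0.125) nor the conventional KING
second-degree inference bound (0.0884); it is preserved as printed and is
configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

KIN_THRESHOLD = 0.0084
F_THRESHOLD = 0.0156
MIN_JOINT_SNPS = 100


@dataclass
class KinshipResult:
    """Pairwise KING-robust kinship with the counts it was built from."""

    pairs: pd.DataFrame      # id1, id2, n_snps, n_both_het, n_opp_hom, phi
    sample_ids: list

    def phi_matrix(self) -> pd.DataFrame:
        n = len(self.sample_ids)
        m = np.zeros((n, n))
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        for row in self.pairs.itertuples():
            i, j = idx[row.id1], idx[row.id2]
            m[i, j] = m[j, i] = row.phi
        return pd.DataFrame(m, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class InbreedingResult:
    """Per-sample method-of-moments F, with negatives clamped to zero."""

    table: pd.DataFrame      # sample_id, n_snps, o_hom, e_hom, f_raw, f, clamped


def king_kinship(gm: GenotypeMatrix, min_joint_snps: int = MIN_JOINT_SNPS) -> KinshipResult:
    """KING-robust between-family kinship for every sample pair.

    phi = (N_both_het - 2 * N_opposite_hom) / (N_het_i + N_het_j), with all
    counts taken over SNPs observed in both samples.  The estimator uses no
    allele frequencies, which makes it robust to population structure;
    duplicates give phi = 0.5, parent-offspring ~0.25, unrelated ~0.
    Pairs with fewer than ``min_joint_snps`` jointly observed SNPs get
    phi = NaN with a warning.
    """
    d = gm.dosage
    het = (d == 1).astype(np.float64)
    hom0 = (d == 0).astype(np.float64)
    hom2 = (d == 2).astype(np.float64)
    obs = (d != MISSING).astype(np.float64)

    n11 = het @ het.T                       # both heterozygous
    n02 = hom0 @ hom2.T + hom2 @ hom0.T     # opposite homozygotes
    het_joint = het @ obs.T                 # het in i over sites observed in j
    joint = obs @ obs.T

    ids = list(gm.samples["sample_id"])
    rows = []
    n_undef = 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            nj = joint[i, j]
            denom = het_joint[i, j] + het_joint[j, i]
            if nj < min_joint_snps or denom == 0:
                phi = np.nan
                n_undef += 1
            else:
                phi = (n11[i, j] - 2 * n02[i, j]) / denom
            rows.append((ids[i], ids[j], int(nj), int(n11[i, j]),
                         int(n02[i, j]), phi))
    if n_undef:
        warnings.warn(f"{n_undef} pairs had < {min_joint_snps} jointly "
                      "observed SNPs; phi reported as NaN")
    pairs = pd.DataFrame(rows, columns=["id1", "id2", "n_snps",
                                        "n_both_het", "n_opp_hom", "phi"])
    return KinshipResult(pairs, ids)


def inbreeding_f(gm: GenotypeMatrix) -> InbreedingResult:
    """Method-of-moments inbreeding coefficient per sample.

    F = (O_hom - E_hom) / (L - E_hom), where the expected homozygote count
    sums 1 - 2p(1-p) * 2n/(2n-1) over the loci observed in that sample
    (allele frequencies p estimated from the cohort itself; the
    2n/(2n-1) factor is the small-sample correction).  Monomorphic loci
    are skipped.  Negative values are clamped to zero — they typically
    reflect sampling error — with a flag recording the clamp.
    """
    d = gm.dosage
    obs = d != MISSING
    n_alleles = 2 * obs.sum(axis=0)
    alt = np.where(obs, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / n_alleles, np.nan)
    poly = (p > 0) & (p < 1)
    corr = np.where(n_alleles > 1, n_alleles / (n_alleles - 1.0), np.nan)
    e_hom_site = 1.0 - 2.0 * p * (1.0 - p) * corr

    rows = []
    for i, sid in enumerate(gm.samples["sample_id"]):
        use = obs[i] & poly
        L = int(use.sum())
        o_hom = int(((d[i] == 0) | (d[i] == 2))[use].sum())
        e_hom = float(e_hom_site[use].sum())
        if L == 0 or L - e_hom == 0:
            f_raw = np.nan
        else:
            f_raw = (o_hom - e_hom) / (L - e_hom)
        clamped = bool(f_raw < 0) if np.isfinite(f_raw) else False
        f = 0.0 if clamped else f_raw
        rows.append((sid, L, o_hom, e_hom, f_raw, f, clamped))
    table = pd.DataFrame(rows, columns=["sample_id", "n_snps", "o_hom",
                                        "e_hom", "f_raw", "f", "clamped"])
    return InbreedingResult(table)


def flag_related_and_inbred(kin: KinshipResult, inb: InbreedingResult,
                            gm: GenotypeMatrix | None = None,
                            kin_thresh: float = KIN_THRESHOLD,
                            f_thresh: float = F_THRESHOLD) -> pd.DataFrame:
    """Build the exclusion list from kinship and inbreeding screens.

    For each pair with phi > ``kin_thresh`` the member with the higher
    genotype missingness is excluded (tie: the later sample id); every
    sample with clamped F >= ``f_thresh`` is excluded.  Returns a
    DataFrame (sample_id, reason) sorted by sample id; empty inputs give
    an empty list.
    """
    missing_rate = {}
    if gm is not None:
        mr = gm.is_missing.mean(axis=1)
        missing_rate = dict(zip(gm.samples["sample_id"], mr))

    excluded: dict[str, str] = {}
    flagged = kin.pairs[kin.pairs["phi"] > kin_thresh]
    for row in flagged.itertuples():
        if row.id1 in excluded or row.id2 in excluded:
            continue
        m1 = missing_rate.get(row.id1, 0.0)
        m2 = missing_rate.get(row.id2, 0.0)
        if m1 > m2:
            drop = row.id1
        elif m2 > m1:
            drop = row.id2
        else:
            drop = max(row.id1, row.id2)
        excluded[drop] = f"kinship phi={row.phi:.4f} with " + (
            row.id2 if drop == row.id1 else row.id1)

    inbred = inb.table[inb.table["f"] >= f_thresh]
    for row in inbred.itertuples():
        if row.sample_id not in excluded:
            excluded[row.sample_id] = f"inbreeding F={row.f:.4f}"
        else:
            excluded[row.sample_id] += f"; inbreeding F={row.f:.4f}"

    return pd.DataFrame(sorted(excluded.items()),
                        columns=["sample_id", "reason"])
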