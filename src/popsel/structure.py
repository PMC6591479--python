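"""Population structure: PCA with projection, score ANOVA, outgroup f3.

PCA uses the smartpca-style per-variant normalization (center by mean
dosage, scale by sqrt(p(1-p)) with a shrunk frequency estimate), with
held-out samples projected onto fixed loadings.  Outgroup f3 measures the
drift shared by two populations since their split from an outgroup, with
standard errors from a weighted block jackknife over contiguous SNP
blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix
from .synthetic_data import PopAlleleCounts


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaModel:
    """Fitted PCA: per-variant normalization constants plus loadings/scores."""

    variant_ids: np.ndarray          # ids of the variants used in the fit
    center: np.ndarray               # per-variant mean dosage
    scale: np.ndarray                # per-variant sqrt(p(1-p)) normalizer
    loadings: np.ndarray             # variants x components
    scores: pd.DataFrame             # samples x components, sample_id index
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def _normalize(dosage: np.ndarray, center: np.ndarray, scale: np.ndarray) -> np.ndarray:
    """Center/scale dosages; missing entries contribute 0 after centering."""
    x = dosage.astype(np.float64)
    miss = dosage == MISSING
    x = (x - center) / scale
    x[miss] = 0.0
    return x


def _fit_normalization(dosage: np.ndarray):
    obs = dosage != MISSING
    n_obs = obs.sum(axis=0)
    tot = np.where(obs, dosage, 0).sum(axis=0)
    if (n_obs == 0).any():
        raise ValueError("variant with no observed genotypes")
    center = tot / n_obs
    # shrunk frequency estimate stabilises rare variants
    p_hat = (1.0 + tot) / (2.0 + 2.0 * n_obs)
    scale = np.sqrt(p_hat * (1.0 - p_hat))
    return center, scale


def pca_fit(gm: GenotypeMatrix, n_components: int = 10) -> PcaModel:
    """Principal components of a QC-filtered, LD-pruned genotype matrix.

    Each variant is centered by its mean observed dosage and scaled by
    sqrt(p(1-p)) with p = (1 + sum dosage) / (2 + 2 n_obs); missing
    entries contribute zero after centering.  Components come from the SVD
    of the normalized matrix (equivalently, eigendecomposition of the
    sample covariance).  The sign of each component is fixed by making its
    largest-magnitude loading positive.
    """
    if gm.n_samples < n_components:
        raise ValueError(
            f"{n_components} components requested from {gm.n_samples} samples")
    center, scale = _fit_normalization(gm.dosage)
    usable = scale > 0
    x = _normalize(gm.dosage[:, usable], center[usable], scale[usable])

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigvals = s ** 2
    evr = eigvals / eigvals.sum()

    loadings = np.zeros((gm.n_variants, n_components))
    loadings[usable] = vt[:n_components].T
    # sign convention: largest-|loading| entry positive
    for k in range(n_components):
        jmax = np.argmax(np.abs(loadings[:, k]))
        if loadings[jmax, k] < 0:
            loadings[:, k] *= -1

    xfull = np.zeros((gm.n_samples, gm.n_variants))
    xfull[:, usable] = x
    scores = xfull @ loadings
    scores_df = pd.DataFrame(
        scores, index=gm.samples["sample_id"],
        columns=[f"PC{k + 1}" for k in range(n_components)])
    return PcaModel(gm.variants["id"].to_numpy(), center, scale,
                    loadings, scores_df, evr[:n_components])


def pca_project(model: PcaModel, gm_new: GenotypeMatrix,
                min_shared: int = 100) -> pd.DataFrame:
    """Project held-out samples onto a fitted model's loadings.

    Normalization constants come from the model and are never
    re-estimated.  Scores over the shared variant subset are divided by
    the shared-variant fraction so that partially overlapping panels stay
    on the fitted scale; projecting a fitted sample with full overlap
    reproduces its fitted score.
    """
    model_index = {v: i for i, v in enumerate(model.variant_ids)}
    new_ids = gm_new.variants["id"].to_numpy()
    shared_new = [j for j, v in enumerate(new_ids) if v in model_index]
    if len(shared_new) < min_shared:
        raise ValueError(
            f"only {len(shared_new)} variants shared with the model "
            f"(minimum {min_shared})")
    shared_model = np.array([model_index[new_ids[j]] for j in shared_new])
    shared_new = np.array(shared_new)

    scale = model.scale[shared_model]
    usable = scale > 0
    x = _normalize(gm_new.dosage[:, shared_new[usable]],
                   model.center[shared_model[usable]], scale[usable])
    frac = len(shared_new) / len(model.variant_ids)
    scores = (x @ model.loadings[shared_model[usable]]) / frac
    return pd.DataFrame(scores, index=gm_new.samples["sample_id"],
                        columns=[f"PC{k + 1}" for k in range(model.n_components)])


def anova_on_scores(scores: pd.DataFrame, labels) -> pd.DataFrame:
    """One-way ANOVA of PC scores across group labels, per component.

    Returns a DataFrame (component, F, p).  Requires at least two groups
    with at least two samples each.
    """
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    sizes = [(labels == g).sum() for g in groups]
    if min(sizes) < 2:
        raise ValueError("every group needs >= 2 samples")
    rows = []
    for col in scores.columns:
        vals = [scores[col].to_numpy()[labels == g] for g in groups]
        F, p = stats.f_oneway(*vals)
        rows.append((col, float(F), float(p)))
    return pd.DataFrame(rows, columns=["component", "F", "p"])


# ---------------------------------------------------------------------------
# Outgroup f3
# ---------------------------------------------------------------------------

@dataclass
class F3Result:
    """Outgroup f3 statistic with block-jackknife uncertainty."""

    outgroup: str
    a: str
    b: str
    f3: float
    se: float
    z: float
    n_snps: int
    n_blocks: int


def _weighted_block_jackknife(per_snp: np.ndarray, block_size: int):
    """Mean and SE of a per-SNP statistic by delete-one-block jackknife.

    Blocks are contiguous runs of ``block_size`` SNPs (the trailing block
    may be shorter); the variance uses the weighted jackknife so unequal
    block sizes are handled exactly.
    """
    n = per_snp.size
    starts = np.arange(0, n, block_size)
    sizes = np.minimum(block_size, n - starts).astype(float)
    B = starts.size
    if B < 2:
        raise ValueError("need >= 2 jackknife blocks; lower block_size")
    total = per_snp.sum()
    theta = total / n
    block_sums = np.add.reduceat(per_snp, starts)
    theta_j = (total - block_sums) / (n - sizes)   # leave-one-block-out
    w = sizes / n
    # Busing et al. (1999) weighted jackknife variance
    pseudo = theta / w - theta_j * (1.0 / w - 1.0)
    theta_dot = B * theta - ((1.0 - w) * theta_j).sum()
    var = np.sum((pseudo - theta_dot) ** 2 / (1.0 / w - 1.0)) / B
    return theta, float(np.sqrt(var)), B


def outgroup_f3(counts: PopAlleleCounts, outgroup: str, a: str, b: str,
                block_size_snps: int = 500) -> F3Result:
    """Outgroup f3(O; A, B): shared drift of A and B relative to O.

    Per SNP the statistic is (o - pa)(o - pb) - h_o / n_o, where o, pa, pb
    are sample allele frequencies and h_o / n_o = o(1 - o)/(n_o - 1)
    corrects for finite outgroup sample size.  SNPs where the outgroup (or
    A or B) is unobserved are skipped.  f3(O;A,B) is symmetric in A and B;
    larger values mean more drift shared by A and B since their divergence
    from O.
    """
    for pop in (outgroup, a, b):
        if pop not in counts.populations:
            raise ValueError(f"population {pop!r} not in the count table")
    alt_o = counts.alt[outgroup].to_numpy(float)
    tot_o = counts.tot[outgroup].to_numpy(float)
    alt_a = counts.alt[a].to_numpy(float)
    tot_a = counts.tot[a].to_numpy(float)
    alt_b = counts.alt[b].to_numpy(float)
    tot_b = counts.tot[b].to_numpy(float)

    use = (tot_o > 1) & (tot_a > 0) & (tot_b > 0)
    o = alt_o[use] / tot_o[use]
    pa = alt_a[use] / tot_a[use]
    pb = alt_b[use] / tot_b[use]
    n_o = tot_o[use]
    per_snp = (o - pa) * (o - pb) - o * (1.0 - o) / (n_o - 1.0)

    f3, se, n_blocks = _weighted_block_jackknife(per_snp, block_size_snps)
    z = f3 / se if se > 0 else np.nan
    return F3Result(outgroup, a, b, float(f3), se, float(z),
                    int(per_snp.size), n_blocks)


def f3_table(counts: PopAlleleCounts, outgroup: str,
             block_size_snps: int = 500) -> pd.DataFrame:
    """All outgroup f3(O; A, B) for unordered pairs of non-outgroup pops."""
    pops = [p for p in counts.populations if p != outgroup]
    rows = []
    for i, a in enumerate(pops):
        for b in pops[i:]:
            r = outgroup_f3(counts, outgroup, a, b, block_size_snps)
            rows.append((r.outgroup, r.a, r.b, r.f3, r.se, r.z,
                         r.n_snps, r.n_blocks))
    return pd.DataFrame(rows, columns=["outgroup", "A", "B", "f3", "se",
                                       "z", "n_snps", "n_blocks"])
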