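"""Candidate-region calling from statistic tracks, and cross-comparison overlap.

The composite rule for recent selection: a genomic region is a candidate
when it contains two or more SNPs in the top 0.1% of the genome-wide
XP-EHH empirical distribution and at least one SNP anywhere in the
spanned interval with an F_ST empirical p-value < 0.01.  Older signals:
sliding-window Tajima's D windows with empirical p < 0.01 (most negative
= most extreme), merged when overlapping or book-ended.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TOP_FRACTION = 0.001
FST_P_MAX = 0.01
TAJIMA_P_MAX = 0.01
MAX_GAP_BP = 200_000
MIN_OUTLIER_SNPS = 2


@dataclass
class CandidateRegion:
    """Contiguous candidate interval, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    n_members: int               # outlier SNPs (composite) or windows (Tajima)
    min_p: float
    label: str = ""              # comparison label, e.g. "sweep-neutral"
    members: list = field(default_factory=list)   # member positions/starts

    def intersects(self, other: "CandidateRegion") -> bool:
        return (self.chrom == other.chrom and self.start <= other.end
                and other.start <= self.end)


def empirical_p(values, direction: str = "high") -> np.ndarray:
    """Empirical p-values by rank: p = rank / N, rank 1 = most extreme.

    ``direction`` "high" ranks the largest value most extreme, "low" the
    smallest.  Ties share the smallest rank of the tied run.  NaNs get
    p = NaN.  Fewer than 100 finite values triggers a resolution warning.
    """
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no finite values")
    if n < 100:
        warnings.warn(f"only {n} values: empirical p resolution is 1/{n}")
    v = values[ok]
    if np.all(v == v[0]):                 # degenerate track: no ranking
        p = np.full(values.shape, np.nan)
        p[ok] = 1.0
        return p
    key = -v if direction == "high" else v
    order = np.argsort(key, kind="mergesort")
    ranks = np.empty(n, dtype=float)
    sorted_key = key[order]
    # ties share the smallest rank of their run
    rank_of_sorted = np.arange(1, n + 1, dtype=float)
    for i in range(1, n):
        if sorted_key[i] == sorted_key[i - 1]:
            rank_of_sorted[i] = rank_of_sorted[i - 1]
    ranks[order] = rank_of_sorted
    p = np.full(values.shape, np.nan)
    p[ok] = ranks / n
    return p


def xpehh_outliers(track: pd.DataFrame, top_fraction: float = TOP_FRACTION,
                   direction: str = "high",
                   score_column: str = "std") -> pd.DataFrame:
    """SNPs in the extreme ``top_fraction`` tail of an XP-EHH track.

    ``direction`` "high" selects the tail indicating longer haplotypes in
    the first-named population; "low" the opposite tail.  Returns the
    outlier rows with their empirical p attached.
    """
    p = empirical_p(track[score_column].to_numpy(), direction=direction)
    out = track.copy()
    out["empirical_p"] = p
    return out[out["empirical_p"] <= top_fraction].reset_index(drop=True)


def _cluster_positions(pos: np.ndarray, max_gap_bp: int) -> list:
    """Single-linkage 1-D clustering: split where adjacent gap > max_gap."""
    if pos.size == 0:
        return []
    order = np.argsort(pos)
    pos = pos[order]
    breaks = np.flatnonzero(np.diff(pos) > max_gap_bp)
    clusters = np.split(pos, breaks + 1)
    return clusters


def call_composite_regions(outliers: pd.DataFrame, fst_track: pd.DataFrame,
                           max_gap_bp: int = MAX_GAP_BP,
                           min_outlier_snps: int = MIN_OUTLIER_SNPS,
                           fst_p_max: float = FST_P_MAX,
                           label: str = "") -> list:
    """Composite XP-EHH + F_ST candidate regions.

    Outlier SNPs (from :func:`xpehh_outliers`) are clustered per
    chromosome by single linkage within ``max_gap_bp``; clusters with at
    least ``min_outlier_snps`` members span [min pos, max pos] and are
    kept only when at least one SNP of ``fst_track`` inside that span has
    F_ST empirical p < ``fst_p_max``.  ``fst_track`` needs columns chrom,
    pos and either ``empirical_p`` or ``theta_clamped`` (in which case
    descending-rank empirical p is computed here).  An empty outlier set
    returns an empty list.
    """
    if "empirical_p" not in fst_track.columns:
        fst_track = fst_track.copy()
        fst_track["empirical_p"] = empirical_p(
            fst_track["theta_clamped"].to_numpy(), direction="high")

    regions = []
    for chrom in pd.unique(outliers["chrom"]) if len(outliers) else []:
        opos = outliers.loc[outliers["chrom"] == chrom, "pos"].to_numpy()
        ftr = fst_track[fst_track["chrom"] == chrom]
        fpos = ftr["pos"].to_numpy()
        fp = ftr["empirical_p"].to_numpy()
        op = outliers.loc[outliers["chrom"] == chrom].set_index("pos")["empirical_p"]
        for cluster in _cluster_positions(opos, max_gap_bp):
            if cluster.size < min_outlier_snps:
                continue
            start, end = int(cluster.min()), int(cluster.max())
            in_span = (fpos >= start) & (fpos <= end)
            if not (fp[in_span] < fst_p_max).any():
                continue
            regions.append(CandidateRegion(
                chrom=str(chrom), start=start, end=end,
                n_members=int(cluster.size),
                min_p=float(op.loc[cluster].min()),
                label=label, members=[int(x) for x in cluster]))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def call_tajima_regions(windows: pd.DataFrame, p_max: float = TAJIMA_P_MAX,
                        label: str = "") -> list:
    """Merge significant Tajima's D windows into candidate regions.

    ``windows`` must carry chrom, start, end, D and (optionally)
    ``empirical_p``; if absent, ascending-rank empirical p over the
    non-skipped windows is computed (most negative D = most extreme).
    Windows with p < ``p_max`` are merged when overlapping or book-ended;
    a region's span runs from the first window start to the last window
    end, so k consecutive windows of length w at step s give a region of
    w + (k-1)*s bp.
    """
    win = windows[~windows.get("skipped", pd.Series(False, index=windows.index))]
    win = win[np.isfinite(win["D"])].copy()
    if "empirical_p" not in win.columns:
        win["empirical_p"] = empirical_p(win["D"].to_numpy(), direction="low")
    sig = win[win["empirical_p"] < p_max].sort_values(["chrom", "start"])

    regions = []
    cur = None
    for row in sig.itertuples():
        if (cur is not None and row.chrom == cur["chrom"]
                and row.start <= cur["end"] + 1):
            cur["end"] = max(cur["end"], int(row.end))
            cur["n"] += 1
            cur["min_p"] = min(cur["min_p"], float(row.empirical_p))
            cur["members"].append(int(row.start))
        else:
            if cur is not None:
                regions.append(cur)
            cur = dict(chrom=str(row.chrom), start=int(row.start),
                       end=int(row.end), n=1,
                       min_p=float(row.empirical_p), members=[int(row.start)])
    if cur is not None:
        regions.append(cur)
    return [CandidateRegion(r["chrom"], r["start"], r["end"], r["n"],
                            r["min_p"], label=label, members=r["members"])
            for r in regions]


@dataclass
class OverlapResult:
    """Venn decomposition of labeled candidate-region lists."""

    unique_counts: dict              # label -> regions intersecting no other list
    venn_cells: dict                 # frozenset of labels -> component count
    pairwise: pd.DataFrame           # label x label: components with both

    @property
    def n_shared(self) -> int:
        return sum(c for k, c in self.venn_cells.items() if len(k) > 1)


def region_overlap(region_lists: dict) -> OverlapResult:
    """Overlap structure of two or more labeled candidate-region lists.

    Two regions are shared iff their genomic intervals intersect in at
    least 1 bp on the same chromosome.  Regions across all lists are
    merged into connected components (single linkage on intersection);
    each component contributes one count to the Venn cell keyed by the set
    of labels it contains.
    """
    if len(region_lists) < 2:
        raise ValueError("need >= 2 labeled region lists")
    flat = [(label, r) for label, regs in region_lists.items() for r in regs]
    n = len(flat)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if flat[i][1].intersects(flat[j][1]):
                parent[find(i)] = find(j)

    comps: dict[int, set] = {}
    for i, (label, _) in enumerate(flat):
        comps.setdefault(find(i), set()).add(label)

    venn_cells: dict[frozenset, int] = {}
    for labels in comps.values():
        key = frozenset(labels)
        venn_cells[key] = venn_cells.get(key, 0) + 1

    labels = list(region_lists)
    unique_counts = {lbl: 0 for lbl in labels}
    for i, (label, _) in enumerate(flat):
        if comps[find(i)] == {label}:
            unique_counts[label] += 1

    pw = pd.DataFrame(0, index=labels, columns=labels)
    for cell, cnt in venn_cells.items():
        for a in cell:
            for b in cell:
                pw.loc[a, b] += cnt
    return OverlapResult(unique_counts, venn_cells, pw)


def annotate_regions(regions: list, gene_intervals: pd.DataFrame) -> list:
    """Attach overlapping gene names (ordered by position) to each region.

    ``gene_intervals`` is a DataFrame with 1-based inclusive chrom, start,
    end, name (as returned by :func:`popsel.genotype_io.read_bed`).
    Returns ``(region, [gene names])`` pairs; nested genes are all listed.
    """
    out = []
    genes = gene_intervals.sort_values(["chrom", "start"])
    for r in regions:
        sub = genes[(genes["chrom"] == r.chrom)
                    & (genes["start"] <= r.end) & (genes["end"] >= r.start)]
        out.append((r, list(sub["name"])))
    return out


def regions_to_frame(regions: list) -> pd.DataFrame:
    """Candidate regions as a Table-2/3-style DataFrame (1-based coords)."""
    rows = [(r.chrom, r.start, r.end, r.end - r.start + 1, r.n_members,
             r.min_p, r.label) for r in regions]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "length_bp",
                                       "n_members", "min_p", "comparison"])
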