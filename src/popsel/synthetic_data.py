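"""Synthetic cohorts with known structure, sweeps, pedigrees and drift trees.

Every generator is a pure function of its spec plus an integer seed, so
downstream estimators (F_ST, KING kinship, PCA, XP-EHH, Tajima's D,
outgroup f3) can be validated against analytic ground truth:

* multi-population genotypes follow the Balding-Nichols model, whose
  expected Weir-Cockerham F_ST equals the ``fst_target`` parameter;
* sweep cohorts come from a discrete-generation Wright-Fisher forward
  simulation with Poisson crossovers, so hitchhiking actually shapes the
  haplotypes;
* pedigree cohorts are gene-dropped, with kinship/inbreeding truth from
  path counting;
* drift-tree frequencies diffuse root-to-leaf by per-branch
  Balding-Nichols perturbations, so shared branch length orders expected
  outgroup f3 values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .genotype_io import GenotypeMatrix, HaplotypeMatrix


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimSpec:
    """Parameters of a structured multi-population cohort."""

    n_pops: int
    samples_per_pop: int
    n_variants: int
    fst_target: float
    seed: int
    ancestral_freq_range: tuple = (0.05, 0.95)
    chrom_length_bp: int = 5_000_000
    # Forward simulations run at a small population-scaled size; the
    # per-bp recombination rate is scaled up by the same factor so that
    # the population recombination rate rho = 4*N*r per bp matches a
    # human-like population (N_e ~ 1e4 at 1e-8 crossovers/bp) and sweep
    # footprints have realistic extent relative to the chromosome.
    recomb_rate: float = 2e-7   # per bp per generation (scaled, see above)
    pop_size: int = 500         # WF diploid size in forward simulations
    chrom: str = "1"

    def __post_init__(self):
        if not (0 <= self.fst_target < 1):
            raise ValueError("fst_target must be in [0, 1)")
        if self.samples_per_pop < 2:
            raise ValueError("need samples_per_pop >= 2")
        if self.n_pops < 1 or self.n_variants < 1:
            raise ValueError("n_pops and n_variants must be positive")
        lo, hi = self.ancestral_freq_range
        if not (0 < lo < hi < 1):
            raise ValueError("ancestral_freq_range must satisfy 0 < lo < hi < 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def to_config(self) -> str:
        lines = []
        for f in self.__dataclass_fields__:
            v = getattr(self, f)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "SimSpec":
        kv = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            kv[k.strip()] = v.strip()
        return cls(
            n_pops=int(kv["n_pops"]),
            samples_per_pop=int(kv["samples_per_pop"]),
            n_variants=int(kv["n_variants"]),
            fst_target=float(kv["fst_target"]),
            seed=int(kv["seed"]),
            ancestral_freq_range=tuple(float(x) for x in
                                       kv["ancestral_freq_range"].split(",")),
            chrom_length_bp=int(kv["chrom_length_bp"]),
            recomb_rate=float(kv["recomb_rate"]),
            pop_size=int(kv.get("pop_size", 500)),
            chrom=kv.get("chrom", "1"),
        )


@dataclass(frozen=True)
class SweepSpec:
    """A recent hard sweep in one population of a two-population cohort."""

    target_pop: str
    s: float                     # per-generation selective advantage
    sweep_pos: int               # bp coordinate of the selected site
    # ~2 copies at the default pop_size: a single-origin (hard) sweep.
    # Larger values seed multiple founder haplotypes and soften the sweep.
    start_freq: float = 0.002
    generations: int = 200
    final_freq_min: float = 0.9
    max_retries: int = 100

    def __post_init__(self):
        if not (0 <= self.s <= 0.5):
            raise ValueError("selection coefficient must satisfy 0 <= s <= 0.5")
        if self.final_freq_min < self.start_freq:
            raise ValueError("final_freq_min must be >= start_freq")


@dataclass(frozen=True)
class PedigreeSpec:
    """A pedigree as founders plus (parentA, parentB, child) matings.

    Founder ids default to ``F0 .. F{founders-1}``; every child named in
    ``matings`` must have exactly two parents and the graph must be
    acyclic.  ``relationships`` optionally labels pairs of interest
    (e.g. ``{("F0","C1"): "parent-offspring"}``) and is carried through
    to the simulation output.
    """

    founders: int
    matings: tuple = ()
    relationships: tuple = ()    # ((idA, idB, label), ...)

    def individual_ids(self) -> list:
        ids = [f"F{i}" for i in range(self.founders)]
        for pa, pb, child in self.matings:
            if child in ids:
                raise ValueError(f"{child} defined twice")
            ids.append(child)
        return ids

    def validate(self) -> None:
        ids = set(f"F{i}" for i in range(self.founders))
        children = set()
        for pa, pb, child in self.matings:
            if pa not in ids or pb not in ids:
                raise ValueError(
                    f"parents of {child} must be defined before it "
                    "(cyclic or out-of-order pedigree)")
            if child in ids:
                raise ValueError(f"{child} has more than one mating record")
            ids.add(child)
            children.add(child)


@dataclass(frozen=True)
class DriftTreeSpec:
    """Population tree with per-branch drift, newick branch lengths = F.

    ``newick`` uses population labels as leaf names and branch lengths as
    Balding-Nichols drift amounts (variance scale of the frequency
    perturbation on that branch).  Exactly one leaf, named by
    ``outgroup``, is the outgroup.
    """

    newick: str
    outgroup: str

    def parse(self):
        import dendropy

        tree = dendropy.Tree.get(data=self.newick, schema="newick")
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if self.outgroup not in leaves:
            raise ValueError(f"outgroup {self.outgroup!r} not among leaves {leaves}")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("drift amounts must be >= 0")
        return tree


# ---------------------------------------------------------------------------
# Balding-Nichols structured genotypes
# ---------------------------------------------------------------------------

def _bn_freqs(rng, p: np.ndarray, F: float) -> np.ndarray:
    """Draw population frequencies around ancestral p with drift F."""
    if F == 0:
        return p.copy()
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    return rng.beta(a, b)


def simulate_structured_genotypes(spec: SimSpec):
    """Balding-Nichols cohort: returns (GenotypeMatrix, population labels).

    Ancestral frequencies are uniform on ``ancestral_freq_range``; each
    population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) with
    F = ``fst_target`` (F = 0 uses p directly), and genotypes are
    Binomial(2, pop frequency).  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    L, K, n = spec.n_variants, spec.n_pops, spec.samples_per_pop
    positions = np.sort(rng.choice(
        np.arange(1, spec.chrom_length_bp + 1), size=L, replace=False))
    p_anc = rng.uniform(*spec.ancestral_freq_range, size=L)

    pops = [f"pop{k + 1}" for k in range(K)]
    dosage = np.empty((K * n, L), dtype=np.int8)
    labels = np.repeat(pops, n)
    for k in range(K):
        pk = _bn_freqs(rng, p_anc, spec.fst_target)
        dosage[k * n:(k + 1) * n] = rng.binomial(2, pk, size=(n, L))

    variants = pd.DataFrame({
        "chrom": spec.chrom, "pos": positions,
        "id": [f"snp{j}" for j in range(L)],
        "ref": "A", "alt": "G",
    })
    samples = pd.DataFrame({
        "sample_id": [f"{lbl}_s{i % n}" for i, lbl in enumerate(labels)],
        "population": labels,
    })
    return GenotypeMatrix(dosage, variants, samples), labels


# ---------------------------------------------------------------------------
# Forward Wright-Fisher sweep simulator
# ---------------------------------------------------------------------------

@njit(cache=True)
def _meiosis_into(haps, i0, i1, positions, lam, chrom_length, out):
    """One recombinant gamete from the parent haplotypes at rows i0/i1."""
    src = i0 if np.random.random() < 0.5 else i1
    n_x = np.random.poisson(lam)
    if n_x == 0:
        out[:] = haps[src]
        return
    bps = np.sort(np.random.random(n_x) * chrom_length)
    k = 0
    for j in range(positions.shape[0]):
        while k < n_x and bps[k] <= positions[j]:
            src = i0 + i1 - src
            k += 1
        out[j] = haps[src, j]


@njit(cache=True)
def _evolve_pop(haps0, positions, chrom_length, recomb_rate, n_gens,
                sel_idx, s, seed):
    """Evolve one Wright-Fisher population in place; returns (haps, freq).

    Discrete generations, random mating, multiplicative fitness
    (1+s)^dosage at the selected site (``sel_idx``; -1 for none).  If the
    selected allele is lost the attempt aborts early with freq 0.

    Mutation-drift renewal: every few generations each monomorphic
    column (other than the selected site) is re-seeded as a fresh
    singleton in a random haplotype.  Since column positions are uniform
    on the chromosome this is an infinite-sites mutation process with
    recycled coordinates; it keeps the number of segregating sites and
    the site-frequency spectrum stationary, where a mutation-free forward
    phase would steadily purge rare variants and push Tajima's D up.
    """
    renew_every = 4
    np.random.seed(seed)
    n2, L = haps0.shape
    N = n2 // 2
    lam = recomb_rate * chrom_length
    cur = haps0.copy()
    nxt = np.empty_like(cur)
    w = np.empty(N)
    for gen in range(n_gens):
        if sel_idx >= 0 and s > 0.0:
            for i in range(N):
                d = cur[2 * i, sel_idx] + cur[2 * i + 1, sel_idx]
                w[i] = (1.0 + s) ** d
        else:
            for i in range(N):
                w[i] = 1.0
        cw = np.cumsum(w)
        tot = cw[-1]
        for i in range(N):
            p1 = np.searchsorted(cw, np.random.random() * tot)
            p2 = np.searchsorted(cw, np.random.random() * tot)
            _meiosis_into(cur, 2 * p1, 2 * p1 + 1, positions, lam,
                          chrom_length, nxt[2 * i])
            _meiosis_into(cur, 2 * p2, 2 * p2 + 1, positions, lam,
                          chrom_length, nxt[2 * i + 1])
        tmp = cur
        cur = nxt
        nxt = tmp
        if (gen + 1) % renew_every == 0 or gen == n_gens - 1:
            counts = np.zeros(L, dtype=np.int64)
            for r in range(n2):
                row = cur[r]
                for j in range(L):
                    counts[j] += row[j]
            for j in range(L):
                if j == sel_idx:
                    continue
                if counts[j] == 0:
                    cur[np.random.randint(n2), j] = 1
                elif counts[j] == n2:
                    cur[np.random.randint(n2), j] = 0
        if sel_idx >= 0 and s > 0.0:
            cnt = 0
            for r in range(n2):
                cnt += cur[r, sel_idx]
            if cnt == 0:
                return cur, 0.0
    if sel_idx >= 0:
        cnt = 0
        for r in range(n2):
            cnt += cur[r, sel_idx]
        return cur, cnt / n2
    return cur, -1.0


@dataclass
class SweepCohort:
    """Output of :func:`simulate_sweep_cohort`."""

    haplotypes: HaplotypeMatrix      # both populations, target first
    sweep_pos: int                   # true swept bp coordinate
    sweep_index: int                 # column index of the selected site
    sweep_interval: tuple            # (start, end) bp of the true footprint
    final_freq: float                # beneficial-allele frequency reached
    attempts: int                    # rejection-sampling attempts used


def _sweep_footprint(haps: np.ndarray, positions: np.ndarray, sel_idx: int,
                     smooth_snps: int = 25, rel_threshold: float = 0.5):
    """Physical footprint of a completed sweep: the diversity trough.

    Measured on the largest single-origin family among the haplotypes
    carrying the beneficial allele: carriers are grouped by identity over
    the ``smooth_snps`` SNPs around the selected site and the biggest
    group is taken (when the allele was seeded as more than one copy,
    several founder families can sweep together and their pooled
    diversity shows no trough even though each hitchhiked segment is
    real).  Expected heterozygosity 2p(1-p) per SNP within that family,
    smoothed by a ``smooth_snps`` moving average; the footprint is the
    contiguous run around the selected site where smoothed diversity is
    below ``rel_threshold`` times the chromosome-wide median — the span
    over which the family retains the homozygosity signature of its
    common origin.
    """
    carriers = haps[haps[:, sel_idx] == 1]
    if carriers.shape[0] >= 2:
        half = smooth_snps // 2
        lo_w = max(0, sel_idx - half)
        hi_w = min(haps.shape[1], sel_idx + half + 1)
        _, inv, counts = np.unique(carriers[:, lo_w:hi_w], axis=0,
                                   return_inverse=True, return_counts=True)
        family = carriers[inv == np.argmax(counts)]
        if family.shape[0] >= 2:
            haps = family
        else:
            haps = carriers
    p = haps.mean(axis=0)
    h = 2.0 * p * (1.0 - p)
    kernel = np.ones(smooth_snps) / smooth_snps
    hs = np.convolve(h, kernel, mode="same")
    low = hs < rel_threshold * np.median(hs)
    lo = sel_idx
    while lo > 0 and low[lo - 1]:
        lo -= 1
    hi = sel_idx
    while hi < low.size - 1 and low[hi + 1]:
        hi += 1
    return int(positions[lo]), int(positions[hi])


def simulate_sweep_cohort(spec: SimSpec, sweep: SweepSpec) -> SweepCohort:
    """Two-population phased cohort with a completed hard sweep in one.

    Both populations descend from a shared founder pool of
    ``spec.pop_size`` diploids (split at generation 0) and evolve under
    identical Wright-Fisher demography for ``sweep.generations``
    generations; only the target population carries selection at
    ``sweep.sweep_pos``.  At the end, ``spec.samples_per_pop`` diploids
    per population are sampled as the cohort — sampling from a larger
    population keeps pure drift from mimicking sweep-scale homozygosity.
    The selected run is rejection-sampled until the beneficial allele
    reaches ``final_freq_min`` (retry cap ``max_retries``), which
    conditions the trajectories on sweep completion exactly as a
    completed-sweep test case requires.
    """
    if spec.n_pops != 2:
        raise ValueError("sweep cohorts are two-population by construction")
    if not (0 < sweep.sweep_pos <= spec.chrom_length_bp):
        raise ValueError("sweep_pos outside the chromosome")
    if spec.pop_size < spec.samples_per_pop:
        raise ValueError("pop_size must be >= samples_per_pop")

    rng = np.random.default_rng(spec.seed)
    L = spec.n_variants
    n = spec.samples_per_pop
    n2 = 2 * spec.pop_size

    positions = np.sort(rng.choice(
        np.arange(1, spec.chrom_length_bp + 1), size=L, replace=False))
    # insert the selected site at its own coordinate
    if sweep.sweep_pos in positions:
        sel_idx = int(np.searchsorted(positions, sweep.sweep_pos))
    else:
        sel_idx = int(np.searchsorted(positions, sweep.sweep_pos))
        positions = np.insert(positions, sel_idx, sweep.sweep_pos)
        L += 1
    pos_f = positions.astype(np.float64)

    # Founder pool in linkage equilibrium with a neutral site-frequency
    # spectrum: allele counts k drawn with P(k) proportional to 1/k, then
    # assigned to exactly k haplotypes.  A uniform frequency draw would
    # leave far too few rare variants and push Tajima's D strongly
    # positive genome-wide.
    kk = np.arange(1, n2)
    sfs_w = (1.0 / kk) / (1.0 / kk).sum()
    counts = rng.choice(kk, size=L, p=sfs_w)
    u = rng.random((n2, L))
    order = np.argsort(u, axis=0)
    founders = np.zeros((n2, L), dtype=np.uint8)
    for j in range(L):
        founders[order[:counts[j], j], j] = 1
    n_init = max(1, int(round(sweep.start_freq * n2)))
    founders[:, sel_idx] = 0
    carriers = rng.choice(n2, size=n_init, replace=False)
    founders[carriers, sel_idx] = 1

    neutral_seed = int(rng.integers(2 ** 31 - 1))
    hapsB, _ = _evolve_pop(founders, pos_f, float(spec.chrom_length_bp),
                           spec.recomb_rate, sweep.generations, -1, 0.0,
                           neutral_seed)

    attempts = 0
    hapsA = None
    freq = 0.0
    while attempts < sweep.max_retries:
        attempts += 1
        attempt_seed = int(rng.integers(2 ** 31 - 1))
        hapsA, freq = _evolve_pop(
            founders, pos_f, float(spec.chrom_length_bp), spec.recomb_rate,
            sweep.generations, sel_idx, sweep.s, attempt_seed)
        if sweep.s == 0 or freq >= sweep.final_freq_min:
            break
    else:
        raise RuntimeError(
            f"sweep (s={sweep.s}, start_freq={sweep.start_freq}, "
            f"final_freq_min={sweep.final_freq_min}, N={n} diploids, "
            f"{sweep.generations} generations) not completed in "
            f"{sweep.max_retries} attempts")

    def sample_rows(haps):
        ind = np.sort(rng.choice(spec.pop_size, size=n, replace=False))
        rows = np.column_stack([2 * ind, 2 * ind + 1]).ravel()
        return haps[rows]

    alleles = np.vstack([sample_rows(hapsA), sample_rows(hapsB)])
    pops = [sweep.target_pop] * n + ["neutral"] * n
    variants = pd.DataFrame({
        "chrom": spec.chrom, "pos": positions,
        "id": [f"snp{j}" for j in range(L)],
        "ref": "A", "alt": "G",
    })
    variants.loc[sel_idx, "id"] = "sweep"
    samples = pd.DataFrame({
        "sample_id": [f"{p}_s{i % n}" for i, p in enumerate(pops)],
        "population": pops,
    })
    hm = HaplotypeMatrix(alleles, variants, samples)
    footprint = _sweep_footprint(hapsA, positions, sel_idx)
    return SweepCohort(hm, int(sweep.sweep_pos), sel_idx, footprint,
                       float(freq), attempts)


# ---------------------------------------------------------------------------
# Pedigree gene-dropping
# ---------------------------------------------------------------------------

def pedigree_kinship(ped: PedigreeSpec):
    """Expected kinship matrix and inbreeding vector by path counting.

    Tabular method: founders are unrelated and non-inbred
    (phi(i,i) = 1/2); a child's kinship with any earlier individual is the
    mean of its parents' kinships with that individual, and its
    self-kinship is (1 + phi(father, mother)) / 2.  The inbreeding
    coefficient of an individual is its parents' kinship.
    """
    ped.validate()
    ids = ped.individual_ids()
    index = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    phi = np.zeros((n, n))
    parents = {index[c]: (index[pa], index[pb]) for pa, pb, c in ped.matings}
    F = np.zeros(n)
    for i in range(n):
        if i in parents:
            fa, mo = parents[i]
            F[i] = phi[fa, mo]
            for j in range(i):
                phi[i, j] = phi[j, i] = 0.5 * (phi[fa, j] + phi[mo, j])
            phi[i, i] = 0.5 * (1 + F[i])
        else:
            phi[i, i] = 0.5
    return pd.DataFrame(phi, index=ids, columns=ids), pd.Series(F, index=ids)


def simulate_pedigree_cohort(ped: PedigreeSpec, n_loci: int = 20_000,
                             founder_freqs=None, seed: int = 0,
                             population: str = "ped"):
    """Gene-drop a pedigree at unlinked loci.

    Returns ``(GenotypeMatrix, expected kinship DataFrame, expected
    inbreeding Series)``.  Founder allele frequencies are supplied or
    drawn uniform(0.1, 0.9); children inherit one randomly chosen allele
    per parent per locus, loci independent (no linkage — kinship
    estimators assume independent markers).
    """
    rng = np.random.default_rng(seed)
    ids = ped.individual_ids()
    phi, F = pedigree_kinship(ped)
    if founder_freqs is None:
        founder_freqs = rng.uniform(0.1, 0.9, size=n_loci)
    else:
        founder_freqs = np.asarray(founder_freqs, dtype=float)
        n_loci = founder_freqs.size

    index = {s: i for i, s in enumerate(ids)}
    parents = {index[c]: (index[pa], index[pb]) for pa, pb, c in ped.matings}
    haps = np.empty((len(ids), 2, n_loci), dtype=np.uint8)
    for i in range(len(ids)):
        if i in parents:
            fa, mo = parents[i]
            pick_f = rng.integers(2, size=n_loci)
            pick_m = rng.integers(2, size=n_loci)
            cols = np.arange(n_loci)
            haps[i, 0] = haps[fa, pick_f, cols]
            haps[i, 1] = haps[mo, pick_m, cols]
        else:
            haps[i] = (rng.random((2, n_loci)) < founder_freqs).astype(np.uint8)

    dosage = haps.sum(axis=1).astype(np.int8)
    variants = pd.DataFrame({
        "chrom": "1", "pos": np.arange(1, n_loci + 1) * 1000,
        "id": [f"loc{j}" for j in range(n_loci)],
        "ref": "A", "alt": "G",
    })
    samples = pd.DataFrame({"sample_id": ids, "population": population})
    return GenotypeMatrix(dosage, variants, samples), phi, F


# ---------------------------------------------------------------------------
# Drift-tree allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class PopAlleleCounts:
    """Per-population alt-allele counts and totals (variants x pops)."""

    alt: pd.DataFrame
    tot: pd.DataFrame

    @property
    def populations(self) -> list:
        return list(self.alt.columns)

    def freq(self) -> pd.DataFrame:
        return self.alt / self.tot

    @classmethod
    def from_genotypes(cls, gm: GenotypeMatrix) -> "PopAlleleCounts":
        pops = pd.unique(gm.populations)
        alt = {}
        tot = {}
        for p in pops:
            idx = np.flatnonzero(gm.populations == p)
            sub = gm.dosage[idx]
            obs = sub != -1
            alt[p] = np.where(obs, sub, 0).sum(axis=0)
            tot[p] = 2 * obs.sum(axis=0)
        return cls(pd.DataFrame(alt), pd.DataFrame(tot))


def simulate_drift_tree_freqs(tree: DriftTreeSpec, n_variants: int, seed: int,
                              samples_per_pop: int = 50,
                              ancestral_freq_range=(0.05, 0.95)):
    """Evolve allele frequencies down a drift tree; returns counts + truth.

    The root frequency of each variant is uniform on
    ``ancestral_freq_range``; along each branch with drift F > 0 the
    frequency is perturbed by a Balding-Nichols Beta draw (F = 0 copies it
    unchanged).  Leaves are populations; each is then sampled as
    ``samples_per_pop`` diploids binomially to give allele counts.

    Returns ``(PopAlleleCounts, true_freqs DataFrame)``.  More shared
    branch length between two non-outgroup leaves implies a larger
    expected outgroup f3.
    """
    t = tree.parse()
    rng = np.random.default_rng(seed)
    p_root = rng.uniform(*ancestral_freq_range, size=n_variants)

    leaf_freqs = {}

    def descend(node, p):
        for child in node.child_nodes():
            Fb = child.edge.length or 0.0
            pc = _bn_freqs(rng, p, Fb)
            if child.is_leaf():
                leaf_freqs[child.taxon.label] = pc
            else:
                descend(child, pc)

    descend(t.seed_node, p_root)
    true_freqs = pd.DataFrame(leaf_freqs)
    tot = 2 * samples_per_pop
    alt = pd.DataFrame({
        pop: rng.binomial(tot, true_freqs[pop].to_numpy())
        for pop in true_freqs.columns
    })
    totals = pd.DataFrame(
        {pop: np.full(n_variants, tot) for pop in true_freqs.columns})
    return PopAlleleCounts(alt, totals), true_freqs
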