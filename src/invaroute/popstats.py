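"""Nuclear and mitochondrial summary statistics.

Per population/locus: allele number, rarefied allelic richness, observed
heterozygosity and unbiased gene diversity; across populations:
Weir-Cockerham theta and permutation tests of group differences; per
population/fragment: haplotype count/diversity, nucleotide diversity and
segregating sites; plus the fixed-order summary vector used by the ABC layer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "allelic_richness",
    "heterozygosities",
    "wc_fst",
    "sequence_diversity",
    "pairwise_difference_matrix",
    "mean_between_difference",
    "permutation_group_test",
    "summary_vector",
    "SummaryVector",
    "diversity_table",
]


def _log_comb(n: np.ndarray | float, k: float) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def allelic_richness(allele_counts, g: int) -> float:
    """Expected number of alleles in a rarefied sample of ``g`` gene copies.

    ``allele_counts`` are the per-allele copy numbers at one locus in one
    population (total N copies).  A = sum_i [1 - C(N-N_i, g)/C(N, g)];
    rarefaction is in gene copies (2 x the smallest diploid sample compared).
    """
    counts = np.asarray(allele_counts, dtype=np.int64)
    counts = counts[counts > 0]
    n_total = int(counts.sum())
    if g > n_total:
        raise ValueError(f"rarefaction size g={g} exceeds sample of {n_total} copies")
    if g < 1:
        raise ValueError("g must be >= 1")
    rest = n_total - counts
    with np.errstate(invalid="ignore"):
        log_ratio = _log_comb(rest, g) - _log_comb(n_total, g)
    prob_absent = np.where(rest >= g, np.exp(log_ratio), 0.0)
    return float(np.sum(1.0 - prob_absent))


def heterozygosities(genotypes) -> tuple[float, float]:
    """Observed heterozygosity and unbiased gene diversity for one locus.

    ``genotypes`` is an (n, 2) array of allele identifiers for n >= 2 diploid
    individuals.  Ho is the fraction of heterozygotes; Hs is the unbiased
    estimator 2n/(2n-1) * (1 - sum p_i^2).
    """
    geno = np.asarray(genotypes)
    n = geno.shape[0]
    if n < 2:
        raise ValueError("need at least 2 diploid individuals")
    ho = float(np.mean(geno[:, 0] != geno[:, 1]))
    alleles = geno.reshape(-1)
    _, counts = np.unique(alleles, return_counts=True)
    p = counts / counts.sum()
    two_n = 2 * n
    hs = two_n / (two_n - 1) * (1.0 - float(np.sum(p**2)))
    return ho, hs


def _wc_components_locus(pop_genos: list[np.ndarray]) -> tuple[float, float, float]:
    """Weir-Cockerham (1984) variance components (a, b, c) summed over
    alleles for one locus.  ``pop_genos`` is a list of (n_i, 2) arrays."""
    r = len(pop_genos)
    n_i = np.array([g.shape[0] for g in pop_genos], dtype=float)
    if np.any(n_i < 1):
        raise ValueError("every population needs at least 1 genotyped individual")
    nbar = n_i.mean()
    n_total = n_i.sum()
    nc = (n_total - np.sum(n_i**2) / n_total) / (r - 1)

    stacked = np.concatenate([g for g in pop_genos], axis=0)
    _, compact = np.unique(stacked.reshape(-1), return_inverse=True)
    compact = compact.reshape(-1, 2)
    n_alleles = int(compact.max()) + 1
    p_mat = np.empty((r, n_alleles))
    h_mat = np.empty((r, n_alleles))
    start = 0
    for i, g in enumerate(pop_genos):
        n = g.shape[0]
        block = compact[start: start + n]
        start += n
        p_mat[i] = np.bincount(block.reshape(-1), minlength=n_alleles) / (2.0 * n)
        het = block[block[:, 0] != block[:, 1]]
        h_mat[i] = np.bincount(het.reshape(-1), minlength=n_alleles) / float(n)

    pbar = n_i @ p_mat / n_total
    s2 = n_i @ (p_mat - pbar) ** 2 / ((r - 1) * nbar)
    hbar = n_i @ h_mat / n_total
    pq = pbar * (1.0 - pbar)
    a = (nbar / nc) * (s2 - (pq - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pq - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return float(a.sum()), float(b.sum()), float(c.sum())


def wc_fst(pop_genos_by_locus) -> float:
    """Multilocus Weir-Cockerham theta.

    ``pop_genos_by_locus`` is a list over loci; each entry a list over
    populations of (n_i, 2) genotype arrays.  Components are summed over
    alleles and loci before the ratio is taken.
    """
    if not pop_genos_by_locus:
        raise ValueError("no loci")
    if len(pop_genos_by_locus[0]) < 2:
        raise ValueError("need at least 2 populations")
    a_tot = d_tot = 0.0
    for pop_genos in pop_genos_by_locus:
        a, b, c = _wc_components_locus(pop_genos)
        a_tot += a
        d_tot += a + b + c
    if d_tot == 0.0:
        return 0.0
    return float(a_tot / d_tot)


def wc_fst_genotypes(genotypes_by_pop: dict[str, np.ndarray]) -> float:
    """Convenience wrapper: dict of pop -> (n, L, 2) arrays, all loci."""
    pops = list(genotypes_by_pop)
    n_loci = genotypes_by_pop[pops[0]].shape[1]
    return wc_fst(
        [[genotypes_by_pop[p][:, l, :] for p in pops] for l in range(n_loci)]
    )


# ---------------------------------------------------------------------------
# sequence statistics


def as_base_array(alignment) -> np.ndarray:
    """Coerce an alignment (list of strings or uint8 array) to an (n, L)
    uint8 array with 0..3 = ACGT and 4 = anything else (gap/ambiguity)."""
    if isinstance(alignment, np.ndarray) and alignment.dtype == np.uint8:
        return alignment
    seqs = [str(s).upper() for s in alignment]
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError("sequences have unequal lengths")
    lut = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    raw = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return lut[raw].reshape(len(seqs), -1)


def _clean_columns(aln: np.ndarray) -> np.ndarray:
    """Drop columns containing any non-ACGT symbol."""
    return aln[:, (aln < 4).all(axis=0)]


def sequence_diversity(alignment) -> tuple[int, float, float, int]:
    """(h, H, theta_pi, S) for one population's fragment alignment.

    h: distinct sequences; H: unbiased haplotype diversity
    n/(n-1) (1 - sum p_i^2); theta_pi: mean pairwise difference count;
    S: segregating sites.  Columns with gaps/ambiguity codes are excluded.
    """
    aln = _clean_columns(as_base_array(alignment))
    n = aln.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sequences")
    seg = np.ascontiguousarray(aln[:, (aln != aln[0]).any(axis=0)])
    s = seg.shape[1]
    if s == 0:
        return 1, 0.0, 0.0, 0
    hap_counts: dict[bytes, int] = {}
    for row in seg:
        key = row.tobytes()
        hap_counts[key] = hap_counts.get(key, 0) + 1
    counts = np.fromiter(hap_counts.values(), dtype=float)
    h = len(counts)
    p = counts / n
    hdiv = n / (n - 1) * (1.0 - float(np.sum(p**2)))
    diffs = (seg[:, None, :] != seg[None, :, :]).sum(axis=2)
    iu = np.triu_indices(n, 1)
    theta_pi = float(diffs[iu].mean()) if iu[0].size else 0.0
    return h, hdiv, theta_pi, s


def pairwise_difference_matrix(alignment) -> np.ndarray:
    """(n, n) matrix of pairwise difference counts (clean columns only)."""
    aln = _clean_columns(as_base_array(alignment))
    seg = aln[:, (aln != aln[0]).any(axis=0)]
    return (seg[:, None, :] != seg[None, :, :]).sum(axis=2)


def mean_between_difference(alignment_a, alignment_b) -> float:
    """Mean pairwise difference count between two populations' alignments."""
    a = as_base_array(alignment_a)
    b = as_base_array(alignment_b)
    if a.shape[1] != b.shape[1]:
        raise ValueError("alignments have different lengths")
    both = _clean_columns(np.concatenate([a, b], axis=0))
    aa, bb = both[: a.shape[0]], both[a.shape[0]:]
    seg_mask = (both != both[0]).any(axis=0)
    aa, bb = aa[:, seg_mask], bb[:, seg_mask]
    return float((aa[:, None, :] != bb[None, :, :]).sum(axis=2).mean())


# ---------------------------------------------------------------------------
# permutation group test


def _group_stat(
    stat: str,
    genotypes_by_pop: dict[str, np.ndarray],
    group_pops: list[str],
    g_rare: int,
) -> float:
    """Multilocus statistic for one group of populations."""
    if stat == "Fst":
        if len(group_pops) < 2:
            raise ValueError("Fst group statistic needs >= 2 populations")
        return wc_fst_genotypes({p: genotypes_by_pop[p] for p in group_pops})
    vals = []
    for p in group_pops:
        geno = genotypes_by_pop[p]
        for l in range(geno.shape[1]):
            if stat == "A":
                _, counts = np.unique(geno[:, l, :].reshape(-1), return_counts=True)
                vals.append(allelic_richness(counts, g_rare))
            else:
                ho, hs = heterozygosities(geno[:, l, :])
                vals.append(ho if stat == "Ho" else hs)
    return float(np.mean(vals))


def permutation_group_test(
    genotypes_by_pop: dict[str, np.ndarray],
    groups: dict[str, int],
    stat: str = "Hs",
    n_perm: int = 15_000,
    rng_seed: int | np.random.Generator = 0,
) -> dict:
    """Two-sided permutation test of a group difference in a multilocus
    statistic (one of ``A``, ``Ho``, ``Hs``, ``Fst``).

    Individuals are permuted among group labels while population sizes and
    the assignment of populations to groups are preserved; the p-value is
    the fraction of permutations whose absolute group difference is at least
    the observed one.
    """
    if stat not in ("A", "Ho", "Hs", "Fst"):
        raise ValueError(f"unknown statistic {stat!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    g0 = [p for p, g in groups.items() if g == 0]
    g1 = [p for p, g in groups.items() if g == 1]
    if not g0 or not g1:
        raise ValueError("both groups must be non-empty")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    pops = g0 + g1
    sizes = [genotypes_by_pop[p].shape[0] for p in pops]
    g_rare = 2 * min(sizes)
    pooled = np.concatenate([genotypes_by_pop[p] for p in pops], axis=0)
    bounds = np.cumsum([0] + sizes)

    def diff(by_pop: dict[str, np.ndarray]) -> float:
        return _group_stat(stat, by_pop, g0, g_rare) - _group_stat(
            stat, by_pop, g1, g_rare
        )

    observed = diff({p: genotypes_by_pop[p] for p in pops})
    n_total = pooled.shape[0]
    hits = 0
    for _ in range(n_perm):
        order = rng.permutation(n_total)
        shuffled = {
            p: pooled[order[bounds[i]: bounds[i + 1]]] for i, p in enumerate(pops)
        }
        if abs(diff(shuffled)) >= abs(observed) - 1e-12:
            hits += 1
    return {
        "stat": stat,
        "observed_difference": observed,
        "p_value": hits / n_perm,
        "n_perm": n_perm,
    }


# ---------------------------------------------------------------------------
# summary vector and diversity table


@dataclass(frozen=True)
class SummaryVector:
    """Fixed-order named vector of summary statistics for one dataset."""

    names: tuple[str, ...]
    values: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def delta_mu_squared(geno_a: np.ndarray, geno_b: np.ndarray) -> float:
    """Goldstein's (delta mu)^2: squared difference of mean allele size
    between two populations, averaged over loci.  Grows linearly with
    divergence time under stepwise mutation."""
    ma = geno_a.mean(axis=(0, 2))
    mb = geno_b.mean(axis=(0, 2))
    return float(np.mean((ma - mb) ** 2))


def size_based_rst(geno_a: np.ndarray, geno_b: np.ndarray) -> float:
    """Allele-size analogue of Fst for a population pair, multilocus.

    Rst = (S_total - S_within) / S_total with S the allele-size variance;
    components are summed over loci before the ratio.  Because numerator
    and denominator both scale with the mutation rate, the rate largely
    cancels, making Rst a cleaner divergence-time signal than Fst under
    stepwise mutation."""
    num = den = 0.0
    for l in range(geno_a.shape[1]):
        a = geno_a[:, l, :].reshape(-1).astype(float)
        b = geno_b[:, l, :].reshape(-1).astype(float)
        s_within = 0.5 * (a.var() + b.var())
        s_total = np.concatenate([a, b]).var()
        num += s_total - s_within
        den += s_total
    if den == 0.0:
        return 0.0
    return float(num / den)


def _microsat_pop_stats(geno: np.ndarray) -> tuple[float, float, float]:
    """(mean Na, mean unbiased He, mean allele-size variance) over loci."""
    n_loci = geno.shape[1]
    nas, hes, variances = [], [], []
    for l in range(n_loci):
        alleles = geno[:, l, :].reshape(-1)
        counts = np.bincount(alleles - alleles.min())
        counts = counts[counts > 0]
        nas.append(len(counts))
        p = counts / counts.sum()
        two_n = alleles.size
        hes.append(two_n / (two_n - 1) * (1.0 - float(np.sum(p**2))))
        variances.append(float(np.var(alleles, ddof=1)) if alleles.size > 1 else 0.0)
    return float(np.mean(nas)), float(np.mean(hes)), float(np.mean(variances))


def summary_vector(dataset) -> SummaryVector:
    """Deterministic fixed-order summary vector for a dataset.

    Per sampled population (canonical sorted order): mean Na, mean expected
    heterozygosity, mean allele-size variance over the microsatellite loci;
    haplotype count h, haplotype diversity H, nucleotide diversity theta_pi
    and segregating sites S over the concatenated mtDNA fragments.  Per
    population pair: microsatellite Weir-Cockerham theta and mean
    between-population pairwise sequence difference.
    """
    pops = sorted(dataset.populations)
    if not pops:
        raise ValueError("dataset has no sampled populations")
    names: list[str] = []
    values: list[float] = []
    seqs = {p: dataset.concat_sequences(p) for p in pops}
    for p in pops:
        na, he, var = _microsat_pop_stats(dataset.genotypes[p])
        h, hdiv, pi, s = sequence_diversity(seqs[p])
        names += [f"{p}:{k}" for k in ("Na", "He", "Vas", "h", "H", "pi", "S")]
        values += [na, he, var, float(h), hdiv, pi, float(s)]
    for pa, pb in itertools.combinations(pops, 2):
        theta = wc_fst_genotypes(
            {pa: dataset.genotypes[pa], pb: dataset.genotypes[pb]}
        )
        dxy = mean_between_difference(seqs[pa], seqs[pb])
        dmu2 = delta_mu_squared(dataset.genotypes[pa], dataset.genotypes[pb])
        rst = size_based_rst(dataset.genotypes[pa], dataset.genotypes[pb])
        names += [
            f"{pa}-{pb}:Fst", f"{pa}-{pb}:dxy", f"{pa}-{pb}:dmu2",
            f"{pa}-{pb}:Rst",
        ]
        values += [theta, dxy, dmu2, rst]
    return SummaryVector(tuple(names), np.asarray(values, dtype=float))


def diversity_table(dataset, rarefaction_g: int | None = None):
    """Per-population diversity summary as a pandas DataFrame (one row per
    population): n, mean Na, rarefied A, mean Ho, mean Hs, and the mtDNA
    h / H / theta_pi / S over the concatenated fragments."""
    import pandas as pd

    pops = sorted(dataset.populations)
    if rarefaction_g is None:
        rarefaction_g = 2 * min(dataset.genotypes[p].shape[0] for p in pops)
    rows = []
    for p in pops:
        geno = dataset.genotypes[p]
        n_loci = geno.shape[1]
        na, _, _ = _microsat_pop_stats(geno)
        richness, hos, hss = [], [], []
        for l in range(n_loci):
            _, counts = np.unique(geno[:, l, :].reshape(-1), return_counts=True)
            richness.append(allelic_richness(counts, rarefaction_g))
            ho, hs = heterozygosities(geno[:, l, :])
            hos.append(ho)
            hss.append(hs)
        h, hdiv, pi, s = sequence_diversity(dataset.concat_sequences(p))
        rows.append(
            {
                "population": p,
                "n": geno.shape[0],
                "Na": na,
                "A": float(np.mean(richness)),
                "Ho": float(np.mean(hos)),
                "Hs": float(np.mean(hss)),
                "h": h,
                "H": hdiv,
                "theta_pi": pi,
                "S": s,
            }
        )
    return pd.DataFrame(rows).set_index("population")
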