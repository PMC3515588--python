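"""Structured-coalescent simulation under a demographic scenario, with
stepwise-mutation microsatellites and HKY sequence evolution overlaid.

Genealogies are simulated backward in time with piecewise-constant population
sizes: founded populations sit at founder size during their bottleneck window
and at their stable size before it; at a founding event all remaining lineages
of the target move to the source; at an admixed founding each lineage moves
independently to one of the two sources.  Waiting times are exponential
(continuous-time approximation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from invaroute.demography import (
    ParameterDraw,
    Scenario,
    ScenarioError,
    resolve_event_times,
)

__all__ = [
    "SampleConfig",
    "Genealogy",
    "HKYModel",
    "SimDataset",
    "simulate_genealogy",
    "mutate_microsat",
    "mutate_sequence",
    "simulate_dataset",
    "N_MICROSAT_LOCI",
    "FRAGMENT_LENGTHS",
]

#: number of microsatellite loci per dataset
N_MICROSAT_LOCI = 5
#: lengths (bp) of the two mtDNA fragments
FRAGMENT_LENGTHS = {"frag600": 600, "frag400": 400}

@dataclass(frozen=True)
class SampleConfig:
    """Sample sizes per sampled population.

    ``diploids`` maps population name to the number of diploid individuals
    genotyped at the microsatellites; ``sequences`` maps population name to
    the number of haploid mtDNA sequences per fragment.
    """

    diploids: dict[str, int]
    sequences: dict[str, int]

    def __post_init__(self):
        for d in (self.diploids, self.sequences):
            for pop, n in d.items():
                if n < 0:
                    raise ValueError(f"negative sample count for {pop!r}")

    @classmethod
    def uniform(cls, populations, n_diploids: int = 30, n_sequences: int = 10):
        pops = list(populations)
        return cls(
            diploids={p: n_diploids for p in pops},
            sequences={p: n_sequences for p in pops},
        )


@dataclass
class Genealogy:
    """A binary coalescent tree over sampled lineages of one locus.

    Nodes ``0..n_tips-1`` are tips at time 0; internal nodes are created in
    coalescence order, so a parent always has a larger index than its
    children and the root is the last node.  ``parent[root] == -1``.
    """

    n_tips: int
    parent: np.ndarray  # (n_nodes,) int32
    time: np.ndarray  # (n_nodes,) float64, generations before present
    tip_populations: tuple[str, ...] = ()

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (root entry 0)."""
        lens = np.zeros(self.n_nodes)
        nonroot = self.parent >= 0
        lens[nonroot] = self.time[self.parent[nonroot]] - self.time[nonroot]
        return lens

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])


@dataclass(frozen=True)
class HKYModel:
    """HKY substitution model with invariant sites and gamma rate variation.

    ``rate`` is the expected number of substitutions per variable site per
    generation at rate-multiplier 1 (the matrix is normalised so the mean
    flux at stationarity is 1).
    """

    length: int
    rate: float
    prop_invariant: float = 0.40
    gamma_shape: float = 0.30
    kappa: float = 2.0
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if not 0.0 <= self.prop_invariant <= 1.0:
            raise ValueError("prop_invariant must be in [0, 1]")
        if abs(sum(self.freqs) - 1.0) > 1e-8 or min(self.freqs) < 0:
            raise ValueError("base frequencies must be non-negative and sum to 1")

    def rate_matrix(self) -> np.ndarray:
        """Normalised HKY rate matrix (mean substitution flux 1)."""
        pi = np.asarray(self.freqs, dtype=float)
        q = np.tile(pi, (4, 1))
        # transitions: A<->G (0,2), C<->T (1,3)
        for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):
            q[i, j] *= self.kappa
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mean_rate = -(pi * np.diag(q)).sum()
        return q / mean_rate


@dataclass
class SimDataset:
    """One simulated (or observed) dual-marker dataset.

    ``genotypes`` maps population name to an ``(n, L, 2)`` int array of
    microsatellite repeat scores; ``sequences`` maps fragment name to a dict
    of population name -> ``(n_seq, length)`` uint8 base-index arrays
    (0..3 = ACGT, 4 = other/gap).
    """

    populations: list[str]
    genotypes: dict[str, np.ndarray]
    sequences: dict[str, dict[str, np.ndarray]]
    provenance: dict = field(default_factory=dict)

    @property
    def fragment_names(self) -> list[str]:
        return list(self.sequences)

    def concat_sequences(self, pop: str) -> np.ndarray:
        """All fragments of one population concatenated column-wise."""
        return np.concatenate(
            [self.sequences[f][pop] for f in self.fragment_names], axis=1
        )

    def equals(self, other: "SimDataset") -> bool:
        if self.populations != other.populations:
            return False
        if set(self.sequences) != set(other.sequences):
            return False
        for p in self.populations:
            if not np.array_equal(self.genotypes[p], other.genotypes[p]):
                return False
            for f in self.sequences:
                if not np.array_equal(self.sequences[f][p], other.sequences[f][p]):
                    return False
        return True


# ---------------------------------------------------------------------------
# genealogy simulation


class _NodeStore:
    __slots__ = ("parent", "time", "count")

    def __init__(self, n_tips: int):
        size = max(2 * n_tips - 1, 1)
        self.parent = np.full(size, -1, dtype=np.int32)
        self.time = np.zeros(size)
        self.count = n_tips

    def merge(self, a: int, b: int, t: float) -> int:
        new = self.count
        self.count = new + 1
        self.parent[a] = new
        self.parent[b] = new
        self.time[new] = t
        return new


def _coalesce_interval(
    ids: list[int],
    t0: float,
    t1: float,
    pair_rate_denom: float,
    rng: np.random.Generator,
    store: _NodeStore,
) -> None:
    """Coalesce lineages in ``ids`` (in place) on [t0, t1) with pairwise
    coalescence rate k(k-1)/2 / pair_rate_denom per generation."""
    k = len(ids)
    if k < 2:
        return
    js = np.arange(k, 1, -1, dtype=np.float64)
    waits = rng.exponential(size=k - 1) * (2.0 * pair_rate_denom) / (js * (js - 1.0))
    times = t0 + np.cumsum(waits)
    n_merge = int(np.searchsorted(times, t1)) if np.isfinite(t1) else k - 1
    if n_merge == 0:
        return
    hi1 = np.arange(k, k - n_merge, -1)
    pick1 = rng.integers(0, hi1)
    pick2 = rng.integers(0, hi1 - 1)
    for e in range(n_merge):
        i = int(pick1[e])
        j = int(pick2[e])
        if j >= i:
            j += 1
        new = store.merge(ids[i], ids[j], float(times[e]))
        ids[i] = new
        ids[j] = ids[-1]
        ids.pop()


def simulate_genealogy(
    s: Scenario,
    draw: ParameterDraw,
    sample_counts: dict[str, int],
    ploidy_mode: str,
    rng_seed: int | np.random.Generator,
) -> Genealogy:
    """Simulate one genealogy under the structured coalescent of ``s``.

    ``sample_counts`` gives the number of sampled *lineages* per population
    (gene copies for nuclear loci, sequences for mtDNA).  ``ploidy_mode`` is
    ``"diploid-nuclear"`` (pair coalescence rate 1/(2N)) or
    ``"haploid-mtDNA"`` (rate 1/N; every hermaphroditic individual transmits
    mtDNA, so the mitochondrial effective size equals the census size here).
    """
    if ploidy_mode not in ("diploid-nuclear", "haploid-mtDNA"):
        raise ValueError(f"unknown ploidy mode {ploidy_mode!r}")
    ploidy_factor = 2.0 if ploidy_mode == "diploid-nuclear" else 1.0
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )

    events = resolve_event_times(s, draw)
    root_pop = s.root

    # founding time and event per founded population
    founded: dict[str, tuple[float, float, int]] = {}  # pop -> (t, db, Nm)
    for t, e in events:
        founded[e.target] = (t, e.bottleneck_duration, e.founders)

    def size_at(pop: str, t: float) -> float:
        spec = s.population(pop)
        if pop in founded:
            tf, db, nm = founded[pop]
            if t > tf:
                raise ScenarioError(
                    f"lineages present in {pop!r} after its founding time"
                )
            if t > tf - db:
                return float(nm)
        return float(spec.stable_size)

    # tips, ordered by sorted population name for canonical layout
    pops_in_order = [p for p in sorted(sample_counts) if sample_counts[p] > 0]
    tip_pops: list[str] = []
    active: dict[str, list[int]] = {p.name: [] for p in s.populations}
    nid = 0
    for p in pops_in_order:
        if p not in active:
            raise ScenarioError(f"sample requested in unknown population {p!r}")
        if not s.population(p).sampled:
            raise ScenarioError(f"sample requested in unsampled population {p!r}")
        for _ in range(sample_counts[p]):
            active[p].append(nid)
            tip_pops.append(p)
            nid += 1
    n_tips = nid
    if n_tips == 0:
        raise ValueError("no lineages sampled")
    store = _NodeStore(n_tips)
    if n_tips == 1:
        return Genealogy(1, store.parent[:1].copy(), store.time[:1].copy(),
                         tuple(tip_pops))

    # epoch boundaries: each event time and each bottleneck start
    boundaries = sorted(
        {t for t, _ in events} | {max(t - e.bottleneck_duration, 0.0) for t, e in events}
    )
    t_prev = 0.0
    for b in boundaries:
        if b > t_prev:
            mid = 0.5 * (t_prev + b)
            for pop, ids in active.items():
                if len(ids) >= 2:
                    _coalesce_interval(
                        ids, t_prev, b, ploidy_factor * size_at(pop, mid), rng, store
                    )
        # apply the demographic events scheduled exactly at b
        for t, e in events:
            if t != b:
                continue
            ids = active[e.target]
            if not ids:
                continue
            if e.kind == "founding":
                active[e.sources[0]].extend(ids)
            else:  # admixture
                r = float(draw[e.admixture_param])
                goes_first = rng.random(len(ids)) < r
                for lid, g in zip(ids, goes_first):
                    active[e.sources[0] if g else e.sources[1]].append(lid)
            active[e.target] = []
        t_prev = b

    for pop, ids in active.items():
        if pop != root_pop and ids:
            raise ScenarioError(
                f"lineages stranded in {pop!r}: root unreachable (mis-specified scenario)"
            )
    root_ids = active[root_pop]
    _coalesce_interval(
        root_ids,
        t_prev,
        np.inf,
        ploidy_factor * s.population(root_pop).stable_size,
        rng,
        store,
    )
    return Genealogy(n_tips, store.parent.copy(), store.time.copy(), tuple(tip_pops))


# ---------------------------------------------------------------------------
# mutation overlay


def mutate_microsat(
    g: Genealogy, rate: float, rng_seed: int | np.random.Generator
) -> np.ndarray:
    """Overlay stepwise mutations; return the tip repeat scores.

    Mutations are Poisson(rate x branch length) per branch; each mutation
    shifts the repeat score by +1 or -1 with probability 1/2.  The ancestral
    score is 0 (scores are relative; unbounded).
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    lens = g.branch_lengths()
    n_mut = rng.poisson(rate * lens)
    # net displacement on a branch with m mutations: 2*Binomial(m, 1/2) - m
    net = 2 * rng.binomial(n_mut, 0.5) - n_mut
    values = np.zeros(g.n_nodes, dtype=np.int64)
    parent = g.parent
    # parents always have higher indices; fill root-down
    for i in range(g.n_nodes - 2, -1, -1):
        values[i] = values[parent[i]] + net[i]
    return values[: g.n_tips].copy()


def mutate_sequence(
    g: Genealogy, m: HKYModel, rng_seed: int | np.random.Generator
) -> np.ndarray:
    """Evolve sequences down the genealogy; return (n_tips, length) uint8
    base indices.

    Each site is invariant with probability ``prop_invariant``; variable
    sites get an iid Gamma(shape, mean 1) rate multiplier.  Substitutions
    follow the HKY jump chain via uniformisation (exact given the virtual
    event counts).
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    L = m.length
    pi = np.asarray(m.freqs)
    root_seq = rng.choice(4, size=L, p=pi).astype(np.uint8)
    tips = np.tile(root_seq, (g.n_tips, 1))
    if m.rate == 0 or m.prop_invariant >= 1.0 or g.n_tips < 2:
        return tips

    q = m.rate_matrix()
    lam = float(np.max(-np.diag(q)))
    jump = np.eye(4) + q / lam  # rows sum to 1
    jump_cum = np.cumsum(jump, axis=1)

    invariant = rng.random(L) < m.prop_invariant
    rates = np.zeros(L)
    n_var = int((~invariant).sum())
    if n_var:
        rates[~invariant] = rng.gamma(m.gamma_shape, 1.0 / m.gamma_shape, size=n_var)

    lens = g.branch_lengths()
    tree_len = lens.sum()
    if tree_len <= 0:
        return tips
    n_events = rng.poisson(lam * m.rate * tree_len * rates)
    hit_sites = np.nonzero(n_events)[0]
    if hit_sites.size == 0:
        return tips

    branch_p = lens / tree_len
    parent = g.parent
    n_nodes = g.n_nodes
    n_tips = g.n_tips
    for site in hit_sites:
        k = int(n_events[site])
        per_branch = rng.multinomial(k, branch_p)
        state = np.empty(n_nodes, dtype=np.uint8)
        state[n_nodes - 1] = root_seq[site]
        for node in range(n_nodes - 2, -1, -1):
            b = state[parent[node]]
            cnt = per_branch[node]
            for _ in range(cnt):
                b = np.searchsorted(jump_cum[b], rng.random())
            state[node] = b
        tips[:, site] = state[:n_tips]
    return tips


# ---------------------------------------------------------------------------
# full dataset simulation


def simulate_dataset(
    s: Scenario,
    draw: ParameterDraw,
    cfg: SampleConfig,
    rng_seed: int,
    fragment_lengths: dict[str, int] | None = None,
    n_loci: int = N_MICROSAT_LOCI,
) -> SimDataset:
    """Simulate a full dual-marker dataset under one parameter draw.

    Microsatellite loci get independent diploid-nuclear genealogies with
    per-locus rates drawn from Gamma(shape 2, mean ``micro_mean_mu``).  The
    mtDNA fragments are fully linked: one haploid genealogy per dataset
    carries both fragments, mutated at per-site rate ``mt_mu``.
    """
    fragment_lengths = fragment_lengths or FRAGMENT_LENGTHS
    ss = np.random.SeedSequence(rng_seed)
    rng = np.random.default_rng(ss)

    sampled = [
        p
        for p in sorted(set(cfg.diploids) | set(cfg.sequences))
        if cfg.diploids.get(p, 0) > 0 or cfg.sequences.get(p, 0) > 0
    ]

    # microsatellites: per-locus rates around the drawn mean
    mean_mu = float(draw["micro_mean_mu"])
    locus_rates = rng.gamma(2.0, mean_mu / 2.0, size=n_loci)
    gene_counts = {p: 2 * cfg.diploids.get(p, 0) for p in sampled}
    geno_cols: list[dict[str, np.ndarray]] = []
    for locus in range(n_loci):
        g = simulate_genealogy(s, draw, gene_counts, "diploid-nuclear", rng)
        scores = mutate_microsat(g, locus_rates[locus], rng)
        tip_pops = np.asarray(g.tip_populations)
        geno_cols.append(
            {p: scores[tip_pops == p].reshape(-1, 2) for p in sampled}
        )
    genotypes = {
        p: np.stack([geno_cols[l][p] for l in range(n_loci)], axis=1)
        for p in sampled
    }

    # mtDNA: one genealogy shared by both fragments
    seq_counts = {p: cfg.sequences.get(p, 0) for p in sampled}
    mt_mu = float(draw["mt_mu"])
    gm = simulate_genealogy(s, draw, seq_counts, "haploid-mtDNA", rng)
    tip_pops_mt = np.asarray(gm.tip_populations)
    sequences: dict[str, dict[str, np.ndarray]] = {}
    for frag, length in fragment_lengths.items():
        model = HKYModel(length=length, rate=mt_mu)
        aln = mutate_sequence(gm, model, rng)
        sequences[frag] = {p: aln[tip_pops_mt == p] for p in sampled}

    return SimDataset(
        populations=sampled,
        genotypes=genotypes,
        sequences=sequences,
        provenance={
            "scenario": s.label,
            "draw": dict(draw.values),
            "seed": int(rng_seed),
            "locus_rates": locus_rates.tolist(),
        },
    )
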