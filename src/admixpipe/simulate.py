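"""Synthetic genotype datasets with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a serial-founder chain of source populations whose heterozygosity
declines along a geographic route (Balding-Nichols drift per colonization
step), two differentiated colonist sources, hybrid populations formed by a
single admixture pulse ``g`` generations ago (so per-individual ancestry
fraction variance is s(1-s)/2^g), genotype missingness, and a synthetic
recombination map with planted low-recombination runs whose block
boundaries are known in advance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, IndividualRecord, SNPRecord


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed (< 2^31) from a master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class AdmixedPopSpec:
    label: str
    s: dict[str, float]  # colonist source label -> founding fraction
    g: int  # generations since the pulse
    n_individuals: int
    latitude: float = 0.0
    longitude: float = 0.0
    indigenous_parent: str | None = None  # route population providing the rest


@dataclass
class SimulationConfig:
    n_snps: int = 5000
    # (label, latitude degN, longitude degE) along the colonization route
    route: list[tuple[str, float, float]] = field(default_factory=list)
    drift_F_per_step: float = 0.02
    colonist_sources: list[tuple[str, float]] = field(default_factory=list)  # (label, F from root)
    admixed_pops: list[AdmixedPopSpec] = field(default_factory=list)
    n_per_route_pop: int = 20
    n_per_colonist_pop: int = 20
    missing_rate: float = 0.005
    pedigree_size: int = 500
    seed: int = 0
    # haplotype-pool mode: within planted low-recombination blocks draw
    # individual haplotypes from a finite population-specific pool
    haplotype_pool_size: int = 0  # 0 disables

    def __post_init__(self):
        if not 0 < self.drift_F_per_step < 1:
            raise ValueError("drift_F_per_step must lie in (0,1)")
        for _, F in self.colonist_sources:
            if not 0 < F < 1:
                raise ValueError("colonist F must lie in (0,1)")
        for spec in self.admixed_pops:
            if spec.g < 1:
                raise ValueError("g must be >= 1")
            if sum(spec.s.values()) > 1 + 1e-12:
                raise ValueError("admixture fractions exceed 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0,1)")


@dataclass
class AncestryTruth:
    """True per-individual ancestry fractions, rows summing to one."""

    individual_ids: list[str]
    sources: list[str]
    fractions: np.ndarray  # n x K

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if not np.allclose(self.fractions.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("ancestry fractions must sum to 1 per individual")

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.fractions, columns=self.sources)
        df.insert(0, "individual_id", self.individual_ids)
        df.to_csv(path, sep="\t", index=False)


@dataclass
class SyntheticRecombinationMap:
    """Per-chromosome (position_bp, rate cM/Mb) rows with planted low-rate runs."""

    rows: pd.DataFrame  # columns: chromosome, position_bp, rate_cM_per_Mb
    planted_runs: list[tuple[int, int, int]]  # (chromosome, first SNP idx, last SNP idx)

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Draw drifted frequencies p' ~ Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    ratio = (1 - F) / F
    out = rng.beta(np.maximum(p * ratio, 1e-12), np.maximum((1 - p) * ratio, 1e-12))
    return np.clip(out, 1e-9, 1 - 1e-9)


def simulate_source_frequencies(cfg: SimulationConfig) -> pd.DataFrame:
    """Per-population allele-2 frequencies: root -> serial-founder chain + colonists.

    Root frequencies are Uniform(0.05, 0.95); each step along the route and
    each colonist source applies one Balding-Nichols draw, compounding
    drift along the chain.
    """
    rng = np.random.default_rng(stage_seed(cfg.seed, "source_frequencies"))
    root = rng.uniform(0.05, 0.95, size=cfg.n_snps)
    freqs: dict[str, np.ndarray] = {}
    parent = root
    for label, _lat, _lon in cfg.route:
        parent = _balding_nichols(rng, parent, cfg.drift_F_per_step)
        freqs[label] = parent
    for label, F in cfg.colonist_sources:
        freqs[label] = _balding_nichols(rng, root, F)
    return pd.DataFrame(freqs).T  # populations x SNPs


def simulate_admixture_fractions(
    n: int, s_vector: dict[str, float] | list[float], g: int, seed: int,
    pedigree_size: int = 500,
) -> AncestryTruth:
    """Monte-Carlo pedigree ancestry fractions after a single pulse.

    Founding-generation individuals have H = (X_m + X_f)/2 with parental
    source labels i.i.d. from ``s_vector``; each later generation draws two
    parents uniformly at random from the previous hybrid generation and
    averages their fractions.  Returns the generation-``g`` fractions for
    ``n`` sampled individuals.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if g < 1:
        raise ValueError("g must be >= 1")
    if isinstance(s_vector, dict):
        sources = list(s_vector)
        s = np.array([s_vector[k] for k in sources], dtype=float)
    else:
        s = np.asarray(s_vector, dtype=float)
        sources = [f"source{k}" for k in range(len(s))]
    if np.any(s < 0) or abs(s.sum() - 1) > 1e-9:
        raise ValueError("s components must be in [0,1] and sum to 1")

    rng = np.random.default_rng(seed)
    K = len(s)
    m = max(pedigree_size, n)
    # generation 1 (the pulse): average of two founder source labels
    labels_m = rng.choice(K, size=m, p=s)
    labels_f = rng.choice(K, size=m, p=s)
    H = (np.eye(K)[labels_m] + np.eye(K)[labels_f]) / 2.0
    for _ in range(g - 1):
        pa = rng.integers(0, m, size=m)
        pb = rng.integers(0, m, size=m)
        H = (H[pa] + H[pb]) / 2.0
    take = rng.choice(m, size=n, replace=False)
    H = H[take]
    ids = [f"ind{i}" for i in range(n)]
    return AncestryTruth(individual_ids=ids, sources=sources, fractions=H)


def simulate_genotypes(
    freqs: pd.DataFrame,
    truth: AncestryTruth,
    missing_rate: float,
    seed: int,
    population: str = "admixed",
    chromosome_of: np.ndarray | None = None,
    positions: np.ndarray | None = None,
    id_prefix: str = "",
) -> GenotypeMatrix:
    """Binomial genotypes from per-individual mixture allele frequencies.

    Individual i's allele-2 frequency at SNP l is sum_k H_ik f_kl; the
    dosage is Binomial(2, .), then masked MISSING i.i.d. at missing_rate.
    """
    f = freqs.loc[truth.sources].to_numpy()  # K x L
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("allele frequencies must lie in [0,1]")
    rng = np.random.default_rng(seed)
    p = truth.fractions @ f  # n x L
    dosage = rng.binomial(2, p).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(dosage.shape) < missing_rate
        dosage[mask] = MISSING
    n, L = dosage.shape
    if chromosome_of is None:
        chromosome_of = np.ones(L, dtype=int)
    if positions is None:
        positions = np.arange(1, L + 1) * 10_000
    snps = [
        SNPRecord(
            identifier=f"snp{j}",
            chromosome=int(chromosome_of[j]),
            position_bp=int(positions[j]),
            allele1="A",
            allele2="G",
        )
        for j in range(L)
    ]
    individuals = [
        IndividualRecord(individual_id=f"{id_prefix}{iid}", population=population)
        for iid in truth.individual_ids
    ]
    return GenotypeMatrix(individuals=individuals, snps=snps, dosage=dosage)


def simulate_recombination_map(
    cfg: SimulationConfig,
    low_rate: float = 0.1,
    high_rate: float = 2.0,
    run_length_range: tuple[int, int] = (5, 15),
    n_chromosomes: int = 2,
) -> SyntheticRecombinationMap:
    """Synthetic map with planted low-rate runs of known extents.

    SNPs are placed every 10 kb; between consecutive SNPs the map carries
    points at low_rate inside planted runs (< 0.5 cM/Mb) and high_rate
    elsewhere, so the expected block boundaries are the planted runs.
    """
    if cfg.n_snps < 20:
        raise ValueError("need at least 20 SNPs")
    rng = np.random.default_rng(stage_seed(cfg.seed, "recombination_map"))
    per_chrom = cfg.n_snps // n_chromosomes
    rows = []
    planted = []
    snp_index = 0
    for chrom in range(1, n_chromosomes + 1):
        n = per_chrom if chrom < n_chromosomes else cfg.n_snps - per_chrom * (n_chromosomes - 1)
        # per-interval rates: high everywhere, low inside planted runs
        rates = np.full(n - 1, high_rate)
        j = 0
        while j < n:
            run = int(rng.integers(run_length_range[0], run_length_range[1] + 1))
            gap = int(rng.integers(2, 6))
            if j + run <= n:
                planted.append((chrom, snp_index + j, snp_index + j + run - 1))
                rates[j : j + run - 1] = low_rate
            j += run + gap
        # SNP k sits at position 10000*k + 1; one map point per interval midpoint
        for k in range(n - 1):
            rows.append((chrom, k * 10_000 + 5_001, rates[k]))
        snp_index += n
    df = pd.DataFrame(rows, columns=["chromosome", "position_bp", "rate_cM_per_Mb"])
    return SyntheticRecombinationMap(rows=df, planted_runs=planted)


def _apply_haplotype_pools(
    g: GenotypeMatrix,
    freqs: pd.DataFrame,
    truth_by_pop: dict[str, AncestryTruth],
    runs: list[tuple[int, int, int]],
    pool_size: int,
    seed: int,
) -> None:
    """Replace genotypes inside planted runs with draws from finite haplotype pools.

    For each population and planted run, a pool of ``pool_size`` haplotypes
    is drawn from the population's (majority-ancestry) allele frequencies;
    each individual then draws two pool haplotypes.  This creates real
    within-block linkage disequilibrium and bounded haplotype diversity.
    """
    rng = np.random.default_rng(seed)
    pops = g.populations()
    for pop in pops:
        rows = g.individual_index(pop)
        truth = truth_by_pop[pop]
        mean_h = truth.fractions.mean(axis=0)
        f_mix = mean_h @ freqs.loc[truth.sources].to_numpy()
        for chrom, lo, hi in runs:
            width = hi - lo + 1
            pool = (rng.random((pool_size, width)) < f_mix[lo : hi + 1]).astype(np.int8)
            pick = rng.integers(0, pool_size, size=(len(rows), 2))
            g.dosage[np.ix_(rows, range(lo, hi + 1))] = pool[pick[:, 0]] + pool[pick[:, 1]]


def make_study_fixture(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, SyntheticRecombinationMap, AncestryTruth]:
    """Complete dataset mimicking the study design.

    Produces a serial-founder route of source populations with declining
    heterozygosity, two colonist sources, and admixed coastal-like and
    interior-like populations with distinct source mixes and pulse times.
    Returns (genotypes, population table, recombination map, ancestry truth).
    """
    if not cfg.route:
        cfg = default_config(seed=cfg.seed, n_snps=cfg.n_snps,
                             missing_rate=cfg.missing_rate,
                             haplotype_pool_size=cfg.haplotype_pool_size)
    freqs = simulate_source_frequencies(cfg)
    rec_map = simulate_recombination_map(cfg)
    L = cfg.n_snps
    chrom_of = np.empty(L, dtype=int)
    positions = np.empty(L, dtype=int)
    per_chrom = L // 2
    chrom_of[:per_chrom] = 1
    chrom_of[per_chrom:] = 2
    positions[:per_chrom] = np.arange(per_chrom) * 10_000 + 1
    positions[per_chrom:] = np.arange(L - per_chrom) * 10_000 + 1

    parts: list[GenotypeMatrix] = []
    pop_rows = []
    truth_blocks: list[AncestryTruth] = []
    truth_by_pop: dict[str, AncestryTruth] = {}
    all_sources = list(freqs.index)

    def expand(truth: AncestryTruth) -> AncestryTruth:
        """Embed a truth matrix into the full source set."""
        full = np.zeros((len(truth.individual_ids), len(all_sources)))
        for k, src in enumerate(truth.sources):
            full[:, all_sources.index(src)] = truth.fractions[:, k]
        return AncestryTruth(truth.individual_ids, all_sources, full)

    route_labels = [r[0] for r in cfg.route]
    for idx, (label, lat, lon) in enumerate(cfg.route):
        truth = AncestryTruth(
            individual_ids=[f"{label}_{i}" for i in range(cfg.n_per_route_pop)],
            sources=[label],
            fractions=np.ones((cfg.n_per_route_pop, 1)),
        )
        gm = simulate_genotypes(
            freqs, truth, cfg.missing_rate, stage_seed(cfg.seed, f"geno:{label}"),
            population=label, chromosome_of=chrom_of, positions=positions,
        )
        parts.append(gm)
        pop_rows.append((label, "route", lat, lon, "none", False, False))
        t = expand(truth)
        truth_blocks.append(t)
        truth_by_pop[label] = t

    for label, _F in cfg.colonist_sources:
        truth = AncestryTruth(
            individual_ids=[f"{label}_{i}" for i in range(cfg.n_per_colonist_pop)],
            sources=[label],
            fractions=np.ones((cfg.n_per_colonist_pop, 1)),
        )
        gm = simulate_genotypes(
            freqs, truth, cfg.missing_rate, stage_seed(cfg.seed, f"geno:{label}"),
            population=label, chromosome_of=chrom_of, positions=positions,
        )
        parts.append(gm)
        pop_rows.append((label, "colonist", 48.0, 2.0, "none", True, False))
        t = expand(truth)
        truth_blocks.append(t)
        truth_by_pop[label] = t

    for spec in cfg.admixed_pops:
        parent = spec.indigenous_parent or route_labels[-1]
        s_full = dict(spec.s)
        s_full[parent] = 1.0 - sum(spec.s.values())
        truth = simulate_admixture_fractions(
            spec.n_individuals, s_full, spec.g,
            stage_seed(cfg.seed, f"pulse:{spec.label}"),
            pedigree_size=cfg.pedigree_size,
        )
        truth = AncestryTruth(
            individual_ids=[f"{spec.label}_{i}" for i in range(spec.n_individuals)],
            sources=truth.sources,
            fractions=truth.fractions,
        )
        gm = simulate_genotypes(
            freqs, truth, cfg.missing_rate, stage_seed(cfg.seed, f"geno:{spec.label}"),
            population=spec.label, chromosome_of=chrom_of, positions=positions,
        )
        parts.append(gm)
        pop_rows.append((spec.label, "admixed", spec.latitude, spec.longitude,
                         "indigenous_NW", False, False))
        t = expand(truth)
        truth_blocks.append(t)
        truth_by_pop[spec.label] = t

    individuals = [ind for p in parts for ind in p.individuals]
    dosage = np.vstack([p.dosage for p in parts])
    genotypes = GenotypeMatrix(individuals=individuals, snps=parts[0].snps, dosage=dosage)

    if cfg.haplotype_pool_size > 0:
        _apply_haplotype_pools(
            genotypes, freqs, truth_by_pop, rec_map.planted_runs,
            cfg.haplotype_pool_size, stage_seed(cfg.seed, "haplotype_pools"),
        )

    truth = AncestryTruth(
        individual_ids=[i for t in truth_blocks for i in t.individual_ids],
        sources=all_sources,
        fractions=np.vstack([t.fractions for t in truth_blocks]),
    )
    pop_table = pd.DataFrame(
        pop_rows,
        columns=["population", "region", "latitude", "longitude", "special_group",
                 "exclude_from_regression", "exclude_from_grouping"],
    )
    return genotypes, pop_table, rec_map, truth


def default_config(seed: int = 0, n_snps: int = 5000, missing_rate: float = 0.005,
                   haplotype_pool_size: int = 0) -> SimulationConfig:
    """Study-like desk-scale default: 10-step route, 2 colonist sources,
    2 coastal-like (g=3) and 2 interior-like (g=2) admixed populations."""
    # roughly along the out-of-Africa -> Beringia -> Pacific coast chain
    route = [
        ("route00_origin", 9.03, 38.74),
        ("route01", 30.05, 31.25),
        ("route02", 41.01, 28.98),
        ("route03", 52.0, 55.0),
        ("route04", 60.0, 90.0),
        ("route05", 64.0, 130.0),
        ("route06", 64.73, 177.51),
        ("route07", 60.0, -150.0),
        ("route08", 54.32, -130.32),
        ("route09_terminal", 50.0, -122.0),
    ]
    admixed = [
        AdmixedPopSpec("coastalA", {"colonistEUR": 0.35, "colonistASIA": 0.10}, g=3, n_individuals=20,
                       latitude=54.4, longitude=-130.4),
        AdmixedPopSpec("coastalB", {"colonistEUR": 0.30, "colonistASIA": 0.08}, g=3, n_individuals=20,
                       latitude=55.0, longitude=-129.5),
        AdmixedPopSpec("interiorA", {"colonistEUR": 0.20, "colonistASIA": 0.20}, g=2, n_individuals=20,
                       latitude=51.6, longitude=-122.1),
        AdmixedPopSpec("interiorB", {"colonistEUR": 0.18, "colonistASIA": 0.22}, g=2, n_individuals=20,
                       latitude=50.6, longitude=-119.1),
    ]
    return SimulationConfig(
        n_snps=n_snps,
        route=route,
        drift_F_per_step=0.02,
        colonist_sources=[("colonistEUR", 0.15), ("colonistASIA", 0.15)],
        admixed_pops=admixed,
        missing_rate=missing_rate,
        seed=seed,
        haplotype_pool_size=haplotype_pool_size,
    )
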