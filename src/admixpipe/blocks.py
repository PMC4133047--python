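"""LD blocks from a recombination map and EM haplotype heterozygosity.

Blocks are runs of 5-15 contiguous SNPs whose inter-SNP mean recombination
rates all fall below (or, in the alternative mode, above) a threshold in
cM/Mb.  Haplotype frequencies within a block are estimated from unphased
genotypes by an expectation-maximization algorithm over phase
configurations, and block heterozygosity uses the unbiased Nei estimator
H = n/(n-1) (1 - sum p^2) with n the number of haplotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class Block:
    chromosome: int
    first: int  # index into the dataset SNP list
    last: int

    @property
    def size(self) -> int:
        return self.last - self.first + 1


@dataclass
class BlockSet:
    blocks: list[Block]
    mode: str  # below | above | random

    def __len__(self):
        return len(self.blocks)

    def to_tsv(self, path, snps) -> None:
        rows = [
            (b.chromosome, snps[b.first].position_bp, snps[b.last].position_bp, b.size)
            for b in self.blocks
        ]
        pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp", "n_snps"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class HaplotypeFrequencySpectrum:
    frequencies: dict[str, float]
    n: int  # effective haplotype count = 2 x individuals used
    loglik_trace: list[float] = field(default_factory=list)


def interval_rates(rec_map: pd.DataFrame, snps) -> np.ndarray:
    """Mean map rate for each interval between contiguous dataset SNPs.

    ``rec_map`` has columns (chromosome, position_bp, rate_cM_per_Mb).  For
    each interval the unweighted mean of map rates at positions strictly
    inside it is taken; intervals containing no map point get the linear
    interpolation of the flanking map rates at the interval midpoint.
    Returns one rate per adjacent same-chromosome SNP pair (NaN across
    chromosome boundaries).
    """
    out = np.full(len(snps) - 1, np.nan)
    by_chrom = {c: grp.sort_values("position_bp") for c, grp in rec_map.groupby("chromosome")}
    for j in range(len(snps) - 1):
        a, b = snps[j], snps[j + 1]
        if a.chromosome != b.chromosome:
            continue
        grp = by_chrom.get(a.chromosome)
        if grp is None:
            raise ValueError(f"chromosome {a.chromosome} absent from recombination map")
        pos = grp["position_bp"].to_numpy()
        rate = grp["rate_cM_per_Mb"].to_numpy()
        inside = (pos > a.position_bp) & (pos < b.position_bp)
        if inside.any():
            out[j] = rate[inside].mean()
        else:
            mid = (a.position_bp + b.position_bp) / 2.0
            if mid < pos[0] or mid > pos[-1]:
                raise ValueError(
                    f"SNP interval [{a.position_bp}, {b.position_bp}] outside map span"
                )
            out[j] = float(np.interp(mid, pos, rate))
    return out


def build_blocks(
    rates: np.ndarray,
    snps,
    min_size: int = 5,
    max_size: int = 15,
    threshold: float = 0.5,
    mode: str = "below",
    seed: int | None = None,
    reference: BlockSet | None = None,
) -> BlockSet:
    """Greedy left-to-right disjoint block construction.

    mode "below": extend a run while the next inter-SNP rate is below
    ``threshold`` and the block holds fewer than ``max_size`` SNPs; emit
    when the run ends if it reached ``min_size``.  mode "above" applies the
    complementary rate rule.  mode "random" places disjoint random blocks
    whose multiset of lengths (and chromosomes) matches ``reference``.
    """
    if mode == "random":
        if reference is None:
            raise ValueError("random mode requires a reference BlockSet")
        return _random_blocks(snps, reference, seed)
    if mode not in ("below", "above"):
        raise ValueError(f"unknown mode {mode!r}")

    def ok(r: float) -> bool:
        if np.isnan(r):
            return False
        return r < threshold if mode == "below" else r > threshold

    blocks: list[Block] = []
    n = len(snps)
    j = 0
    while j < n:
        start = j
        # grow while the interval to the next SNP passes the rate rule
        while (
            j + 1 < n
            and snps[j + 1].chromosome == snps[start].chromosome
            and (j - start + 1) < max_size
            and ok(rates[j])
        ):
            j += 1
        size = j - start + 1
        if size >= min_size:
            blocks.append(Block(chromosome=snps[start].chromosome, first=start, last=j))
        j += 1
    return BlockSet(blocks=blocks, mode=mode)


def _random_blocks(snps, reference: BlockSet, seed: int | None) -> BlockSet:
    rng = np.random.default_rng(seed)
    chrom_ranges: dict[int, tuple[int, int]] = {}
    for idx, s in enumerate(snps):
        lo, hi = chrom_ranges.get(s.chromosome, (idx, idx))
        chrom_ranges[s.chromosome] = (min(lo, idx), max(hi, idx))
    occupied: dict[int, np.ndarray] = {
        c: np.zeros(hi - lo + 1, dtype=bool) for c, (lo, hi) in chrom_ranges.items()
    }
    blocks: list[Block] = []
    # place longest first to reduce rejection
    for ref in sorted(reference.blocks, key=lambda b: -b.size):
        c = ref.chromosome
        if c not in chrom_ranges:
            raise ValueError(f"reference block on chromosome {c} absent from SNP set")
        lo, hi = chrom_ranges[c]
        width = ref.size
        occ = occupied[c]
        candidates = [
            s for s in range(0, hi - lo + 2 - width) if not occ[s : s + width].any()
        ]
        if not candidates:
            raise ValueError(f"chromosome {c} too short for random block of {width} SNPs")
        s = int(rng.choice(candidates))
        occ[s : s + width] = True
        blocks.append(Block(chromosome=c, first=lo + s, last=lo + s + width - 1))
    blocks.sort(key=lambda b: (b.chromosome, b.first))
    return BlockSet(blocks=blocks, mode="random")


# ---------------------------------------------------------------------------
# EM haplotype frequencies
# ---------------------------------------------------------------------------


def _compatible_pair_codes(genotype: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All unordered haplotype pairs compatible with one unphased genotype.

    Haplotypes are encoded as integers with bit j set when site j carries
    allele 2.  The first heterozygous site is fixed to one phase so mirror
    configurations are not double-counted.
    """
    het = np.flatnonzero(genotype == 1)
    hom2 = np.flatnonzero(genotype == 2).astype(np.int64)
    base = int((np.int64(1) << hom2).sum())
    h = len(het)
    if h == 0:
        return np.array([base]), np.array([base])
    site_bits = (1 << het).astype(np.int64)
    k = np.arange(2 ** (h - 1), dtype=np.int64)
    # phase of het sites 1..h-1 from the bits of k; site 0 fixed to h1
    rest = ((k[:, None] >> np.arange(h - 1)) & 1).astype(np.int64)
    h1 = base + site_bits[0] + rest @ site_bits[1:]
    h2 = base + (1 - rest) @ site_bits[1:]
    return h1, h2


def em_haplotype_frequencies(
    g: GenotypeMatrix,
    block: Block,
    population: str,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> HaplotypeFrequencySpectrum:
    """EM haplotype frequency estimation within a block for one population.

    Individuals with any missing call inside the block are excluded.  The
    E-step distributes each individual over its compatible ordered
    haplotype pairs with weight f(h1) f(h2); the M-step re-estimates the
    frequencies; initialization is the linkage-equilibrium product of
    single-SNP frequencies.  Converged when the largest frequency change
    falls below ``tol``.
    """
    if block.size > 15:
        raise ValueError("block size exceeds 15 SNPs")
    rows = g.individual_index(population)
    geno = g.dosage[rows, block.first : block.last + 1]
    complete = ~(geno == MISSING).any(axis=1)
    geno = geno[complete]
    if geno.shape[0] == 0:
        raise ValueError(f"no complete individuals for block in population {population}")

    pair_codes = [_compatible_pair_codes(row) for row in geno]
    n_ind = geno.shape[0]
    sizes = np.array([len(a) for a, _ in pair_codes])
    a_codes = np.concatenate([a for a, _ in pair_codes])
    b_codes = np.concatenate([b for _, b in pair_codes])
    codes, inverse = np.unique(np.concatenate([a_codes, b_codes]), return_inverse=True)
    a_idx, b_idx = inverse[: len(a_codes)], inverse[len(a_codes) :]
    H = len(codes)
    width = geno.shape[1]
    haps = ((codes[:, None] >> np.arange(width)) & 1).astype(np.int8)  # H x width

    # linkage-equilibrium init
    p_site = geno.mean(axis=0) / 2.0
    with np.errstate(divide="ignore"):
        logf = (haps * np.log(np.clip(p_site, 1e-12, 1))).sum(axis=1) + (
            (1 - haps) * np.log(np.clip(1 - p_site, 1e-12, 1))
        ).sum(axis=1)
    f = np.exp(logf - logf.max())
    f /= f.sum()

    # unordered heterozygous pairs carry weight 2 f1 f2; homozygous pairs once
    mult = np.where(a_idx == b_idx, 1.0, 2.0)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    owner = np.repeat(np.arange(n_ind), sizes)

    trace: list[float] = []
    for _ in range(max_iter):
        w = f[a_idx] * f[b_idx] * mult
        totals = np.add.reduceat(w, starts)
        trace.append(float(np.log(np.maximum(totals, 1e-300)).sum()))
        w = w / np.maximum(totals, 1e-300)[owner]
        counts = np.bincount(a_idx, weights=w, minlength=H) + np.bincount(
            b_idx, weights=w, minlength=H
        )
        new_f = counts / (2 * n_ind)
        delta = np.abs(new_f - f).max()
        f = new_f
        if delta < tol:
            break

    freqs = {
        "".join(map(str, haps[i])): float(f[i]) for i in range(H) if f[i] > 0
    }
    return HaplotypeFrequencySpectrum(frequencies=freqs, n=2 * n_ind, loglik_trace=trace)


def em_log_likelihood(spec_f: np.ndarray, pair_idx: list[np.ndarray]) -> float:
    """Multinomial phase log-likelihood for given haplotype frequencies."""
    ll = 0.0
    for idx in pair_idx:
        w = spec_f[idx[:, 0]] * spec_f[idx[:, 1]]
        w = np.where(idx[:, 0] == idx[:, 1], w, 2 * w)
        ll += np.log(max(w.sum(), 1e-300))
    return float(ll)


def block_heterozygosity(spec: HaplotypeFrequencySpectrum, unbiased: bool = True) -> float:
    """Nei expected haplotype heterozygosity for one block."""
    if spec.n < 2:
        raise ValueError("need at least 2 haplotypes")
    p = np.array(list(spec.frequencies.values()))
    h = 1.0 - float((p**2).sum())
    if unbiased:
        h *= spec.n / (spec.n - 1)
    return h


@dataclass
class HeterozygosityTable:
    table: pd.DataFrame  # population, mean_H, sd_H plus per-chromosome columns

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def genomewide_heterozygosity(
    g: GenotypeMatrix,
    blocks: BlockSet,
    populations: list[str] | None = None,
    unbiased: bool = True,
) -> HeterozygosityTable:
    """Population mean haplotype heterozygosity: blocks averaged within
    chromosomes, then mean and SD taken across chromosome means."""
    if populations is None:
        populations = g.populations()
    by_chrom: dict[int, list[Block]] = {}
    for b in blocks.blocks:
        by_chrom.setdefault(b.chromosome, []).append(b)
    rows = []
    for pop in populations:
        chrom_means = {}
        for chrom, blist in sorted(by_chrom.items()):
            vals = []
            for b in blist:
                try:
                    spec = em_haplotype_frequencies(g, b, pop)
                except ValueError:
                    continue
                vals.append(block_heterozygosity(spec, unbiased=unbiased))
            if vals:
                chrom_means[chrom] = float(np.mean(vals))
            else:
                log.warning("population %s: chromosome %d has no usable blocks", pop, chrom)
        means = np.array(list(chrom_means.values()))
        rows.append(
            {
                "population": pop,
                "mean_H": float(means.mean()),
                "sd_H": float(means.std(ddof=1)) if len(means) > 1 else 0.0,
                **{f"chr{c}": v for c, v in chrom_means.items()},
            }
        )
    return HeterozygosityTable(table=pd.DataFrame(rows))
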