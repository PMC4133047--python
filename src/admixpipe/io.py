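"""Genotype IO, quality control, dataset merging and LD pruning.

Genotypes are held as a dense dosage matrix (individuals x SNPs) counting
copies of ``allele2`` at each SNP; by convention ``allele2`` is the
lexicographically larger of the two observed alleles unless a caller
overrides it.  Missing genotypes use the sentinel :data:`MISSING` (-1),
which maps to the "0 0" allele pair in PED text files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

log = logging.getLogger(__name__)

MISSING = -1

_VALID_ALLELES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SNPRecord:
    identifier: str
    chromosome: int
    position_bp: int
    allele1: str
    allele2: str

    def __post_init__(self):
        if self.allele1 == self.allele2:
            raise ValueError(f"SNP {self.identifier}: allele1 == allele2")
        for a in (self.allele1, self.allele2):
            if a not in _VALID_ALLELES:
                raise ValueError(f"SNP {self.identifier}: invalid allele {a!r}")
        if self.position_bp < 1:
            raise ValueError(f"SNP {self.identifier}: position must be >= 1")


@dataclass(frozen=True)
class IndividualRecord:
    individual_id: str
    population: str


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix with SNP and individual metadata."""

    individuals: list[IndividualRecord]
    snps: list[SNPRecord]
    dosage: np.ndarray  # int8, entries in {0,1,2} or MISSING

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = self.dosage.shape
        if n != len(self.individuals) or m != len(self.snps):
            raise ValueError("dosage shape inconsistent with metadata")
        ids = [s.identifier for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP identifiers")
        iids = [i.individual_id for i in self.individuals]
        if len(set(iids)) != len(iids):
            raise ValueError("duplicate individual identifiers")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.population, None)
        return list(seen)

    def individual_index(self, population: str) -> np.ndarray:
        return np.array(
            [i for i, ind in enumerate(self.individuals) if ind.population == population],
            dtype=int,
        )

    def allele_frequencies(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Frequency of allele2 per SNP over non-missing genotypes."""
        d = self.dosage if rows is None else self.dosage[rows]
        obs = d != MISSING
        counts = np.where(obs, d, 0).sum(axis=0)
        n = 2 * obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, counts / np.maximum(n, 1), np.nan)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            individuals=list(self.individuals),
            snps=[self.snps[j] for j in keep],
            dosage=self.dosage[:, keep].copy(),
        )

    def subset_individuals(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in keep],
            snps=list(self.snps),
            dosage=self.dosage[keep, :].copy(),
        )


@dataclass
class QCReport:
    input_snps: int = 0
    removed_missingness: int = 0
    removed_monomorphic: int = 0
    removed_maf: int = 0
    removed_hwe: int = 0
    individuals_removed: int = 0
    retained_snps: int = 0

    @property
    def removed_total(self) -> int:
        return (
            self.removed_missingness
            + self.removed_monomorphic
            + self.removed_maf
            + self.removed_hwe
        )

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "filter": ["missingness", "monomorphic", "maf", "hwe", "retained"],
                "snps": [
                    self.removed_missingness,
                    self.removed_monomorphic,
                    self.removed_maf,
                    self.removed_hwe,
                    self.retained_snps,
                ],
            }
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read a PLINK-style whitespace-delimited PED/MAP pair.

    Dosage counts copies of the lexicographically larger observed allele
    ("allele2"); the "0 0" pair becomes :data:`MISSING`.
    """
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) not in (3, 4):
                raise ValueError(f"{map_path}: malformed MAP line {lineno}")
            chrom, ident = tok[0], tok[1]
            pos = tok[-1]
            map_rows.append((int(chrom), ident, int(pos)))

    n_snps = len(map_rows)
    rows = []
    individuals = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{ped_path}: malformed PED line {lineno}: expected "
                    f"{6 + 2 * n_snps} fields, got {len(tok)}"
                )
            fid, iid = tok[0], tok[1]
            individuals.append(IndividualRecord(individual_id=iid, population=fid))
            rows.append(tok[6:])

    n_ind = len(individuals)
    a1 = np.empty((n_ind, n_snps), dtype="U1")
    a2 = np.empty((n_ind, n_snps), dtype="U1")
    for i, r in enumerate(rows):
        a1[i] = r[0::2]
        a2[i] = r[1::2]

    snps = []
    dosage = np.full((n_ind, n_snps), MISSING, dtype=np.int8)
    for j, (chrom, ident, pos) in enumerate(map_rows):
        col = np.concatenate([a1[:, j], a2[:, j]])
        observed = sorted(set(col) - {"0"})
        bad = set(observed) - _VALID_ALLELES
        if bad:
            raise ValueError(f"SNP {ident}: invalid allele(s) {sorted(bad)}")
        if len(observed) > 2:
            raise ValueError(f"SNP {ident}: more than 2 alleles observed: {observed}")
        if len(observed) == 0:
            # fully missing column; pick an arbitrary valid pair
            ref, alt = "A", "C"
        elif len(observed) == 1:
            ref = observed[0]
            alt = next(a for a in "ACGT" if a != ref)
        else:
            ref, alt = observed  # sorted: alt is lexicographically larger
        snps.append(
            SNPRecord(identifier=ident, chromosome=chrom, position_bp=pos, allele1=ref, allele2=alt)
        )
        miss = (a1[:, j] == "0") | (a2[:, j] == "0")
        dos = (a1[:, j] == alt).astype(np.int8) + (a2[:, j] == alt).astype(np.int8)
        dosage[:, j] = np.where(miss, MISSING, dos)

    return GenotypeMatrix(individuals=individuals, snps=snps, dosage=dosage)


def write_ped_map(g: GenotypeMatrix, prefix) -> tuple[str, str]:
    """Write ``prefix``.ped and ``prefix``.map readable by :func:`read_ped_map`."""
    prefix = str(prefix)
    ped_path, map_path = prefix + ".ped", prefix + ".map"
    with open(map_path, "w") as fh:
        for s in g.snps:
            fh.write(f"{s.chromosome}\t{s.identifier}\t0\t{s.position_bp}\n")
    allele_pairs = {
        0: lambda s: (s.allele1, s.allele1),
        1: lambda s: (s.allele1, s.allele2),
        2: lambda s: (s.allele2, s.allele2),
        MISSING: lambda s: ("0", "0"),
    }
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(g.individuals):
            fields = [ind.population, ind.individual_id, "0", "0", "0", "-9"]
            for j, s in enumerate(g.snps):
                fields.extend(allele_pairs[int(g.dosage[i, j])](s))
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------


def _is_strand_ambiguous(s: SNPRecord) -> bool:
    return {s.allele1, s.allele2} in ({"A", "T"}, {"C", "G"})


def merge_datasets(
    a: GenotypeMatrix,
    b: GenotypeMatrix,
    drop_ambiguous: bool = False,
) -> GenotypeMatrix:
    """Merge two datasets on shared SNP identifiers, concatenating individuals.

    When ``b`` is coded on the opposite strand at a SNP (its allele pair is
    the base-complement of ``a``'s), ``b``'s alleles are complement-flipped
    to ``a``'s strand; dosages are re-oriented so that they count ``a``'s
    allele2.  SNPs with irreconcilable allele pairs are dropped with a
    logged count.  A/T and C/G SNPs (self-complementary pairs) are assumed
    to be on the same strand unless ``drop_ambiguous``.
    """
    b_index = {s.identifier: j for j, s in enumerate(b.snps)}
    keep_a: list[int] = []
    keep_b: list[int] = []
    flip_dosage: list[bool] = []
    n_irreconcilable = 0
    n_ambiguous = 0

    for ja, sa in enumerate(a.snps):
        jb = b_index.get(sa.identifier)
        if jb is None:
            continue
        sb = b.snps[jb]
        set_a = {sa.allele1, sa.allele2}
        if _is_strand_ambiguous(sa):
            n_ambiguous += 1
            if drop_ambiguous:
                continue
        set_b = {sb.allele1, sb.allele2}
        set_b_comp = {_COMPLEMENT[x] for x in set_b}
        if set_b == set_a:
            b_allele2 = sb.allele2
        elif set_b_comp == set_a:
            b_allele2 = _COMPLEMENT[sb.allele2]
        else:
            n_irreconcilable += 1
            continue
        keep_a.append(ja)
        keep_b.append(jb)
        flip_dosage.append(b_allele2 != sa.allele2)

    if n_irreconcilable:
        warnings.warn(f"{n_irreconcilable} SNP(s) excluded: irreconcilable alleles")
    if n_ambiguous and not drop_ambiguous:
        log.info("%d strand-ambiguous (A/T or C/G) SNP(s) kept assuming same strand", n_ambiguous)
    if not keep_a:
        raise ValueError("no shared SNPs after merging")

    snps = [a.snps[j] for j in keep_a]
    da = a.dosage[:, keep_a]
    db = b.dosage[:, keep_b].copy()
    flip = np.array(flip_dosage)
    if flip.any():
        cols = np.flatnonzero(flip)
        block = db[:, cols]
        db[:, cols] = np.where(block == MISSING, MISSING, 2 - block)

    individuals = list(a.individuals) + list(b.individuals)
    return GenotypeMatrix(individuals=individuals, snps=snps, dosage=np.vstack([da, db]))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Two-sided exact conditional Hardy-Weinberg test.

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one.
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    # minor allele count
    na = 2 * n_hom1 + n_het
    nb = 2 * n_hom2 + n_het
    rare = min(na, nb)
    # possible het counts share the parity of the rare allele count
    hets = range(rare % 2, rare + 1, 2)
    # unnormalized probabilities via recurrence, numerically stable in log
    from math import lgamma

    def logp(h):
        homr = (rare - h) // 2
        homc = n - h - homr
        return (
            lgamma(n + 1)
            - lgamma(h + 1)
            - lgamma(homr + 1)
            - lgamma(homc + 1)
            + h * np.log(2.0)
            - (lgamma(2 * n + 1) - lgamma(rare + 1) - lgamma(2 * n - rare + 1))
        )

    lps = np.array([logp(h) for h in hets])
    ps = np.exp(lps - lps.max())
    ps /= ps.sum()
    p_obs = ps[list(hets).index(n_het)]
    return float(min(1.0, ps[ps <= p_obs * (1 + 1e-12)].sum()))


def qc_filter(
    g: GenotypeMatrix,
    max_missing: float = 0.10,
    drop_monomorphic: bool = True,
    min_maf: float = 0.0,
    hwe_alpha: float = 0.0,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove SNPs failing missingness / monomorphism / MAF / HWE filters.

    HWE is tested separately within each population with the exact test; a
    SNP is removed if any population's p-value falls below ``hwe_alpha``.
    Filters are applied in the order listed; each SNP is counted against
    the first filter it violates.
    """
    report = QCReport(input_snps=g.n_snps)
    d = g.dosage
    obs = d != MISSING
    n_ind = g.n_individuals

    miss_frac = 1.0 - obs.sum(axis=0) / n_ind
    fail_miss = miss_frac > max_missing

    freq = g.allele_frequencies()
    with np.errstate(invalid="ignore"):
        mono = (freq <= 0.0) | (freq >= 1.0) | np.isnan(freq)
    fail_mono = mono & drop_monomorphic & ~fail_miss

    maf = np.minimum(freq, 1 - freq)
    with np.errstate(invalid="ignore"):
        fail_maf = (maf < min_maf) & ~fail_miss & ~fail_mono if min_maf > 0 else np.zeros(g.n_snps, bool)

    fail_hwe = np.zeros(g.n_snps, dtype=bool)
    if hwe_alpha > 0:
        candidates = np.flatnonzero(~(fail_miss | fail_mono | fail_maf))
        pop_rows = [g.individual_index(p) for p in g.populations()]
        for j in candidates:
            for rows in pop_rows:
                col = d[rows, j]
                col = col[col != MISSING]
                n_het = int((col == 1).sum())
                n_hom1 = int((col == 0).sum())
                n_hom2 = int((col == 2).sum())
                if hwe_exact_p(n_het, n_hom1, n_hom2) < hwe_alpha:
                    fail_hwe[j] = True
                    break

    report.removed_missingness = int(fail_miss.sum())
    report.removed_monomorphic = int(fail_mono.sum())
    report.removed_maf = int(fail_maf.sum())
    report.removed_hwe = int(fail_hwe.sum())
    keep = ~(fail_miss | fail_mono | fail_maf | fail_hwe)
    report.retained_snps = int(keep.sum())
    if report.retained_snps == 0:
        raise ValueError("qc_filter removed all SNPs")
    return g.subset_snps(keep), report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def _dosage_r2(d: np.ndarray, j: int, k: int) -> float:
    """Squared Pearson correlation of two dosage columns over pairwise-complete rows."""
    x, y = d[:, j], d[:, k]
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    x = x[ok].astype(float)
    y = y[ok].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_prune(
    g: GenotypeMatrix, window: int = 50, step: int = 10, r2_max: float = 0.1
) -> GenotypeMatrix:
    """Greedy sliding-window LD pruning on dosage correlation.

    Within each window, while any SNP pair exceeds ``r2_max``, the member
    of the pair with more missing data is removed (ties break toward the
    larger column index); the window then advances by ``step`` SNPs.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    order = sorted(range(g.n_snps), key=lambda j: (g.snps[j].chromosome, g.snps[j].position_bp))
    if order != list(range(g.n_snps)):
        g = g.subset_snps(np.array(order))

    d = g.dosage
    missing_count = (d == MISSING).sum(axis=0)
    removed = np.zeros(g.n_snps, dtype=bool)

    chroms: dict[int, list[int]] = {}
    for j, s in enumerate(g.snps):
        chroms.setdefault(s.chromosome, []).append(j)

    def clean_window(win: list[int]) -> bool:
        """Remove SNPs until no pair in ``win`` exceeds r2_max; True if any removed."""
        any_removed = False
        changed = True
        while changed and len(win) > 1:
            changed = False
            for a_i in range(len(win)):
                for b_i in range(a_i + 1, len(win)):
                    ja, jb = win[a_i], win[b_i]
                    if _dosage_r2(d, ja, jb) > r2_max:
                        # drop the more-missing SNP; tie -> larger index
                        if missing_count[ja] > missing_count[jb]:
                            drop = ja
                        elif missing_count[jb] > missing_count[ja]:
                            drop = jb
                        else:
                            drop = max(ja, jb)
                        removed[drop] = True
                        win.remove(drop)
                        any_removed = changed = True
                        break
                if changed:
                    break
        return any_removed

    # Sweep windows over the retained SNPs, repeating until a full sweep is
    # clean, so no window over the *output* contains a pair above r2_max.
    for cols in chroms.values():
        dirty = True
        while dirty:
            dirty = False
            retained = [j for j in cols if not removed[j]]
            start = 0
            while start < len(retained):
                win = [j for j in retained[start : start + window] if not removed[j]]
                dirty |= clean_window(win)
                if start + window >= len(retained):
                    break
                start += step

    return g.subset_snps(~removed)
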