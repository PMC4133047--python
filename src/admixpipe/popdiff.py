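"""Population-level structure: Weir-Cockerham F_ST, classical MDS, BIONJ.

The multilocus F_ST is the Weir & Cockerham (1984) theta computed as a
ratio of sums of the per-locus variance components a (among populations),
b (among individuals within populations) and c (within individuals), over
SNPs passing a whole-sample minor-allele-frequency filter.  Classical
(Torgerson) metric MDS embeds the F_ST matrix in the plane; BIONJ
(Gascuel 1997) builds an unrooted tree with variance-weighted branch
estimates, with bootstrap support over loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from .io import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    flavor: str  # FST | ASD | Euclidean

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape inconsistent with labels")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12, equal_nan=True):
            raise ValueError("matrix must be symmetric")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.labels, columns=self.labels).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, flavor: str) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=list(df.index), matrix=df.to_numpy(), flavor=flavor)


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------


def _wc_components(g: GenotypeMatrix, rows_a: np.ndarray, rows_b: np.ndarray, use: np.ndarray):
    """Per-locus Weir-Cockerham variance components (a, b, c) for two populations.

    Vectorized over the SNPs selected by ``use``; loci without at least two
    genotyped individuals in each population are dropped.
    """
    comps = []
    d = g.dosage[:, use]
    da, db = d[rows_a], d[rows_b]
    r = 2.0

    def summarize(block):
        obs = block != MISSING
        n = obs.sum(axis=0).astype(float)  # individuals with data
        cnt = np.where(obs, block, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = cnt / (2 * n)
            h = np.where(obs, block == 1, False).sum(axis=0) / n
        return n, p, h

    n1, p1, h1 = summarize(da)
    n2, p2, h2 = summarize(db)
    ok = (n1 >= 2) & (n2 >= 2)

    n1, p1, h1, n2, p2, h2 = (x[ok] for x in (n1, p1, h1, n2, p2, h2))
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2.0
    return a, b, c


def pairwise_fst(
    g: GenotypeMatrix, pop_a: str, pop_b: str, min_maf: float = 0.05
) -> float:
    """Multilocus Weir-Cockerham theta between two populations.

    The ratio-of-sums estimator sum(a) / sum(a+b+c) over SNPs whose minor
    allele frequency in the whole sample exceeds ``min_maf``.  Negative
    per-locus components are kept (not truncated) before summation.
    """
    freq = g.allele_frequencies()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freq, 1 - freq)
    use = np.flatnonzero(~np.isnan(maf) & (maf > min_maf)) if min_maf > 0 else np.flatnonzero(~np.isnan(maf))
    if len(use) == 0:
        raise ValueError("no SNP passes the MAF filter")
    rows_a = g.individual_index(pop_a)
    rows_b = g.individual_index(pop_b)
    a, b, c = _wc_components(g, rows_a, rows_b, use)
    denom = (a + b + c).sum()
    if denom == 0:
        return 0.0
    return float(a.sum() / denom)


def fst_matrix(
    g: GenotypeMatrix, populations: list[str] | None = None, min_maf: float = 0.05
) -> DistanceMatrix:
    """Symmetric matrix of pairwise multilocus theta values (diagonal zero)."""
    if populations is None:
        populations = g.populations()
    if len(populations) < 2:
        raise ValueError("need at least 2 populations")
    n = len(populations)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pairwise_fst(g, populations[i], populations[j], min_maf=min_maf)
    return DistanceMatrix(labels=list(populations), matrix=m, flavor="FST")


# ---------------------------------------------------------------------------
# Classical MDS
# ---------------------------------------------------------------------------


@dataclass
class MDSConfiguration:
    labels: list[str]
    coordinates: np.ndarray  # n x dims
    eigenvalues: np.ndarray
    rho: float  # Spearman fidelity of plot distances vs input distances

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.coordinates, columns=[f"dim{k+1}" for k in range(self.coordinates.shape[1])]
        )
        df.insert(0, "label", self.labels)
        df.to_csv(path, sep="\t", index=False)


def classical_mds(d: DistanceMatrix, dims: int = 2) -> MDSConfiguration:
    """Torgerson metric MDS: eigendecomposition of -1/2 J D^2 J.

    Coordinates are the top eigenvectors scaled by the square root of their
    eigenvalues; an error is raised when any of the requested dimensions
    has a negative eigenvalue.  The fidelity rho is the Spearman rank
    correlation between embedded Euclidean distances and input distances
    over the lower triangle.
    """
    D = np.asarray(d.matrix, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if np.any(vals[:dims] < -1e-10 * max(1.0, abs(vals[0]))):
        raise ValueError("negative eigenvalue among the requested dimensions")
    if np.any(vals[dims:] < 0):
        log.info("MDS: %d negative trailing eigenvalues retained", int((vals[dims:] < 0).sum()))
    top = np.clip(vals[:dims], 0, None)
    coords = vecs[:, :dims] * np.sqrt(top)
    # deterministic orientation: largest-magnitude coordinate positive
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    iu = np.triu_indices(n, k=1)
    emb = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    if len(iu[0]) > 1 and np.ptp(D[iu]) > 0:
        rho = float(stats.spearmanr(emb[iu], D[iu]).statistic)
    else:
        rho = 1.0
    return MDSConfiguration(labels=list(d.labels), coordinates=coords, eigenvalues=vals, rho=rho)


# ---------------------------------------------------------------------------
# BIONJ
# ---------------------------------------------------------------------------


def bionj_tree(d: DistanceMatrix) -> TreeNode:
    """BIONJ agglomeration (variance-weighted neighbor joining).

    Follows Gascuel (1997): the pair minimizing the standard NJ criterion
    is joined, branch lengths use the NJ formulas, and the reduction step
    weights the two distances by lambda chosen to minimize the variance of
    the new distance estimates.  Negative branch lengths are clamped to
    zero (logged).  Returns an unrooted ``skbio.TreeNode`` (trifurcating
    root).
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("need at least 3 labels")
    D = d.matrix.astype(float).copy()
    V = D.copy()  # variance estimates, initialized at the distances
    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in d.labels]
    active = list(range(n))
    clamped = 0

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        sums = sub.sum(axis=1)
        Q = (m - 2) * sub - sums[:, None] - sums[None, :]
        np.fill_diagonal(Q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(Q), Q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        gi, gj = active[i_loc], active[j_loc]

        dij = D[gi, gj]
        Li = 0.5 * dij + (sums[i_loc] - sums[j_loc]) / (2 * (m - 2))
        Lj = dij - Li
        if Li < 0:
            clamped += 1
            Li = 0.0
        if Lj < 0:
            clamped += 1
            Lj = 0.0

        others = [k for k in active if k not in (gi, gj)]
        vij = V[gi, gj]
        if vij > 0 and m > 2:
            lam = 0.5 + (V[gj, others].sum() - V[gi, others].sum()) / (2 * (m - 2) * vij)
            lam = float(np.clip(lam, 0.0, 1.0))
        else:
            lam = 0.5

        new = TreeNode()
        a, b = nodes[gi], nodes[gj]
        a.length = float(Li)
        b.length = float(Lj)
        new.extend([a, b])
        nodes.append(new)
        gnew = len(nodes) - 1

        D = np.pad(D, ((0, 1), (0, 1)))
        V = np.pad(V, ((0, 1), (0, 1)))
        for k in others:
            duk = lam * (D[gi, k] - Li) + (1 - lam) * (D[gj, k] - Lj)
            vuk = lam * V[gi, k] + (1 - lam) * V[gj, k] - lam * (1 - lam) * vij
            D[gnew, k] = D[k, gnew] = duk
            V[gnew, k] = V[k, gnew] = vuk

        active = [k for k in active if k not in (gi, gj)] + [gnew]

    # final star: three-point formulas
    x, y, z = active
    lx = (D[x, y] + D[x, z] - D[y, z]) / 2.0
    ly = (D[x, y] + D[y, z] - D[x, z]) / 2.0
    lz = (D[x, z] + D[y, z] - D[x, y]) / 2.0
    root = TreeNode()
    for g_idx, L in ((x, lx), (y, ly), (z, lz)):
        node = nodes[g_idx]
        if L < 0:
            clamped += 1
            L = 0.0
        node.length = float(L)
        root.append(node)
    if clamped:
        log.info("BIONJ: %d negative branch length(s) clamped to 0", clamped)
    return root


def tree_bipartitions(tree: TreeNode) -> set[frozenset]:
    """Canonical internal-edge bipartitions of an unrooted tree.

    Each internal edge splits the leaves into two sides; the smaller side
    (ties broken lexicographically) represents the bipartition, making the
    set invariant to rotation and re-rooting.
    """
    leaves = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = leaves - side
        if 1 < len(side) < len(leaves) - 1:
            if len(side) < len(other) or (len(side) == len(other) and sorted(side) < sorted(other)):
                out.add(side)
            else:
                out.add(other)
    return out


@dataclass
class BootstrapTree:
    tree: TreeNode
    support: dict[frozenset, int]  # bipartition -> replicate count
    n_boot: int

    def newick_with_support(self) -> str:
        tree = self.tree.copy()
        leaves = frozenset(t.name for t in tree.tips())
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            other = leaves - side
            key = side if (len(side) < len(other) or (len(side) == len(other) and sorted(side) < sorted(other))) else other
            if key in self.support:
                node.name = str(self.support[key])
        return str(tree)


def bootstrap_support(
    g: GenotypeMatrix,
    populations: list[str] | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    min_maf: float = 0.05,
) -> BootstrapTree:
    """Locus-bootstrap edge support for the BIONJ tree of the F_ST matrix.

    Each replicate resamples SNP columns with replacement, recomputes the
    pairwise F_ST matrix and its BIONJ tree, and counts, for every internal
    edge of the full-data tree, the replicates containing the same leaf
    bipartition.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if populations is None:
        populations = g.populations()
    base_matrix = fst_matrix(g, populations, min_maf=min_maf)
    base_tree = bionj_tree(base_matrix)
    target = tree_bipartitions(base_tree)
    support = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    from dataclasses import replace as _dc_replace

    for _ in range(n_boot):
        cols = rng.integers(0, g.n_snps, size=g.n_snps)
        # resampling with replacement duplicates SNPs; rename identifiers
        snps = [_dc_replace(g.snps[c], identifier=f"b{k}") for k, c in enumerate(cols)]
        gb = GenotypeMatrix(list(g.individuals), snps, g.dosage[:, cols])
        try:
            rep = bionj_tree(fst_matrix(gb, populations, min_maf=min_maf))
        except ValueError:
            continue
        found = tree_bipartitions(rep)
        for bp in target:
            if bp in found:
                support[bp] += 1
    return BootstrapTree(tree=base_tree, support=support, n_boot=n_boot)
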