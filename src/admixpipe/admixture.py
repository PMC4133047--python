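"""Individual ancestry proportions by EM, and replicate-mode grouping.

Both estimators maximize the binomial admixture likelihood
L = prod_il Binom(x_il | 2, sum_k q_ik f_kl): the supervised variant holds
the source allele frequencies fixed and fits each individual's membership
vector q on the simplex, the unsupervised variant fits (Q, F) jointly from
a random start.  Replicate runs of the unsupervised estimator are grouped
into modes by a symmetric similarity coefficient (SSC) maximized over
cluster-column permutations, and memberships are averaged within modes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .io import MISSING, GenotypeMatrix


@dataclass
class AncestryMatrix:
    individual_ids: list[str]
    Q: np.ndarray  # n x K memberships
    F: np.ndarray | None = None  # K x L source frequencies (unsupervised)
    log_likelihood: float = np.nan
    seed: int | None = None
    source_labels: list[str] | None = None
    loglik_trace: list[float] | None = None

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        if np.any(self.Q < -1e-9) or np.any(self.Q > 1 + 1e-9):
            raise ValueError("memberships must lie in [0,1]")
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("membership rows must sum to 1")

    @property
    def K(self) -> int:
        return self.Q.shape[1]

    def to_table(self, path) -> None:
        np.savetxt(path, self.Q, fmt="%.6f")


def _masked_dosage(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    x = g.dosage.astype(float)
    obs = g.dosage != MISSING
    x[~obs] = 0.0
    return x, obs.astype(float)


def _loglik(x, obs, Q, F) -> float:
    P1 = np.clip(Q @ F, 1e-12, 1 - 1e-12)
    return float((obs * (x * np.log(P1) + (2 - x) * np.log(1 - P1))).sum())


def estimate_ancestry_supervised(
    g: GenotypeMatrix,
    source_freqs: pd.DataFrame | np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 5000,
) -> AncestryMatrix:
    """EM for membership vectors with source allele frequencies held fixed.

    ``source_freqs`` is K x L (rows = sources).  Frequencies are clamped
    away from 0 and 1.  Convergence is a log-likelihood increase below
    ``tol``.
    """
    if isinstance(source_freqs, pd.DataFrame):
        labels = list(source_freqs.index)
        F = source_freqs.to_numpy(dtype=float)
    else:
        F = np.asarray(source_freqs, dtype=float)
        labels = [f"source{k}" for k in range(F.shape[0])]
    K, L = F.shape
    if L != g.n_snps:
        raise ValueError("source frequency matrix does not match SNP count")
    F = np.clip(F, 1e-6, 1 - 1e-6)
    x, obs = _masked_dosage(g)
    if np.any(obs.sum(axis=1) == 0):
        raise ValueError("individual with no genotyped SNPs")
    n = g.n_individuals
    if K == 1:
        Q = np.ones((n, 1))
        return AncestryMatrix(
            individual_ids=[i.individual_id for i in g.individuals],
            Q=Q, F=F, log_likelihood=_loglik(x, obs, Q, F), source_labels=labels,
        )
    Q = np.full((n, K), 1.0 / K)
    ll = _loglik(x, obs, Q, F)
    trace = [ll]
    for _ in range(max_iter):
        P1 = np.clip(Q @ F, 1e-12, None)
        P0 = np.clip(Q @ (1 - F), 1e-12, None)
        A = Q * (((obs * x) / P1) @ F.T + ((obs * (2 - x)) / P0) @ (1 - F).T)
        Q = A / A.sum(axis=1, keepdims=True)
        new_ll = _loglik(x, obs, Q, F)
        trace.append(new_ll)
        if new_ll - ll < tol:
            ll = new_ll
            break
        ll = new_ll
    return AncestryMatrix(
        individual_ids=[i.individual_id for i in g.individuals],
        Q=Q, F=F, log_likelihood=ll, source_labels=labels, loglik_trace=trace,
    )


def estimate_ancestry_unsupervised(
    g: GenotypeMatrix,
    K: int,
    seed: int,
    tol: float = 1e-4,
    max_iter: int = 5000,
) -> AncestryMatrix:
    """Joint EM on (Q, F) under the binomial admixture likelihood.

    Q rows start from a flat Dirichlet and F from Uniform(0.05, 0.95), both
    seeded; iteration stops when the log-likelihood increases by less than
    ``tol``.  LD-pruned input is recommended (the likelihood assumes
    independent loci).
    """
    if K < 2:
        raise ValueError("K must be >= 2 for unsupervised estimation")
    if K > g.n_individuals:
        raise ValueError("K exceeds the number of individuals")
    rng = np.random.default_rng(seed)
    x, obs = _masked_dosage(g)
    n, L = x.shape
    Q = rng.dirichlet(np.ones(K), size=n)
    F = rng.uniform(0.05, 0.95, size=(K, L))
    clamp = 1.0 / (2.0 * n)
    ll = _loglik(x, obs, Q, F)
    trace = [ll]
    for _ in range(max_iter):
        P1 = np.clip(Q @ F, 1e-12, None)
        P0 = np.clip(Q @ (1 - F), 1e-12, None)
        R1 = (obs * x) / P1  # n x L
        R0 = (obs * (2 - x)) / P0
        # expected allele-copy counts attributed to each source
        A = Q * (R1 @ F.T + R0 @ (1 - F).T)  # n x K
        C1 = (Q.T @ R1) * F  # K x L: expected allele-2 copies from source k
        C0 = (Q.T @ R0) * (1 - F)
        Q = A / A.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            F = np.where(C1 + C0 > 0, C1 / (C1 + C0), 0.5)
        F = np.clip(F, clamp, 1 - clamp)
        new_ll = _loglik(x, obs, Q, F)
        trace.append(new_ll)
        if new_ll - ll < tol:
            ll = new_ll
            break
        ll = new_ll
    return AncestryMatrix(
        individual_ids=[i.individual_id for i in g.individuals],
        Q=Q, F=F, log_likelihood=ll, seed=seed, loglik_trace=trace,
    )


# ---------------------------------------------------------------------------
# SSC and mode grouping
# ---------------------------------------------------------------------------


def ssc(q1: AncestryMatrix, q2: AncestryMatrix) -> tuple[float, np.ndarray]:
    """Symmetric similarity coefficient between two membership matrices.

    SSC = max over column permutations pi of
    1 - ||Q1 - Q2[:, pi]||_F / sqrt(2 n); the optimum is found by
    exhaustive search for K <= 8 and by the assignment algorithm on
    column-distance costs for larger K.  Returns (SSC, permutation) where
    ``permutation[j]`` is the column of Q2 aligned to column j of Q1.
    """
    A, B = q1.Q, q2.Q
    if A.shape != B.shape:
        raise ValueError("membership matrices must share (n, K)")
    n, K = A.shape
    # cost[j, k] = squared distance between Q1 column j and Q2 column k
    cost = ((A[:, :, None] - B[:, None, :]) ** 2).sum(axis=0)
    if K <= 8:
        best_perm = None
        best_val = np.inf
        for perm in itertools.permutations(range(K)):
            v = cost[range(K), perm].sum()
            if v < best_val:
                best_val = v
                best_perm = perm
        perm = np.array(best_perm)
        val = best_val
    else:
        rows, cols = linear_sum_assignment(cost)
        perm = cols[np.argsort(rows)]
        val = cost[rows, cols].sum()
    similarity = 1.0 - np.sqrt(max(val, 0.0)) / np.sqrt(2.0 * n)
    return float(similarity), perm


@dataclass
class ModeSet:
    modes: list[list[int]]  # partition of run indices
    permutations: list[list[np.ndarray]]  # per mode, per run: alignment to mode's first run
    averaged: list[AncestryMatrix]  # per mode
    ssc_matrix: np.ndarray  # runs x runs

    def report(self) -> pd.DataFrame:
        rows = []
        for mid, runs in enumerate(self.modes):
            sub = self.ssc_matrix[np.ix_(runs, runs)]
            iu = np.triu_indices(len(runs), k=1)
            mean_ssc = float(sub[iu].mean()) if len(iu[0]) else 1.0
            rows.append({"mode": mid, "n_runs": len(runs),
                         "runs": ",".join(map(str, runs)), "mean_ssc": mean_ssc})
        return pd.DataFrame(rows)


def group_modes(runs: list[AncestryMatrix], threshold: float = 0.9) -> ModeSet:
    """Single-linkage grouping of replicate runs on the SSC > threshold relation.

    Within each mode every run is aligned to the mode's first run by its
    optimal column permutation, memberships are averaged elementwise, and
    rows renormalized.
    """
    if not runs:
        raise ValueError("need at least one run")
    R = len(runs)
    S = np.eye(R)
    perms: dict[tuple[int, int], np.ndarray] = {}
    for i in range(R):
        for j in range(i + 1, R):
            s, p = ssc(runs[i], runs[j])
            S[i, j] = S[j, i] = s
            perms[(i, j)] = p

    # union-find single linkage
    parent = list(range(R))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(R):
        for j in range(i + 1, R):
            if S[i, j] > threshold:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[rb] = ra

    groups: dict[int, list[int]] = {}
    for i in range(R):
        groups.setdefault(find(i), []).append(i)
    modes = sorted(groups.values(), key=lambda g: (-len(g), g[0]))

    averaged = []
    mode_perms = []
    for members in modes:
        first = members[0]
        stack = []
        pl = []
        for m in members:
            if m == first:
                p = np.arange(runs[first].K)
            else:
                _, p = ssc(runs[first], runs[m])
            pl.append(p)
            stack.append(runs[m].Q[:, p])
        mean_q = np.mean(stack, axis=0)
        mean_q = mean_q / mean_q.sum(axis=1, keepdims=True)
        averaged.append(
            AncestryMatrix(individual_ids=list(runs[first].individual_ids), Q=mean_q)
        )
        mode_perms.append(pl)
    return ModeSet(modes=modes, permutations=mode_perms, averaged=averaged, ssc_matrix=S)
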