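"""Moment-based dating of a single admixture pulse.

Under a single founding pulse followed by closed random mating, the
variance of individual ancestry fractions halves each generation:
Var_g(H) = s(1-s)/2^g for founding contribution s.  Inverting with the
sample moments gives g_hat = log2( mu(1-mu) / sigma^2 ).  The estimate is
expressed in years before present as YBP = (g_hat + 1) x generation_years,
the extra generation being that of the sampled individuals themselves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class AdmixtureTimeEstimate:
    group: str
    source: str
    K: int | None
    mu: float
    sigma2: float
    g_hat: float
    ybp: float
    n: int
    flag: str = ""


def admixture_time_moments(
    memberships: np.ndarray,
    generation_years: float = 25.0,
    unbiased: bool = True,
    group: str = "",
    source: str = "",
    K: int | None = None,
) -> AdmixtureTimeEstimate:
    """Estimate generations since a single admixture pulse from moments.

    ``memberships`` are the ancestry fractions of one source in the pooled
    individuals.  Uses the unbiased (n-1) sample variance by default.
    A variance at or above mu(1-mu) yields g_hat <= 0 and is flagged as
    inconsistent with post-founding random mating.
    """
    h = np.asarray(memberships, dtype=float)
    if h.size < 2:
        raise ValueError("need at least 2 individuals")
    mu = float(h.mean())
    if not 0.0 < mu < 1.0:
        raise ValueError("mean membership must lie strictly between 0 and 1")
    sigma2 = float(h.var(ddof=1 if unbiased else 0))
    if sigma2 == 0.0:
        raise ValueError("zero variance of memberships: dating undefined")
    g_hat = math.log2(mu * (1 - mu) / sigma2)
    flag = ""
    if sigma2 >= mu * (1 - mu):
        flag = "inconsistent with post-founding mating"
    ybp = (g_hat + 1.0) * generation_years
    return AdmixtureTimeEstimate(
        group=group, source=source, K=K, mu=mu, sigma2=sigma2,
        g_hat=g_hat, ybp=ybp, n=h.size, flag=flag,
    )


def dating_report(
    memberships_by_k: dict[int, pd.DataFrame],
    pooling: dict[str, list[str]],
    individual_pops: dict[str, str],
    source_columns_by_k: dict[int, dict[str, str]],
    generation_years: float = 25.0,
    unbiased: bool = True,
) -> pd.DataFrame:
    """Per pooled group, per source, per K dating estimates plus cross-K summary.

    ``memberships_by_k`` maps K to a DataFrame of memberships (index =
    individual ids, columns = cluster labels).  ``pooling`` maps a group
    name to its member populations; pooling concatenates the member
    populations' membership vectors before the moments are taken.
    ``source_columns_by_k`` maps K to {source name -> cluster column}; a
    source absent at some K is skipped with a log entry.  The report
    carries the mean and SD of YBP across the K range per (group, source).
    """
    rows = []
    for group, pop_list in pooling.items():
        for K, q in sorted(memberships_by_k.items()):
            ids = [i for i in q.index if individual_pops.get(i) in pop_list]
            if not ids:
                continue
            for source, col in source_columns_by_k.get(K, {}).items():
                if col not in q.columns:
                    log.info("group %s: source %s absent at K=%d, skipped", group, source, K)
                    continue
                try:
                    est = admixture_time_moments(
                        q.loc[ids, col].to_numpy(),
                        generation_years=generation_years,
                        unbiased=unbiased,
                        group=group, source=source, K=K,
                    )
                except ValueError as exc:
                    log.info("group %s source %s K=%d: %s", group, source, K, exc)
                    continue
                rows.append(est.__dict__)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    summary = (
        df.groupby(["group", "source"])["ybp"]
        .agg(ybp_mean="mean", ybp_sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
        .reset_index()
    )
    return df.merge(summary, on=["group", "source"])
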