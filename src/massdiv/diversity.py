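"""Per-site diversity statistics over a sites x OTUs count table.

Implements the singleton bookkeeping (absolute and relative
single-sequence OTUs), Good's coverage with singletons defined as
SSO_abs + SSO_rel, the inverse Simpson index, the closed-form hypergeometric
rarefaction expectation, seeded subsampling to a common depth, and the
occupancy classification into cosmopolitan / locally restricted /
intermediate OTUs.

The OTU table is a pandas DataFrame with one row per site and one column
per OTU (non-negative integer read counts), as produced by
:func:`massdiv.otucluster.build_otu_table`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "SiteDiversityReport",
    "count_sso",
    "goods_coverage",
    "inverse_simpson",
    "rarefaction_curve",
    "subsample_table",
    "classify_occupancy",
    "site_report",
    "table_report",
]


@dataclass
class SiteDiversityReport:
    """All per-site statistics of the survey summary table."""

    site: str
    n_reads: int
    s_obs: int
    sso_abs: int
    sso_rel: int
    coverage: float
    inv_simpson: float
    s_subsampled: int | None = None

    def __post_init__(self) -> None:
        if self.sso_abs + self.sso_rel > self.s_obs:
            raise ValueError("singleton OTUs exceed observed OTUs")
        if not 0.0 <= self.coverage <= 100.0:
            raise ValueError("coverage out of [0, 100]")


def _check_site(table: pd.DataFrame, site: str) -> None:
    if site not in table.index:
        raise KeyError(f"site {site!r} not in table")


def count_sso(table: pd.DataFrame, site: str) -> tuple[int, int]:
    """(absolute, relative) single-sequence OTU counts at ``site``.

    An absolute SSO has exactly one read at this site and none elsewhere
    (a dataset-wide singleton); a relative SSO has one read here but
    occurs again at one or more other sites.
    """
    _check_site(table, site)
    here = table.loc[site].to_numpy()
    elsewhere = table.drop(index=site).to_numpy().sum(axis=0) if len(table) > 1 \
        else np.zeros_like(here)
    singleton = here == 1
    sso_abs = int((singleton & (elsewhere == 0)).sum())
    sso_rel = int((singleton & (elsewhere >= 1)).sum())
    return sso_abs, sso_rel


def goods_coverage(n_reads: int, n_singletons: int, ndigits: int | None = 0) -> float:
    """Good's coverage C = [1 - n/N] * 100 in percent.

    ``n_singletons`` is the number of singleton OTUs (absolute plus
    relative SSO) and ``n_reads`` the total sequences analyzed.  Rounded
    to ``ndigits`` (default integer percent; ``None`` for full precision).
    """
    if n_reads <= 0:
        raise ValueError("N must be positive")
    if not 0 <= n_singletons <= n_reads:
        raise ValueError("singleton count must be in [0, N]")
    c = (1.0 - n_singletons / n_reads) * 100.0
    return c if ndigits is None else round(c, ndigits)


def inverse_simpson(counts, small_sample: bool = False) -> float:
    """Inverse Simpson diversity 1/D of one site's OTU counts.

    Default is the plug-in form 1 / sum(p_i^2); ``small_sample`` switches
    to the unbiased form with D = sum n_i (n_i - 1) / (N (N - 1)), which is
    undefined (NaN) for a site with a single read or no second ranked read.
    """
    c = np.asarray([x for x in counts if x > 0], dtype=float)
    n = c.sum()
    if n <= 0:
        raise ValueError("site has no reads")
    if small_sample:
        if n < 2:
            return float("nan")
        d = (c * (c - 1)).sum() / (n * (n - 1))
        return float("inf") if d == 0 else 1.0 / d
    p = c / n
    return float(1.0 / (p ** 2).sum())


def rarefaction_curve(counts, depths) -> list[float]:
    """Expected OTU richness at each subsampling depth (closed form).

    E[S_m] = S - sum_i C(N - n_i, m) / C(N, m), evaluated in log space.
    """
    c = np.asarray([x for x in counts if x > 0], dtype=float)
    n = int(c.sum())
    out = []
    for m in depths:
        if not 0 <= m <= n:
            raise ValueError(f"depth {m} exceeds site total {n}")
        if m == 0:
            out.append(0.0)
            continue
        keep = (n - c) >= m
        absent = np.zeros_like(c)
        nc = n - c[keep]
        absent_log = (gammaln(nc + 1) - gammaln(m + 1) - gammaln(nc - m + 1)
                      - (gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)))
        absent[keep] = np.exp(absent_log)
        out.append(float(len(c) - absent.sum()))
    return out


def subsample_table(table: pd.DataFrame, depth: int | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Rarefy every site to ``depth`` reads without replacement (seeded).

    Default depth is the smallest per-site total.  A requested depth
    exceeding some site's total is an error naming the site.
    """
    totals = table.sum(axis=1)
    if depth is None:
        depth = int(totals.min())
    bad = totals[totals < depth]
    if len(bad):
        raise ValueError(f"depth {depth} exceeds reads at site(s) "
                         f"{list(bad.index)}")
    rng = np.random.default_rng(seed)
    rows = []
    for site in table.index:
        counts = table.loc[site].to_numpy().astype(np.int64)
        rows.append(rng.multivariate_hypergeometric(counts, depth))
    return pd.DataFrame(rows, index=table.index, columns=table.columns)


def classify_occupancy(table: pd.DataFrame,
                       min_sites_cosmopolitan: int = 10) -> dict[str, str]:
    """Classify OTUs by site occupancy.

    Cosmopolitan: present (count >= 1) at >= ``min_sites_cosmopolitan``
    sites; locally restricted: present at exactly one site; everything
    else intermediate.  The classes partition the OTU set.
    """
    if len(table.index) < 2:
        raise ValueError("occupancy classification needs >= 2 sites")
    occ = (table > 0).sum(axis=0)
    out = {}
    for otu in table.columns:
        if occ[otu] >= min_sites_cosmopolitan:
            out[otu] = "cosmopolitan"
        elif occ[otu] == 1:
            out[otu] = "locally_restricted"
        else:
            out[otu] = "intermediate"
    return out


def site_report(table: pd.DataFrame, site: str,
                subsample_depth: int | None = None,
                seed: int = 0) -> SiteDiversityReport:
    """Assemble all per-site statistics into one report.

    Coverage uses n = SSO_abs + SSO_rel at the site.  ``subsample_depth``
    defaults to the smallest per-site total.
    """
    _check_site(table, site)
    counts = table.loc[site]
    n_reads = int(counts.sum())
    s_obs = int((counts > 0).sum())
    sso_abs, sso_rel = count_sso(table, site)
    sub = subsample_table(table, subsample_depth, seed=seed)
    return SiteDiversityReport(
        site=site,
        n_reads=n_reads,
        s_obs=s_obs,
        sso_abs=sso_abs,
        sso_rel=sso_rel,
        coverage=goods_coverage(n_reads, sso_abs + sso_rel),
        inv_simpson=inverse_simpson(counts),
        s_subsampled=int((sub.loc[site] > 0).sum()),
    )


def table_report(table: pd.DataFrame, subsample_depth: int | None = None,
                 seed: int = 0) -> pd.DataFrame:
    """Per-site reports for every site, as a DataFrame shaped like the
    classic survey summary (N, S_obs, SSO counts, coverage, subsampled S,
    inverse Simpson)."""
    rows = []
    for site in table.index:
        r = site_report(table, site, subsample_depth, seed)
        rows.append({
            "site": r.site, "quality_reads": r.n_reads, "otus": r.s_obs,
            "sso_rel": r.sso_rel, "sso_abs": r.sso_abs,
            "coverage_pct": r.coverage, "otus_subsampled": r.s_subsampled,
            "inverse_simpson": r.inv_simpson,
        })
    return pd.DataFrame(rows).set_index("site")
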