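"""Published per-site survey statistics, used as checkable inputs.

The bundled table carries the per-site summary of the 12-site MasD seep
survey as printed (read counts, observed OTU numbers, singleton
percentages, coverage, subsampled richness, inverse Simpson).  Only the
printed numbers are stored; derived quantities (singleton counts, Good's
coverage, diversity ratios) are recomputed from them at run time, which is
what makes the table useful as a consistency check of the statistics
implemented in :mod:`massdiv.diversity`.

The printed row for site AMV760 is internally inconsistent (its singleton
percentages imply a coverage of about 86% against a printed 89%), so
consistency checks conventionally exclude it.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_seep_site_table",
    "reconstruct_singletons",
    "INCONSISTENT_SITES",
]

#: Sites whose printed statistics do not reproduce from their own row.
INCONSISTENT_SITES = ("AMV760",)


def load_seep_site_table() -> pd.DataFrame:
    """The published per-site summary table, indexed by site."""
    with resources.files("massdiv.data").joinpath("seep_sites.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="site")


def reconstruct_singletons(otus: int, sso_rel_pct: float,
                           sso_abs_pct: float) -> int:
    """Singleton OTU count implied by printed OTU count and SSO percentages.

    n = round(S_obs * (rel% + abs%) / 100); this is the ``n`` entering
    Good's coverage.
    """
    return round(otus * (sso_rel_pct + sso_abs_pct) / 100.0)
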