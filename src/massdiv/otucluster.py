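"""Protein distance matrices and OTU clustering at calibrated thresholds.

Accepted MasD fragments are projected onto the anchor coordinate system,
restricted to the clustering region (anchor columns 398-500, 1-based), and
clustered agglomeratively into OTUs at the calibrated identity thresholds
(species 0.04, genus 0.14, family 0.28 as distances).

Distances are computed column-wise on the anchor-induced alignment (the
convention of alignment-based amplicon distance tools): columns where both
sequences carry a residue are match/mismatch columns, internal gap columns
count as mismatches, and columns outside either sequence's covered span are
excluded.  A per-pair global-alignment mode is available as a config
switch (``pairwise="global"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import anchors
from ._align import align_to_anchor_columns, percent_identity

__all__ = [
    "DEFAULT_THRESHOLDS",
    "RegionExtract",
    "DistanceMatrix",
    "OTUAssignment",
    "extract_region",
    "extract_regions",
    "dereplicate",
    "distance_matrix",
    "cluster_otus",
    "build_otu_table",
]

#: Species / genus / family distance thresholds from the calibrated
#: 96 / 86 / 72 % identity cutoffs.
DEFAULT_THRESHOLDS = {"species": 0.04, "genus": 0.14, "family": 0.28}

#: Default clustering region in 0-based half-open anchor columns
#: (1-based inclusive 398-500).
DEFAULT_REGION = (anchors.REGION_1BASED[0] - 1, anchors.REGION_1BASED[1])

#: Minimum fraction of the region a sequence must cover to be clustered.
MIN_REGION_COVERAGE = 0.8


@dataclass
class RegionExtract:
    """A sequence's residues over the anchor region.

    ``projection`` has one character per anchor column ('-' where the
    sequence has no residue); ``sequence`` is the ungapped residue string.
    """

    read_id: str
    projection: str
    coverage: float
    site: str | None = None

    @property
    def sequence(self) -> str:
        return self.projection.replace("-", "")


@dataclass
class DistanceMatrix:
    """Symmetric distances in [0, 1] with a zero diagonal."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0.0):
            raise ValueError("matrix must be symmetric with zero diagonal")
        self.matrix = m

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


@dataclass
class OTUAssignment:
    """Partition of sequences into OTUs at one threshold."""

    assignment: dict[str, int]
    threshold: float
    linkage: str


def extract_region(
    protein: str,
    anchor: str = anchors.ANCHOR_PROTEIN,
    region: tuple[int, int] = DEFAULT_REGION,
    read_id: str = "",
    site: str | None = None,
) -> RegionExtract | None:
    """Project ``protein`` onto anchor columns ``[start, end)``.

    Returns ``None`` when the protein is unalignable or covers less than
    80% of the region.
    """
    start, end = region
    col_map, identity = align_to_anchor_columns(anchor, protein)
    if identity < 25.0:
        return None
    cols = col_map[start:end]
    chars = [protein[q] if 0 <= q < len(protein) else "-" for q in cols]
    projection = "".join(chars)
    coverage = 1.0 - projection.count("-") / (end - start)
    if coverage < MIN_REGION_COVERAGE:
        return None
    return RegionExtract(read_id=read_id, projection=projection,
                         coverage=coverage, site=site)


def extract_regions(translated_reads, anchor: str = anchors.ANCHOR_PROTEIN,
                    region: tuple[int, int] = DEFAULT_REGION):
    """Extract the clustering region from every accepted read.

    Returns ``(extracts, dropped_ids)``; drops are reads that were
    unalignable or covered less than 80% of the region.
    """
    extracts, dropped = [], []
    for tr in translated_reads:
        ex = extract_region(tr.protein, anchor, region,
                            read_id=tr.read_id, site=tr.site)
        if ex is None:
            dropped.append(tr.read_id)
        else:
            extracts.append(ex)
    return extracts, dropped


def dereplicate(seqs: list[str]) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Unique sequences plus the input->unique index map and counts.

    Uniques are ordered by decreasing multiplicity, ties by sequence, so
    downstream labels are independent of input order.
    """
    counts: dict[str, int] = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    uniques = sorted(counts, key=lambda s: (-counts[s], s))
    index_of = {s: i for i, s in enumerate(uniques)}
    rep = np.array([index_of[s] for s in seqs], dtype=int)
    mult = np.array([counts[s] for s in uniques], dtype=int)
    return uniques, rep, mult


def _aligned_distances(projections: list[str]) -> np.ndarray:
    """Column-wise distances over equal-length anchor projections."""
    arr = np.array([list(p.encode()) for p in projections], dtype=np.uint8)
    gap = ord("-")
    n, ncol = arr.shape
    res = arr != gap
    first = res.argmax(axis=1)
    last = ncol - 1 - res[:, ::-1].argmax(axis=1)
    d = np.zeros((n, n))
    for i in range(n):
        lo = np.maximum(first[i], first[i + 1:])
        hi = np.minimum(last[i], last[i + 1:])
        for k, j in enumerate(range(i + 1, n)):
            if hi[k] < lo[k]:
                d[i, j] = d[j, i] = 1.0
                continue
            a = arr[i, lo[k]:hi[k] + 1]
            b = arr[j, lo[k]:hi[k] + 1]
            valid = ~((a == gap) & (b == gap))
            nv = int(valid.sum())
            ident = int(((a == b) & (a != gap)).sum())
            d[i, j] = d[j, i] = 1.0 - ident / nv if nv else 1.0
    return d


def distance_matrix(
    regions,
    pairwise: str = "aligned",
) -> tuple[DistanceMatrix, np.ndarray, np.ndarray]:
    """Dereplicate regions and compute their pairwise distance matrix.

    ``regions`` is a list of :class:`RegionExtract` (or plain strings in
    ``pairwise="global"`` mode).  ``pairwise`` chooses the distance
    backend: ``"aligned"`` (column-wise on the anchor projection, default)
    or ``"global"`` (per-pair end-gap-free global alignment identity).

    Returns ``(dm, rep_index, multiplicities)`` where ``rep_index[i]`` maps
    input ``i`` to its row in ``dm`` and ``multiplicities`` gives per-row
    abundance.
    """
    if len(regions) < 1:
        raise ValueError("no regions supplied")
    if pairwise not in ("aligned", "global"):
        raise ValueError(f"unknown pairwise mode {pairwise!r}")
    if pairwise == "aligned":
        seqs = [r.projection if isinstance(r, RegionExtract) else r
                for r in regions]
    else:
        seqs = [r.sequence if isinstance(r, RegionExtract) else r
                for r in regions]
    uniques, rep, mult = dereplicate(seqs)
    labels = [f"u{i:05d}" for i in range(len(uniques))]
    if pairwise == "aligned":
        if len({len(s) for s in uniques}) != 1:
            raise ValueError("aligned mode requires equal-length projections")
        mat = _aligned_distances(uniques)
    else:
        n = len(uniques)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ident = percent_identity(uniques[i], uniques[j], "protein")
                mat[i, j] = mat[j, i] = 1.0 - ident / 100.0
    return DistanceMatrix(labels=labels, matrix=mat), rep, mult


def cluster_otus(
    dm: DistanceMatrix,
    threshold: float = DEFAULT_THRESHOLDS["species"],
    linkage: str = "nearest",
) -> OTUAssignment:
    """Agglomerative clustering stopped at a distance threshold.

    ``linkage`` is one of ``furthest`` (complete), ``average`` (UPGMA) or
    ``nearest`` (single).  Clusters are merged while the minimal
    inter-cluster linkage distance is <= ``threshold``; ties are broken by
    the lexicographically smallest pair of cluster representative labels
    (a representative is the smallest member label).  The result is a
    deterministic partition independent of input order.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if linkage not in ("furthest", "average", "nearest"):
        raise ValueError(f"unknown linkage {linkage!r}")
    n = len(dm.labels)
    if n == 0:
        raise ValueError("empty distance matrix")
    d = dm.matrix.copy()
    np.fill_diagonal(d, np.inf)
    active = list(range(n))
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    reps = {i: dm.labels[i] for i in range(n)}
    sizes = {i: 1 for i in range(n)}

    while len(active) > 1:
        sub = d[np.ix_(active, active)]
        mn = sub.min()
        if mn > threshold:
            break
        ii, jj = np.where(sub == mn)
        # deterministic tie-break on representative labels
        best = min(
            ((active[a], active[b]) for a, b in zip(ii, jj) if a < b),
            key=lambda p: tuple(sorted((reps[p[0]], reps[p[1]]))),
        )
        a, b = best
        if reps[b] < reps[a]:
            a, b = b, a
        # Lance-Williams update of cluster a; retire b
        da, db = d[a, :], d[b, :]
        if linkage == "nearest":
            new = np.minimum(da, db)
        elif linkage == "furthest":
            new = np.maximum(da, db)
        else:
            new = (sizes[a] * da + sizes[b] * db) / (sizes[a] + sizes[b])
        d[a, :] = new
        d[:, a] = new
        d[a, a] = np.inf
        d[b, :] = np.inf
        d[:, b] = np.inf
        members[a].extend(members.pop(b))
        sizes[a] += sizes.pop(b)
        reps[a] = min(reps[a], reps.pop(b))
        active.remove(b)

    assignment: dict[str, int] = {}
    for otu_id, root in enumerate(sorted(members, key=lambda r: reps[r])):
        for m in members[root]:
            assignment[dm.labels[m]] = otu_id
    return OTUAssignment(assignment=assignment, threshold=threshold,
                         linkage=linkage)


def build_otu_table(
    assignment: OTUAssignment,
    sites: list[str],
    rep_index: np.ndarray,
    dm_labels: list[str] | None = None,
    site_order: list[str] | None = None,
) -> pd.DataFrame:
    """Accumulate per-site read counts into a sites x OTUs table.

    ``sites[i]`` is the site of input sequence ``i`` and ``rep_index[i]``
    its dereplicated row (as returned by :func:`distance_matrix`).  OTU
    columns are labelled ``OTU#1, OTU#2, ...`` in decreasing total
    abundance (ties by first-seen cluster).
    """
    if len(sites) != len(rep_index):
        raise ValueError("sites and rep_index must have equal length")
    if any(s is None for s in sites):
        raise ValueError("every sequence must have a site")
    if dm_labels is None:
        nmax = int(np.max(rep_index)) + 1 if len(rep_index) else 0
        dm_labels = [f"u{i:05d}" for i in range(nmax)]
    cluster_of_row = np.array([assignment.assignment[lab] for lab in dm_labels])
    n_clusters = cluster_of_row.max() + 1 if len(cluster_of_row) else 0
    if site_order is None:
        site_order = sorted(set(sites))
    site_idx = {s: i for i, s in enumerate(site_order)}
    counts = np.zeros((len(site_order), n_clusters), dtype=int)
    for s, r in zip(sites, rep_index):
        counts[site_idx[s], cluster_of_row[r]] += 1
    totals = counts.sum(axis=0)
    order = sorted(range(n_clusters), key=lambda c: (-totals[c], c))
    counts = counts[:, order]
    columns = [f"OTU#{k + 1}" for k in range(n_clusters)]
    return pd.DataFrame(counts, index=pd.Index(site_order, name="site"),
                        columns=columns)
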