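"""Region extraction, distances and agglomerative OTU clustering."""

import random

import numpy as np
import pytest

from massdiv import anchors
from massdiv.otucluster import (DistanceMatrix, RegionExtract, build_otu_table,
                                cluster_otus, dereplicate, distance_matrix,
                                extract_region, extract_regions)

REGION = (anchors.REGION_1BASED[0] - 1, anchors.REGION_1BASED[1])


class TestExtractRegion:
    def test_anchor_yields_its_own_region(self):
        ex = extract_region(anchors.ANCHOR_PROTEIN)
        assert ex.sequence == anchors.ANCHOR_PROTEIN[REGION[0]:REGION[1]]
        assert ex.coverage == 1.0

    def test_internal_deletion_shortens_region(self):
        start, end = REGION
        p = anchors.ANCHOR_PROTEIN
        deleted = p[:440] + p[443:]  # 3-residue deletion inside the region
        ex = extract_region(deleted)
        assert len(ex.sequence) == (end - start) - 3

    def test_unalignable_dropped(self):
        rng = random.Random(13)
        junk = "".join(rng.choice("ACDEFG") for _ in range(30))
        assert extract_region(junk) is None

    def test_clean_read_region_equals_reference_region(self, clean_demuxed):
        from massdiv.orfscreen import screen
        _spec, refs, kept, _rep, truth = clean_demuxed
        accepted, _ = screen(kept[:10])
        extracts, dropped = extract_regions(accepted)
        assert not dropped
        for ex in extracts:
            otu = int(truth.loc[ex.read_id].otu)
            ref_ex = extract_region(refs[otu])
            assert ex.sequence == ref_ex.sequence


class TestDistanceMatrix:
    def test_duplicates_collapse_to_zero_distance(self):
        seqs = ["AAAA", "AAAA", "AAAC"]
        dm, rep, mult = distance_matrix(seqs)
        assert len(dm.labels) == 2
        assert mult.tolist() == [2, 1]
        assert dm.matrix[0, 0] == 0.0

    def test_four_differences_in_hundred_columns(self):
        rng = random.Random(14)
        a = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(100))
        b = list(a)
        for pos in rng.sample(range(100), 4):
            b[pos] = rng.choice([x for x in "ACDEFGHIKLMNPQRSTVWY"
                                 if x != b[pos]])
        dm, _, _ = distance_matrix([a, "".join(b)])
        assert dm.matrix[0, 1] == pytest.approx(0.04)

    def test_matches_bruteforce_recomputation(self):
        # pure-python oracle over gapped projections, same column convention
        rng = random.Random(15)
        projs = []
        for _ in range(12):
            p = [rng.choice("ACDEFG-") for _ in range(40)]
            p[0], p[-1] = "A", "C"  # keep spans full for a few
            projs.append("".join(p))

        def oracle(x, y):
            xs = [i for i, c in enumerate(x) if c != "-"]
            ys = [i for i, c in enumerate(y) if c != "-"]
            lo, hi = max(xs[0], ys[0]), min(xs[-1], ys[-1])
            if hi < lo:
                return 1.0
            cols = [(a, b) for a, b in zip(x[lo:hi + 1], y[lo:hi + 1])
                    if not (a == "-" and b == "-")]
            ident = sum(a == b and a != "-" for a, b in cols)
            return 1.0 - ident / len(cols)

        dm, rep, _ = distance_matrix(projs)
        uniques, _, _ = dereplicate(projs)
        for i in range(len(uniques)):
            for j in range(i + 1, len(uniques)):
                assert dm.matrix[i, j] == pytest.approx(
                    oracle(uniques[i], uniques[j]))

    def test_global_mode_agrees_on_ungapped_sequences(self):
        rng = random.Random(16)
        seqs = []
        base = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(60))
        for _ in range(5):
            s = list(base)
            for pos in rng.sample(range(60), 3):
                s[pos] = rng.choice([x for x in "ACDEFGHIKLMNPQRSTVWY"
                                     if x != s[pos]])
            seqs.append("".join(s))
        dm_a, _, _ = distance_matrix(seqs, pairwise="aligned")
        dm_g, _, _ = distance_matrix(seqs, pairwise="global")
        assert np.allclose(dm_a.matrix, dm_g.matrix, atol=1e-9)


def _random_dm(n, seed):
    rng = np.random.default_rng(seed)
    m = rng.uniform(0.01, 0.5, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(labels=[f"u{i:05d}" for i in range(n)], matrix=m)


def _oracle_cluster(dm, threshold, linkage):
    """Straightforward list-based agglomerative clustering (test oracle)."""
    clusters = [[i] for i in range(len(dm.labels))]

    def linkdist(a, b):
        ds = [dm.matrix[i, j] for i in a for j in b]
        if linkage == "furthest":
            return max(ds)
        if linkage == "nearest":
            return min(ds)
        return sum(ds) / len(ds)

    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                d = linkdist(clusters[x], clusters[y])
                key = (d, sorted((min(clusters[x]), min(clusters[y]))))
                if best is None or key < best[0]:
                    best = (key, x, y)
        (d, _), x, y = best
        if d > threshold:
            break
        clusters[x] = clusters[x] + clusters[y]
        del clusters[y]
    out = {}
    for c in clusters:
        for i in c:
            out[dm.labels[i]] = min(c)
    return out


def _partition(assignment):
    groups = {}
    for label, cid in assignment.items():
        groups.setdefault(cid, set()).add(label)
    return {frozenset(g) for g in groups.values()}


class TestClusterOTUs:
    def test_all_distances_above_threshold_gives_singletons(self):
        dm = _random_dm(6, 17)
        asn = cluster_otus(dm, threshold=0.001, linkage="furthest")
        assert len(set(asn.assignment.values())) == 6

    def test_all_distances_below_threshold_gives_one_otu(self):
        dm = _random_dm(6, 18)
        asn = cluster_otus(dm, threshold=0.9, linkage="furthest")
        assert len(set(asn.assignment.values())) == 1

    @pytest.mark.parametrize("linkage", ["furthest", "average", "nearest"])
    def test_matches_bruteforce_oracle(self, linkage):
        for seed in range(5):
            dm = _random_dm(10, 100 + seed)
            asn = cluster_otus(dm, threshold=0.25, linkage=linkage)
            oracle = _oracle_cluster(dm, 0.25, linkage)
            got = _partition(asn.assignment)
            want = {frozenset(k for k, v in oracle.items() if v == root)
                    for root in set(oracle.values())}
            assert got == want

    def test_otu_count_monotone_in_threshold(self):
        dm = _random_dm(12, 19)
        counts = [len(set(cluster_otus(dm, t, "furthest").assignment.values()))
                  for t in (0.05, 0.15, 0.25, 0.35, 0.45)]
        assert counts == sorted(counts, reverse=True)

    def test_linkage_ordering(self):
        dm = _random_dm(12, 20)
        n = {lk: len(set(cluster_otus(dm, 0.2, lk).assignment.values()))
             for lk in ("nearest", "average", "furthest")}
        assert n["nearest"] <= n["average"] <= n["furthest"]

    def test_partition_invariant_to_input_order(self):
        dm = _random_dm(9, 21)
        perm = np.random.default_rng(0).permutation(9)
        dm2 = DistanceMatrix(labels=[dm.labels[i] for i in perm],
                             matrix=dm.matrix[np.ix_(perm, perm)])
        p1 = _partition(cluster_otus(dm, 0.2, "furthest").assignment)
        p2 = _partition(cluster_otus(dm2, 0.2, "furthest").assignment)
        assert p1 == p2

    def test_agrees_with_scipy_on_generic_data(self):
        # independent cross-check against scipy's agglomerative clustering
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform
        for seed in range(3):
            dm = _random_dm(15, 300 + seed)
            for ours, theirs in (("furthest", "complete"),
                                 ("average", "average"),
                                 ("nearest", "single")):
                asn = cluster_otus(dm, 0.2, ours)
                fc = fcluster(linkage(squareform(dm.matrix, checks=False),
                                      theirs), t=0.2, criterion="distance")
                ours_part = _partition(asn.assignment)
                theirs_part = {
                    frozenset(dm.labels[i] for i in range(15) if fc[i] == c)
                    for c in set(fc)}
                assert ours_part == theirs_part


class TestBuildOTUTable:
    def test_single_site_single_otu(self):
        seqs = ["AAAA", "AAAA", "AAAA"]
        dm, rep, _ = distance_matrix(seqs)
        asn = cluster_otus(dm, 0.04)
        table = build_otu_table(asn, ["S01"] * 3, rep, dm.labels)
        assert table.shape == (1, 1) and table.iloc[0, 0] == 3

    def test_row_sums_conserved(self, random_otu_table):
        rng = random.Random(22)
        seqs, sites = [], []
        base = "ACDEFGHIKL" * 4
        for i in range(30):
            s = list(base)
            s[i % 40] = "W"
            seqs.append("".join(s))
            sites.append(f"S{i % 3}")
        dm, rep, _ = distance_matrix(seqs)
        asn = cluster_otus(dm, 0.04)
        table = build_otu_table(asn, sites, rep, dm.labels)
        for s in set(sites):
            assert table.loc[s].sum() == sites.count(s)

    def test_columns_ordered_by_total_abundance(self):
        seqs = ["AAAA"] * 5 + ["CCCC"] * 2 + ["GGGG"] * 8
        dm, rep, _ = distance_matrix(seqs)
        asn = cluster_otus(dm, 0.01)
        table = build_otu_table(asn, ["S01"] * 15, rep, dm.labels)
        totals = table.sum(axis=0).tolist()
        assert totals == sorted(totals, reverse=True)
        assert list(table.columns) == ["OTU#1", "OTU#2", "OTU#3"]

    def test_zero_error_table_matches_truth_aggregation(self, clean_demuxed):
        from massdiv.orfscreen import screen
        spec, _refs, kept, _rep, truth = clean_demuxed
        accepted, _ = screen(kept)
        extracts, _ = extract_regions(accepted)
        dm, rep, _ = distance_matrix(extracts)
        asn = cluster_otus(dm, 0.04)
        table = build_otu_table(asn, [e.site for e in extracts], rep, dm.labels)
        truth_counts = truth.groupby(["site", "otu"]).size().unstack(fill_value=0)
        assert table.shape == truth_counts.shape
        for site in table.index:
            assert sorted(table.loc[site].tolist()) == \
                sorted(truth_counts.loc[site].tolist())

    def test_missing_site_rejected(self):
        dm, rep, _ = distance_matrix(["AAAA", "CCCC"])
        asn = cluster_otus(dm, 0.01)
        with pytest.raises(ValueError):
            build_otu_table(asn, ["S01", None], rep, dm.labels)
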