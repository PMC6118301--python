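"""Cross-validation design construction: sizes, counts and disjointness."""

import numpy as np
import pandas as pd
import pytest

import gsdesign as g
from gsdesign.structure import ClusterAssignment


def make_assignment(k=5, per_cluster=1500):
    n = k * per_cluster
    ids = np.array([f"l{i:05d}" for i in range(n)])
    labels = np.repeat(np.arange(1, k + 1), per_cluster)
    return ClusterAssignment(ids, labels, k, within_ss=0.0, seed=0)


class TestSizeSeries:
    def test_replicate_counts_from_large_pool(self):
        """An 8,300-line pool yields 33/16/8/4/2/2/1 disjoint subsets for
        sizes 250 to 5,000."""
        ids = [f"l{i}" for i in range(10375)]
        sizes = [250, 500, 1000, 2000, 3000, 4000, 5000, 6000, 7000]
        design = g.size_series_design(ids, sizes, n_folds=5, seed=0)
        df = pd.DataFrame([s.meta | {"n": len(s.train)} for s in design])
        counts = df.groupby(["fold", "size"]).size().unstack()
        expected = {250: 33, 500: 16, 1000: 8, 2000: 4, 3000: 2, 4000: 2,
                    5000: 1, 6000: 1, 7000: 1}
        for size, n_rep in expected.items():
            assert (counts[size] == n_rep).all()
        # folds of a 10,375-line panel hold 2,075 lines each
        assert all(len(s.valid) == 2075 for s in design)
        # and the maximal training set is the full 8,300-line pool
        assert counts[8300].eq(1).all()

    def test_disjointness_exhaustive(self):
        ids = [f"l{i}" for i in range(200)]
        design = g.size_series_design(ids, [30, 60], n_folds=4, seed=1)
        by_fold_size = {}
        for s in design:
            assert not set(s.train) & set(s.valid)
            by_fold_size.setdefault((s.meta["fold"], s.meta["size"]),
                                    []).append(set(s.train))
        for (_, size), trains in by_fold_size.items():
            seen = set()
            for t in trains:
                assert len(t) == size
                assert not t & seen  # replicates sampled without replacement
                seen |= t

    def test_size_equal_to_pool(self):
        ids = [f"l{i}" for i in range(100)]
        design = g.size_series_design(ids, [75], n_folds=4, seed=0)
        for s in design:
            if s.meta["size"] == 75:
                assert set(s.train) | set(s.valid) == set(ids)

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError, match="exceeds the pool"):
            g.size_series_design([f"l{i}" for i in range(100)], [90],
                                 n_folds=4, seed=0)


class TestClusterDesigns:
    def test_fixed_training_and_validation_sizes(self):
        designs = g.cluster_designs(make_assignment(), seed=0)
        assert {d.label for d in designs} == {
            "all_clusters", "within_cluster", "between_narrow",
            "between_broad"}
        for d in designs:
            for s in d:
                assert len(s.train) == 1000 and len(set(s.train)) == 1000
                assert len(s.valid) == 500 and len(set(s.valid)) == 500
                assert not set(s.train) & set(s.valid)

    def test_between_narrow_covers_all_ordered_pairs(self):
        designs = {d.label: d for d in g.cluster_designs(make_assignment(),
                                                         seed=0)}
        narrow = designs["between_narrow"]
        pairs = {(s.meta["train_cluster"], s.meta["valid_cluster"])
                 for s in narrow}
        assert len(pairs) == 20  # 5 x 4 ordered cluster pairs

    def test_within_cluster_split_stays_in_one_cluster(self):
        asg = make_assignment()
        membership = asg.series()
        designs = {d.label: d for d in g.cluster_designs(asg, seed=0)}
        for s in designs["within_cluster"]:
            clusters = set(membership.loc[list(s.train + s.valid)])
            assert len(clusters) == 1

    def test_all_clusters_uses_equal_quotas(self):
        asg = make_assignment()
        membership = asg.series()
        designs = {d.label: d for d in g.cluster_designs(asg, seed=0)}
        for s in designs["all_clusters"]:
            t = membership.loc[list(s.train)].value_counts()
            v = membership.loc[list(s.valid)].value_counts()
            assert (t == 200).all() and (v == 100).all()

    def test_broad_training_excludes_validation_cluster(self):
        asg = make_assignment()
        membership = asg.series()
        designs = {d.label: d for d in g.cluster_designs(asg, seed=0)}
        for s in designs["between_broad"]:
            t = membership.loc[list(s.train)].value_counts()
            assert s.meta["valid_cluster"] not in t.index
            assert (t == 250).all()

    def test_small_cluster_rejected_by_name(self):
        asg = make_assignment(per_cluster=1000)
        with pytest.raises(ValueError, match="cluster 1"):
            g.cluster_designs(asg, per_cluster=1500, seed=0)


class TestCohortDesigns:
    def _labels(self, n_years=4, per_year=996, start=2010):
        idx, years = [], []
        for j in range(n_years):
            for i in range(per_year):
                idx.append(f"y{start + j}_l{i}")
                years.append(start + j)
        return pd.Series(years, index=pd.Index(idx))

    def test_training_subset_sizes(self):
        """One/two/three prior cohorts train with 996/498/332 lines each."""
        designs = {d.label: d for d in g.cohort_designs(self._labels(),
                                                        seed=0)}
        for d, per in ((1, 996), (2, 498), (3, 332)):
            for s in designs[f"cohort_{d}prior"]:
                assert len(s.train) == per * d
                years = pd.Series([int(i[1:5]) for i in s.train])
                assert (years.value_counts() == per).all()

    def test_one_prior_enumerates_consecutive_years(self):
        designs = {d.label: d for d in g.cohort_designs(self._labels(),
                                                        seed=0)}
        steps = {(min(int(i[1:5]) for i in s.train), s.meta["target"])
                 for s in designs["cohort_1prior"]}
        assert steps == {(2010, 2011), (2011, 2012), (2012, 2013)}

    def test_validation_is_the_following_cohort(self):
        designs = g.cohort_designs(self._labels(), seed=0)
        for d in designs:
            for s in d:
                valid_years = {int(i[1:5]) for i in s.valid}
                assert valid_years == {s.meta["target"]}
                assert max(int(i[1:5]) for i in s.train) < s.meta["target"]

    def test_rotations_are_disjoint(self):
        designs = {d.label: d for d in g.cohort_designs(self._labels(),
                                                        seed=0)}
        two = [s for s in designs["cohort_2prior"]
               if s.meta["target"] == 2012]
        assert len(two) == 2
        assert not set(two[0].train) & set(two[1].train)


def test_split_rejects_overlap():
    with pytest.raises(ValueError, match="overlap"):
        g.Split(("a", "b"), ("b", "c"), 0)
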