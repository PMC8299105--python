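import numpy as np
import pytest

from microniche import (OtuTable, SampleMetadata, NicheBreadthClassifier,
                        classify, niche_breadth, suggest_outlier_threshold)

from conftest import random_table


class TestNicheBreadth:
    @pytest.mark.parametrize("profile,expected", [
        ([0.25, 0.25, 0.25, 0.25], 4.0),
        ([1.0, 0.0, 0.0], 1.0),
        ([0.75, 0.25], 1.6),
    ])
    def test_known_values(self, profile, expected):
        assert niche_breadth(profile) == pytest.approx(expected, abs=1e-12)

    def test_zero_sum_rejected(self):
        with pytest.raises(ValueError):
            niche_breadth([0.0, 0.0])

    def test_bounded_by_occurrence_on_random_profiles(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            k = rng.integers(1, 30)
            v = rng.random(k) + 1e-9
            v = np.concatenate([v, np.zeros(rng.integers(0, 10))])
            p = v / v.sum()
            b = niche_breadth(p)
            occ = (p > 0).sum()
            assert 1 - 1e-9 <= b <= occ + 1e-9

    def test_invariant_to_count_scaling(self):
        counts = np.array([3.0, 1.0, 0.0, 6.0])
        p1 = counts / counts.sum()
        p2 = (counts * 17) / (counts * 17).sum()
        assert niche_breadth(p1) == pytest.approx(niche_breadth(p2), abs=1e-12)


class TestOutlierThreshold:
    def test_integer_range_upper_fence(self):
        vals = np.arange(1, 101)
        assert suggest_outlier_threshold(vals, "upper") == pytest.approx(149.5)

    def test_constant_values_collapse(self):
        vals = [5.0] * 10
        assert suggest_outlier_threshold(vals, "upper") == 5.0
        assert suggest_outlier_threshold(vals, "lower") == 5.0

    def test_flags_extreme_value(self):
        fence = suggest_outlier_threshold([0, 0, 0, 100], "upper")
        assert 100 > fence

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            suggest_outlier_threshold([1, 2, 3], "upper")


def _region_map(n_north, n_south):
    region = {}
    ids = []
    for i in range(n_north):
        s = f"n{i}"
        region[s] = "north"
        ids.append(s)
    for i in range(n_south):
        s = f"s{i}"
        region[s] = "south"
        ids.append(s)
    return ids, region


class TestClassifyRules:
    def _classify(self, counts, region, **kw):
        p, n = counts.shape
        table = OtuTable([f"o{i}" for i in range(p)], list(region), counts)
        meta = SampleMetadata(region=region)
        kw.setdefault("specialist_b_thresholds", {"north": 12.0, "south": 17.0})
        return classify(table, meta, **kw)

    def test_generalist_rule_fires(self):
        ids, region = _region_map(15, 15)
        counts = np.ones((2, 30), dtype=int)
        counts[0, 20:] = 0          # focal OTU in 20/30 samples, even -> B=20
        counts[1] = 5               # companion keeps columns non-zero
        res = self._classify(counts, region)
        assert res.loc["o0", "label"] == "generalist"

    def test_boundary_b_not_generalist(self):
        # uniform over 17 samples -> B = 17.0, not strictly above threshold
        ids, region = _region_map(10, 7)
        counts = np.vstack([np.ones(17, dtype=int),
                            np.full(17, 5, dtype=int)])
        res = self._classify(counts, region)
        assert res.loc["o0", "B_global"] == pytest.approx(17.0)
        assert res.loc["o0", "label"] != "generalist"

    def test_specialist_rule_fires(self):
        ids, region = _region_map(15, 15)
        counts = np.zeros((2, 30), dtype=int)
        counts[0, :6] = 10          # 6 north samples only -> B_north <= 6 < 12
        counts[1] = 3
        res = self._classify(counts, region)
        assert res.loc["o0", "label"] == "specialist:north"

    def test_specialist_needs_occurrence_above_four(self):
        ids, region = _region_map(15, 15)
        counts = np.zeros((2, 30), dtype=int)
        counts[0, :4] = 10          # exactly 4 -> "higher than four" fails
        counts[1] = 3
        res = self._classify(counts, region)
        assert not res.loc["o0", "label"].startswith("specialist")

    def test_abundance_filter_blocks_generalist(self):
        # region sizes chosen so the OTU also fails both specialist rules
        # (B_north = 13 > 12; B_south = 18 > 17)
        ids, region = _region_map(13, 18)
        counts = np.ones((2, 31), dtype=int)
        counts[1] = 100_000         # pushes o0's mean relabund below 2e-5
        res = self._classify(counts, region)
        assert res.loc["o0", "label"] == "filtered"
        assert res.loc["o0", "mean_relabund"] < 2e-5

    def test_multi_region_qualification_is_tie(self):
        ids, region = _region_map(15, 15)
        counts = np.zeros((2, 30), dtype=int)
        counts[0, :6] = 10          # qualifies in north (B<=6<12)
        counts[0, 15:21] = 10       # and in south (B<=6<17)
        counts[1] = 3
        res = self._classify(counts, region)
        assert res.loc["o0", "label"] == "medium"
        assert set(res.loc["o0", "specialist_tie_regions"].split(";")) == {
            "north", "south"}

    def test_region_with_one_sample_rejected(self):
        region = {"a": "north", "b": "south", "c": "south"}
        counts = np.ones((1, 3), dtype=int)
        table = OtuTable(["o0"], ["a", "b", "c"], counts)
        with pytest.raises(ValueError, match="fewer than 2"):
            classify(table, SampleMetadata(region=region),
                     specialist_b_thresholds=17.0)

    def test_unknown_sample_rejected(self):
        table = OtuTable(["o0"], ["a", "b"], np.ones((1, 2), dtype=int))
        with pytest.raises(ValueError, match="missing region"):
            classify(table, SampleMetadata(region={"a": "north"}))


# ---------------------------------------------------------------------------
# independent brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_labels(table, metadata, gen_b=17.0, gen_occ=0.5,
                       min_ra=2e-5, spec_b=None, spec_occ=4):
    """Straightforward re-derivation of every quantity from the definitions."""
    labels = {}
    n = len(table.sample_ids)
    regions = sorted(set(metadata.region.values()))
    for i, otu in enumerate(table.otu_ids):
        row = table.counts[i].astype(float)
        # mean within-sample relative abundance
        ras = []
        for j in range(n):
            col = table.counts[:, j].astype(float)
            ras.append(row[j] / col.sum())
        mean_ra = sum(ras) / n
        occ = sum(1 for v in row if v > 0)
        if row.sum() > 0:
            prof = [v / row.sum() for v in row]
            b_global = 1.0 / sum(p * p for p in prof)
        else:
            b_global = None
        is_gen = (mean_ra >= min_ra and b_global is not None
                  and b_global > gen_b and occ / n > gen_occ)
        if is_gen:
            labels[otu] = "generalist"
            continue
        qual = []
        for r in regions:
            js = [j for j, s in enumerate(table.sample_ids)
                  if metadata.region[s] == r]
            sub = [row[j] for j in js]
            tot = sum(sub)
            occ_r = sum(1 for v in sub if v > 0)
            if tot == 0:
                continue
            b_r = 1.0 / sum((v / tot) ** 2 for v in sub)
            cut = spec_b[r] if isinstance(spec_b, dict) else spec_b
            if occ_r > spec_occ and b_r < cut:
                qual.append(r)
        if len(qual) == 1:
            labels[otu] = f"specialist:{qual[0]}"
        elif mean_ra < min_ra:
            labels[otu] = "filtered"
        else:
            labels[otu] = "medium"
    return labels


class TestOracleEquivalence:
    def test_labels_match_brute_force_on_random_tables(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            table = random_table(rng, max_otus=20, max_samples=16)
            if table.n_samples < 4:
                continue
            half = table.n_samples // 2
            region = {s: ("north" if j < half else "south")
                      for j, s in enumerate(table.sample_ids)}
            if half < 2 or table.n_samples - half < 2:
                continue
            meta = SampleMetadata(region=region)
            cuts = {"north": 12.0, "south": 17.0}
            res = classify(table, meta, specialist_b_thresholds=cuts,
                           generalist_b_threshold=3.0)
            oracle = brute_force_labels(table, meta, gen_b=3.0, spec_b=cuts)
            assert res["label"].to_dict() == oracle

    def test_b_values_match_oracle(self):
        rng = np.random.default_rng(7)
        table = random_table(rng, max_otus=15, max_samples=12)
        region = {s: ("north" if j % 2 else "south")
                  for j, s in enumerate(table.sample_ids)}
        meta = SampleMetadata(region=region)
        res = classify(table, meta, specialist_b_thresholds=17.0)
        for i, otu in enumerate(table.otu_ids):
            row = table.counts[i].astype(float)
            if row.sum() == 0:
                continue
            b = 1.0 / sum((v / row.sum()) ** 2 for v in row)
            assert res.loc[otu, "B_global"] == pytest.approx(b, abs=1e-12)


class TestRecoveryOnSyntheticCommunity:
    def test_planted_archetype_recovery(self, default_community):
        table, meta, truth = default_community
        res = classify(table, meta)
        pred_gen = set(res.index[res["label"] == "generalist"])
        true_gen = set(truth.of_kind("generalist"))
        pred_spec = set(res.index[res["label"].str.startswith("specialist")])
        true_spec = set(truth.of_kind("specialist"))
        gp = len(pred_gen & true_gen) / len(pred_gen)
        gr = len(pred_gen & true_gen) / len(true_gen)
        sp = len(pred_spec & true_spec) / len(pred_spec)
        sr = len(pred_spec & true_spec) / len(true_spec)
        assert gp >= 0.9 and gr >= 0.9
        assert sp >= 0.8 and sr >= 0.8
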