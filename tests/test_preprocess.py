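"""Omic filters against brute-force oracles; TMM against a direct transcription."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from omixplain.io_tabular import FeatureTable, TableError, TargetVector
from omixplain import preprocess as pp


def _table(values, prefix="S", fprefix="f"):
    values = np.asarray(values, dtype=float)
    return FeatureTable(
        pd.DataFrame(
            values,
            index=[f"{prefix}{i}" for i in range(values.shape[0])],
            columns=[f"{fprefix}{j}" for j in range(values.shape[1])],
        )
    )


def _random_table(rng, n=12, p=10, sparse=0.4):
    values = rng.poisson(20, size=(n, p)).astype(float)
    values[rng.random((n, p)) < sparse] = 0.0
    return _table(values)


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def tmm_oracle(counts):
    """Independent step-by-step transcription of the TMM definition."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=1)
    uq = np.array([np.quantile(row / l, 0.75) for row, l in zip(counts, lib)])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    def avg_rank(v):
        # average ranks computed by explicit position counting
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            mean_rank = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = mean_rank
            i = j + 1
        return ranks

    factors = np.ones(counts.shape[0])
    for s in range(counts.shape[0]):
        if s == ref:
            continue
        ok = (counts[s] > 0) & (counts[ref] > 0)
        ys, yr = counts[s][ok], counts[ref][ok]
        ns, nr = lib[s], lib[ref]
        m = np.log2((ys / ns) / (yr / nr))
        a = 0.5 * np.log2((ys / ns) * (yr / nr))
        w = 1.0 / ((ns - ys) / (ns * ys) + (nr - yr) / (nr * yr))
        g = len(m)
        lo_m, hi_m = np.floor(g * 0.30) + 1, g - np.floor(g * 0.30)
        lo_a, hi_a = np.floor(g * 0.05) + 1, g - np.floor(g * 0.05)
        rm, ra = avg_rank(m), avg_rank(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        factors[s] = 2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    return factors / np.exp(np.mean(np.log(factors)))


class TestTMM:
    def test_identical_samples_all_factors_one(self):
        table = _table(np.tile([5, 10, 0, 7, 30], (3, 1)))
        factors = pp.tmm_factors(table.values)
        np.testing.assert_allclose(factors, 1.0)
        out, _ = pp.tmm_normalize(table)
        np.testing.assert_allclose(out.values[0], out.values[1])

    def test_whole_matrix_depth_scaling_invariance(self):
        rng = np.random.default_rng(5)
        counts = rng.negative_binomial(5, 0.1, size=(4, 30)).astype(float) + 1
        np.testing.assert_allclose(
            pp.tmm_factors(counts), pp.tmm_factors(counts * 7), atol=1e-12
        )

    def test_single_sample_depth_doubling_near_invariant(self):
        # M-values and trimming are depth-invariant; only the precision
        # weights move, so factors change by at most a few per mille
        rng = np.random.default_rng(6)
        counts = rng.negative_binomial(5, 0.05, size=(4, 100)).astype(float) + 1
        doubled = counts.copy()
        doubled[0] *= 2
        np.testing.assert_allclose(
            pp.tmm_factors(doubled), pp.tmm_factors(counts), atol=0.02
        )

    def test_factors_match_direct_transcription(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            counts = rng.negative_binomial(8, 0.08, size=(4, 20)).astype(float) + 1
            np.testing.assert_allclose(
                pp.tmm_factors(counts), tmm_oracle(counts), atol=1e-6
            )

    def test_geometric_mean_of_factors_is_one(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(40, size=(6, 50)).astype(float) + 1
        assert np.exp(np.mean(np.log(pp.tmm_factors(counts)))) == pytest.approx(1.0)

    def test_zero_total_sample_rejected(self):
        with pytest.raises(TableError, match="zero total"):
            pp.tmm_factors(np.array([[0.0, 0.0], [1.0, 2.0]]))

    def test_cpm_output_rows_scale_with_factors(self):
        rng = np.random.default_rng(9)
        table = _table(rng.poisson(30, size=(4, 40)).astype(float) + 1)
        out, report = pp.tmm_normalize(table)
        factors = np.array(
            list(report.parameters["tmm_factors"].values())
            if isinstance(report.parameters["tmm_factors"], dict)
            else report.parameters["tmm_factors"]
        )
        eff = table.values.sum(axis=1) * factors
        np.testing.assert_allclose(out.values, table.values / eff[:, None] * 1e6)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_factors_match_edger(self, tmp_path):
        """Cross-check against Bioconductor edgeR's calcNormFactors."""
        rng = np.random.default_rng(10)
        counts = rng.negative_binomial(5, 0.05, size=(4, 200)).astype(float)
        counts += (counts.sum(axis=1) == 0)[:, None]
        csv = tmp_path / "counts.csv"
        np.savetxt(csv, counts.T, delimiter=",")
        script = (
            "suppressMessages(library(edgeR));"
            f"x <- as.matrix(read.csv('{csv}', header=FALSE));"
            "cat(sprintf('%.12f ', calcNormFactors(x, method='TMM')))"
        )
        res = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert res.returncode == 0, res.stderr
        f_r = np.array([float(v) for v in res.stdout.split()])
        np.testing.assert_allclose(pp.tmm_factors(counts), f_r, atol=1e-8)


# ---------------------------------------------------------------------------
# Filters vs brute force
# ---------------------------------------------------------------------------

class TestSampleSdFilter:
    def test_identical_samples_nothing_removed(self):
        table = _table(np.tile([1, 0, 2], (5, 1)))
        out, report = pp.filter_samples_by_sd(table, 0.0)
        assert out.shape == table.shape
        assert report.samples_removed["filter_samples_by_sd"] == []

    def test_outlier_sample_removed(self):
        values = np.ones((10, 50))
        values[9] = 0.0  # zero covered features among samples with 50
        table = _table(values)
        out, _ = pp.filter_samples_by_sd(table, 2.0)
        assert "S9" not in out.sample_ids and out.shape[0] == 9

    def test_zero_sd_threshold_keeps_only_mean_coverage(self):
        values = np.zeros((4, 5))
        values[0, :3] = 1
        values[1, :3] = 1
        values[2, :4] = 1
        values[3, :2] = 1
        out, _ = pp.filter_samples_by_sd(_table(values), 0.0)
        # mean coverage = 3: only the samples with exactly 3 covered remain
        assert out.sample_ids == ["S0", "S1"]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            table = _random_table(rng)
            x_sd = rng.uniform(0, 2)
            out, _ = pp.filter_samples_by_sd(table, x_sd)
            cov = [(row > 0).sum() for row in table.values]
            mean = sum(cov) / len(cov)
            sd = (sum((c - mean) ** 2 for c in cov) / len(cov)) ** 0.5
            expect = [
                s
                for s, c in zip(table.sample_ids, cov)
                if sd == 0 or abs(c - mean) <= x_sd * sd
            ]
            assert out.sample_ids == expect


class TestFeatureMinValueFilter:
    def test_expressed_gene_kept(self):
        values = np.zeros((12, 2))
        values[:, 0] = 2.0  # over x=1 in all 12 samples
        out, _ = pp.filter_features_by_min_value(_table(values), 1.0, 10)
        assert out.feature_ids == ["f0"]

    def test_zero_thresholds_identity(self):
        rng = np.random.default_rng(1)
        table = _random_table(rng)
        out, _ = pp.filter_features_by_min_value(table, 0.0, 0)
        assert out.feature_ids == table.feature_ids

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            table = _random_table(rng, n=5)
            x, y = rng.uniform(0, 30), int(rng.integers(0, 6))
            out, _ = pp.filter_features_by_min_value(table, x, y)
            expect = [
                f
                for j, f in enumerate(table.feature_ids)
                if sum(v > x for v in table.values[:, j]) >= y
            ]
            assert out.feature_ids == expect


class TestCollapseTaxonomy:
    def _lineage_table(self):
        features = [
            "k__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales;f__Lactobacillaceae;g__Lactobacillus;s__casei",
            "k__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales;f__Lactobacillaceae;g__Lactobacillus;s__gasseri",
            "k__Bacteria;p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;f__Bacteroidaceae;g__Bacteroides;s__fragilis",
        ]
        values = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        return FeatureTable(pd.DataFrame(values, index=["a", "b"], columns=features))

    def test_same_genus_summed(self):
        out = pp.collapse_taxonomy(self._lineage_table(), "g")
        assert out.shape[1] == 2
        genus_col = [c for c in out.feature_ids if c.endswith("g__Lactobacillus")][0]
        np.testing.assert_allclose(out.data[genus_col].to_numpy(), [3.0, 9.0])

    def test_species_rank_identity_up_to_truncation(self):
        table = self._lineage_table()
        out = pp.collapse_taxonomy(table, "s")
        assert out.shape == table.shape
        np.testing.assert_allclose(np.sort(out.values), np.sort(table.values))

    def test_per_sample_totals_conserved(self):
        rng = np.random.default_rng(3)
        ranks = "kpcofgs"
        features = [
            ";".join(
                f"{r}__{rng.integers(0, 3)}" for r in ranks
            )
            + f";tail{i}" * 0
            for i in range(25)
        ]
        values = rng.poisson(10, size=(6, 25)).astype(float)
        table = FeatureTable(
            pd.DataFrame(values, index=[f"S{i}" for i in range(6)], columns=_dedup(features))
        )
        out = pp.collapse_taxonomy(table, "p")
        np.testing.assert_allclose(out.values.sum(axis=1), values.sum(axis=1))

    def test_unparseable_lineage_pooled(self):
        table = FeatureTable(
            pd.DataFrame([[1.0, 2.0]], index=["a"], columns=["k__B;p__F", "garbled"])
        )
        out = pp.collapse_taxonomy(table, "p")
        assert "unassigned_p" in out.feature_ids

    def test_bad_rank_rejected(self):
        with pytest.raises(TableError, match="rank"):
            pp.collapse_taxonomy(self._lineage_table(), "x")


def _dedup(names):
    seen, out = {}, []
    for n in names:
        c = seen.get(n, 0)
        out.append(n if c == 0 else f"{n}__{c}")
        seen[n] = c + 1
    return out


class TestReadFilters:
    def test_min_reads_strict_boundary(self):
        values = np.diag([999.0, 1000.0, 1500.0])
        out, _ = pp.filter_min_reads(_table(values), 1000)
        assert out.sample_ids == ["S1", "S2"]

    def test_min_reads_zero_identity(self):
        rng = np.random.default_rng(4)
        table = _random_table(rng)
        out, _ = pp.filter_min_reads(table, 0)
        assert out.sample_ids == table.sample_ids

    def test_min_reads_matches_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            table = _random_table(rng)
            thr = int(rng.integers(0, 300))
            out, _ = pp.filter_min_reads(table, thr)
            expect = [
                s for s, row in zip(table.sample_ids, table.values)
                if sum(row) >= thr
            ]
            assert out.sample_ids == expect

    def test_normalize_reads_row_sums(self):
        rng = np.random.default_rng(6)
        table = _table(rng.poisson(20, size=(8, 15)) + 1.0)
        out = pp.normalize_reads(table, 1000)
        np.testing.assert_allclose(out.values.sum(axis=1), 1000.0, rtol=1e-9)

    def test_normalize_reads_halves_double_sum(self):
        table = _table([[800.0, 1200.0], [500.0, 500.0]])
        out = pp.normalize_reads(table, 1000)
        np.testing.assert_allclose(out.values[0], [400.0, 600.0])
        np.testing.assert_allclose(out.values[1], [500.0, 500.0])

    def test_normalize_reads_zero_row_rejected(self):
        with pytest.raises(TableError, match="zero-sum"):
            pp.normalize_reads(_table([[0.0, 0.0], [1.0, 1.0]]), 100)


class TestAbundancePrevalence:
    def test_abundance_strict_boundary(self):
        values = np.tile([3.0, 10.0 / 3, 11.0 / 3], (3, 1))
        out, _ = pp.filter_abundance(_table(values), 10.0)
        assert out.feature_ids == ["f1", "f2"]

    def test_abundance_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            table = _random_table(rng)
            thr = rng.uniform(0, 200)
            out, _ = pp.filter_abundance(table, thr)
            expect = [
                f for j, f in enumerate(table.feature_ids)
                if sum(table.values[:, j]) >= thr
            ]
            assert out.feature_ids == expect

    def test_prevalence_absent_feature_removed_rare_kept(self):
        values = np.zeros((50, 2))
        values[0, 1] = 5.0  # present in 1/50 = 2% of samples
        out, _ = pp.filter_prevalence(_table(values), 0.01)
        assert out.feature_ids == ["f1"]

    def test_prevalence_matches_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            table = _random_table(rng, sparse=0.7)
            prop = rng.uniform(0, 0.5)
            out, _ = pp.filter_prevalence(table, prop)
            n = table.shape[0]
            expect = [
                f for j, f in enumerate(table.feature_ids)
                if sum(v > 0 for v in table.values[:, j]) / n >= prop
            ]
            assert out.feature_ids == expect


class TestMetadataFilter:
    def _meta(self, ids, country):
        return pd.DataFrame({"COUNTRY": country}, index=ids)

    def test_single_rule(self):
        table = _table(np.ones((10, 3)))
        meta = self._meta(table.sample_ids, ["UK"] * 3 + ["FR"] * 7)
        out, _ = pp.filter_samples_by_metadata(table, meta, [{"COUNTRY": "UK"}])
        assert out.shape[0] == 7

    def test_null_rules_identity(self):
        table = _table(np.ones((4, 2)))
        meta = self._meta(table.sample_ids, ["UK"] * 4)
        out, report = pp.filter_samples_by_metadata(table, meta, None)
        assert out.sample_ids == table.sample_ids
        assert report.samples_removed["filter_samples_by_metadata"] == []

    def test_two_rules_union_removed(self):
        table = _table(np.ones((10, 2)))
        meta = pd.DataFrame(
            {
                "COUNTRY": ["UK"] * 3 + ["FR"] * 7,
                "SITE": ["x"] * 8 + ["y"] * 2,
            },
            index=table.sample_ids,
        )
        out, _ = pp.filter_samples_by_metadata(
            table, meta, [{"COUNTRY": "UK"}, {"SITE": "y"}]
        )
        expect = {
            s
            for s in table.sample_ids
            if not (meta.loc[s, "COUNTRY"] == "UK" or meta.loc[s, "SITE"] == "y")
        }
        assert set(out.sample_ids) == expect


class TestTargetManipulation:
    def _target(self, labels):
        return TargetVector(
            pd.Series(labels, index=[f"S{i}" for i in range(len(labels))]), "class"
        )

    def test_remove_classes(self):
        target, removed = pp.remove_classes(self._target(list("AABBCC")), ["C"])
        assert sorted(set(target.values)) == ["A", "B"]
        assert len(removed) == 2

    def test_remove_empty_list_identity(self):
        target = self._target(list("AABB"))
        out, removed = pp.remove_classes(target, [])
        assert out is target and removed == []

    def test_remove_all_classes_error(self):
        with pytest.raises(TableError, match="every sample"):
            pp.remove_classes(self._target(list("AABB")), ["A", "B"])

    def test_merge_classes(self):
        out = pp.merge_classes(self._target(list("ABCABC")), {"X": ["A", "B"]})
        assert list(out.values) == ["X", "X", "C", "X", "X", "C"]

    def test_merge_empty_identity(self):
        target = self._target(list("AABB"))
        assert pp.merge_classes(target, None) is target

    def test_overlapping_merge_groups_rejected(self):
        with pytest.raises(TableError, match="more than one"):
            pp.merge_classes(
                self._target(list("AABB")), {"X": ["A"], "Y": ["A", "B"]}
            )
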