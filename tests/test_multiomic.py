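"""Correlations, CIN score and mutation enrichment."""

import numpy as np
import pandas as pd
import pytest

from arid1a_hcc.association import ContingencyTable2x2, fisher_exact
from arid1a_hcc.errors import InvalidArgumentError, UndefinedCorrelationError
from arid1a_hcc.multiomic import (cin_score, maf_to_flags, mutation_enrichment,
                                  pearson, summarize_methylation,
                                  variant_class_distribution)
from arid1a_hcc.synthetic_data import simulate_multiomic


def _series(values, prefix="s"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))],
                     dtype=float)


class TestPearson:
    def test_perfect_linearity(self):
        x = _series([1, 2, 3, 4, 5])
        assert pearson(x, 2 * x + 1).r == pytest.approx(1.0)

    def test_hand_covariance_example(self):
        """x=(1,2,3), y=(6,4,5): r = -0.5 by direct covariance arithmetic."""
        res = pearson(_series([1, 2, 3]), _series([6, 4, 5]))
        assert res.r == pytest.approx(-0.5, abs=1e-12)
        assert res.n_pairs == 3

    def test_symmetry_and_affine_invariance(self, rng):
        x = _series(rng.normal(0, 1, 30))
        y = _series(rng.normal(0, 1, 30))
        assert pearson(x, y).r == pytest.approx(pearson(y, x).r, abs=1e-12)
        assert pearson(3 * x + 2, y).r == pytest.approx(pearson(x, y).r, abs=1e-12)

    def test_pairwise_deletion(self):
        x = _series([1, 2, 3, 4, np.nan])
        y = _series([2, 4, 6, np.nan, 10])
        res = pearson(x, y)
        assert res.n_pairs == 3
        assert res.r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson(_series([1, 1, 1]), _series([1, 2, 3]))

    def test_permutation_null_behavior(self, rng):
        x = _series(rng.normal(0, 1, 50))
        y = rng.normal(0, 1, 50)
        crit = 1.96 / np.sqrt(50 - 3)  # Fisher-z null quantile
        exceed = 0
        rs = []
        for _ in range(100):
            r = pearson(x, _series(rng.permutation(y))).r
            rs.append(r)
            exceed += int(abs(np.arctanh(r)) > crit)
        assert abs(np.mean(rs)) < 0.05
        assert exceed <= 15  # about 5 expected at the 5% level


class TestSimulatedCorrelations:
    def test_exact_correlation_when_noiseless(self):
        mrna = _series(np.linspace(0, 2, 50))
        om = simulate_multiomic(50, mrna, target_r={"protein": 1.0}, seed=3,
                                protein_fraction=1.0)
        assert pearson(om.samples["mrna"], om.samples["protein"]).r \
            == pytest.approx(1.0, abs=1e-12)

    def test_invalid_target_rejected(self):
        with pytest.raises(InvalidArgumentError):
            simulate_multiomic(10, _series(np.arange(10.0)),
                               target_r={"protein": 1.5}, seed=0)

    def test_null_target_r_stays_below_null_quantile(self):
        n = 100
        crit = 1.96 / np.sqrt(n - 3)
        exceed = 0
        for seed in range(200):
            g = np.random.default_rng(np.random.SeedSequence([seed, 9]))
            mrna = _series(g.normal(0, 1, n))
            om = simulate_multiomic(n, mrna, target_r={"protein": 0.0},
                                    seed=seed, protein_fraction=1.0)
            r = pearson(om.samples["mrna"], om.samples["protein"]).r
            exceed += int(abs(np.arctanh(r)) > crit)
        # nominal 5%: expect about 10/200 exceedances
        assert exceed / 200 < 0.10


class TestCIN:
    def _seg(self, rows):
        return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                           "num_mark", "seg_mean"])

    def test_flat_genome_scores_zero(self):
        seg = self._seg([("s1", "chr1", 0, 100, 10, 0.0),
                         ("s1", "chr2", 0, 300, 10, 0.0)])
        assert cin_score(seg)["s1"] == 0.0

    def test_half_genome_altered(self):
        seg = self._seg([("s1", "chr1", 0, 500, 10, 1.0),
                         ("s1", "chr2", 0, 500, 10, 0.0)])
        assert cin_score(seg)["s1"] == pytest.approx(0.5)

    def test_matches_brute_force_recomputation(self, rng):
        rows = []
        for s in ("s1", "s2", "s3"):
            pos = 0
            for _ in range(30):
                length = int(rng.integers(1, 1000))
                rows.append((s, "chr1", pos, pos + length, 5,
                             float(rng.normal(0, 0.3))))
                pos += length
        seg = self._seg(rows)
        result = cin_score(seg, threshold=0.2)
        for s in ("s1", "s2", "s3"):
            total = altered = 0.0
            for _, row in seg[seg["sample"] == s].iterrows():
                length = row["end"] - row["start"]
                total += length
                if abs(row["seg_mean"]) > 0.2:
                    altered += length
            assert result[s] == pytest.approx(altered / total, abs=1e-12)

    def test_monotone_in_threshold(self, rng):
        rows = [("s1", "chr1", i * 10, (i + 1) * 10, 2, float(rng.normal(0, 0.3)))
                for i in range(50)]
        seg = self._seg(rows)
        assert cin_score(seg, 0.1)["s1"] >= cin_score(seg, 0.3)["s1"]

    def test_nonpositive_length_rejected(self):
        with pytest.raises(InvalidArgumentError):
            cin_score(self._seg([("s1", "chr1", 5, 5, 1, 0.0)]))


class TestMutations:
    def test_reduces_to_fisher_on_each_gene(self, rng):
        flags = pd.DataFrame(rng.integers(0, 2, (40, 3)),
                             index=[f"s{i}" for i in range(40)],
                             columns=["TP53", "AXIN1", "TSC2"])
        groups = pd.Series(["low"] * 20 + ["high"] * 20, index=flags.index)
        table = mutation_enrichment(flags, groups)
        for gene in flags.columns:
            in0 = groups == sorted(groups.unique())[0]
            a = int(flags.loc[in0, gene].sum()); b = int((1 - flags.loc[in0, gene]).sum())
            c = int(flags.loc[~in0, gene].sum()); d = int((1 - flags.loc[~in0, gene]).sum())
            expected = fisher_exact(ContingencyTable2x2(a, b, c, d))
            assert table.loc[gene, "p_value"] == pytest.approx(expected, abs=1e-12)

    def test_unmutated_gene_reports_one_and_skips_bh(self):
        flags = pd.DataFrame({"NEVER": [0] * 10, "SOME": [1] * 5 + [0] * 5},
                             index=[f"s{i}" for i in range(10)])
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=flags.index)
        table = mutation_enrichment(flags, groups)
        assert table.loc["NEVER", "p_value"] == 1.0
        assert np.isnan(table.loc["NEVER", "p_adj_bh"])

    def test_planted_enrichment_detected(self):
        """30% vs 5% mutation rates at n=100/group: flagged in >=95% of seeds."""
        hits = 0
        for seed in range(40):
            g = np.random.default_rng(seed)
            low = (g.random(100) < 0.30).astype(int)
            high = (g.random(100) < 0.05).astype(int)
            flags = pd.DataFrame({"GENE": np.concatenate([low, high])},
                                 index=[f"s{i}" for i in range(200)])
            groups = pd.Series(["low"] * 100 + ["high"] * 100, index=flags.index)
            table = mutation_enrichment(flags, groups)
            hits += int(table.loc["GENE", "p_value"] < 0.05)
        assert hits >= 38

    def test_maf_round_trip_to_flags(self):
        maf = pd.DataFrame({"sample": ["s1", "s3"], "gene": ["TP53", "TP53"],
                            "variant_class": ["missense", "truncating"]})
        flags = maf_to_flags(maf, ["s1", "s2", "s3"])
        assert flags["TP53"].tolist() == [1, 0, 1]

    def test_variant_class_percentages(self):
        maf = pd.DataFrame({
            "sample": [f"s{i}" for i in range(33)],
            "gene": ["ARID1A"] * 33,
            "variant_class": ["truncating"] * 24 + ["missense"] * 8 + ["in_frame"]})
        pct = variant_class_distribution(maf, "ARID1A")
        assert pct["truncating"] == pytest.approx(72.7, abs=0.05)


def test_methylation_probe_summary():
    beta = pd.DataFrame([[0.1, 0.2], [0.3, 0.4], [0.9, 0.8]],
                        index=["p1", "p2", "p3"], columns=["s1", "s2"])
    probe_map = pd.Series({"p1": "GENEA", "p2": "GENEA", "p3": "GENEB"})
    out = summarize_methylation(beta, probe_map)
    assert out.loc["GENEA", "s1"] == pytest.approx(0.2)
    assert out.loc["GENEB", "s2"] == pytest.approx(0.8)
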