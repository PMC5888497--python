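"""Background sampling, Fisher enrichment, metaplot and seed/PAM density."""

import numpy as np
import pytest
from scipy import stats

from guidemeth.enrichment import (
    compare_densities,
    count_pattern_both_strands,
    dhs_core_fraction,
    dhs_metaplot,
    feature_enrichment,
    pam_density,
    sample_background,
    seed_pam_density,
)
from guidemeth.guides import GuideRNA, reverse_complement
from guidemeth.intervals import Interval, IntervalSet
from guidemeth.methylation import MethylomeTable


def hypergeom_two_sided_p(a, b, c, d):
    """Brute-force two-sided Fisher p: sum of all tables at most as probable."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    pmf = {k: stats.hypergeom.pmf(k, n, row1, col1) for k in range(lo, hi + 1)}
    cutoff = pmf[a] * (1 + 1e-7)
    return float(sum(v for v in pmf.values() if v <= cutoff))


def brute_force_density(seq, seed):
    """All-offset scan of seed+NGG on both explicit strands."""
    def scan(s):
        pattern_len = len(seed) + 3
        count = 0
        for i in range(len(s) - pattern_len + 1):
            window = s[i : i + pattern_len]
            if window.startswith(seed) and window[-2:] == "GG":
                count += 1
        return count

    return scan(seq) + scan(reverse_complement(seq))


GUIDE = GuideRNA("T2", "GAGCCGGGCGGGAGAGGGAG", "GGG")


class TestSampleBackground:
    SIZES = {"chr1": 100_000, "chr2": 60_000}

    def regions(self, rng, n=200):
        out = []
        for _ in range(n):
            start = int(rng.integers(0, 50_000))
            out.append(Interval("chr1", start, start + int(rng.integers(50, 400))))
        return out

    def test_count_and_determinism(self, rng):
        regions = self.regions(rng)
        bg1 = sample_background(regions, self.SIZES, 42)
        bg2 = sample_background(regions, self.SIZES, 42)
        assert len(bg1) == len(regions)
        assert bg1 == bg2
        assert bg1 != sample_background(regions, self.SIZES, 43)

    def test_lengths_resampled_from_input(self, rng):
        regions = self.regions(rng, 2000)
        bg = sample_background(regions, self.SIZES, 1)
        input_lengths = {iv.length for iv in regions}
        assert all(iv.length in input_lengths for iv in bg)
        ks = stats.ks_2samp(
            [iv.length for iv in regions], [iv.length for iv in bg]
        )
        assert ks.pvalue > 0.001

    def test_windows_inside_chromosomes(self, rng):
        bg = sample_background(self.regions(rng), self.SIZES, 5)
        for iv in bg:
            assert 0 <= iv.start < iv.end <= self.SIZES[iv.chrom]

    def test_background_neutrality(self, rng):
        # background vs an independent background: near-uniform p-values
        regions = self.regions(rng, 200)
        features = {
            "f": IntervalSet(
                [Interval("chr1", s, s + 500) for s in range(0, 100_000, 2000)]
                + [Interval("chr2", s, s + 500) for s in range(0, 60_000, 2000)]
            )
        }
        n_sig = 0
        n_seeds = 100
        for seed in range(n_seeds):
            a = sample_background(regions, self.SIZES, 1000 + seed)
            b = sample_background(regions, self.SIZES, 5000 + seed)
            p = feature_enrichment(a, b, features)["p"].iloc[0]
            n_sig += p < 0.05
        assert 0.0 <= n_sig / n_seeds <= 0.12


class TestFeatureEnrichment:
    def test_odds_ratio_and_exact_p_oracle(self):
        # 30/70 in vs 10/90 in: odds ratio 30*90/(70*10)
        regions = [Interval("chr1", i * 1000, i * 1000 + 100) for i in range(100)]
        background = [
            Interval("chr2", i * 1000, i * 1000 + 100) for i in range(100)
        ]
        features = {
            "f": IntervalSet(
                [Interval("chr1", i * 1000, i * 1000 + 50) for i in range(30)]
                + [Interval("chr2", i * 1000, i * 1000 + 50) for i in range(10)]
            )
        }
        df = feature_enrichment(regions, background, features)
        row = df.iloc[0]
        assert row["odds_ratio"] == pytest.approx(30 * 90 / (70 * 10))
        assert row["p"] == pytest.approx(hypergeom_two_sided_p(30, 70, 10, 90), abs=1e-10)

    def test_identical_sets_are_null(self):
        regions = [Interval("chr1", i * 100, i * 100 + 50) for i in range(40)]
        features = {"f": IntervalSet([Interval("chr1", 0, 1500)])}
        df = feature_enrichment(regions, regions, features)
        assert df["odds_ratio"].iloc[0] == pytest.approx(1.0)
        assert df["p"].iloc[0] == pytest.approx(1.0)

    def test_empty_feature_class_reported_flat(self):
        regions = [Interval("chr1", 0, 10)]
        df = feature_enrichment(regions, regions, {"empty": IntervalSet()})
        assert df["p"].iloc[0] == 1.0

    def test_dhs_core_fraction_extremes(self):
        regions = [Interval("chr1", i * 100, i * 100 + 10) for i in range(10)]
        dhs = IntervalSet([Interval("chr1", 0, 2000)])
        frac, p, _ = dhs_core_fraction(regions, dhs, regions)
        assert frac == 1.0
        far = IntervalSet([Interval("chr2", 0, 100)])
        frac, p, _ = dhs_core_fraction(regions, far, regions)
        assert frac == 0.0 and p == 1.0


class TestMetaplot:
    def _flat_table(self, level=0.5):
        pos = np.arange(0, 30_000, 25)
        n = np.full(len(pos), 20)
        m = (n * level).astype(int)
        return MethylomeTable(
            np.full(len(pos), "chr1", dtype=object), pos, {"t": (m, n), "c": (m, n)}
        )

    def test_constant_methylome_flat_profile(self):
        table = self._flat_table()
        dhs = [Interval("chr1", s, s + 400) for s in range(3000, 27_000, 3000)]
        res = dhs_metaplot(
            table, {"t": ["t"], "c": ["c"]}, dhs, control="c", flank=1000
        )
        prof = res["profile"]
        vals = prof[prof["group"] == "t"]["mean_methylation"].dropna()
        assert np.allclose(vals, 0.5)
        assert res["tests"]["t"]["p"] == 1.0

    def test_treated_above_control_detected(self, small_study):
        res = dhs_metaplot(
            small_study.table,
            {"treated": ["g1_r1"], "control": ["g9_r1"]},
            small_study.annotations["dhs"],
            control="control",
        )
        assert res["tests"]["treated"]["p"] < 0.05
        prof = res["profile"].pivot(
            index="bin", columns="group", values="mean_methylation"
        )
        body = prof.iloc[10:30]  # body bins with default flank_bins=10
        assert (body["treated"] - body["control"]).mean() > 0

    def test_reversed_pairing_keeps_p(self):
        rng = np.random.default_rng(3)
        pos = np.arange(0, 30_000, 25)
        n = np.full(len(pos), 20)
        table = MethylomeTable(
            np.full(len(pos), "chr1", dtype=object),
            pos,
            {
                "t": (rng.binomial(n, 0.6), n),
                "c": (rng.binomial(n, 0.4), n),
            },
        )
        dhs = [Interval("chr1", s, s + 400) for s in range(2000, 28_000, 2000)]
        fwd = dhs_metaplot(table, {"t": ["t"], "c": ["c"]}, dhs, control="c")
        rev = dhs_metaplot(table, {"c": ["c"], "t": ["t"]}, dhs, control="t")
        assert fwd["tests"]["t"]["p"] == pytest.approx(rev["tests"]["c"]["p"])


class TestSeedPamDensity:
    def test_seed_fields_match_motif(self):
        assert GUIDE.seed5 == "GGGAG"
        assert GUIDE.seed11 == "GGGAGAGGGAG"
        # the seed11+NGG pattern matches its own site sequence
        assert count_pattern_both_strands("GGGAGAGGGAGTGG", GUIDE.seed11) == 1

    def test_no_match_in_poly_a(self):
        assert count_pattern_both_strands("AAAAAAAAAA", GUIDE.seed5) == 0

    def test_forward_example(self):
        assert count_pattern_both_strands("TTGGGAGAGGCC", "GGGAG") == 1

    def test_pam_examples(self):
        assert count_pattern_both_strands("AGGA", "") == 1
        assert count_pattern_both_strands("GGGG", "") == 2
        assert count_pattern_both_strands("AAAAA", "") == 0

    def test_matches_brute_force_on_random_windows(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(100):
            seq = "".join(rng.choice(bases, size=int(rng.integers(30, 120))))
            for seed in ("", "GGGAG", "GGGAGAGGGAG", "CGT"):
                assert count_pattern_both_strands(seq, seed) == brute_force_density(
                    seq, seed
                ), (seq, seed)

    def test_strand_symmetry(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(50):
            seq = "".join(rng.choice(bases, size=200))
            for seed in ("GGGAG", ""):
                assert count_pattern_both_strands(
                    seq, seed
                ) == count_pattern_both_strands(reverse_complement(seq), seed)

    def test_density_normalisation_and_comparison(self):
        genome = {"chr1": "GGGAGTGG" + "A" * 992 + "T" * 1000}
        windows = [Interval("chr1", 0, 1000)]
        other = [Interval("chr1", 1000, 2000)]
        res = seed_pam_density(windows, genome, GUIDE)
        assert res.counts.tolist() == [1]
        assert res.densities.tolist() == [1.0]  # one match per kb
        null = seed_pam_density(other, genome, GUIDE)
        cmp = compare_densities(res, null)
        assert cmp["median_a"] > cmp["median_b"]

    def test_pam_density_counts(self):
        genome = {"chr1": "AGGA" + "C" * 96}
        res = pam_density([Interval("chr1", 0, 4)], genome)
        assert res.counts.tolist() == [1]
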