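"""Synthetic genome, guides, counts, lambda spike-in and ChIP peaks."""

import numpy as np
import pytest
from scipy import stats

from guidemeth.design import GroupDesign, GroupSpec, default_design
from guidemeth.errors import ConfigurationError, GenerationError
from guidemeth.guides import reverse_complement
from guidemeth.intervals import Interval, IntervalSet
from guidemeth.methylation import conversion_rate
from guidemeth.simulate import (
    EffectModel,
    LAMBDA_GENOME_LENGTH,
    SyntheticGenomeSpec,
    generate_genome,
    place_guides,
    simulate_chip_peaks,
    simulate_counts,
    simulate_lambda,
    simulate_study,
)

SMALL = dict(genome_length=200_000, n_chromosomes=1)


class TestGenerateGenome:
    def test_determinism(self):
        g1, a1 = generate_genome(SyntheticGenomeSpec(**SMALL, rng_seed=3))
        g2, a2 = generate_genome(SyntheticGenomeSpec(**SMALL, rng_seed=3))
        assert g1 == g2
        assert a1 == a2
        g3, _ = generate_genome(SyntheticGenomeSpec(**SMALL, rng_seed=4))
        assert g1 != g3

    def test_fractions_over_one_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticGenomeSpec(
                feature_fractions={"promoter": 0.8, "intron": 0.5}
            )

    def test_zero_fractions_give_empty_annotations(self):
        spec = SyntheticGenomeSpec(
            **SMALL, feature_fractions={c: 0.0 for c in ("promoter", "cgi")}
        )
        genome, ann = generate_genome(spec)
        assert sum(len(v) for v in ann.values()) == 0
        assert len(genome["chr1"]) == 200_000

    def test_intervals_in_bounds_and_class_disjoint(self, small_study):
        sizes = small_study.chrom_sizes
        for cls, ivs in small_study.annotations.items():
            for iv in ivs:
                assert 0 <= iv.start < iv.end <= sizes[iv.chrom]
            by_chrom = {}
            for iv in ivs:
                by_chrom.setdefault(iv.chrom, []).append(iv)
            for group in by_chrom.values():
                group = sorted(group, key=lambda i: i.start)
                for a, b in zip(group, group[1:]):
                    assert a.end <= b.start, (cls, a, b)

    def test_cgi_cpg_rate_exceeds_background(self):
        genome, ann = generate_genome(SyntheticGenomeSpec(**SMALL, rng_seed=3))
        seq = genome["chr1"]
        cpg_total = seq.count("CG")
        cgi_bp = sum(iv.length for iv in ann["cgi"])
        cgi_cpg = sum(seq[iv.start : iv.end].count("CG") for iv in ann["cgi"])
        assert cgi_bp > 0
        assert cgi_cpg / cgi_bp > cpg_total / len(seq)

    def test_shores_flank_cgis_without_overlap(self):
        genome, ann = generate_genome(SyntheticGenomeSpec(**SMALL, rng_seed=3))
        cgis = IntervalSet(ann["cgi"])
        for shore in ann["cgi_shore"]:
            assert not cgis.overlaps_any(shore)


class TestPlaceGuides:
    def test_known_motif_sequence_yields_expected_guide(self):
        genome = {"chr1": "TTTT" + "GAGCCGGGCGGGAGAGGGAGGGG" + "TTTT"}
        guides = place_guides(
            genome, 1, within=Interval("chr1", 0, len(genome["chr1"]))
        )
        (g,) = guides
        assert g.protospacer == "GAGCCGGGCGGGAGAGGGAG"
        assert g.pam == "GGG"
        assert (g.start, g.end, g.strand) == (4, 24, "+")

    def test_zero_guides(self):
        assert place_guides({"chr1": "ACGT" * 100}, 0) == []

    def test_minus_strand_contract(self, small_study):
        minus = [
            g
            for gs in small_study.guides.values()
            for g in gs
            if g.strand == "-"
        ]
        for g in minus:
            forward = small_study.genome[g.chrom][g.start : g.end]
            assert g.protospacer == reverse_complement(forward)

    def test_protospacers_verified_at_coordinates(self, small_study):
        for gs in small_study.guides.values():
            for g in gs:
                forward = small_study.genome[g.chrom][g.start : g.end]
                if g.strand == "+":
                    assert g.protospacer == forward
                    pam = small_study.genome[g.chrom][g.end : g.end + 3]
                    assert pam == g.pam

    def test_insufficient_sites_error_names_class(self):
        genome = {"chr1": "AT" * 200}
        with pytest.raises(GenerationError, match="promoter"):
            place_guides(
                genome,
                3,
                target_feature="promoter",
                annotations={"promoter": [Interval("chr1", 0, 400)]},
            )


class TestSimulateCounts:
    def test_determinism_and_conservation(self, small_study):
        t1, _ = simulate_counts(
            small_study.genome,
            small_study.annotations,
            small_study.guides,
            small_study.design,
            small_study.effects,
            rng_seed=5,
        )
        t2, _ = simulate_counts(
            small_study.genome,
            small_study.annotations,
            small_study.guides,
            small_study.design,
            small_study.effects,
            rng_seed=5,
        )
        for s in t1.samples:
            assert np.array_equal(t1.counts[s][0], t2.counts[s][0])
            assert np.array_equal(t1.counts[s][1], t2.counts[s][1])
            m, n = t1.counts[s]
            assert (m >= 0).all() and (m <= n).all()

    def test_control_group_matches_baseline_at_cgi(self, small_study):
        table = small_study.table
        m, n = table.counts["g9_r1"]
        cgi = IntervalSet(small_study.annotations["cgi"])
        idx = np.array(
            [
                i
                for i in range(len(table))
                if cgi.overlapping(table.chrom[i], table.pos[i], table.pos[i] + 1)
            ]
        )
        level = m[idx].sum() / n[idx].sum()
        assert level == pytest.approx(
            small_study.effects.baseline_methylation["cgi"], abs=0.02
        )

    def test_protospacer_interior_gets_no_delta(self, small_study):
        table = small_study.table
        m1, n1 = table.counts["g1_r1"]
        m9, n9 = table.counts["g9_r1"]
        interior = []
        for g in small_study.guides["uPA"]:
            idx = table.region_indices(Interval(g.chrom, g.start, g.end))
            interior.extend(idx)
        if interior:
            interior = np.array(interior)
            d = m1[interior].sum() / max(n1[interior].sum(), 1) - m9[
                interior
            ].sum() / max(n9[interior].sum(), 1)
            assert abs(d) < 0.25

    def test_dose_response_at_ontarget_flanks(self, small_study):
        """Monte-Carlo check of the closed-form flank expectation.

        Expected added methylation at full-weight flank CpGs is
        ontarget_delta * construct * dose^2; group 1 (500 ng) must exceed
        group 7 (50 ng), which must exceed control.
        """
        table = small_study.table
        eff = small_study.effects
        flank_idx = []
        for g in small_study.guides["uPA"]:
            lo, hi = eff.ontarget_flank
            for iv in (
                Interval(g.chrom, g.start - hi, max(0, g.start - lo) + 1),
                Interval(g.chrom, g.end + lo - 1, g.end + hi),
            ):
                flank_idx.extend(table.region_indices(iv))
        flank_idx = np.unique(np.array(flank_idx))
        assert flank_idx.size >= 3

        def level(sample):
            m, n = table.counts[sample]
            return m[flank_idx].sum() / n[flank_idx].sum()

        l1, l7, l9 = level("g1_r1"), level("g7_r1"), level("g9_r1")
        assert l1 > l7 > l9
        expected_full = eff.ontarget_delta * eff.dose_scale[500] ** 2
        assert l1 - l9 == pytest.approx(expected_full, abs=0.12)

    def test_mutant_constructs_are_null(self, small_study):
        """Catalytically dead fusions behave like the pUC19 control."""
        design = GroupDesign(
            groups=[
                GroupSpec(1, "DNMT3A-E752A", 500, "uPA"),
                GroupSpec(9, "none", 0, "none"),
            ]
        )
        table, truth = simulate_counts(
            small_study.genome,
            small_study.annotations,
            small_study.guides,
            design,
            small_study.effects,
            rng_seed=11,
        )
        idx = []
        for iv in truth.all_intervals():
            idx.extend(table.region_indices(iv))
        idx = np.unique(np.array(idx))[:1000]
        m_mut, n_mut = table.counts["g1_r1"]
        m_ctl, n_ctl = table.counts["g9_r1"]
        ok = (n_mut[idx] > 0) & (n_ctl[idx] > 0)
        lev_mut = m_mut[idx][ok] / n_mut[idx][ok]
        lev_ctl = m_ctl[idx][ok] / n_ctl[idx][ok]
        res = stats.mannwhitneyu(lev_mut, lev_ctl)
        assert res.pvalue > 0.01

    def test_truth_tables_carry_signed_deltas(self, small_study):
        eff = small_study.effects
        assert all(iv.score == eff.offtarget_hyper_delta for iv in small_study.truth.hyper)
        assert all(iv.score == -eff.offtarget_hypo_delta for iv in small_study.truth.hypo)
        assert all(iv.score == eff.ontarget_delta for iv in small_study.truth.ontarget)


class TestSimulateLambda:
    def test_default_genome_length(self):
        assert LAMBDA_GENOME_LENGTH == 48_502

    def test_perfect_conversion_gives_zero_m(self):
        t = simulate_lambda(conversion_rate=1.0, rng_seed=2)
        m, _ = t.counts["lambda"]
        assert (m == 0).all()

    def test_rate_recovered_within_binomial_error(self):
        t = simulate_lambda(conversion_rate=0.995, mean_depth=10, rng_seed=2)
        _, n = t.counts["lambda"]
        total = int(n.sum())
        assert total > 1e5
        est = conversion_rate(t) / 100
        se = np.sqrt(0.995 * 0.005 / total)
        assert abs(est - 0.995) < 3 * se

    def test_invalid_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_lambda(conversion_rate=0.0)
        with pytest.raises(ConfigurationError):
            simulate_lambda(conversion_rate=1.5)


class TestSimulateChipPeaks:
    def test_zero_fraction_emits_only_ontarget(self, small_study):
        peaks = simulate_chip_peaks(
            small_study.guides["uPA"],
            small_study.genome,
            IntervalSet(small_study.annotations["dhs"]),
            rng_seed=1,
            fraction=0.0,
        )
        assert len(peaks) == len(small_study.guides["uPA"])
        assert all(iv.name.startswith("ontarget") for iv in peaks)

    def test_offtarget_centers_near_seed_matches(self, small_study):
        from guidemeth.enrichment import count_pattern_both_strands

        peaks = simulate_chip_peaks(
            small_study.guides["uPA"],
            small_study.genome,
            IntervalSet(small_study.annotations["dhs"]),
            rng_seed=1,
            fraction=0.8,
        )
        offtarget = [p for p in peaks if p.name.startswith("offtarget")]
        assert offtarget
        seeds = [g.seed5 for g in small_study.guides["uPA"]]
        for p in offtarget:
            center = (p.start + p.end) // 2
            window = small_study.genome[p.chrom][
                max(0, center - 35) : center + 35
            ]
            assert any(count_pattern_both_strands(window, s) > 0 for s in seeds)

    def test_peaks_prefer_dhs(self, small_study):
        dhs = IntervalSet(small_study.annotations["dhs"])
        peaks = simulate_chip_peaks(
            small_study.guides["uPA"],
            small_study.genome,
            dhs,
            rng_seed=1,
            fraction=0.8,
        )
        offtarget = [p for p in peaks if p.name.startswith("offtarget")]
        in_dhs = sum(1 for p in offtarget if dhs.overlaps_any(p))
        genome_bp = sum(small_study.chrom_sizes.values())
        dhs_frac = dhs.total_length() / genome_bp
        assert in_dhs / len(offtarget) > 5 * dhs_frac


def test_study_determinism():
    spec = SyntheticGenomeSpec(genome_length=150_000, n_chromosomes=1, rng_seed=9)
    s1 = simulate_study(genome_spec=spec, seed=9, n_planted_offtargets=3)
    s2 = simulate_study(genome_spec=spec, seed=9, n_planted_offtargets=3)
    assert s1.genome == s2.genome
    for smp in s1.table.samples:
        assert np.array_equal(s1.table.counts[smp][0], s2.table.counts[smp][0])
    assert list(s1.peaks) == list(s2.peaks)
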