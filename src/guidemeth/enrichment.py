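"""Region-set characterisation: feature enrichment, DHS profiles, seed density.

Enrichment of a region set (DMRs, ChIP peaks) in genomic feature classes is
measured against matched background windows — random genomic intervals of
the same number and length distribution — with two-sided Fisher exact tests
on 2x2 (in/out x region/background) tables.  A region "falls into" a class
when it overlaps >= 1 bp of any class interval, and may count in several
classes.

Seed–PAM density scans count occurrences of a gRNA's PAM-proximal seed
followed by NGG on either strand (overlapping occurrences all counted),
normalised per kb; region sets are summarised as median +- SD and compared
both by an exact test on pooled counts and by a two-sample t-test on the
per-window densities.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, GenerationError
from .guides import GuideRNA, reverse_complement
from .intervals import Interval, IntervalSet
from .methylation import DEFAULT_MIN_DEPTH, MethylomeTable, site_levels

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------- #
# matched background


def sample_background(
    regions: Sequence[Interval],
    chrom_sizes: Mapping[str, int],
    rng_seed: int,
) -> List[Interval]:
    """Random genomic windows matched in number and length distribution.

    Window lengths are resampled with replacement from the input length
    multiset; placement is uniform over the genome (chromosomes weighted by
    length) and constrained to chromosome bounds.  Deterministic per seed.
    """
    if not regions:
        raise ConfigurationError("sample_background: empty region set")
    rng = np.random.default_rng(rng_seed)
    lengths = np.array([iv.length for iv in regions], dtype=np.int64)
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    if lengths.min() > sizes.max():
        raise GenerationError(
            "background window longer than every chromosome"
        )
    out: List[Interval] = []
    for length in rng.choice(lengths, size=len(regions), replace=True):
        ok = sizes >= length
        weights = np.where(ok, sizes, 0).astype(float)
        weights /= weights.sum()
        ci = int(rng.choice(len(chroms), p=weights))
        start = int(rng.integers(0, sizes[ci] - length + 1))
        out.append(Interval(chroms[ci], start, start + int(length), name="bg"))
    return out


# ---------------------------------------------------------------------- #
# feature enrichment


def _overlap_tally(regions: Sequence[Interval], features: IntervalSet) -> int:
    return sum(1 for iv in regions if features.overlaps_any(iv))


def feature_enrichment(
    regions: Sequence[Interval],
    background: Sequence[Interval],
    features: Mapping[str, IntervalSet],
) -> pd.DataFrame:
    """Per-class overlap counts, odds ratios and Fisher exact p-values.

    One row per feature class: (n_regions_in, n_regions, n_background_in,
    n_background, odds_ratio, p).  The odds ratio is (a*d)/(b*c) for the
    table [[in_regions, out_regions], [in_background, out_background]].
    """
    rows = []
    for name, feats in features.items():
        if len(feats) == 0:
            logger.warning("feature class %s is empty; p = 1", name)
            rows.append(
                {
                    "feature": name,
                    "regions_in": 0,
                    "regions_total": len(regions),
                    "background_in": 0,
                    "background_total": len(background),
                    "regions_pct": 0.0,
                    "background_pct": 0.0,
                    "odds_ratio": float("nan"),
                    "p": 1.0,
                }
            )
            continue
        a = _overlap_tally(regions, feats)
        b = len(regions) - a
        c = _overlap_tally(background, feats)
        d = len(background) - c
        odds = (a * d) / (b * c) if b * c > 0 else float("inf")
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "feature": name,
                "regions_in": a,
                "regions_total": len(regions),
                "background_in": c,
                "background_total": len(background),
                "regions_pct": 100.0 * a / len(regions) if regions else 0.0,
                "background_pct": 100.0 * c / len(background) if background else 0.0,
                "odds_ratio": odds,
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def dhs_core_fraction(
    regions: Sequence[Interval],
    dhs: IntervalSet,
    background: Sequence[Interval],
) -> Tuple[float, float, pd.DataFrame]:
    """Fraction of regions overlapping DHS core intervals, with exact-test p.

    The core is the DHS interval itself (no flanks); overlap rule >= 1 bp.
    """
    df = feature_enrichment(regions, background, {"dhs_core": dhs})
    row = df.iloc[0]
    fraction = row["regions_in"] / row["regions_total"] if row["regions_total"] else 0.0
    return float(fraction), float(row["p"]), df


# ---------------------------------------------------------------------- #
# DHS metaplot


def dhs_metaplot(
    table: MethylomeTable,
    group_samples: Mapping[str, Sequence[str]],
    dhs: Sequence[Interval],
    control: str,
    flank: int = 1000,
    body_bins: int = 20,
    flank_bins: int = 10,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> Dict[str, object]:
    """Average methylation over length-scaled DHS bodies plus 1 kb flanks.

    Bin value = unweighted mean of passing per-site fractions across all
    DHSs.  Each treated group is compared to the control with a Wilcoxon
    matched-pairs signed-rank test over per-DHS body mean methylation
    (same DHS paired across groups); DHSs lacking a passing site in either
    member of a pair are dropped from that pairing.

    Returns {"profile": long DataFrame (group, bin, mean), "tests":
    {group: {"p":, "statistic":, "n_pairs":}}, "per_dhs": DataFrame}.
    """
    if control not in group_samples:
        raise ConfigurationError(f"control group {control!r} not in group_samples")
    n_bins = body_bins + 2 * flank_bins
    flank_bin_width = flank / flank_bins
    group_levels: Dict[str, np.ndarray] = {}
    for gname, samples in group_samples.items():
        m, n = table.pooled(samples)
        group_levels[gname] = site_levels(m, n, min_depth)

    bin_sums = {g: np.zeros(n_bins) for g in group_samples}
    bin_counts = {g: np.zeros(n_bins) for g in group_samples}
    per_dhs_records = []
    for di, iv in enumerate(dhs):
        idx = table.region_indices(
            Interval(iv.chrom, max(0, iv.start - flank), iv.end + flank)
        )
        if idx.size == 0:
            continue
        pos = table.pos[idx]
        bins = np.empty(idx.size, dtype=np.int64)
        upstream = pos < iv.start
        body = (pos >= iv.start) & (pos < iv.end)
        downstream = pos >= iv.end
        bins[upstream] = np.minimum(
            flank_bins - 1,
            ((pos[upstream] - (iv.start - flank)) / flank_bin_width).astype(np.int64),
        )
        bins[body] = flank_bins + np.minimum(
            body_bins - 1,
            ((pos[body] - iv.start) / iv.length * body_bins).astype(np.int64),
        )
        bins[downstream] = (
            flank_bins
            + body_bins
            + np.minimum(
                flank_bins - 1,
                ((pos[downstream] - iv.end) / flank_bin_width).astype(np.int64),
            )
        )
        body_idx = idx[body]
        rec = {"dhs_index": di, "chrom": iv.chrom, "start": iv.start, "end": iv.end}
        for gname, levels in group_levels.items():
            vals = levels[idx]
            ok = ~np.isnan(vals)
            np.add.at(bin_sums[gname], bins[ok], vals[ok])
            np.add.at(bin_counts[gname], bins[ok], 1)
            body_vals = levels[body_idx]
            body_vals = body_vals[~np.isnan(body_vals)]
            rec[gname] = float(body_vals.mean()) if body_vals.size else np.nan
        per_dhs_records.append(rec)

    per_dhs = pd.DataFrame.from_records(per_dhs_records)
    profile_rows = []
    for gname in group_samples:
        with np.errstate(invalid="ignore"):
            means = np.where(
                bin_counts[gname] > 0, bin_sums[gname] / bin_counts[gname], np.nan
            )
        for b in range(n_bins):
            profile_rows.append(
                {"group": gname, "bin": b, "mean_methylation": means[b]}
            )
    tests: Dict[str, Dict[str, float]] = {}
    for gname in group_samples:
        if gname == control:
            continue
        if per_dhs.empty:
            tests[gname] = {"p": float("nan"), "statistic": float("nan"), "n_pairs": 0}
            continue
        paired = per_dhs[[gname, control]].dropna()
        dropped = len(per_dhs) - len(paired)
        if dropped:
            logger.info(
                "metaplot pairing %s vs %s: dropped %d DHSs without coverage",
                gname,
                control,
                dropped,
            )
        diffs = paired[gname] - paired[control]
        if len(diffs) < 5 or np.allclose(diffs, 0):
            tests[gname] = {
                "p": 1.0,
                "statistic": 0.0,
                "n_pairs": int(len(diffs)),
            }
            continue
        res = stats.wilcoxon(paired[gname], paired[control])
        tests[gname] = {
            "p": float(res.pvalue),
            "statistic": float(res.statistic),
            "n_pairs": int(len(diffs)),
        }
    return {
        "profile": pd.DataFrame(profile_rows),
        "tests": tests,
        "per_dhs": per_dhs,
    }


# ---------------------------------------------------------------------- #
# seed / PAM density


def count_pattern_both_strands(seq: str, seed: str) -> int:
    """Occurrences of seed+NGG on either strand of ``seq`` (overlaps counted).

    Reverse-strand matches are found as the reverse complement of the
    pattern on the forward sequence, so both strands are scanned without
    materialising the reverse complement of the window.
    """
    seq = seq.upper()
    fwd = re.compile("(?=" + re.escape(seed.upper()) + "[ACGT]GG)")
    rev_pat = reverse_complement(seed.upper() + "NGG").replace("N", "[ACGT]")
    rev = re.compile("(?=" + rev_pat + ")")
    return len(fwd.findall(seq)) + len(rev.findall(seq))


@dataclass
class DensityResult:
    """Per-window seed/PAM match counts and densities (matches per kb)."""

    label: str
    counts: np.ndarray
    lengths_bp: np.ndarray

    @property
    def densities(self) -> np.ndarray:
        return self.counts / (self.lengths_bp / 1000.0)

    @property
    def median_density(self) -> float:
        return float(np.median(self.densities)) if len(self.counts) else float("nan")

    @property
    def sd_density(self) -> float:
        return float(np.std(self.densities, ddof=1)) if len(self.counts) > 1 else float("nan")

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())

    @property
    def total_bp(self) -> int:
        return int(self.lengths_bp.sum())


def _window_sequences(
    windows: Sequence[Interval], genome: Mapping[str, str]
) -> List[str]:
    seqs = []
    for iv in windows:
        if iv.chrom not in genome:
            raise ConfigurationError(f"window on unknown chromosome {iv.chrom}")
        chrom_seq = genome[iv.chrom]
        if iv.end > len(chrom_seq):
            raise ConfigurationError(
                f"window {iv.chrom}:{iv.start}-{iv.end} beyond chromosome end"
            )
        seqs.append(chrom_seq[iv.start : iv.end])
    return seqs


def seed_pam_density(
    windows: Sequence[Interval],
    genome: Mapping[str, str],
    guide: GuideRNA,
    seed_len: int = 5,
    label: str = "",
) -> DensityResult:
    """Density of the guide's PAM-proximal seed followed by NGG, both strands."""
    if seed_len not in (5, 11):
        raise ConfigurationError("seed_len must be 5 or 11")
    seed = guide.seed5 if seed_len == 5 else guide.seed11
    seqs = _window_sequences(windows, genome)
    counts = np.array([count_pattern_both_strands(s, seed) for s in seqs])
    lengths = np.array([iv.length for iv in windows], dtype=np.int64)
    return DensityResult(label or guide.name, counts, lengths)


def pam_density(
    windows: Sequence[Interval],
    genome: Mapping[str, str],
    label: str = "PAM",
) -> DensityResult:
    """Density of bare NGG PAM sites on both strands."""
    seqs = _window_sequences(windows, genome)
    counts = np.array([count_pattern_both_strands(s, "") for s in seqs])
    lengths = np.array([iv.length for iv in windows], dtype=np.int64)
    return DensityResult(label, counts, lengths)


def compare_densities(
    a: DensityResult, b: DensityResult
) -> Dict[str, float]:
    """Compare two window sets' match densities.

    Two complementary tests are reported: a Fisher exact test on pooled
    match counts vs non-match bp, and a two-sample (Welch) t-test on the
    per-window densities.
    """
    table = [
        [a.total_count, max(a.total_bp - a.total_count, 0)],
        [b.total_count, max(b.total_bp - b.total_count, 0)],
    ]
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    if len(a.counts) > 1 and len(b.counts) > 1:
        t_res = stats.ttest_ind(a.densities, b.densities, equal_var=False)
        t_p = float(t_res.pvalue)
        t_stat = float(t_res.statistic)
    else:
        t_p, t_stat = float("nan"), float("nan")
    return {
        "fisher_p": float(fisher_p),
        "t_p": t_p,
        "t_statistic": t_stat,
        "median_a": a.median_density,
        "median_b": b.median_density,
        "sd_a": a.sd_density,
        "sd_b": b.sd_density,
    }
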