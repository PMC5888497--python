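"""Two-group DMR detection.

The caller reproduces the published call parameters (delta >= 0.1, per-CpG
P <= 0.01, >= 3 CpGs, length >= 10 bp, 100 bp smoothing window) around a
fully specified Wald statistic of its own.  Per condition, replicate counts
are pooled, levels are smoothed with a depth-weighted +-window/2 moving
window, and each CpG is tested with

    z = (p1s - p2s) / sqrt( pbar (1 - pbar) (1/n1 + 1/n2) + phi0 )

where n1, n2 are the summed passing depths inside the smoothing window,
pbar is the pooled smoothed level with one methylated and one unmethylated
pseudo-read, and phi0 is a prior extra-binomial variance (fixed 0.001 by
default, replaced by a method-of-moments beta-binomial estimate when both
conditions carry >= 2 replicates).  P-values come from the standard normal
and are deliberately not multiplicity-adjusted, matching the per-CpG
"P value <= 0.01" usage the call parameters are quoted from.

Qualifying CpGs (p <= p_max and |delta| >= delta_min) seed DMRs; runs of
same-direction seeds with inter-seed gaps <= merge_gap form candidates,
which must then pass the CpG-count, length and region-delta thresholds.
A region spans its first to last member CpG plus 2 bp, covering the final
CpG dinucleotide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .methylation import DEFAULT_MIN_DEPTH, MethylomeTable

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 100
DEFAULT_PHI0 = 0.001


@dataclass(frozen=True)
class DMR:
    """A differentially methylated region (0-based, half-open).

    ``direction`` is relative to condition 1: "hyper" means condition 1 is
    more methylated than condition 2.
    """

    chrom: str
    start: int
    end: int
    direction: str  # "hyper" | "hypo"
    n_cpg: int
    mean_delta: float
    p_min: float
    area_stat: float

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.direction}"


def _windowed_sums(
    pos: np.ndarray,
    values: np.ndarray,
    half_window: int,
) -> np.ndarray:
    """Sum of ``values`` over sites within +-half_window bp of each site."""
    csum = np.concatenate([[0], np.cumsum(values)])
    lo = np.searchsorted(pos, pos - half_window, side="left")
    hi = np.searchsorted(pos, pos + half_window, side="right")
    return csum[hi] - csum[lo]


def smooth_levels(
    table: MethylomeTable,
    samples: Sequence[str],
    window: int = DEFAULT_WINDOW,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Depth-weighted moving-window methylation level per site.

    Returns (smoothed level, windowed M sum, windowed N sum); passing sites
    within +-window/2 bp on the same chromosome contribute their raw counts.
    Sites whose window holds no passing site (including themselves) are NaN.
    window=0 reduces to the raw per-site ratio.
    """
    m, n = table.pooled(samples)
    pass_mask = n >= min_depth
    m_eff = np.where(pass_mask, m, 0).astype(np.int64)
    n_eff = np.where(pass_mask, n, 0).astype(np.int64)
    half = window // 2
    m_win = np.zeros(len(table.pos), dtype=np.int64)
    n_win = np.zeros(len(table.pos), dtype=np.int64)
    for chrom, (s, e) in table._chrom_slices.items():
        pos = table.pos[s:e]
        m_win[s:e] = _windowed_sums(pos, m_eff[s:e], half)
        n_win[s:e] = _windowed_sums(pos, n_eff[s:e], half)
    level = np.full(len(table.pos), np.nan)
    np.divide(m_win, n_win, out=level, where=n_win > 0)
    return level, m_win, n_win


def estimate_phi0(
    table: MethylomeTable,
    samples: Sequence[str],
    min_depth: int = DEFAULT_MIN_DEPTH,
    max_sites: int = 50_000,
) -> Optional[float]:
    """Method-of-moments extra-binomial variance across replicates.

    For sites where every replicate passes the depth filter, the excess of
    the between-replicate variance of per-replicate levels over its binomial
    expectation estimates the beta-binomial overdispersion contribution to
    the variance of a level.  Returns None with < 2 replicates.
    """
    if len(samples) < 2:
        return None
    levels = []
    inv_n = []
    mask = np.ones(len(table.pos), dtype=bool)
    for s in samples:
        m, n = table.counts[s]
        mask &= n >= min_depth
    if mask.sum() < 100:
        return None
    idx = np.nonzero(mask)[0]
    if idx.size > max_sites:
        idx = idx[:: idx.size // max_sites + 1]
    for s in samples:
        m, n = table.counts[s]
        levels.append(m[idx] / n[idx])
        inv_n.append(1.0 / n[idx])
    levels = np.vstack(levels)
    inv_n = np.vstack(inv_n)
    pbar = levels.mean(axis=0)
    var_between = levels.var(axis=0, ddof=1)
    binom_part = pbar * (1 - pbar) * inv_n.mean(axis=0)
    excess = var_between - binom_part
    phi0 = float(np.clip(np.median(excess), 0.0, None))
    return phi0


def cpg_test(
    table: MethylomeTable,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    window: int = DEFAULT_WINDOW,
    min_depth: int = DEFAULT_MIN_DEPTH,
    phi0: Optional[float] = None,
) -> pd.DataFrame:
    """Per-CpG Wald test between two conditions on smoothed levels.

    Returns one row per site with coverage in both conditions: columns
    chrom, pos, p1s, p2s, delta, z, p.  Sites without passing coverage in
    either condition's window are skipped (and counted in the log).
    """
    if phi0 is None:
        phi_a = estimate_phi0(table, samples_a, min_depth)
        phi_b = estimate_phi0(table, samples_b, min_depth)
        if phi_a is not None and phi_b is not None:
            phi0 = max(DEFAULT_PHI0, (phi_a + phi_b) / 2.0)
            logger.info("method-of-moments phi0 = %.3g", phi0)
        else:
            phi0 = DEFAULT_PHI0
    p1, m1, n1 = smooth_levels(table, samples_a, window, min_depth)
    p2, m2, n2 = smooth_levels(table, samples_b, window, min_depth)
    ok = (n1 > 0) & (n2 > 0)
    skipped = int((~ok).sum())
    if skipped:
        logger.info("cpg_test: skipped %d sites without coverage", skipped)
    delta = p1 - p2
    pbar = (m1 + m2 + 1.0) / (n1 + n2 + 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(pbar * (1 - pbar) * (1.0 / n1 + 1.0 / n2) + phi0)
        z = delta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    df = pd.DataFrame(
        {
            "chrom": table.chrom,
            "pos": table.pos,
            "p1s": p1,
            "p2s": p2,
            "delta": delta,
            "z": z,
            "p": p,
        }
    )
    return df[ok].reset_index(drop=True)


def call_dmrs(
    results: pd.DataFrame,
    delta_min: float = 0.1,
    p_max: float = 0.01,
    min_cpg: int = 3,
    min_len: int = 10,
    merge_gap: int = 100,
) -> List[DMR]:
    """Group qualifying CpGs into DMRs under the published thresholds."""
    dmrs: List[DMR] = []
    seed_mask = (results["p"] <= p_max) & (results["delta"].abs() >= delta_min)
    seeds = results[seed_mask]
    for chrom, grp in seeds.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        delta = grp["delta"].to_numpy()
        pval = grp["p"].to_numpy()
        zval = grp["z"].to_numpy()
        sign = np.sign(delta)
        start_idx = 0
        for i in range(1, len(pos) + 1):
            if (
                i == len(pos)
                or pos[i] - pos[i - 1] > merge_gap
                or sign[i] != sign[i - 1]
            ):
                run = slice(start_idx, i)
                dmr = _emit_candidate(
                    str(chrom),
                    pos[run],
                    delta[run],
                    pval[run],
                    zval[run],
                    delta_min,
                    min_cpg,
                    min_len,
                )
                if dmr is not None:
                    dmrs.append(dmr)
                start_idx = i
    return dmrs


def _emit_candidate(
    chrom: str,
    pos: np.ndarray,
    delta: np.ndarray,
    pval: np.ndarray,
    zval: np.ndarray,
    delta_min: float,
    min_cpg: int,
    min_len: int,
) -> Optional[DMR]:
    if len(pos) < min_cpg:
        return None
    start = int(pos[0])
    end = int(pos[-1]) + 2  # cover the final CpG dinucleotide
    if end - start < min_len:
        return None
    mean_delta = float(delta.mean())
    if abs(mean_delta) < delta_min:
        return None
    return DMR(
        chrom=chrom,
        start=start,
        end=end,
        direction="hyper" if mean_delta > 0 else "hypo",
        n_cpg=int(len(pos)),
        mean_delta=mean_delta,
        p_min=float(pval.min()),
        area_stat=float(zval.sum()),
    )


def dmrs_to_frame(dmrs: Iterable[DMR]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "name": d.name,
                "area_stat": d.area_stat,
                "direction": d.direction,
                "n_cpg": d.n_cpg,
                "mean_delta": d.mean_delta,
                "p_min": d.p_min,
            }
            for d in dmrs
        ],
        columns=[
            "chrom",
            "start",
            "end",
            "name",
            "area_stat",
            "direction",
            "n_cpg",
            "mean_delta",
            "p_min",
        ],
    )
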