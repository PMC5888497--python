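"""Per-CpG methylation levels and summaries.

A :class:`MethylomeTable` holds the per-site (M, N) read counts of one or
more samples over a shared, sorted site list.  A site is addressed by the
position of the C on the forward strand; counts from both strands are
assumed pooled.  Levels are M/N and a site only contributes when its depth
passes the ``min_depth`` filter (default 4 reads), applied per sample and
per site; failing sites are *missing*, never zero.

Two region-level weightings are exposed: ``depth`` (sum M / sum N over
passing sites — the default everywhere) and ``unweighted`` (mean of the
per-site fractions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DataError
from .guides import GuideRNA
from .intervals import Interval

DEFAULT_MIN_DEPTH = 4


class MethylomeTable:
    """Per-CpG (M, N) counts for a set of samples over one sorted site list."""

    def __init__(
        self,
        chrom: Sequence[str],
        pos: Sequence[int],
        counts: Mapping[str, Tuple[np.ndarray, np.ndarray]],
        context: Optional[Sequence[str]] = None,
        strand: Optional[Sequence[str]] = None,
    ) -> None:
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        n = len(self.pos)
        if len(self.chrom) != n:
            raise DataError("chrom and pos length mismatch")
        self.context = (
            np.asarray(context, dtype=object)
            if context is not None
            else np.full(n, "CpG", dtype=object)
        )
        self.strand = (
            np.asarray(strand, dtype=object)
            if strand is not None
            else np.full(n, "+", dtype=object)
        )
        self.counts: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for sample, (m, nn) in counts.items():
            m = np.asarray(m, dtype=np.int64)
            nn = np.asarray(nn, dtype=np.int64)
            if len(m) != n or len(nn) != n:
                raise DataError(f"sample {sample}: count arrays mismatch site list")
            bad = np.nonzero((m < 0) | (nn < 0) | (m > nn))[0]
            if bad.size:
                i = int(bad[0])
                raise DataError(
                    f"sample {sample}: M > N or negative count at "
                    f"{self.chrom[i]}:{self.pos[i]} (M={m[i]}, N={nn[i]})"
                )
            self.counts[sample] = (m, nn)
        self._check_sorted()
        # per-chromosome contiguous slices for fast region queries
        self._chrom_slices: Dict[str, Tuple[int, int]] = {}
        if n:
            boundaries = np.nonzero(self.chrom[1:] != self.chrom[:-1])[0] + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [n]])
            for s, e in zip(starts, ends):
                self._chrom_slices[str(self.chrom[s])] = (int(s), int(e))

    def _check_sorted(self) -> None:
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(len(self.pos))):
            raise DataError("sites must be sorted by (chrom, pos)")
        dup = np.nonzero(
            (self.chrom[1:] == self.chrom[:-1]) & (self.pos[1:] == self.pos[:-1])
        )[0]
        if dup.size:
            i = int(dup[0])
            raise DataError(f"duplicate site {self.chrom[i]}:{self.pos[i]}")

    # ------------------------------------------------------------------ #

    @property
    def samples(self) -> List[str]:
        return list(self.counts)

    def __len__(self) -> int:
        return len(self.pos)

    def n_sites(self) -> int:
        return len(self.pos)

    def chrom_slice(self, chrom: str) -> Tuple[int, int]:
        return self._chrom_slices.get(chrom, (0, 0))

    def region_indices(self, region: Interval) -> np.ndarray:
        s, e = self.chrom_slice(region.chrom)
        pos = self.pos[s:e]
        lo = int(np.searchsorted(pos, region.start, side="left"))
        hi = int(np.searchsorted(pos, region.end, side="left"))
        return np.arange(s + lo, s + hi)

    def pooled(self, samples: Sequence[str]) -> Tuple[np.ndarray, np.ndarray]:
        """Sum M and N over samples (replicate pooling before any ratio)."""
        m = np.zeros(len(self.pos), dtype=np.int64)
        n = np.zeros(len(self.pos), dtype=np.int64)
        for sample in samples:
            sm, sn = self.counts[sample]
            m += sm
            n += sn
        return m, n

    def subset_samples(self, samples: Sequence[str]) -> "MethylomeTable":
        return MethylomeTable(
            self.chrom,
            self.pos,
            {s: self.counts[s] for s in samples},
            context=self.context,
            strand=self.strand,
        )

    def to_frame(self, sample: str) -> pd.DataFrame:
        m, n = self.counts[sample]
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "strand": self.strand,
                "context": self.context,
                "M": m,
                "N": n,
            }
        )

    @classmethod
    def from_frames(cls, frames: Mapping[str, pd.DataFrame]) -> "MethylomeTable":
        """Combine per-sample count frames sharing one site list."""
        first = None
        counts = {}
        for sample, df in frames.items():
            df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
                drop=True
            )
            key = df[["chrom", "pos"]]
            if first is None:
                first = df
            elif not key.equals(first[["chrom", "pos"]]):
                raise DataError(
                    f"sample {sample}: site list differs from other samples"
                )
            counts[sample] = (
                df["M"].to_numpy(np.int64),
                df["N"].to_numpy(np.int64),
            )
        if first is None:
            raise DataError("no samples provided")
        return cls(
            first["chrom"].to_numpy(object),
            first["pos"].to_numpy(np.int64),
            counts,
            context=first["context"].to_numpy(object)
            if "context" in first
            else None,
            strand=first["strand"].to_numpy(object) if "strand" in first else None,
        )


# ---------------------------------------------------------------------- #
# site- and region-level operations


def site_methylation(
    m: int, n: int, min_depth: int = DEFAULT_MIN_DEPTH
) -> float:
    """M/N if depth passes the filter, else NaN (missing).

    Missing propagates: downstream means exclude missing sites rather than
    treating them as zero.
    """
    if m > n or m < 0:
        raise DataError(f"invalid counts M={m}, N={n}")
    if n < min_depth:
        return float("nan")
    return m / n


def site_levels(
    m: np.ndarray, n: np.ndarray, min_depth: int = DEFAULT_MIN_DEPTH
) -> np.ndarray:
    """Vectorised per-site levels with NaN where depth < min_depth."""
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    out = np.full(m.shape, np.nan)
    ok = n >= min_depth
    np.divide(m, n, out=out, where=ok & (n > 0))
    return out


def conversion_rate(table: MethylomeTable) -> float:
    """Bisulfite conversion rate (%) from an unmethylated spike-in.

    100 * (1 - sum M / sum N) over every cytosine in every sample, all
    sequence contexts, no depth filter — every read of the spike-in informs
    the conversion estimate.
    """
    total_m = 0
    total_n = 0
    for m, n in table.counts.values():
        total_m += int(m.sum())
        total_n += int(n.sum())
    if total_n == 0:
        raise DataError("conversion_rate: no reads in spike-in table")
    return 100.0 * (1.0 - total_m / total_n)


def region_mean(
    table: MethylomeTable,
    region: Interval,
    samples: Sequence[str],
    weighting: str = "depth",
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> float:
    """Mean methylation of a region over pooled samples, or NaN if no site passes."""
    idx = table.region_indices(region)
    if idx.size == 0:
        return float("nan")
    m, n = table.pooled(samples)
    m, n = m[idx], n[idx]
    ok = n >= min_depth
    if not ok.any():
        return float("nan")
    if weighting == "depth":
        return float(m[ok].sum() / n[ok].sum())
    if weighting == "unweighted":
        return float(np.mean(m[ok] / n[ok]))
    raise ValueError(f"unknown weighting {weighting!r}")


def global_summary(
    table: MethylomeTable,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> pd.DataFrame:
    """Per-chromosome and genome-wide mean methylation, per sample and context.

    Means are unweighted averages of passing per-site fractions.  Rows with
    chrom == "genome" carry the genome-wide values.
    """
    records = []
    for sample in table.samples:
        m, n = table.counts[sample]
        levels = site_levels(m, n, min_depth)
        df = pd.DataFrame(
            {
                "chrom": table.chrom,
                "context": table.context,
                "level": levels,
            }
        ).dropna(subset=["level"])
        for (chrom, ctx), grp in df.groupby(["chrom", "context"], sort=True):
            records.append(
                {
                    "sample": sample,
                    "chrom": chrom,
                    "context": ctx,
                    "mean_methylation": float(grp["level"].mean()),
                    "n_sites": int(len(grp)),
                }
            )
        for ctx, grp in df.groupby("context", sort=True):
            records.append(
                {
                    "sample": sample,
                    "chrom": "genome",
                    "context": ctx,
                    "mean_methylation": float(grp["level"].mean()),
                    "n_sites": int(len(grp)),
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["sample", "chrom", "context", "mean_methylation", "n_sites"]
    )


def ontarget_profile(
    table: MethylomeTable,
    guides: Sequence[GuideRNA],
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    max_dist: int = 300,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> pd.DataFrame:
    """Per-CpG methylation around each guide's protospacer, A vs B.

    Distance is signed in genome orientation: negative upstream of the
    protospacer start, positive downstream of its end, and 0 (with the
    ``interior`` flag set) for CpGs inside the protospacer — the dCas9
    footprint where no de novo methylation is deposited.  Levels pool
    replicates within each group (sum M / sum N per site).
    """
    from .errors import ConfigurationError

    ma, na = table.pooled(samples_a)
    mb, nb = table.pooled(samples_b)
    lev_a = site_levels(ma, na, min_depth)
    lev_b = site_levels(mb, nb, min_depth)
    records = []
    for guide in guides:
        if not guide.has_site:
            raise ConfigurationError(
                f"guide {guide.name} has no genomic site; cannot profile"
            )
        window = Interval(
            guide.chrom, max(0, guide.start - max_dist), guide.end + max_dist
        )
        for i in table.region_indices(window):
            pos = int(table.pos[i])
            if pos < guide.start:
                dist = pos - guide.start
            elif pos >= guide.end:
                dist = pos - guide.end + 1
            else:
                dist = 0
            interior = dist == 0
            if abs(dist) > max_dist:
                continue
            records.append(
                {
                    "guide": guide.name,
                    "chrom": guide.chrom,
                    "pos": pos,
                    "distance": dist,
                    "interior": interior,
                    "level_a": lev_a[i],
                    "level_b": lev_b[i],
                    "delta": lev_a[i] - lev_b[i],
                }
            )
    df = pd.DataFrame.from_records(
        records,
        columns=[
            "guide",
            "chrom",
            "pos",
            "distance",
            "interior",
            "level_a",
            "level_b",
            "delta",
        ],
    )
    return df.sort_values(["distance", "guide"], kind="mergesort").reset_index(
        drop=True
    )
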