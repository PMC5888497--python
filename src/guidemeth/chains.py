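"""Stochastic-DMR exclusion by dose/gRNA monotonicity chains.

A called DMR could be a stochastic methylation difference unrelated to the
dCas9 methyltransferase treatment.  The filter removes such regions by
requiring the group mean methylation over the DMR interval to respect the
ordered inequality chains of the comparison design (see
:mod:`guidemeth.design`): non-strict inequalities, exact ties pass, and a
configurable slack ``eps`` (default 0, i.e. the literal chains) is exposed
because sampling noise makes exact ordering brittle.

Group levels are computed over the DMR interval only (no flank),
depth-weighted with replicates pooled.  A DMR whose chained groups include
one with no passing site is *unresolvable* — distinct from failing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import math

from .design import ChainConstraint, FilterDesign, GroupDesign
from .dmr import DMR
from .intervals import Interval
from .methylation import DEFAULT_MIN_DEPTH, MethylomeTable, region_mean

logger = logging.getLogger(__name__)


def group_levels(
    dmr: DMR,
    table: MethylomeTable,
    design: GroupDesign,
    min_depth: int = DEFAULT_MIN_DEPTH,
    weighting: str = "depth",
) -> Dict[int, float]:
    """Mean methylation per group over the DMR interval (NaN = missing)."""
    region = Interval(dmr.chrom, dmr.start, dmr.end)
    levels: Dict[int, float] = {}
    for group in design.groups:
        samples = design.sample_ids(group.group_id)
        levels[group.group_id] = region_mean(
            table, region, samples, weighting=weighting, min_depth=min_depth
        )
    return levels


def evaluate_chains(
    levels: Mapping[int, float],
    chains: Sequence[ChainConstraint],
    direction: str,
    eps: float = 0.0,
) -> Tuple[str, Optional[Tuple[int, int]]]:
    """Evaluate every chain inequality for one DMR.

    Returns ("pass", None), ("fail", first failing (left, right) pair) or
    ("unresolvable", None) when a chained group's level is missing.  For
    direction "hyper" each pair requires level(l) <= level(r) (+ eps); for
    "hypo" the mirrored level(l) >= level(r) (- eps).
    """
    if direction not in ("hyper", "hypo"):
        raise ValueError(f"unknown direction {direction!r}")
    for chain in chains:
        for gid in chain.group_ids:
            lv = levels.get(gid)
            if lv is None or (isinstance(lv, float) and math.isnan(lv)):
                logger.info("chain group %d has missing level; unresolvable", gid)
                return "unresolvable", None
    for chain in chains:
        for left, right in chain.comparisons:
            lv_l, lv_r = levels[left], levels[right]
            if direction == "hyper":
                ok = lv_l <= lv_r + eps
            else:
                ok = lv_l >= lv_r - eps
            if not ok:
                return "fail", (left, right)
    return "pass", None


def passes_chains(
    levels: Mapping[int, float],
    chains: Sequence[ChainConstraint],
    direction: str = "hyper",
    eps: float = 0.0,
) -> bool:
    """True iff every chain inequality holds; raises on a missing level."""
    status, _ = evaluate_chains(levels, chains, direction, eps)
    if status == "unresolvable":
        raise ValueError("missing level for a chained group")
    return status == "pass"


@dataclass
class FilteredDMR:
    dmr: DMR
    levels: Dict[int, float]
    status: str  # pass | fail | unresolvable
    failed_comparison: Optional[Tuple[int, int]] = None


@dataclass
class FilterResult:
    kept: List[FilteredDMR] = field(default_factory=list)
    dropped: List[FilteredDMR] = field(default_factory=list)
    unresolvable: List[FilteredDMR] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.kept) + len(self.dropped) + len(self.unresolvable)


def filter_dmrs(
    dmrs: Sequence[DMR],
    table: MethylomeTable,
    design: GroupDesign,
    filter_design: FilterDesign,
    eps: float = 0.0,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> FilterResult:
    """Partition DMRs into (kept, dropped, unresolvable) by the chains.

    Hyper DMRs are tested against the hyper reading of the chains, hypo
    against the mirrored reading; the partition is exhaustive and disjoint
    and every record carries its first failing comparison (if any).
    """
    filter_design.validate_against(design)
    result = FilterResult()
    for dmr in dmrs:
        levels = group_levels(dmr, table, design, min_depth=min_depth)
        status, failed = evaluate_chains(
            levels, filter_design.chains, dmr.direction, eps
        )
        record = FilteredDMR(dmr, levels, status, failed)
        if status == "pass":
            result.kept.append(record)
        elif status == "fail":
            result.dropped.append(record)
        else:
            result.unresolvable.append(record)
    return result
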