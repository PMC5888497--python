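"""DMR-set comparison and DMR–ChIP-peak overlap."""

from __future__ import annotations

from typing import Dict, Mapping, Optional, Sequence

from scipy import stats

from .intervals import Interval, IntervalSet, expand_flanks, overlap_count
from .enrichment import sample_background


def peak_overlap_analysis(
    dmrs: Sequence[Interval],
    peaks: IntervalSet,
    chrom_sizes: Mapping[str, int],
    flank: int = 100,
    background_seed: int = 0,
    background: Optional[Sequence[Interval]] = None,
) -> Dict[str, float]:
    """Fraction of flank-expanded DMRs overlapping ChIP peaks, vs background.

    DMRs are expanded by ``flank`` bp (the methylation footprint extends
    beyond the binding site) before overlap counting; enrichment against
    matched background windows is assessed with a two-sided Fisher exact
    test on the 2x2 overlap table.
    """
    expanded = expand_flanks(dmrs, flank, chrom_sizes)
    if background is None:
        background = sample_background(expanded, chrom_sizes, background_seed)
    n_overlap, _ = overlap_count(IntervalSet(expanded), peaks)
    bg_overlap, _ = overlap_count(IntervalSet(background), peaks)
    n, nb = len(expanded), len(background)
    table = [[n_overlap, n - n_overlap], [bg_overlap, nb - bg_overlap]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return {
        "fraction": n_overlap / n if n else 0.0,
        "n_overlap": float(n_overlap),
        "n_regions": float(n),
        "background_fraction": bg_overlap / nb if nb else 0.0,
        "p": float(p),
    }
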