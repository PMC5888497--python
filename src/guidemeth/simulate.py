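"""Synthetic genome, guide and bisulfite-count simulation.

The generator produces a small annotated genome, places gRNAs, and draws
multi-sample per-CpG (M, N) count tables under the nine-group transfection
design, with ground-truth tables of every injected effect so downstream
recovery can be scored without re-derivation.

Genome model
------------
Chromosomes are random 41% GC sequence onto which forward-strand gene
models are laid: 2 kb promoter, 5'UTR, CDS exons split by introns, 3'UTR.
CpG islands cover the TSS of (a configurable number of) genes and receive
extra planted CG dinucleotides; outside islands most CpGs are thinned,
least aggressively inside repeats, so islands end with an observed/expected
CpG ratio well above background — the qualitative CpG landscape the feature
enrichment analyses need.  DHSs sit preferentially at TSSs (open promoter
chromatin), the rest at random positions.

Effect model
------------
Counts are beta-binomial: N ~ Poisson(mean_depth), M ~ BetaBinomial(N, p,
phi) with p clamped to [0, 1] after adding, to a feature-class baseline:

* an on-target delta at CpGs 1–50 bp outside a protospacer of the sample's
  gRNA set (reduced weight within 1–9 bp, zero inside the protospacer —
  the bound dCas9 footprint excludes the methyltransferase);
* a hypermethylating off-target delta at DHS windows carrying a seed–PAM
  match of the set's guides (gRNA-dose dependent, with a small residual
  enzyme-alone component at open chromatin);
* a hypomethylating off-target delta at a random subset of Alu/LINE1
  repeats.

Effects scale with construct activity (DNMT3A > DNMT3B; catalytic-dead
E752A/E697A mutants contribute nothing) and transfected dose, which makes
the dose/gRNA inequality chains of the filter hold in expectation.
Bisulfite conversion failure adds (1 - p) * (1 - conversion_rate) apparent
methylation; an unmethylated lambda spike-in is simulated alongside for the
conversion-rate estimate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .design import GroupDesign, GroupSpec, default_design
from .enrichment import count_pattern_both_strands
from .errors import ConfigurationError, GenerationError
from .guides import GuideRNA, reverse_complement
from .intervals import Interval, IntervalSet
from .methylation import MethylomeTable

LAMBDA_GENOME_LENGTH = 48_502  # bp, the unmethylated phage spike-in reference

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_C, _G, _A = ord("C"), ord("G"), ord("A")

FEATURE_CLASSES = (
    "promoter",
    "utr5",
    "utr3",
    "cds",
    "intron",
    "cgi",
    "cgi_shore",
    "alu",
    "line1",
    "line2",
    "dhs",
)


@dataclass
class SyntheticGenomeSpec:
    """Parameters of the synthetic annotated genome."""

    genome_length: int = 5_000_000
    n_chromosomes: int = 2
    feature_fractions: Dict[str, float] = field(
        default_factory=lambda: {
            "promoter": 0.04,
            "utr5": 0.006,
            "utr3": 0.01,
            "cds": 0.012,
            "intron": 0.09,
            "cgi": 0.024,
            "alu": 0.03,
            "line1": 0.04,
            "line2": 0.01,
            "dhs": 0.015,
        }
    )
    cgi_density: float = 0.10  # CG planting prob per dinucleotide inside CGIs
    cpg_keep_repeat: float = 0.5  # CpG survival outside CGIs, inside repeats
    cpg_keep_other: float = 0.22  # CpG survival elsewhere
    dhs_tss_fraction: float = 0.7  # DHSs centred on a TSS
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.feature_fractions.values()) > 1.0:
            raise ConfigurationError("feature fractions sum to more than 1")
        if self.genome_length < self.n_chromosomes:
            raise ConfigurationError("genome too short for chromosome count")


@dataclass
class EffectModel:
    """Methylation baselines and injected dCas9-methyltransferase effects."""

    baseline_methylation: Dict[str, float] = field(
        default_factory=lambda: {
            "cgi": 0.08,
            "cgi_shore": 0.35,
            "promoter": 0.20,
            "utr5": 0.25,
            "utr3": 0.70,
            "cds": 0.70,
            "alu": 0.80,
            "line1": 0.80,
            "line2": 0.75,
            "intron": 0.70,
            "default": 0.70,
        }
    )
    dispersion: float = 0.01  # beta-binomial phi
    ontarget_delta: float = 0.5
    ontarget_flank: Tuple[int, int] = (10, 50)  # full-weight flank, bp
    near_flank_weight: float = 0.5  # weight for the 1..(flank_lo-1) bp band
    dose_scale: Dict[int, float] = field(
        default_factory=lambda: {0: 0.0, 50: 0.55, 500: 1.0}
    )
    construct_scale: Dict[str, float] = field(
        default_factory=lambda: {
            "DNMT3A": 1.0,
            "DNMT3B": 0.6,
            "DNMT3A-E752A": 0.0,
            "DNMT3B-E697A": 0.0,
            "none": 0.0,
        }
    )
    offtarget_hyper_delta: float = 0.45
    offtarget_hypo_delta: float = 0.40
    no_guide_offtarget_scale: float = 0.15  # enzyme-alone open-chromatin effect
    n_offtarget_hypo: int = 40  # repeat intervals demethylated per gRNA set
    conversion_rate: float = 0.995
    mean_depth: float = 30.0

    def offtarget_multiplier(self, group: GroupSpec, grna_set: str) -> float:
        """Scale of a set's off-target delta in one transfection group."""
        base = self.construct_scale[group.construct] * self.dose_scale[group.dose]
        if group.grna_set == grna_set:
            return base * self.dose_scale[group.dose]
        return base * self.no_guide_offtarget_scale

    def ontarget_multiplier(self, group: GroupSpec, grna_set: str) -> float:
        if group.grna_set != grna_set:
            return 0.0
        return (
            self.construct_scale[group.construct]
            * self.dose_scale[group.dose] ** 2
        )


# ---------------------------------------------------------------------- #
# genome generation


def _spread_spans(
    rng: np.random.Generator, chrom_len: int, span: int, count: int
) -> List[int]:
    """Start positions for `count` non-overlapping spans with random gaps."""
    free = chrom_len - span * count
    if free < 0:
        raise ConfigurationError("feature spans exceed chromosome length")
    cuts = rng.random(count + 1)
    gaps = np.floor(cuts / cuts.sum() * free).astype(np.int64)
    starts = []
    cursor = 0
    for i in range(count):
        cursor += int(gaps[i])
        starts.append(cursor)
        cursor += span
    return starts


def _place_random(
    rng: np.random.Generator,
    chrom_sizes: Mapping[str, int],
    width_fn,
    count: int,
    same_class: Optional[Dict[str, List[Tuple[int, int]]]] = None,
    max_tries: int = 200,
) -> List[Interval]:
    """Rejection-sample `count` intervals avoiding same-class overlap."""
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights = sizes / sizes.sum()
    placed: Dict[str, List[Tuple[int, int]]] = (
        same_class if same_class is not None else {c: [] for c in chroms}
    )
    out: List[Interval] = []
    for _ in range(count):
        for _try in range(max_tries):
            ci = int(rng.choice(len(chroms), p=weights))
            chrom = chroms[ci]
            width = int(width_fn(rng))
            if width >= chrom_sizes[chrom]:
                continue
            start = int(rng.integers(0, chrom_sizes[chrom] - width))
            end = start + width
            if any(start < e and s < end for s, e in placed.get(chrom, [])):
                continue
            placed.setdefault(chrom, []).append((start, end))
            out.append(Interval(chrom, start, end))
            break
        else:
            raise GenerationError("could not place interval without overlap")
    return out


def generate_genome(
    spec: SyntheticGenomeSpec,
) -> Tuple[Dict[str, str], Dict[str, List[Interval]]]:
    """Generate chromosome sequences and per-class feature annotations.

    Returns (genome, annotations): genome maps chromosome name to sequence;
    annotations maps each feature class to a list of intervals that are
    non-overlapping within the class and lie inside chromosome bounds.
    CGI shores are the 2 kb flanks of each CGI minus any CGI overlap.
    Deterministic for a fixed ``rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    L = spec.genome_length
    n_chrom = spec.n_chromosomes
    base_len = L // n_chrom
    chrom_sizes = {
        f"chr{i + 1}": base_len + (L % n_chrom if i == n_chrom - 1 else 0)
        for i in range(n_chrom)
    }
    seqs: Dict[str, np.ndarray] = {
        c: rng.choice(_BASES, size=size, p=[0.295, 0.205, 0.205, 0.295])
        for c, size in chrom_sizes.items()
    }
    ann: Dict[str, List[Interval]] = {cls: [] for cls in FEATURE_CLASSES}
    frac = {cls: spec.feature_fractions.get(cls, 0.0) for cls in FEATURE_CLASSES}

    # --- gene models -------------------------------------------------- #
    promoter_len = 2000
    n_genes = int(round(frac["promoter"] * L / promoter_len))
    tss_list: List[Tuple[str, int]] = []
    if n_genes > 0:
        u5 = max(0, int(round(frac["utr5"] * L / n_genes)))
        u3 = max(0, int(round(frac["utr3"] * L / n_genes)))
        cds_total = max(0, int(round(frac["cds"] * L / n_genes)))
        intron_total = max(0, int(round(frac["intron"] * L / n_genes)))
        n_exons = 3 if cds_total >= 3 else 1
        exon_len = cds_total // n_exons if n_exons else 0
        n_introns = n_exons - 1
        intron_len = intron_total // n_introns if n_introns else 0
        gene_span = (
            promoter_len + u5 + exon_len * n_exons + intron_len * n_introns + u3
        )
        # genes per chromosome, proportional to size
        remaining = n_genes
        for ci, (chrom, size) in enumerate(chrom_sizes.items()):
            n_c = (
                remaining
                if ci == n_chrom - 1
                else int(round(n_genes * size / L))
            )
            n_c = min(n_c, remaining)
            remaining -= n_c
            if n_c == 0:
                continue
            for start in _spread_spans(rng, size, gene_span, n_c):
                cursor = start
                ann["promoter"].append(
                    Interval(chrom, cursor, cursor + promoter_len)
                )
                cursor += promoter_len
                tss = cursor
                tss_list.append((chrom, tss))
                if u5:
                    ann["utr5"].append(Interval(chrom, cursor, cursor + u5))
                    cursor += u5
                for e in range(n_exons):
                    if exon_len:
                        ann["cds"].append(
                            Interval(chrom, cursor, cursor + exon_len)
                        )
                        cursor += exon_len
                    if e < n_introns and intron_len:
                        ann["intron"].append(
                            Interval(chrom, cursor, cursor + intron_len)
                        )
                        cursor += intron_len
                if u3:
                    ann["utr3"].append(Interval(chrom, cursor, cursor + u3))

    # --- CpG islands at TSSs ------------------------------------------ #
    cgi_len = 1200
    n_cgi = min(int(round(frac["cgi"] * L / cgi_len)), len(tss_list))
    if n_cgi > 0:
        chosen = rng.permutation(len(tss_list))[:n_cgi]
        for i in sorted(chosen):
            chrom, tss = tss_list[i]
            start = max(0, tss - 700)
            end = min(chrom_sizes[chrom], start + cgi_len)
            ann["cgi"].append(Interval(chrom, start, end))

    # --- repeats in the remaining space ------------------------------- #
    for cls, width in (("alu", 300), ("line1", 1000), ("line2", 500)):
        count = int(round(frac[cls] * L / width))
        if count:
            ann[cls] = _place_random(
                rng, chrom_sizes, lambda r, w=width: w, count
            )

    # --- DHSs: TSS-centred plus random -------------------------------- #
    n_dhs = int(round(frac["dhs"] * L / 325))
    if n_dhs > 0:
        n_tss_dhs = min(int(round(spec.dhs_tss_fraction * n_dhs)), len(tss_list))
        placed: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chrom_sizes}
        order = rng.permutation(len(tss_list))[:n_tss_dhs]
        for i in sorted(order):
            chrom, tss = tss_list[i]
            width = int(rng.integers(150, 501))
            start = max(0, tss - width // 2)
            end = min(chrom_sizes[chrom], start + width)
            placed[chrom].append((start, end))
            ann["dhs"].append(Interval(chrom, start, end))
        extra = _place_random(
            rng,
            chrom_sizes,
            lambda r: int(r.integers(150, 501)),
            n_dhs - n_tss_dhs,
            same_class=placed,
        )
        ann["dhs"].extend(extra)

    # --- sequence rewrite: CGI CpG planting, CpG thinning -------------- #
    cgi_mask = {c: np.zeros(size, dtype=bool) for c, size in chrom_sizes.items()}
    for iv in ann["cgi"]:
        cgi_mask[iv.chrom][iv.start : iv.end] = True
    repeat_mask = {c: np.zeros(size, dtype=bool) for c, size in chrom_sizes.items()}
    for cls in ("alu", "line1", "line2"):
        for iv in ann[cls]:
            repeat_mask[iv.chrom][iv.start : iv.end] = True

    for iv in ann["cgi"]:
        seq = seqs[iv.chrom]
        offs = np.arange(iv.start, iv.end - 1, 2)
        plant = offs[rng.random(len(offs)) < spec.cgi_density]
        seq[plant] = _C
        seq[plant + 1] = _G

    for chrom, seq in seqs.items():
        is_cpg = (seq[:-1] == _C) & (seq[1:] == _G)
        pos = np.nonzero(is_cpg)[0]
        outside = pos[~cgi_mask[chrom][pos]]
        keep_p = np.where(
            repeat_mask[chrom][outside], spec.cpg_keep_repeat, spec.cpg_keep_other
        )
        drop = outside[rng.random(len(outside)) >= keep_p]
        seq[drop + 1] = _A  # break the dinucleotide

    # --- CGI shores: 2 kb flanks minus CGI ----------------------------- #
    cgi_by_chrom: Dict[str, List[Interval]] = {}
    for iv in ann["cgi"]:
        cgi_by_chrom.setdefault(iv.chrom, []).append(iv)
    for iv in ann["cgi"]:
        for s, e in (
            (iv.start - 2000, iv.start),
            (iv.end, iv.end + 2000),
        ):
            s = max(0, s)
            e = min(chrom_sizes[iv.chrom], e)
            for other in cgi_by_chrom.get(iv.chrom, []):
                if other is iv:
                    continue
                if other.start < e and s < other.end:
                    if other.start <= s:
                        s = max(s, other.end)
                    else:
                        e = min(e, other.start)
            if s < e:
                ann["cgi_shore"].append(Interval(iv.chrom, s, e))

    for cls in ann:
        ann[cls].sort(key=lambda iv: (iv.chrom, iv.start))
    genome = {c: seq.tobytes().decode("ascii") for c, seq in seqs.items()}
    return genome, ann


def chrom_sizes(genome: Mapping[str, str]) -> Dict[str, int]:
    return {c: len(s) for c, s in genome.items()}


# ---------------------------------------------------------------------- #
# guide placement


def place_guides(
    genome: Mapping[str, str],
    n_guides: int,
    target_feature: str = "promoter",
    annotations: Optional[Mapping[str, Sequence[Interval]]] = None,
    within: Optional[Interval] = None,
    rng_seed: int = 0,
    name_prefix: str = "T",
    min_gap: int = 25,
) -> List[GuideRNA]:
    """Place gRNAs at N20-NGG sites inside a feature class (or interval).

    Both strands are scanned; each returned guide's protospacer is verified
    to match the genome at its recorded coordinates (reverse-complemented
    for minus-strand guides).  Raises a generation error naming the feature
    class when too few PAM sites exist.
    """
    if n_guides == 0:
        return []
    if within is not None:
        search = [within]
    else:
        if annotations is None or target_feature not in annotations:
            raise ConfigurationError(
                f"no annotation for feature class {target_feature!r}"
            )
        search = list(annotations[target_feature])
    rng = np.random.default_rng(rng_seed)
    candidates: List[Tuple[str, int, int, str]] = []  # chrom, start, end, strand
    for iv in search:
        seq = genome[iv.chrom][iv.start : iv.end]
        for m in re.finditer("(?=[ACGT]{21}GG)", seq):
            i = iv.start + m.start()
            candidates.append((iv.chrom, i, i + 20, "+"))
        for m in re.finditer("(?=CC[ACGT]{21})", seq):
            i = iv.start + m.start()
            candidates.append((iv.chrom, i + 3, i + 23, "-"))
    rng.shuffle(candidates)
    chosen: List[Tuple[str, int, int, str]] = []
    for cand in candidates:
        if len(chosen) == n_guides:
            break
        chrom, start, end, strand = cand
        if any(
            c == chrom and start < e + min_gap and s - min_gap < end
            for c, s, e, _ in chosen
        ):
            continue
        chosen.append(cand)
    if len(chosen) < n_guides:
        raise GenerationError(
            f"only {len(chosen)} usable N20-NGG sites in feature class "
            f"{target_feature!r}; requested {n_guides}"
        )
    guides = []
    for k, (chrom, start, end, strand) in enumerate(
        sorted(chosen, key=lambda c: (c[0], c[1]))
    ):
        if strand == "+":
            proto = genome[chrom][start:end]
            pam = genome[chrom][end : end + 3]
        else:
            proto = reverse_complement(genome[chrom][start:end])
            pam = reverse_complement(genome[chrom][start - 3 : start])
        guides.append(
            GuideRNA(
                name=f"{name_prefix}{k + 1}",
                protospacer=proto,
                pam=pam,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
            )
        )
    return guides


def plant_seed_matches(
    genome: Mapping[str, str],
    targets: Sequence[Interval],
    guides: Sequence[GuideRNA],
    rng_seed: int = 0,
    pad: int = 40,
) -> Dict[str, str]:
    """Write a guide seed5+TGG motif into each target interval.

    Returns a new genome with the 8-nt motifs embedded; used to guarantee
    seed–PAM matches inside chosen DHS windows.
    """
    rng = np.random.default_rng(rng_seed)
    mutable = {c: bytearray(s, "ascii") for c, s in genome.items()}
    for iv in targets:
        guide = guides[int(rng.integers(0, len(guides)))]
        motif = (guide.seed5 + "TGG").encode("ascii")
        lo = iv.start + pad
        hi = iv.end - pad - len(motif)
        if hi <= lo:
            lo, hi = iv.start, max(iv.start + 1, iv.end - len(motif))
        pos = int(rng.integers(lo, hi))
        mutable[iv.chrom][pos : pos + len(motif)] = motif
    return {c: bytes(b).decode("ascii") for c, b in mutable.items()}


# ---------------------------------------------------------------------- #
# count simulation


@dataclass
class TruthTables:
    """Every interval where a nonzero delta was injected, with its sign."""

    ontarget: List[Interval] = field(default_factory=list)
    hyper: List[Interval] = field(default_factory=list)
    hypo: List[Interval] = field(default_factory=list)

    def all_intervals(self) -> List[Interval]:
        return self.ontarget + self.hyper + self.hypo


def _class_membership(
    positions: np.ndarray, intervals: Sequence[Interval]
) -> np.ndarray:
    """Boolean membership of positions in a set of non-overlapping intervals."""
    if len(intervals) == 0 or positions.size == 0:
        return np.zeros(positions.size, dtype=bool)
    starts = np.array([iv.start for iv in intervals])
    ends = np.array([iv.end for iv in intervals])
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    idx = np.searchsorted(starts, positions, side="right") - 1
    ok = idx >= 0
    member = np.zeros(positions.size, dtype=bool)
    member[ok] = positions[ok] < ends[idx[ok]]
    return member


def _beta_binomial(
    rng: np.random.Generator, n: np.ndarray, p: np.ndarray, phi: float
) -> np.ndarray:
    """Draw M ~ BetaBinomial(n, p, phi) with Var(q) = p(1-p)*phi."""
    if phi <= 0:
        return rng.binomial(n, p)
    conc = 1.0 / phi - 1.0
    pc = np.clip(p, 1e-9, 1 - 1e-9)
    q = rng.beta(pc * conc, (1 - pc) * conc)
    return rng.binomial(n, q)


def simulate_counts(
    genome: Mapping[str, str],
    annotations: Mapping[str, Sequence[Interval]],
    guides_by_set: Mapping[str, Sequence[GuideRNA]],
    design: GroupDesign,
    effects: EffectModel,
    rng_seed: int = 0,
) -> Tuple[MethylomeTable, TruthTables]:
    """Simulate per-CpG (M, N) counts for every sample of the design.

    Off-target hyper effects are injected at every DHS containing a
    seed5–NGG match of a gRNA set's guides (plant matches beforehand with
    :func:`plant_seed_matches` to control their number); off-target hypo
    effects at a random subset of Alu/LINE1 repeats.  Returns the combined
    table plus truth tables of injected intervals whose score column
    carries the signed full-scale delta.
    """
    rng = np.random.default_rng(rng_seed)

    # CpG site list
    chroms: List[str] = []
    positions: List[np.ndarray] = []
    for chrom in genome:
        seq = np.frombuffer(genome[chrom].encode("ascii"), dtype=np.uint8)
        pos = np.nonzero((seq[:-1] == _C) & (seq[1:] == _G))[0]
        chroms.append(chrom)
        positions.append(pos)
    all_chrom = np.concatenate(
        [np.full(len(p), c, dtype=object) for c, p in zip(chroms, positions)]
    )
    all_pos = np.concatenate(positions)
    n_sites = all_pos.size

    # feature-class baselines, first matching class wins
    baseline = np.full(n_sites, effects.baseline_methylation["default"])
    assigned = np.zeros(n_sites, dtype=bool)
    priority = [
        "cgi",
        "cgi_shore",
        "promoter",
        "utr5",
        "utr3",
        "cds",
        "alu",
        "line1",
        "line2",
        "intron",
    ]
    for cls in priority:
        if cls not in effects.baseline_methylation:
            continue
        member = np.zeros(n_sites, dtype=bool)
        offset = 0
        for chrom, pos in zip(chroms, positions):
            ivs = [iv for iv in annotations.get(cls, []) if iv.chrom == chrom]
            member[offset : offset + len(pos)] = _class_membership(pos, ivs)
            offset += len(pos)
        member &= ~assigned
        baseline[member] = effects.baseline_methylation[cls]
        assigned |= member

    # per-set delta templates
    truth = TruthTables()
    set_on: Dict[str, np.ndarray] = {}
    set_hyper: Dict[str, np.ndarray] = {}
    set_hypo: Dict[str, np.ndarray] = {}
    dhs = list(annotations.get("dhs", []))
    repeats = list(annotations.get("alu", [])) + list(annotations.get("line1", []))
    repeats.sort(key=lambda iv: (iv.chrom, iv.start))
    hypo_pool = rng.permutation(len(repeats))
    hypo_cursor = 0
    flank_lo, flank_hi = effects.ontarget_flank
    for set_name, guides in guides_by_set.items():
        real = [g for g in guides if g.has_site]
        on = np.zeros(n_sites)
        interior_any = np.zeros(n_sites, dtype=bool)
        offset = 0
        for chrom, pos in zip(chroms, positions):
            for g in real:
                if g.chrom != chrom:
                    continue
                dist = np.where(
                    pos < g.start,
                    g.start - pos,
                    np.where(pos >= g.end, pos - g.end + 1, 0),
                )
                near = (dist >= 1) & (dist < flank_lo)
                full = (dist >= flank_lo) & (dist <= flank_hi)
                seg = on[offset : offset + len(pos)]
                seg[near] = np.maximum(
                    seg[near], effects.near_flank_weight * effects.ontarget_delta
                )
                seg[full] = np.maximum(seg[full], effects.ontarget_delta)
                interior_any[offset : offset + len(pos)] |= dist == 0
            offset += len(pos)
        # the bound dCas9 footprint: no deposition strictly inside any
        # protospacer of the set, even in a neighbouring guide's flank
        on[interior_any] = 0.0
        set_on[set_name] = on
        for g in real:
            truth.ontarget.append(
                Interval(
                    g.chrom,
                    max(0, g.start - flank_hi),
                    g.end + flank_hi,
                    name=f"ontarget|{set_name}|{g.name}",
                    score=effects.ontarget_delta,
                )
            )

        # hyper: DHS containing a seed-PAM match of any guide in the set;
        # the on-target locus itself is excluded (it is on-target truth)
        hyper_iv = []
        for iv in dhs:
            if any(
                g.chrom == iv.chrom
                and iv.start < g.end + flank_hi
                and g.start - flank_hi < iv.end
                for g in real
            ):
                continue
            window = genome[iv.chrom][iv.start : iv.end]
            if any(
                count_pattern_both_strands(window, g.seed5) > 0 for g in guides
            ):
                hyper_iv.append(iv)
        hyper_mask = np.zeros(n_sites, dtype=bool)
        offset = 0
        for chrom, pos in zip(chroms, positions):
            ivs = [iv for iv in hyper_iv if iv.chrom == chrom]
            hyper_mask[offset : offset + len(pos)] |= _class_membership(pos, ivs)
            offset += len(pos)
        set_hyper[set_name] = hyper_mask * effects.offtarget_hyper_delta
        truth.hyper.extend(
            replace(
                iv,
                name=f"hyper|{set_name}",
                score=effects.offtarget_hyper_delta,
            )
            for iv in hyper_iv
        )

        # hypo: disjoint random repeats per set
        take = hypo_pool[hypo_cursor : hypo_cursor + effects.n_offtarget_hypo]
        hypo_cursor += effects.n_offtarget_hypo
        hypo_iv = [repeats[i] for i in sorted(take)]
        hypo_mask = np.zeros(n_sites, dtype=bool)
        offset = 0
        for chrom, pos in zip(chroms, positions):
            ivs = [iv for iv in hypo_iv if iv.chrom == chrom]
            hypo_mask[offset : offset + len(pos)] |= _class_membership(pos, ivs)
            offset += len(pos)
        set_hypo[set_name] = hypo_mask * effects.offtarget_hypo_delta
        truth.hypo.extend(
            replace(
                iv,
                name=f"hypo|{set_name}",
                score=-effects.offtarget_hypo_delta,
            )
            for iv in hypo_iv
        )

    # draw counts per sample
    counts: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for group in design.groups:
        p = baseline.copy()
        for set_name in guides_by_set:
            p = p + set_on[set_name] * effects.ontarget_multiplier(group, set_name)
            p = p + set_hyper[set_name] * effects.offtarget_multiplier(
                group, set_name
            )
            p = p - set_hypo[set_name] * effects.offtarget_multiplier(
                group, set_name
            )
        p = np.clip(p, 0.0, 1.0)
        p_obs = p + (1.0 - p) * (1.0 - effects.conversion_rate)
        for sample in design.sample_ids(group.group_id):
            n = rng.poisson(effects.mean_depth, size=n_sites)
            m = _beta_binomial(rng, n, p_obs, effects.dispersion)
            counts[sample] = (m, n)

    table = MethylomeTable(all_chrom, all_pos, counts)
    return table, truth


def simulate_lambda(
    conversion_rate: float = 0.995,
    mean_depth: float = 30.0,
    n_cytosines: Optional[int] = None,
    genome_length: int = LAMBDA_GENOME_LENGTH,
    rng_seed: int = 0,
    sample: str = "lambda",
) -> MethylomeTable:
    """Unmethylated lambda spike-in counts for the conversion-rate estimate.

    Every cytosine is truly unmethylated; unconverted reads appear
    methylated at rate (1 - conversion_rate).
    """
    if not (0.0 < conversion_rate <= 1.0):
        raise ConfigurationError(
            f"conversion_rate must be in (0, 1], got {conversion_rate}"
        )
    rng = np.random.default_rng(rng_seed)
    if n_cytosines is None:
        n_cytosines = genome_length // 4
    pos = np.sort(
        rng.choice(genome_length, size=min(n_cytosines, genome_length), replace=False)
    )
    n = rng.poisson(mean_depth, size=pos.size)
    m = rng.binomial(n, 1.0 - conversion_rate)
    return MethylomeTable(
        np.full(pos.size, "lambda", dtype=object),
        pos,
        {sample: (m, n)},
        context=np.full(pos.size, "CHH", dtype=object),
    )


def simulate_chip_peaks(
    guides: Sequence[GuideRNA],
    genome: Mapping[str, str],
    dhs: IntervalSet,
    rng_seed: int = 0,
    fraction: float = 0.5,
    dhs_bias: float = 0.15,
    peak_halfwidth: int = 100,
    jitter: int = 20,
) -> IntervalSet:
    """Synthetic dCas9 ChIP peaks at seed–PAM matches, biased toward DHSs.

    A ``fraction`` of genome-wide seed5–NGG matches inside DHSs emit a peak
    (matches outside DHSs at ``fraction * dhs_bias``); every off-target
    peak centre lies within +-jitter bp of its match.  On-target guide
    sites always emit a peak.
    """
    rng = np.random.default_rng(rng_seed)
    peaks: List[Interval] = []
    for g in guides:
        if g.has_site:
            peaks.append(
                Interval(
                    g.chrom,
                    max(0, g.start - peak_halfwidth),
                    g.end + peak_halfwidth,
                    name=f"ontarget|{g.name}",
                )
            )
    if fraction > 0:
        for chrom, seq in genome.items():
            size = len(seq)
            for g in guides:
                seed = g.seed5
                centers = []
                for m in re.finditer(
                    "(?=" + re.escape(seed) + "[ACGT]GG)", seq
                ):
                    centers.append(m.start() + len(seed) // 2)
                rc = reverse_complement(seed + "NGG").replace("N", "[ACGT]")
                for m in re.finditer("(?=" + rc + ")", seq):
                    centers.append(m.start() + (len(seed) + 3) // 2)
                for center in centers:
                    in_dhs = bool(dhs.overlapping(chrom, center, center + 1))
                    p_keep = fraction if in_dhs else fraction * dhs_bias
                    if rng.random() >= p_keep:
                        continue
                    c = center + int(rng.integers(-jitter, jitter + 1))
                    start = max(0, c - peak_halfwidth)
                    end = min(size, c + peak_halfwidth)
                    if start < end:
                        peaks.append(
                            Interval(chrom, start, end, name=f"offtarget|{g.name}")
                        )
    return IntervalSet(peaks)


# ---------------------------------------------------------------------- #
# full-study orchestration


@dataclass
class SimulatedStudy:
    """Everything one synthetic run of the nine-group experiment produces."""

    genome: Dict[str, str]
    annotations: Dict[str, List[Interval]]
    guides: Dict[str, List[GuideRNA]]
    design: GroupDesign
    effects: EffectModel
    table: MethylomeTable
    truth: TruthTables
    lambda_table: MethylomeTable
    peaks: IntervalSet

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return chrom_sizes(self.genome)


def simulate_study(
    genome_spec: Optional[SyntheticGenomeSpec] = None,
    design: Optional[GroupDesign] = None,
    effects: Optional[EffectModel] = None,
    seed: int = 0,
    n_upa_guides: int = 5,
    n_tgfbr3_guides: int = 3,
    n_planted_offtargets: int = 40,
    planted_tss_fraction: float = 0.75,
) -> SimulatedStudy:
    """Run the full generator: genome, guides, planted off-targets, counts.

    Guides cluster at the CGI promoters of two target genes (the uPA-like
    and TGFBR3-like loci); per gRNA set, ``n_planted_offtargets`` DHS
    windows receive a planted seed–PAM match (preferentially TSS-proximal
    DHSs) and become hypermethylation off-target sites.
    """
    genome_spec = genome_spec or SyntheticGenomeSpec(rng_seed=seed)
    design = design or default_design()
    effects = effects or EffectModel()
    rng = np.random.default_rng(seed + 1)

    genome, ann = generate_genome(genome_spec)
    sizes = chrom_sizes(genome)

    # two CGI-promoter target loci
    cgis = ann["cgi"]
    if len(cgis) < 2:
        raise GenerationError("need at least two CGIs for the two target loci")
    order = rng.permutation(len(cgis))
    upa_locus, tgfbr3_locus = cgis[order[0]], cgis[order[1]]
    guides = {
        "uPA": place_guides(
            genome,
            n_upa_guides,
            within=upa_locus,
            rng_seed=seed + 2,
            name_prefix="uPA-T",
        ),
        "TGFBR3": place_guides(
            genome,
            n_tgfbr3_guides,
            within=tgfbr3_locus,
            rng_seed=seed + 3,
            name_prefix="TGFBR3-T",
        ),
    }

    # plant seed matches into DHSs (disjoint between sets, TSS-preferential)
    dhs = ann["dhs"]
    promoter_set = IntervalSet(ann["promoter"] + ann["utr5"])
    tss_dhs = [i for i, iv in enumerate(dhs) if promoter_set.overlaps_any(iv)]
    other_dhs = [i for i in range(len(dhs)) if i not in set(tss_dhs)]
    rng.shuffle(tss_dhs)
    rng.shuffle(other_dhs)
    cursor_tss = cursor_other = 0
    planted_genome = genome
    for k, set_name in enumerate(guides):
        n_tss = int(round(planted_tss_fraction * n_planted_offtargets))
        picks = tss_dhs[cursor_tss : cursor_tss + n_tss]
        cursor_tss += n_tss
        n_other = n_planted_offtargets - len(picks)
        picks += other_dhs[cursor_other : cursor_other + n_other]
        cursor_other += n_other
        targets = [dhs[i] for i in picks]
        planted_genome = plant_seed_matches(
            planted_genome, targets, guides[set_name], rng_seed=seed + 10 + k
        )
    genome = planted_genome

    table, truth = simulate_counts(
        genome, ann, guides, design, effects, rng_seed=seed + 20
    )
    lambda_table = simulate_lambda(
        conversion_rate=effects.conversion_rate,
        mean_depth=effects.mean_depth,
        rng_seed=seed + 21,
    )
    peaks = simulate_chip_peaks(
        guides["uPA"], genome, IntervalSet(dhs), rng_seed=seed + 22
    )
    return SimulatedStudy(
        genome=genome,
        annotations=ann,
        guides=guides,
        design=design,
        effects=effects,
        table=table,
        truth=truth,
        lambda_table=lambda_table,
        peaks=peaks,
    )
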