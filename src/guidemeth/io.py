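"""Standard-format readers and writers.

BED is native (0-based, half-open).  One-based inputs (supplementary-style
DMR tables) are converted at the boundary and the conversion logged.
Malformed lines are rejected with the file name and line number.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dmr import DMR
from .errors import ParseError
from .intervals import Interval
from .methylation import MethylomeTable

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

COUNT_COLUMNS = ["chrom", "pos", "strand", "context", "M", "N"]


# ---------------------------------------------------------------------- #
# FASTA


def read_fasta(path: PathLike) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path: PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------- #
# BED


def read_bed(path: PathLike) -> List[Interval]:
    """Read BED3/BED6(+); extra columns beyond 6 are ignored."""
    intervals: List[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from exc
            if end <= start:
                raise ParseError(
                    f"{path}:{lineno}: end {end} <= start {start}"
                )
            name = fields[3] if len(fields) > 3 else "."
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(Interval(fields[0], start, end, name, score, strand))
    return intervals


def write_bed(intervals: Iterable[Interval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                f"{iv.score:g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------- #
# count tables


def write_counts(table: MethylomeTable, out_dir: PathLike) -> List[Path]:
    """One TSV per sample: chrom, pos, strand, context, M, N."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sample in table.samples:
        path = out_dir / f"{sample}.counts.tsv"
        table.to_frame(sample).to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


def _validate_count_frame(df: pd.DataFrame, path: PathLike) -> None:
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    bad = df.index[(df["M"] > df["N"]) | (df["M"] < 0) | (df["N"] < 0)]
    if len(bad):
        # +2: one for the header line, one for 1-based line numbering
        raise ParseError(
            f"{path}:{int(bad[0]) + 2}: M > N or negative count "
            f"(M={df.loc[bad[0], 'M']}, N={df.loc[bad[0], 'N']})"
        )


def read_counts(paths: Mapping[str, PathLike]) -> MethylomeTable:
    """Read per-sample count TSVs ({sample: path}) into one table."""
    frames = {}
    for sample, path in paths.items():
        try:
            df = pd.read_csv(path, sep="\t")
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
        _validate_count_frame(df, path)
        frames[sample] = df
    return MethylomeTable.from_frames(frames)


def read_bedgraph_counts(path: PathLike, sample: str) -> MethylomeTable:
    """Import a bedGraph-dialect methylation file.

    Expected columns (no header): chrom, start, end, percent_methylation,
    M, N.  The site position is the interval start (the forward-strand C).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
                m, n = int(fields[4]), int(fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field") from exc
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start")
            if m > n or m < 0:
                raise ParseError(f"{path}:{lineno}: M > N")
            rows.append((fields[0], start, "+", "CpG", m, n))
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    return MethylomeTable.from_frames({sample: df})


# ---------------------------------------------------------------------- #
# DMR tables


def write_dmrs(dmrs: Sequence[DMR], path: PathLike, fmt: str = "tsv") -> None:
    from .dmr import dmrs_to_frame

    df = dmrs_to_frame(dmrs)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "bed":
        with open(path, "w") as fh:
            for _, r in df.iterrows():
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r['name']}\t"
                    f"{r.area_stat:g}\t{r.direction}\t{r.n_cpg}\t"
                    f"{r.mean_delta:g}\t{r.p_min:g}\n"
                )
    else:
        raise ValueError(f"unknown DMR format {fmt!r}")


def read_dmr_table(
    path: PathLike, one_based: bool = False, direction: Optional[str] = None
) -> List[DMR]:
    """Parse a DMR table into records.

    Accepts this package's TSV output and supplementary-style tables with
    (chrom, start, end, length, nCpG, meanMethyl...) column layouts; column
    names are matched case-insensitively.  ``one_based=True`` converts
    1-based inclusive starts to 0-based half-open (logged).
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}

    def pick(*names, required=True):
        for n in names:
            if n in cols:
                return cols[n]
        if required:
            raise ParseError(f"{path}: none of the columns {names} found")
        return None

    chrom_c = pick("chrom", "chr", "chromosome")
    start_c = pick("start", "dmr_start")
    end_c = pick("end", "stop", "dmr_end")
    ncpg_c = pick("n_cpg", "ncpg", "cpg_sites", "ncg", required=False)
    delta_c = pick("mean_delta", "meandelta", "delta", "diff.methy", required=False)
    dir_c = pick("direction", required=False)
    p_c = pick("p_min", "p", "pval", required=False)
    if one_based:
        logger.info("%s: converting 1-based inclusive coordinates", path)
    out: List[DMR] = []
    for i, row in df.iterrows():
        start = int(row[start_c]) - (1 if one_based else 0)
        end = int(row[end_c])
        if end <= start:
            raise ParseError(f"{path}: row {i}: end <= start")
        delta = float(row[delta_c]) if delta_c else 0.0
        if dir_c:
            direc = str(row[dir_c])
        elif direction:
            direc = direction
        else:
            direc = "hyper" if delta >= 0 else "hypo"
        out.append(
            DMR(
                chrom=str(row[chrom_c]),
                start=start,
                end=end,
                direction=direc,
                n_cpg=int(row[ncpg_c]) if ncpg_c else 0,
                mean_delta=delta,
                p_min=float(row[p_c]) if p_c else float("nan"),
                area_stat=0.0,
            )
        )
    return out


# ---------------------------------------------------------------------- #
# config


def read_config(path: PathLike) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config root must be a mapping")
    return cfg


def write_config(cfg: Mapping, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=False)
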