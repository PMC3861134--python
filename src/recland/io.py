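"""Readers/writers for the plain-text formats used throughout the package.

Formats
-------
* genetic map TSV: columns ``chromosome  position  rate`` (1-based positions,
  cM/Mb rates; the rate on the last boundary row of a chromosome is ignored,
  conventionally written as 0),
* BED for intervals (0-based half-open, optional name/score/strand),
* FASTA via Biopython,
* chromosome-lengths TSV: ``chromosome  length``,
* SNP table TSV ("VCF-lite"): ``chrom  pos  allele1  allele2  outgroup
  left  right`` with 1-based positions.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from recland.errors import EmptyInputError, MapFormatError
from recland.genetic_map import GeneticMap, Hotspot
from recland.intervals import Interval, IntervalSet

PathLike = Union[str, Path]

MAP_COLUMNS = ("chromosome", "position", "rate")


def read_genetic_map(path: PathLike) -> Dict[str, GeneticMap]:
    """Read a genetic-map TSV into one :class:`GeneticMap` per chromosome."""
    df = pd.read_csv(path, sep="\t")
    missing = set(MAP_COLUMNS) - set(df.columns)
    if missing:
        raise MapFormatError(f"map file missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise MapFormatError("empty genetic map file")
    maps: Dict[str, GeneticMap] = {}
    for chrom, grp in df.groupby("chromosome", sort=False):
        pos = grp["position"].to_numpy(dtype=np.int64)
        rate = grp["rate"].to_numpy(dtype=float)
        if len(pos) < 2:
            raise MapFormatError(f"{chrom}: needs at least two boundary rows")
        if np.any(np.diff(pos) <= 0):
            raise MapFormatError(f"{chrom}: positions must be strictly ascending")
        if np.any(rate[:-1] < 0):
            raise ValueError(f"{chrom}: negative recombination rate")
        maps[str(chrom)] = GeneticMap(str(chrom), pos, rate[:-1])
    return maps


def write_genetic_map(maps: Mapping[str, GeneticMap], path: PathLike) -> None:
    rows = []
    for chrom in maps:
        m = maps[chrom]
        rates = np.concatenate([m.rates, [0.0]])
        for p, r in zip(m.boundaries, rates):
            rows.append((chrom, int(p), float(r)))
    pd.DataFrame(rows, columns=list(MAP_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_bed(path: PathLike, label: str = "") -> IntervalSet:
    intervals: List[Interval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            strand = parts[5] if len(parts) > 5 else "."
            intervals.append(Interval(chrom, start, end, name=name, strand=strand))
    return IntervalSet(intervals, label=label or Path(path).stem)


def write_bed(intervals: Iterable[Interval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand != ".":
                fields += [iv.name or ".", "0", iv.strand]
            fh.write("\t".join(fields) + "\n")


def write_hotspots_bed(hotspots: Sequence[Hotspot], path: PathLike) -> None:
    """BED6 with peak rate as score (4 decimals) and class as name."""
    with open(path, "w") as fh:
        for h in hotspots:
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{h.strength_class or '.'}\t"
                f"{h.peak_rate:.4f}\t.\n"
            )


def read_fasta(path: PathLike) -> Dict[str, str]:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise EmptyInputError(f"no sequences in {path}")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: PathLike, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_chrom_lengths(path: PathLike) -> Dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chromosome", "length"])
    return dict(zip(df["chromosome"].astype(str), df["length"].astype(int)))


def write_chrom_lengths(lengths: Mapping[str, int], path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in lengths.items():
            fh.write(f"{chrom}\t{int(length)}\n")


SNP_COLUMNS = ("chrom", "pos", "allele1", "allele2", "outgroup", "left", "right")


def read_snp_table(path: PathLike) -> pd.DataFrame:
    """Read a VCF-lite SNP TSV; on-disk positions are 1-based, in-memory 0-based."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SNP_COLUMNS) - set(df.columns)
    if missing:
        raise MapFormatError(f"SNP table missing columns: {sorted(missing)}")
    df = df.copy()
    df["pos"] = df["pos"].astype(np.int64) - 1
    return df


def write_snp_table(df: pd.DataFrame, path: PathLike) -> None:
    out = df.copy()
    out["pos"] = out["pos"].astype(np.int64) + 1
    out.to_csv(path, sep="\t", index=False, columns=list(SNP_COLUMNS))
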