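"""Genome recruitment: ambiguity filtering, windowed coverage and the
expression-ratio statistic.

Reads recruited onto a panel of reference genomes are first disambiguated
(reads whose best and second-best genome differ by less than 5% in bit
score are discarded), then summarized as mean per-base depth over
non-overlapping 300-bp windows.  The expression-ratio of a window is the
library-size-normalized RNA coverage over the library-size-normalized DNA
coverage — a per-window measure of transcriptional enrichment over gene
copy number.  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnnotatedGenome",
    "Gene",
    "RecruitmentHit",
    "RecruitedRead",
    "disambiguate",
    "window_coverage",
    "expression_ratio",
    "gene_ratio",
]


@dataclass(frozen=True)
class Gene:
    gene_id: str
    start: int
    end: int
    strand: str = "+"
    product: str = ""

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad gene interval {self.gene_id!r}")


@dataclass(frozen=True)
class AnnotatedGenome:
    genome_id: str
    length: int
    genes: tuple[Gene, ...] = ()

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("gene ids must be unique")
        for g in self.genes:
            if g.end > self.length:
                raise ValueError(f"gene {g.gene_id!r} exceeds genome length")


@dataclass(frozen=True)
class RecruitmentHit:
    """One read-vs-genome alignment candidate prior to disambiguation."""

    read_id: str
    genome_id: str
    start: int
    end: int
    bit_score: float
    molecule: str = "DNA"
    sample_id: str = ""


@dataclass(frozen=True)
class RecruitedRead:
    read_id: str
    genome_id: str
    start: int
    end: int
    bit_score: float
    molecule: str = "DNA"
    sample_id: str = ""


def disambiguate(
    hits: Iterable[RecruitmentHit], rel_margin: float = 0.05
) -> tuple[list[RecruitedRead], list[str]]:
    """Resolve reads hitting several genomes into non-overlapping sets.

    For each read, the best hit per genome is kept; if the read hits two or
    more genomes and (best - second) / best < ``rel_margin`` the read is
    discarded as ambiguous, otherwise it is assigned to its best genome.
    Returns (recruited reads, discarded read ids); every input read appears
    in exactly one of the two.
    """
    per_read: dict[str, dict[str, RecruitmentHit]] = {}
    for h in hits:
        genomes = per_read.setdefault(h.read_id, {})
        if h.genome_id not in genomes or h.bit_score > genomes[h.genome_id].bit_score:
            genomes[h.genome_id] = h
    recruited, discarded = [], []
    for read_id in sorted(per_read):
        best_per_genome = sorted(
            per_read[read_id].values(), key=lambda h: (-h.bit_score, h.genome_id)
        )
        best = best_per_genome[0]
        if len(best_per_genome) >= 2:
            second = best_per_genome[1]
            if (best.bit_score - second.bit_score) / best.bit_score < rel_margin:
                discarded.append(read_id)
                continue
        recruited.append(
            RecruitedRead(
                read_id=best.read_id,
                genome_id=best.genome_id,
                start=best.start,
                end=best.end,
                bit_score=best.bit_score,
                molecule=best.molecule,
                sample_id=best.sample_id,
            )
        )
    return recruited, discarded


def window_coverage(
    reads: Iterable[RecruitedRead], genome: AnnotatedGenome, window: int = 300
) -> pd.DataFrame:
    """Mean per-base depth over non-overlapping windows.

    depth(window) = sum of read-window overlap lengths / window width.  The
    final window is shortened to the genome end and uses its true width, so
    sum(depth * width) over windows equals the total recruited bases
    (coverage conservation).
    """
    if window <= 0:
        raise ValueError("window width must be positive")
    n_windows = (genome.length + window - 1) // window
    starts = np.arange(n_windows) * window
    ends = np.minimum(starts + window, genome.length)
    overlap = np.zeros(n_windows, dtype=float)
    for r in reads:
        if r.genome_id != genome.genome_id:
            continue
        if not 0 <= r.start < r.end <= genome.length:
            raise ValueError(f"read {r.read_id!r} outside genome {genome.genome_id!r}")
        first = r.start // window
        last = (r.end - 1) // window
        for w in range(first, last + 1):
            overlap[w] += min(r.end, ends[w]) - max(r.start, starts[w])
    return pd.DataFrame(
        {
            "genome_id": genome.genome_id,
            "window_index": np.arange(n_windows),
            "start": starts,
            "end": ends,
            "depth": overlap / (ends - starts),
        }
    )


def expression_ratio(
    rna_windows: pd.DataFrame,
    dna_windows: pd.DataFrame,
    rna_lib_size: float,
    dna_lib_size: float,
    pseudocount: float | None = None,
    size_correction: float = 1.0,
) -> pd.DataFrame:
    """Per-window expression-ratio track.

    ratio_w = (rna_depth_w / rna_lib_size) / (dna_depth_w / dna_lib_size),
    each library normalized by its total protein-coding hit count.  Windows
    with zero DNA coverage are flagged undefined by default, or stabilized
    by adding ``pseudocount`` to both depths.  ``size_correction`` is an
    optional extra scalar for strict replication of workflows that applied
    a separate library-size correction on top of the normalization.
    """
    if rna_lib_size <= 0 or dna_lib_size <= 0:
        raise ValueError("library sizes must be positive")
    if not np.array_equal(rna_windows["start"].to_numpy(), dna_windows["start"].to_numpy()):
        raise ValueError("RNA and DNA window grids differ")
    rna = rna_windows["depth"].to_numpy(dtype=float)
    dna = dna_windows["depth"].to_numpy(dtype=float)
    if pseudocount is not None:
        rna = rna + pseudocount
        dna = dna + pseudocount
    undefined = dna == 0
    ratio = np.full(rna.shape, np.nan)
    np.divide(rna / rna_lib_size, dna / dna_lib_size, out=ratio, where=~undefined)
    ratio *= size_correction
    with np.errstate(divide="ignore"):
        log10 = np.where(undefined, np.nan, np.log10(np.where(ratio > 0, ratio, np.nan)))
    out = rna_windows[["genome_id", "window_index", "start", "end"]].copy()
    out["rna_depth"] = rna_windows["depth"].to_numpy()
    out["dna_depth"] = dna_windows["depth"].to_numpy()
    out["ratio"] = ratio
    out["log10_ratio"] = log10
    out["undefined"] = undefined
    return out


def gene_ratio(track: pd.DataFrame, genes: Sequence[Gene]) -> pd.DataFrame:
    """Mean expression-ratio per gene, weighted by window overlap length.

    Only windows with a defined ratio contribute; a gene covered by no
    defined window is reported with a NaN ratio.
    """
    starts = track["start"].to_numpy()
    ends = track["end"].to_numpy()
    ratios = track["ratio"].to_numpy(dtype=float)
    defined = ~track["undefined"].to_numpy(dtype=bool)
    rows = []
    for g in genes:
        mask = (starts < g.end) & (ends > g.start) & defined
        if mask.any():
            w = np.minimum(ends[mask], g.end) - np.maximum(starts[mask], g.start)
            value = float(np.average(ratios[mask], weights=w))
        else:
            value = np.nan
        rows.append({"gene_id": g.gene_id, "start": g.start, "end": g.end, "ratio": value})
    return pd.DataFrame(rows, columns=["gene_id", "start", "end", "ratio"])
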