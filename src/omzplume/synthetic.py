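"""Synthetic data with known ground truth for every downstream stage.

Four generators emulate the inputs of a sulfidic oxygen-minimum-zone study:

* a ranked reference taxonomy with per-rank sequence divergence (stands in
  for a curated rRNA reference database),
* depth-stratified community read sets (DNA reads from whole genomes, RNA
  reads from annotated gene intervals with per-gene transcription
  multipliers), with a provenance sidecar recording the truth per read,
* piecewise-linear CTD-style depth profiles with additive Gaussian noise,
* isotope-incubation time series with a known production slope.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
spec + seed yields identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .taxonomy import TaxonomyNode, TaxonomyTree

__all__ = [
    "TaxonomySpec",
    "CommunitySpec",
    "ProfileSpec",
    "IncubationSpec",
    "GeneInterval",
    "SequenceRecord",
    "IncubationSeries",
    "make_reference_taxonomy",
    "simulate_reads",
    "simulate_profile",
    "simulate_incubation",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SequenceRecord:
    """A read (or reference fragment) with its sample context."""

    id: str
    sample_id: str
    depth: float
    molecule: str  # "DNA" | "RNA"
    bases: str

    def __post_init__(self):
        if not self.bases:
            raise ValueError("empty sequence")
        if self.molecule not in ("DNA", "RNA"):
            raise ValueError(f"molecule must be DNA or RNA, got {self.molecule!r}")
        if set(self.bases) - set("ACGTN"):
            raise ValueError(f"invalid bases in record {self.id!r}")


@dataclass(frozen=True)
class GeneInterval:
    """0-based half-open gene interval on a reference sequence."""

    gene_id: str
    taxon: str
    start: int
    end: int

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad gene interval {self.gene_id!r}: [{self.start}, {self.end})")


@dataclass(frozen=True)
class TaxonomySpec:
    ranks: tuple[str, ...] = ("phylum", "genus", "species")
    children_per_rank: tuple[int, ...] = (2, 2, 2)
    divergence_per_rank: tuple[float, ...] = (0.10, 0.05, 0.01)
    seq_length: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not self.ranks:
            raise ValueError("ranks must be non-empty")
        if len(self.children_per_rank) != len(self.ranks):
            raise ValueError("children_per_rank must match ranks")
        if len(self.divergence_per_rank) != len(self.ranks):
            raise ValueError("divergence_per_rank must match ranks")
        if any(c <= 0 for c in self.children_per_rank):
            raise ValueError("children_per_rank must be positive")
        if any(not (0 <= d < 0.5) for d in self.divergence_per_rank):
            raise ValueError("divergence_per_rank values must lie in [0, 0.5)")
        if self.seq_length <= 0:
            raise ValueError("seq_length must be positive")


@dataclass(frozen=True)
class CommunitySpec:
    """Depth-stratified community with known abundances and transcription."""

    abundances: Mapping[str, float]  # taxon -> fraction, summing to 1
    multipliers: Mapping[str, float] = field(default_factory=dict)  # gene -> x
    n_reads_dna: int = 1000
    n_reads_rna: int = 1000
    read_length_mean: float = 150.0
    read_length_sd: float = 30.0
    error_rate: float = 0.0
    sample_id: str = "S1"
    depth: float = 0.0
    seed: int = 0

    def __post_init__(self):
        total = sum(self.abundances.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1 (got {total})")
        if any(m <= 0 for m in self.multipliers.values()):
            raise ValueError("transcription multipliers must be positive")
        if not 0.0 <= self.error_rate <= 0.2:
            raise ValueError("error_rate must lie in [0, 0.2]")
        if self.n_reads_dna < 0 or self.n_reads_rna < 0:
            raise ValueError("read counts must be non-negative")


@dataclass(frozen=True)
class ProfileSpec:
    """Piecewise-linear property-vs-depth curves plus Gaussian noise."""

    breakpoints: Mapping[str, Sequence[tuple[float, float]]]  # prop -> [(depth m, value)]
    noise_sd: Mapping[str, float] = field(default_factory=dict)
    grid_spacing: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not self.breakpoints:
            raise ValueError("at least one property is required")
        for prop, pts in self.breakpoints.items():
            depths = [d for d, _ in pts]
            if len(depths) < 2:
                raise ValueError(f"{prop}: need at least two breakpoints")
            if any(b <= a for a, b in zip(depths, depths[1:])):
                raise ValueError(f"{prop}: breakpoint depths must be strictly increasing")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")


@dataclass(frozen=True)
class IncubationSpec:
    """A labelled-substrate time course with known production slope.

    ``true_slope`` is in nmol l-1 d-1, timepoints in hours (the field-standard
    sampling design is 0, 6, 12, 24 and 48 h).
    """

    true_slope: float = 10.0
    intercept: float = 0.0
    timepoints: tuple[float, ...] = (0.0, 6.0, 12.0, 24.0, 48.0)
    noise_sd: float = 0.0
    label_fraction: float = 1.0
    product_species: str = "29N2"
    amendment: float = 10.0  # µmol l-1 of labelled substrate added
    depth: float = 0.0
    experiment_id: str = "inc"
    seed: int = 0

    def __post_init__(self):
        if len(self.timepoints) < 3:
            raise ValueError("need at least 3 timepoints for a slope t-test")
        if any(t < 0 for t in self.timepoints):
            raise ValueError("timepoints must be non-negative")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if not 0.0 < self.label_fraction <= 1.0:
            raise ValueError("label_fraction must lie in (0, 1]")
        if self.product_species not in ("29N2", "30N2", "15NO2", "15NH4"):
            raise ValueError(f"unknown product species {self.product_species!r}")


@dataclass(frozen=True)
class IncubationSeries:
    """Observed product concentrations (nmol l-1) over time (hours)."""

    experiment_id: str
    depth: float
    product_species: str
    label_fraction: float
    amendment: float
    timepoints: tuple[float, ...]
    concentrations: tuple[float, ...]
    true_slope: float | None = None  # ground truth when simulated

    def __post_init__(self):
        if len(self.timepoints) != len(self.concentrations):
            raise ValueError("timepoints and concentrations differ in length")
        if len(self.timepoints) < 3:
            raise ValueError("need at least 3 timepoints")
        if not 0.0 < self.label_fraction <= 1.0:
            raise ValueError("label_fraction must lie in (0, 1]")


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with probability ``p`` (always to a different base)."""
    if p <= 0:
        return seq.copy()
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < p)
    if hit.size:
        # shift by 1..3 positions in base order -> guaranteed different base
        idx = np.searchsorted(_BASES, out[hit])
        shift = rng.integers(1, 4, size=hit.size)
        out[hit] = _BASES[(idx + shift) % 4]
    return out


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def make_reference_taxonomy(spec: TaxonomySpec) -> tuple[TaxonomyTree, dict[str, str]]:
    """Grow a ranked taxonomy and one reference sequence per leaf.

    The root sequence is i.i.d. uniform over ACGT; each child mutates its
    parent's sequence independently with the per-rank substitution
    probability, so sequence identity decays with taxonomic distance.
    """
    rng = np.random.default_rng(spec.seed)
    root_seq = _BASES[rng.integers(0, 4, size=spec.seq_length)]
    nodes = [TaxonomyNode(id="root", name="root", rank="root", parent_id=None)]
    references: dict[str, str] = {}

    frontier = [("root", root_seq)]
    for level, (rank, n_children, div) in enumerate(
        zip(spec.ranks, spec.children_per_rank, spec.divergence_per_rank)
    ):
        nxt = []
        for parent_id, parent_seq in frontier:
            for i in range(n_children):
                nid = f"{parent_id}.{i}" if parent_id != "root" else f"t{i}"
                seq = _mutate(parent_seq, div, rng)
                nodes.append(TaxonomyNode(id=nid, name=nid, rank=rank, parent_id=parent_id))
                nxt.append((nid, seq))
        frontier = nxt
    for leaf_id, seq in frontier:
        references[leaf_id] = _decode(seq)
    return TaxonomyTree(nodes), references


def _draw_lengths(
    n: int, mean: float, sd: float, upper: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Normal read lengths truncated to [50, upper] (upper per read)."""
    lengths = np.rint(rng.normal(mean, sd, size=n)).astype(int)
    return np.clip(lengths, np.minimum(50, upper), upper)


def simulate_reads(
    community: CommunitySpec,
    references: Mapping[str, str],
    genes: Mapping[str, Sequence[GeneInterval]] | None = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Draw DNA and RNA reads with recorded provenance.

    DNA reads are drawn from whole reference sequences with probability
    proportional to taxon abundance.  RNA reads are drawn only from annotated
    gene intervals, with probability proportional to abundance x per-gene
    transcription multiplier.  Start positions are uniform; per-base
    substitution errors are applied at ``error_rate``.

    Returns the reads and a provenance table (read_id, molecule, taxon,
    gene_id, start, end) with one row per emitted read.
    """
    rng = np.random.default_rng(community.seed)
    taxa = sorted(community.abundances)
    missing = [t for t in taxa if t not in references]
    if missing:
        raise ValueError(f"abundances reference unknown taxa: {missing}")
    enc = {t: np.frombuffer(references[t].encode("ascii"), dtype=np.uint8) for t in references}

    records: list[SequenceRecord] = []
    prov: list[dict] = []

    def emit(i: int, molecule: str, taxon: str, gene_id: str, start: int, length: int):
        seq = enc[taxon][start : start + length]
        seq = _mutate(seq, community.error_rate, rng) if community.error_rate > 0 else seq
        rid = f"{community.sample_id}_{molecule.lower()}_{i}"
        records.append(
            SequenceRecord(
                id=rid,
                sample_id=community.sample_id,
                depth=community.depth,
                molecule=molecule,
                bases=_decode(seq),
            )
        )
        prov.append(
            {
                "read_id": rid,
                "molecule": molecule,
                "taxon": taxon,
                "gene_id": gene_id,
                "start": start,
                "end": start + length,
            }
        )

    # ---- DNA: genome-wide, abundance-weighted --------------------------
    if community.n_reads_dna > 0:
        probs = np.array([community.abundances[t] for t in taxa])
        choice = rng.choice(len(taxa), size=community.n_reads_dna, p=probs / probs.sum())
        ref_len = np.array([enc[t].size for t in taxa])
        upper = ref_len[choice]
        lengths = _draw_lengths(
            community.n_reads_dna, community.read_length_mean, community.read_length_sd, upper, rng
        )
        starts = rng.integers(0, upper - lengths + 1)
        for i in range(community.n_reads_dna):
            emit(i, "DNA", taxa[choice[i]], "", int(starts[i]), int(lengths[i]))

    # ---- RNA: gene intervals, abundance x multiplier -------------------
    if community.n_reads_rna > 0:
        if not genes:
            raise ValueError("RNA reads requested but no gene annotation supplied")
        pool: list[GeneInterval] = []
        weights: list[float] = []
        for taxon in taxa:
            for gene in genes.get(taxon, ()):
                if gene.end > enc[taxon].size:
                    raise ValueError(f"gene {gene.gene_id!r} exceeds reference {taxon!r}")
                pool.append(gene)
                weights.append(
                    community.abundances[taxon] * community.multipliers.get(gene.gene_id, 1.0)
                )
        if not pool:
            raise ValueError("no gene intervals on taxa with non-zero abundance")
        w = np.asarray(weights, dtype=float)
        choice = rng.choice(len(pool), size=community.n_reads_rna, p=w / w.sum())
        gene_len = np.array([g.end - g.start for g in pool])
        upper = gene_len[choice]
        lengths = _draw_lengths(
            community.n_reads_rna, community.read_length_mean, community.read_length_sd, upper, rng
        )
        for i in range(community.n_reads_rna):
            gene = pool[choice[i]]
            length = int(lengths[i])
            start = gene.start + int(rng.integers(0, gene.end - gene.start - length + 1))
            emit(i, "RNA", gene.taxon, gene.gene_id, start, length)

    columns = ["read_id", "molecule", "taxon", "gene_id", "start", "end"]
    return records, pd.DataFrame(prov, columns=columns)


def simulate_profile(spec: ProfileSpec) -> pd.DataFrame:
    """Sample piecewise-linear depth profiles on a regular grid.

    The grid spans the depth range common to all properties (values are never
    extrapolated outside a property's breakpoints).  With ``noise_sd = 0`` the
    output is exactly piecewise-linear; noisy values are clipped at zero
    (concentrations are non-negative).
    """
    rng = np.random.default_rng(spec.seed)
    top = max(pts[0][0] for pts in spec.breakpoints.values())
    bottom = min(pts[-1][0] for pts in spec.breakpoints.values())
    if bottom <= top:
        raise ValueError("properties have no common depth range")
    n = int(np.floor((bottom - top) / spec.grid_spacing + 1e-9)) + 1
    depth = top + spec.grid_spacing * np.arange(n)
    out = {"depth": depth}
    for prop in spec.breakpoints:
        pts = spec.breakpoints[prop]
        xs = np.array([d for d, _ in pts])
        ys = np.array([v for _, v in pts])
        vals = np.interp(depth, xs, ys)
        sd = spec.noise_sd.get(prop, 0.0)
        if sd > 0:
            vals = np.clip(vals + rng.normal(0.0, sd, size=vals.size), 0.0, None)
        out[prop] = vals
    return pd.DataFrame(out)


def simulate_incubation(spec: IncubationSpec) -> IncubationSeries:
    """Simulate product accumulation: c(t) = intercept + slope * t/24 + noise."""
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.timepoints, dtype=float)
    conc = spec.intercept + spec.true_slope * t / 24.0
    if spec.noise_sd > 0:
        conc = np.clip(conc + rng.normal(0.0, spec.noise_sd, size=t.size), 0.0, None)
    return IncubationSeries(
        experiment_id=spec.experiment_id,
        depth=spec.depth,
        product_species=spec.product_species,
        label_fraction=spec.label_fraction,
        amendment=spec.amendment,
        timepoints=tuple(float(x) for x in t),
        concentrations=tuple(float(x) for x in conc),
        true_slope=spec.true_slope,
    )
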