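"""Read annotation: toy similarity search, greedy clustering, rRNA
partitioning, LCA taxonomic assignment and threshold calibration.

The pipeline mirrors a pyrosequencing-era metagenome workflow: reads are
collapsed at 98% identity (CD-HIT convention: matching columns over the
length of the shorter sequence, word length 8), rRNA-like sequences are
split off at a reference-database bit-score cutoff of 86, and the remainder
is placed on a taxonomy by a MEGAN-style LCA with a 10% score range and a
minimum support of 5.  The cutoff itself can be re-derived with the
fragmentation/threshold-sweep calibration simulation.

The built-in ``search`` is a deliberately small k-mer-seeded, ungapped
local aligner so the pipeline is self-contained on synthetic data; BLAST
outfmt-6 tables from an external aligner are equally accepted (see
:mod:`omzplume.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .synthetic import SequenceRecord
from .taxonomy import TaxonomyTree

__all__ = [
    "Scoring",
    "SimilarityHit",
    "SequenceCluster",
    "TaxonAssignment",
    "CalibrationCurve",
    "UNASSIGNED",
    "search",
    "greedy_cluster",
    "partition_rrna",
    "lca_assign",
    "build_taxonomic_profile",
    "fragment_reference_db",
    "threshold_sweep",
]

UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class Scoring:
    """Ungapped nucleotide scoring with classic BLASTn statistics.

    Defaults (+2/-3, lambda = 0.625, K = 0.41) are the textbook values for
    ungapped nucleotide alignment; they are declared here so hits produced
    by the toy search are distinguishable from imported external tables.
    """

    match: int = 2
    mismatch: int = -3
    lam: float = 0.625
    k: float = 0.41

    def bit_score(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.k)) / math.log(2.0)


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    bit_score: float
    percent_identity: float
    alignment_length: int
    subject_taxon: str | None = None

    def __post_init__(self):
        if not math.isfinite(self.bit_score):
            raise ValueError("bit_score must be finite")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity must lie in [0, 100]")
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")


@dataclass
class SequenceCluster:
    representative_id: str
    member_ids: list[str]

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class TaxonAssignment:
    query_id: str
    taxon: str  # node id or UNASSIGNED
    support: int  # hits retained in the score window


def _encode_query(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    arr[arr == ord("N")] = 0  # query Ns never match subject Ns (encoded 255)
    return arr


def _encode_subject(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    arr[arr == ord("N")] = 255
    return arr


def _best_on_diagonal(
    q: np.ndarray, s: np.ndarray, diag: int, scoring: Scoring
) -> tuple[float, int, int] | None:
    """Best-scoring ungapped local segment on one diagonal.

    Returns (raw score, matches, length) via a max-subarray over the
    match/mismatch score vector (prefix sums with a running minimum).
    """
    a = max(0, -diag)
    b = min(q.size, s.size - diag)
    if b - a < 1:
        return None
    m = q[a:b] == s[a + diag : b + diag]
    sc = np.where(m, float(scoring.match), float(scoring.mismatch))
    prefix = np.concatenate(([0.0], np.cumsum(sc)))
    running_min = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - running_min
    j = int(np.argmax(gains))
    score = float(gains[j])
    if score <= 0:
        return None
    i = int(np.argmin(prefix[: j + 1]))
    matches = int(m[i : j + 1].sum())
    return score, matches, j + 1 - i


def search(
    queries: Iterable[SequenceRecord],
    subjects: Mapping[str, str],
    subject_taxa: Mapping[str, str] | None = None,
    scoring: Scoring = Scoring(),
    word_length: int = 11,
    min_raw_score: int = 40,
) -> list[SimilarityHit]:
    """k-mer-seeded, ungapped local search of reads against references.

    For every query, each (subject, diagonal) pair reached by a shared
    ``word_length``-mer is extended once to the best-scoring ungapped
    segment; the best segment per subject above ``min_raw_score`` is
    reported.  Hits are ordered best-first per query, ties broken by
    ascending subject id.  Queries shorter than the seed length produce no
    hits.
    """
    if not subjects:
        raise ValueError("subjects must be non-empty")
    subject_ids = sorted(subjects)
    enc = [_encode_subject(subjects[sid]) for sid in subject_ids]

    index: dict[bytes, list[tuple[int, int]]] = {}
    for si, arr in enumerate(enc):
        data = arr.tobytes()
        for pos in range(arr.size - word_length + 1):
            word = data[pos : pos + word_length]
            if 255 in word:
                continue
            index.setdefault(word, []).append((si, pos))

    hits: list[SimilarityHit] = []
    for rec in queries:
        qarr = _encode_query(rec.bases)
        qbytes = qarr.tobytes()
        best: dict[int, tuple[float, int, int]] = {}
        seen: set[tuple[int, int]] = set()
        for qpos in range(qarr.size - word_length + 1):
            word = qbytes[qpos : qpos + word_length]
            if 0 in word:
                continue
            for si, spos in index.get(word, ()):
                key = (si, spos - qpos)
                if key in seen:
                    continue
                seen.add(key)
                res = _best_on_diagonal(qarr, enc[si], spos - qpos, scoring)
                if res is not None and (si not in best or res[0] > best[si][0]):
                    best[si] = res
        query_hits = []
        for si, (raw, matches, length) in best.items():
            if raw < min_raw_score:
                continue
            sid = subject_ids[si]
            query_hits.append(
                SimilarityHit(
                    query_id=rec.id,
                    subject_id=sid,
                    bit_score=scoring.bit_score(raw),
                    percent_identity=100.0 * matches / length,
                    alignment_length=length,
                    subject_taxon=None if subject_taxa is None else subject_taxa.get(sid),
                )
            )
        query_hits.sort(key=lambda h: (-h.bit_score, h.subject_id))
        hits.extend(query_hits)
    return hits


def pairwise_identity(a: str, b: str) -> float:
    """CD-HIT-style identity: matching columns / length of the shorter sequence.

    The shorter sequence is aligned semi-globally (infix) into the longer one;
    matching columns are estimated as shorter length minus edit distance.
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    dist = edlib.align(short, long_, mode="HW", task="distance")["editDistance"]
    return max(0.0, (len(short) - dist) / len(short))


def greedy_cluster(
    records: Sequence[SequenceRecord],
    identity_threshold: float = 0.98,
    word_length: int = 8,
) -> list[SequenceCluster]:
    """Greedy incremental clustering, longest sequence first.

    Each record joins the first existing cluster whose representative it
    matches at >= ``identity_threshold``; a shared ``word_length``-mer is
    required before the (exact) identity is computed, mirroring the k-mer
    prefilter of greedy clustering tools.  Every record lands in exactly one
    cluster, and the representative is a longest member.
    """
    if not records:
        raise ValueError("no records to cluster")
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must lie in (0, 1]")

    def kmers(seq: str) -> set[str]:
        return {seq[i : i + word_length] for i in range(len(seq) - word_length + 1)}

    order = sorted(records, key=lambda r: (-len(r.bases), r.id))
    clusters: list[SequenceCluster] = []
    rep_seqs: list[str] = []
    rep_kmers: list[set[str]] = []
    for rec in order:
        words = kmers(rec.bases)
        for ci, cl in enumerate(clusters):
            if words & rep_kmers[ci] and pairwise_identity(rec.bases, rep_seqs[ci]) >= identity_threshold:
                cl.member_ids.append(rec.id)
                break
        else:
            clusters.append(SequenceCluster(representative_id=rec.id, member_ids=[rec.id]))
            rep_seqs.append(rec.bases)
            rep_kmers.append(words)
    return clusters


def _hits_by_query(hits: Iterable[SimilarityHit]) -> dict[str, list[SimilarityHit]]:
    grouped: dict[str, list[SimilarityHit]] = {}
    for h in hits:
        grouped.setdefault(h.query_id, []).append(h)
    for hs in grouped.values():
        hs.sort(key=lambda h: (-h.bit_score, h.subject_id))
    return grouped


def partition_rrna(
    hits: Iterable[SimilarityHit],
    query_ids: Iterable[str],
    bit_score_cutoff: float = 86.0,
) -> tuple[set[str], set[str]]:
    """Split queries into rRNA-like and remainder at a bit-score cutoff.

    A query is rRNA-like iff its best reference-database hit reaches
    ``bit_score_cutoff`` (boundary inclusive).  Queries with no hits fall in
    the remainder, which is forwarded to protein-level assignment.
    """
    grouped = _hits_by_query(hits)
    rrna, remainder = set(), set()
    for qid in query_ids:
        qhits = grouped.get(qid)
        if qhits and qhits[0].bit_score >= bit_score_cutoff:
            rrna.add(qid)
        else:
            remainder.add(qid)
    return rrna, remainder


def lca_assign(
    hits: Iterable[SimilarityHit],
    tree: TaxonomyTree,
    min_support: int = 5,
    score_range_fraction: float = 0.10,
    min_support_mode: str = "promote",
) -> list[TaxonAssignment]:
    """Two-stage MEGAN-style LCA assignment.

    Stage 1: per query, hits within ``score_range_fraction`` of the best bit
    score are retained and the query is placed at the lowest common ancestor
    of their subject taxa.  Stage 2: taxa whose cumulative support (own
    queries plus descendants) falls below ``min_support`` have their queries
    promoted to the nearest sufficiently supported ancestor
    (``min_support_mode="promote"``) or dropped to UNASSIGNED
    (``min_support_mode="discard"``).
    """
    if min_support_mode not in ("promote", "discard"):
        raise ValueError("min_support_mode must be 'promote' or 'discard'")
    grouped = _hits_by_query(hits)

    stage1: dict[str, tuple[str, int]] = {}
    for qid, qhits in grouped.items():
        best = qhits[0].bit_score
        window = [h for h in qhits if h.bit_score >= (1.0 - score_range_fraction) * best]
        taxa = []
        for h in window:
            if h.subject_taxon is None:
                raise ValueError(f"hit {h.query_id!r}->{h.subject_id!r} has no subject taxon")
            if h.subject_taxon not in tree:
                raise ValueError(f"unknown subject taxon id {h.subject_taxon!r}")
            taxa.append(h.subject_taxon)
        stage1[qid] = (tree.lca(taxa), len(window))

    # cumulative support per node (direct assignments summed up the lineage)
    direct: dict[str, int] = {}
    for taxon, _ in stage1.values():
        direct[taxon] = direct.get(taxon, 0) + 1
    cumulative: dict[str, int] = {}
    for taxon, count in direct.items():
        for nid in tree.lineage(taxon):
            cumulative[nid] = cumulative.get(nid, 0) + count

    assignments = []
    for qid in sorted(stage1):
        taxon, support = stage1[qid]
        if cumulative.get(taxon, 0) < min_support:
            if min_support_mode == "discard":
                taxon = UNASSIGNED
            else:
                placed = UNASSIGNED
                for nid in reversed(tree.lineage(taxon)[:-1]):
                    if cumulative.get(nid, 0) >= min_support:
                        placed = nid
                        break
                taxon = placed
        assignments.append(TaxonAssignment(query_id=qid, taxon=taxon, support=support))
    return assignments


def build_taxonomic_profile(
    assignments: Iterable[TaxonAssignment],
    sample_of_query: Mapping[str, str],
) -> pd.DataFrame:
    """Per-sample taxon counts with two fraction columns.

    ``frac_assigned`` is the taxon count over all assigned queries of the
    sample; ``frac_total`` is over all queries including UNASSIGNED ones
    (the convention of reporting "percent of all sequences").
    """
    rows = []
    per_sample: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    for a in assignments:
        sample = sample_of_query[a.query_id]
        totals[sample] = totals.get(sample, 0) + 1
        if a.taxon != UNASSIGNED:
            per_sample.setdefault(sample, {})[a.taxon] = (
                per_sample.setdefault(sample, {}).get(a.taxon, 0) + 1
            )
    for sample in sorted(totals):
        counts = per_sample.get(sample, {})
        assigned = sum(counts.values())
        for taxon in sorted(counts):
            rows.append(
                {
                    "sample_id": sample,
                    "taxon": taxon,
                    "count": counts[taxon],
                    "frac_assigned": counts[taxon] / assigned if assigned else np.nan,
                    "frac_total": counts[taxon] / totals[sample],
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "taxon", "count", "frac_assigned", "frac_total"])


def fragment_reference_db(
    references: Mapping[str, str],
    n_fragments: int,
    length_mean: float = 420.0,
    length_sd: float = 150.0,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Randomly fragment a reference database to emulate a sequencing run.

    Sources are sampled uniformly over references; lengths are normal
    (mean 420 bp, sd 150 bp by default, the fragment model of a
    pyrosequencing run) truncated to [50, source length]; start positions
    are uniform.  Returns (fragment_id, source_id, sequence) triples.
    """
    if n_fragments <= 0:
        raise ValueError("n_fragments must be positive")
    if not references:
        raise ValueError("references must be non-empty")
    rng = np.random.default_rng(seed)
    ids = sorted(references)
    src = rng.integers(0, len(ids), size=n_fragments)
    src_len = np.array([len(references[i]) for i in ids])
    upper = src_len[src]
    lengths = np.clip(
        np.rint(rng.normal(length_mean, length_sd, size=n_fragments)).astype(int),
        np.minimum(50, upper),
        upper,
    )
    starts = rng.integers(0, upper - lengths + 1)
    out = []
    for i in range(n_fragments):
        sid = ids[src[i]]
        seq = references[sid][starts[i] : starts[i] + lengths[i]]
        out.append((f"frag_{i}", sid, seq))
    return out


@dataclass
class CalibrationCurve:
    """Sensitivity/specificity of best-hit correctness vs bit-score threshold."""

    rows: pd.DataFrame  # threshold, tp, fp, tn, fn, sensitivity, specificity
    selected_threshold: float | None
    specificity_criterion: float


def lineage_mismatch(tree: TaxonomyTree, taxon_a: str, taxon_b: str) -> int:
    """Number of root-aligned rank positions at which two lineages differ."""
    la = tree.lineage_names(taxon_a)
    lb = tree.lineage_names(taxon_b)
    n = max(len(la), len(lb))
    la += [None] * (n - len(la))
    lb += [None] * (n - len(lb))
    return sum(1 for a, b in zip(la, lb) if a is not None and b is not None and a != b)


def threshold_sweep(
    hits: Iterable[SimilarityHit],
    tree: TaxonomyTree,
    fragment_source: Mapping[str, str],
    subject_taxa: Mapping[str, str],
    max_lineage_mismatch: int = 2,
    specificity_criterion: float = 0.99,
) -> CalibrationCurve:
    """Calibrate a bit-score cutoff from self-search of database fragments.

    A fragment's best hit is CORRECT if it is the fragment's source sequence
    or a sequence whose lineage differs from the truth at no more than
    ``max_lineage_mismatch`` ranks.  At each distinct best-hit score t:
    TP = correct with score >= t, FP = incorrect with score >= t,
    FN = correct below t, TN = incorrect below t.  The selected threshold is
    the smallest t whose specificity reaches ``specificity_criterion``.
    Fragments with no hits carry no score and are excluded from the counts.
    """
    grouped = _hits_by_query(hits)
    if not grouped:
        raise ValueError("no hits to sweep")
    scores, correct = [], []
    for qid, qhits in grouped.items():
        best = qhits[0]
        source = fragment_source[qid]
        true_taxon = subject_taxa[source]
        hit_taxon = subject_taxa[best.subject_id]
        ok = best.subject_id == source or lineage_mismatch(tree, true_taxon, hit_taxon) <= max_lineage_mismatch
        scores.append(best.bit_score)
        correct.append(ok)
    scores_arr = np.asarray(scores)
    correct_arr = np.asarray(correct, dtype=bool)

    thresholds = np.unique(scores_arr)
    rows = []
    for t in thresholds:
        above = scores_arr >= t
        tp = int(np.sum(above & correct_arr))
        fp = int(np.sum(above & ~correct_arr))
        fn = int(np.sum(~above & correct_arr))
        tn = int(np.sum(~above & ~correct_arr))
        sens = tp / (tp + fn) if (tp + fn) else np.nan
        spec = tn / (tn + fp) if (tn + fp) else 1.0
        rows.append(
            {"threshold": float(t), "tp": tp, "fp": fp, "tn": tn, "fn": fn,
             "sensitivity": sens, "specificity": spec}
        )
    curve = pd.DataFrame(rows)

    sens_vals = curve["sensitivity"].to_numpy()
    spec_vals = curve["specificity"].to_numpy()
    if np.any(np.diff(sens_vals) > 1e-12) or np.any(np.diff(spec_vals) < -1e-12):
        raise AssertionError("calibration curve is not monotone in the threshold")

    eligible = curve[curve["specificity"] >= specificity_criterion]
    selected = float(eligible["threshold"].iloc[0]) if len(eligible) else None
    return CalibrationCurve(rows=curve, selected_threshold=selected,
                            specificity_criterion=specificity_criterion)
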