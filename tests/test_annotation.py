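"""Annotation pipeline: toy search, clustering, rRNA split, LCA, calibration."""

import math

import numpy as np
import pytest

import omzplume as oz
from omzplume.annotation import lineage_mismatch, pairwise_identity

from conftest import make_record, random_seq


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def smith_waterman(a: str, b: str, match=2, mismatch=-3, gap=-5) -> int:
    """Full local-alignment dynamic program (the slow reference)."""
    n, m = len(a), len(b)
    best = 0
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            cur[j] = max(0, diag, prev[j] + gap, cur[j - 1] + gap)
            best = max(best, cur[j])
        prev = cur
    return best


def infix_levenshtein(short: str, long_: str) -> int:
    """Edit distance of `short` aligned anywhere inside `long_` (DP reference)."""
    prev = [0] * (len(long_) + 1)  # free start gap in long_
    for i in range(1, len(short) + 1):
        cur = [i] + [0] * len(long_)
        for j in range(1, len(long_) + 1):
            cost = 0 if short[i - 1] == long_[j - 1] else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)


def oracle_identity(a: str, b: str) -> float:
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    return max(0.0, (len(short) - infix_levenshtein(short, long_)) / len(short))


def greedy_cluster_oracle(records, threshold):
    """All-pairs greedy clustering without the k-mer prefilter shortcut,
    using the independent DP identity."""
    order = sorted(records, key=lambda r: (-len(r.bases), r.id))
    clusters = []
    for rec in order:
        for cl in clusters:
            if oracle_identity(rec.bases, cl[0].bases) >= threshold:
                cl.append(rec)
                break
        else:
            clusters.append([rec])
    return [{r.id for r in cl} for cl in clusters]


def lca_oracle(tree, taxa):
    """LCA by brute-force ancestor-set intersection."""
    common = set(tree.lineage(taxa[0]))
    for t in taxa[1:]:
        common &= set(tree.lineage(t))
    return max(common, key=lambda n: len(tree.lineage(n)))


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------

class TestSearch:
    def test_identical_sequences_bit_score_formula(self):
        seq = random_seq(np.random.default_rng(0), 100)
        rec = make_record("q", seq)
        hits = oz.search([rec], {"s": seq})
        assert len(hits) == 1
        expected_bits = (0.625 * 200 - math.log(0.41)) / math.log(2)
        assert hits[0].bit_score == pytest.approx(expected_bits)
        assert hits[0].percent_identity == 100.0
        assert hits[0].alignment_length == 100

    def test_all_n_query_has_no_hits(self):
        rec = make_record("q", "N" * 80)
        assert oz.search([rec], {"s": random_seq(np.random.default_rng(1), 200)}) == []

    def test_short_query_has_no_hits(self):
        rec = make_record("q", "ACGTACG")
        assert oz.search([rec], {"s": "ACGTACG" * 20}) == []

    def test_top_hit_matches_smith_waterman_oracle(self):
        """Top-hit subject equals the full-DP best local-alignment subject
        for 30 mutated-fragment queries against 10 subjects."""
        rng = np.random.default_rng(5)
        subjects = {f"s{i:02d}": random_seq(rng, 300) for i in range(10)}
        sids = sorted(subjects)
        queries = []
        for qi in range(30):
            src = sids[rng.integers(0, 10)]
            start = int(rng.integers(0, 200))
            frag = subjects[src][start : start + 100]
            frag = "".join(
                c if rng.random() > 0.05 else "ACGT"[rng.integers(0, 4)] for c in frag
            )
            queries.append(make_record(f"q{qi}", frag))
        hits = oz.search(queries, subjects)
        by_query = {}
        for h in hits:
            by_query.setdefault(h.query_id, h)  # hits are best-first per query
        assert by_query, "search produced no hits"
        for rec in queries:
            if rec.id not in by_query:
                continue
            sw = {sid: smith_waterman(rec.bases, subjects[sid]) for sid in sids}
            best_sw = max(sw.values())
            assert sw[by_query[rec.id].subject_id] == best_sw


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

class TestGreedyCluster:
    def test_identical_pair_forms_one_cluster(self):
        seq = random_seq(np.random.default_rng(2), 120)
        clusters = oz.greedy_cluster([make_record("a", seq), make_record("b", seq)])
        assert len(clusters) == 1 and clusters[0].size == 2

    def test_disjoint_words_form_singletons(self):
        clusters = oz.greedy_cluster([make_record("a", "A" * 60), make_record("b", "C" * 60)])
        assert len(clusters) == 2 and all(c.size == 1 for c in clusters)

    def test_identity_definition_matches_dp_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = random_seq(rng, int(rng.integers(60, 140)))
            b = random_seq(rng, int(rng.integers(60, 140)))
            assert pairwise_identity(a, b) == pytest.approx(oracle_identity(a, b))

    def test_matches_all_pairs_oracle_on_mutated_reads(self):
        """50 reads at known mutation distances cluster exactly as the
        brute-force all-pairs greedy oracle."""
        rng = np.random.default_rng(17)
        centers = [random_seq(rng, 200) for _ in range(8)]
        records = []
        for i in range(50):
            center = centers[int(rng.integers(0, 8))]
            p = 0.01 if rng.random() < 0.7 else 0.10  # within vs beyond threshold
            seq = "".join(c if rng.random() > p else "ACGT"[rng.integers(0, 4)] for c in center)
            records.append(make_record(f"r{i:02d}", seq))
        ours = [set(c.member_ids) for c in oz.greedy_cluster(records, 0.98)]
        oracle = greedy_cluster_oracle(records, 0.98)
        assert ours == oracle

    def test_partition_invariant(self, small_taxonomy):
        _, _, refs = small_taxonomy
        taxon = sorted(refs)[0]
        spec = oz.CommunitySpec(abundances={taxon: 1.0}, n_reads_dna=40, n_reads_rna=0,
                                error_rate=0.03, seed=8)
        reads, _ = oz.simulate_reads(spec, refs)
        clusters = oz.greedy_cluster(reads)
        assert sum(c.size for c in clusters) == len(reads)
        all_members = [m for c in clusters for m in c.member_ids]
        assert len(all_members) == len(set(all_members))
        for c in clusters:
            lengths = {m: len(r.bases) for r in reads for m in c.member_ids if r.id == m}
            assert lengths[c.representative_id] == max(lengths.values())


# ---------------------------------------------------------------------------
# rRNA partition and LCA
# ---------------------------------------------------------------------------

def hit(q, s, bits, taxon=None):
    return oz.SimilarityHit(query_id=q, subject_id=s, bit_score=bits,
                            percent_identity=99.0, alignment_length=100, subject_taxon=taxon)


class TestPartitionRrna:
    @pytest.mark.parametrize(
        "best_bits,expect_rrna",
        [(86.0, True), (85.9, False), (120.0, True), (None, False)],
    )
    def test_cutoff_boundary_inclusive(self, best_bits, expect_rrna):
        hits = [] if best_bits is None else [hit("q1", "s", best_bits)]
        rrna, rest = oz.partition_rrna(hits, ["q1"])
        assert ("q1" in rrna) is expect_rrna
        assert ("q1" in rest) is (not expect_rrna)


class TestLcaAssign:
    def test_single_hit_assigns_species(self, small_taxonomy):
        _, tree, refs = small_taxonomy
        leaf = sorted(refs)[0]
        out = oz.lca_assign([hit("q", "s", 100, leaf)], tree, min_support=1)
        assert out[0].taxon == leaf

    def test_sibling_species_within_window_collapse_to_genus(self, small_taxonomy):
        """Hits at 100 and 95 bits (within the 10% window) to sibling species
        place the query at their genus — verified against the brute-force
        ancestor-set-intersection oracle."""
        _, tree, refs = small_taxonomy
        leaves = sorted(refs)
        a, b = leaves[0], leaves[1]
        assert tree.parent(a) == tree.parent(b)  # siblings by construction
        out = oz.lca_assign([hit("q", "sa", 100, a), hit("q", "sb", 95, b)], tree, min_support=1)
        assert out[0].taxon == tree.parent(a)
        assert out[0].taxon == lca_oracle(tree, [a, b])

    def test_hit_below_score_window_is_ignored(self, small_taxonomy):
        _, tree, refs = small_taxonomy
        leaves = sorted(refs)
        base = [hit("q", "sa", 100, leaves[0])]
        extra = base + [hit("q", "sx", 85, leaves[-1])]  # below 90-bit window
        r1 = oz.lca_assign(base, tree, min_support=1)
        r2 = oz.lca_assign(extra, tree, min_support=1)
        assert r1[0].taxon == r2[0].taxon

    def test_min_support_promotes_to_ancestor(self, small_taxonomy):
        """4 queries on species X (below support 5) are promoted to the genus
        once the genus holds >= 5 cumulative queries."""
        _, tree, refs = small_taxonomy
        leaves = sorted(refs)
        a, b = leaves[0], leaves[1]  # siblings
        hits = [hit(f"qa{i}", "sa", 100, a) for i in range(4)]
        hits += [hit(f"qb{i}", "sb", 100, b) for i in range(4)]
        out = {x.query_id: x.taxon for x in oz.lca_assign(hits, tree, min_support=5)}
        genus = tree.parent(a)
        assert all(t == genus for t in out.values())  # genus holds 8 cumulative

    def test_min_support_discard_mode(self, small_taxonomy):
        _, tree, refs = small_taxonomy
        leaf = sorted(refs)[0]
        out = oz.lca_assign([hit("q", "s", 100, leaf)], tree, min_support=5,
                            min_support_mode="discard")
        assert out[0].taxon == oz.annotation.UNASSIGNED

    def test_unknown_taxon_raises_with_id(self, small_taxonomy):
        _, tree, _ = small_taxonomy
        with pytest.raises(ValueError, match="nonexistent"):
            oz.lca_assign([hit("q", "s", 100, "nonexistent")], tree)


class TestTaxonomicProfile:
    def test_fraction_conventions(self, small_taxonomy):
        _, tree, refs = small_taxonomy
        leaf = sorted(refs)[0]
        assignments = [oz.TaxonAssignment(f"q{i}", leaf, 1) for i in range(5)]
        assignments += [oz.TaxonAssignment(f"u{i}", oz.annotation.UNASSIGNED, 0) for i in range(5)]
        prof = oz.build_taxonomic_profile(assignments, {a.query_id: "S1" for a in assignments})
        row = prof.iloc[0]
        assert row["frac_assigned"] == pytest.approx(1.0)
        assert row["frac_total"] == pytest.approx(0.5)

    def test_recovers_known_community_fractions(self, small_taxonomy):
        """A 0.7/0.3 two-taxon community, error-free reads, recovered through
        search + LCA within the multinomial 95% CI at n = 2,000 reads."""
        _, tree, refs = small_taxonomy
        leaves = sorted(refs)
        a, b = leaves[0], leaves[-1]  # different phyla
        n = 2000
        spec = oz.CommunitySpec(
            abundances={a: 0.7, b: 0.3}, n_reads_dna=n, n_reads_rna=0,
            read_length_mean=150, read_length_sd=20, error_rate=0.0, seed=23,
        )
        reads, _ = oz.simulate_reads(spec, refs)
        hits = oz.search(reads, {a: refs[a], b: refs[b]}, subject_taxa={a: a, b: b})
        assignments = oz.lca_assign(hits, tree, min_support=5)
        prof = oz.build_taxonomic_profile(
            assignments, {r.id: r.sample_id for r in reads}
        ).set_index("taxon")
        frac_a = prof.loc[a, "frac_assigned"]
        se = np.sqrt(0.7 * 0.3 / n)
        assert abs(frac_a - 0.7) < 1.96 * se + 0.01  # CI plus slack for LCA losses


# ---------------------------------------------------------------------------
# fragmentation and threshold sweep
# ---------------------------------------------------------------------------

class TestFragmentReferenceDb:
    def test_reproducible(self, small_taxonomy):
        _, _, refs = small_taxonomy
        assert oz.fragment_reference_db(refs, 100, seed=4) == oz.fragment_reference_db(
            refs, 100, seed=4
        )

    def test_truncation_to_source_length(self):
        refs = {"r": "ACGT" * 25}  # length 100 << mean 420
        frags = oz.fragment_reference_db(refs, 200, seed=1)
        lengths = [len(seq) for _, _, seq in frags]
        assert max(lengths) == 100  # never beyond the source
        # draws below 100 survive untruncated but are a ~1.7% normal tail
        assert np.mean(np.array(lengths) == 100) > 0.95

    def test_untruncated_length_distribution(self):
        rng = np.random.default_rng(0)
        refs = {"r": random_seq(rng, 5000)}
        frags = oz.fragment_reference_db(refs, 10_000, length_mean=420, length_sd=150, seed=2)
        lengths = np.array([len(s) for _, _, s in frags])
        se = 150 / np.sqrt(len(lengths))
        assert abs(lengths.mean() - 420) < 3 * se + 0.5  # +0.5 for integer rounding

    def test_nonpositive_count_rejected(self, small_taxonomy):
        _, _, refs = small_taxonomy
        with pytest.raises(ValueError):
            oz.fragment_reference_db(refs, 0)


@pytest.fixture(scope="module")
def sweep_inputs(deep_taxonomy):
    _, tree, refs = deep_taxonomy
    taxa = {rid: rid for rid in refs}
    frags = oz.fragment_reference_db(refs, 200, length_mean=150, length_sd=80, seed=6)
    records = [make_record(fid, seq) for fid, _, seq in frags]
    hits = oz.search(records, refs, subject_taxa=taxa)
    return tree, taxa, frags, hits


class TestThresholdSweep:
    def test_boundary_rows(self, sweep_inputs):
        tree, taxa, frags, hits = sweep_inputs
        curve = oz.threshold_sweep(hits, tree, {f: s for f, s, _ in frags}, taxa)
        first, last = curve.rows.iloc[0], curve.rows.iloc[-1]
        assert first["sensitivity"] == pytest.approx(1.0)  # lowest threshold keeps all
        assert last["fp"] <= first["fp"] and last["specificity"] >= first["specificity"]

    def test_confusion_counts_match_enumeration_oracle(self, sweep_inputs):
        """TP/FP/TN/FN at five thresholds equal exhaustive enumeration over
        best hits on a 200-fragment synthetic database."""
        tree, taxa, frags, hits = sweep_inputs
        source = {f: s for f, s, _ in frags}
        curve = oz.threshold_sweep(hits, tree, source, taxa)

        # oracle: recompute best hit and correctness by exhaustive scan
        best = {}
        for h in hits:
            cur = best.get(h.query_id)
            if cur is None or (h.bit_score, ) > (cur.bit_score, ) or (
                h.bit_score == cur.bit_score and h.subject_id < cur.subject_id
            ):
                best[h.query_id] = h
        rows = curve.rows
        picks = np.linspace(0, len(rows) - 1, 5).astype(int)
        for idx in picks:
            t = rows.iloc[idx]["threshold"]
            tp = fp = tn = fn = 0
            for qid, h in best.items():
                ok = h.subject_id == source[qid] or lineage_mismatch(
                    tree, taxa[source[qid]], taxa[h.subject_id]
                ) <= 2
                if h.bit_score >= t:
                    tp, fp = tp + ok, fp + (not ok)
                else:
                    fn, tn = fn + ok, tn + (not ok)
            assert (rows.iloc[idx][["tp", "fp", "tn", "fn"]].to_numpy() == [tp, fp, tn, fn]).all()

    def test_monotonicity_and_constant_total(self, sweep_inputs):
        tree, taxa, frags, hits = sweep_inputs
        curve = oz.threshold_sweep(hits, tree, {f: s for f, s, _ in frags}, taxa)
        totals = curve.rows[["tp", "fp", "tn", "fn"]].sum(axis=1)
        assert totals.nunique() == 1
        sens = curve.rows["sensitivity"].to_numpy()
        spec = curve.rows["specificity"].to_numpy()
        assert np.all(np.diff(sens) <= 1e-12)
        assert np.all(np.diff(spec) >= -1e-12)

    def test_source_recovery_on_divergent_taxa(self):
        """Fragments overwhelmingly hit their own source once taxa are well
        separated (>= 0.95 recovery at 10% inter-species divergence)."""
        spec = oz.TaxonomySpec(
            ranks=("phylum", "species"), children_per_rank=(4, 5),
            divergence_per_rank=(0.15, 0.10), seq_length=600, seed=13,
        )
        _, refs = oz.make_reference_taxonomy(spec)
        frags = oz.fragment_reference_db(refs, 100, length_mean=150, length_sd=80, seed=14)
        records = [make_record(fid, seq) for fid, _, seq in frags]
        hits = oz.search(records, refs)
        source = {f: s for f, s, _ in frags}
        best = {}
        for h in hits:
            best.setdefault(h.query_id, h)
        own = sum(1 for qid, h in best.items() if h.subject_id == source[qid])
        assert own / len(best) >= 0.95

    def test_no_hits_is_an_error(self, deep_taxonomy):
        _, tree, _ = deep_taxonomy
        with pytest.raises(ValueError):
            oz.threshold_sweep([], tree, {}, {})
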