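"""Read annotation end-to-end on a synthetic two-taxon community.

Generates a ranked reference taxonomy, draws error-free reads from a 70/30
community, clusters them at 98% identity, searches them against the
references with the built-in toy aligner and recovers the community
composition through LCA assignment.
"""

import omzplume as oz

tree, refs = oz.make_reference_taxonomy(
    oz.TaxonomySpec(
        ranks=("phylum", "genus", "species"),
        children_per_rank=(2, 2, 2),
        divergence_per_rank=(0.10, 0.05, 0.01),
        seq_length=600,
        seed=7,
    )
)
leaves = sorted(refs)
a, b = leaves[0], leaves[-1]  # two taxa from different phyla

community = oz.CommunitySpec(
    abundances={a: 0.7, b: 0.3},
    n_reads_dna=500, n_reads_rna=0,
    read_length_mean=150, read_length_sd=20,
    error_rate=0.0, sample_id="20m", depth=20.0, seed=1,
)
reads, provenance = oz.simulate_reads(community, refs)

clusters = oz.greedy_cluster(reads, identity_threshold=0.98, word_length=8)
hits = oz.search(reads, {a: refs[a], b: refs[b]}, subject_taxa={a: a, b: b})
assignments = oz.lca_assign(hits, tree, min_support=5, score_range_fraction=0.10)
profile = oz.build_taxonomic_profile(assignments, {r.id: r.sample_id for r in reads})

print(f"reads: {len(reads)}, clusters at 98% identity: {len(clusters)}")
print(profile.to_string(index=False))
print()
truth = provenance["taxon"].value_counts(normalize=True)
print("true composition:", {t: round(f, 3) for t, f in truth.items()})
print("The frac_assigned column recovers the simulated 0.7/0.3 community "
      "within multinomial sampling error.")
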