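"""Select a group of target genomes around a seed genome.

Genomes are compared by their transcription-factor repertoires: presence
bit vectors, Hamming distances, a neighbor-joining tree, and the largest
clade around the seed in which every genome pair still shares at least
half of its TFs.
"""

from phylofoot import (
    FixtureConfig,
    generate_group,
    hamming_matrix,
    neighbor_joining,
    select_target_group,
    shared_tf_fraction,
    tf_presence_matrix,
)

bundle = generate_group(FixtureConfig(seed=7))
genome_ids = sorted(bundle.genomes)
m = tf_presence_matrix(bundle.tf_table, genome_ids)
ids, d = hamming_matrix(m)
tree = neighbor_joining(ids, d)

print("TF repertoire sizes:", {g: len(m.tf_set(g)) for g in genome_ids})
print("tree:", str(tree).strip())
for other in genome_ids[1:]:
    print(f"shared TF fraction g0 vs {other}: {shared_tf_fraction('g0', other, m):.2f}")
group = select_target_group(tree, m, seed_genome="g0", min_shared=0.5)
print("selected target group:", sorted(group))

# With the default fixture all genomes carry the four planted regulators
# plus overlapping accessory families, so the whole group qualifies; raise
# min_shared to see the clade walk stop earlier.
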