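"""Cluster orthologous operons (COORs) and extract upstream sequences.

Runs bi-directional-best-hit orthology on the group's protein similarity
tables, recruits orthologous operons into SCOORs, joins them into COORs,
and extracts each COOR's upstream inter-operonic sequence set.
"""

from phylofoot import FixtureConfig, generate_group
from phylofoot.pipeline import build_coors

bundle = generate_group(FixtureConfig(seed=7))
build = build_coors(bundle.genomes, bundle.operons_by_genome, bundle.hit_tables)

print(f"ortholog pairs: {len(build.orthologs)}")
print(f"COORs:          {len(build.coors)}")
sizes = sorted((len(c.operons) for c in build.coors), reverse=True)
print(f"COOR sizes:     min {sizes[-1]}, max {sizes[0]}")
print(f"sequence sets:  {len(build.sequence_sets)} (>= 3 sequences each)")

ss = build.sequence_sets[0]
print(f"\nfirst set ({ss.coor_id}):")
for operon_id, site in ss.entries:
    print(f"  {operon_id}: {site.genome_id}:{site.start}-{site.end}({site.strand}) "
          f"{len(site)} bp")

# Each sequence set pools the upstream regions of one orthologous operon
# family across all genomes — the unit on which motif finders are run.
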