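"""Generate a synthetic genome group with planted regulatory motifs.

Builds five related genomes whose orthologous operons carry conserved
binding sites of four planted transcription factors, then prints what was
generated. The same bundle drives every other example.
"""

from phylofoot import FixtureConfig, generate_group

cfg = FixtureConfig(seed=7)
bundle = generate_group(cfg)

print(f"genomes:        {', '.join(bundle.genomes)}")
print(f"genome length:  ~{len(next(iter(bundle.genomes.values()))):,} bp each")
print(f"operons:        {len(bundle.operons)} ({cfg.n_operons} orthologous families)")
print(f"planted motifs: {len(bundle.planted_pwms)}")
for name, pwm in bundle.planted_pwms.items():
    consensus = "".join("ACGT"[c.argmax()] for c in pwm.T)
    n_sites = sum(1 for n, _ in bundle.truth.rows if n == name)
    print(f"  {name}: consensus {consensus}, {n_sites} planted sites")
print(f"truth table:    {len(bundle.truth)} sites "
      f"(= motifs x carrier operons x genomes)")

# bundle.write("scratch/group")  # emits FASTA/TSV files for the CLI

# The consensus strings are what the pipeline must rediscover: each planted
# site diverges from its ancestral sequence by ~5% per base per genome,
# emulating the conservation signal phylogenetic footprinting exploits.
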