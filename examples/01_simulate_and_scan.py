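"""Plant origin cassettes in a synthetic genome and find them with the scan.

The genome scan keeps 500-bp window pairs whose G content steps down from a
G-rich upstream window to a moderately G-rich downstream window, in either
orientation, and merges retained pairs into candidate regions.
"""

from oriscan import generate_genome, overlap_flags, scan_genome
from oriscan.simulate import SyntheticSpec

spec = SyntheticSpec(genome_length=2_000_000, n_origins=100, seed=42)
genome, truth = generate_genome(spec)
print(f"genome: {genome.length:,} bp, {len(truth.origins)} planted cassettes")

result = scan_genome(genome)
print(f"retained {result.retained_pairs} window pairs "
      f"in {len(result.regions)} candidate regions")

hit = overlap_flags(truth.origins, result.regions)
print(f"sensitivity: {hit.mean():.3f}")

strands = [r.strand for r in result.regions]
print(f"forward regions: {strands.count('+')}, reverse: {strands.count('-')}")
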