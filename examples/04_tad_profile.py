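"""Origin density across topologically associating domains (TADs).

Each TAD is split into 100 equal bins; the first and last ten bins are
"borders", bins 41-60 are "centres". Origins placed with a border
enrichment factor should hand that factor back as the profile's
border/centre density ratio.
"""

from oriscan import normalize_profile_to_centre, simulate_tads, tad_density_profile
from oriscan.simulate import SyntheticSpec

spec = SyntheticSpec(genome_length=10_000_000, tad_count=20, seed=3)

for factor in (1.0, 1.53, 3.0):
    tads, origins = simulate_tads(spec, border_factor=factor, n_placed=10_000)
    profile = tad_density_profile(origins, tads)
    print(f"planted border factor {factor:.2f} -> "
          f"recovered border/centre ratio {profile.border_centre_ratio:.2f}")

tads, origins = simulate_tads(spec, border_factor=1.53, n_placed=10_000)
norm = normalize_profile_to_centre(tad_density_profile(origins, tads))
print("normalised density, bins 1-5:", [round(float(v), 2) for v in norm[:5]])
print("normalised density, bins 48-52:", [round(float(v), 2) for v in norm[47:52]])
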