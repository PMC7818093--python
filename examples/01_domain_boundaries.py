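"""Call domain boundaries from the contact-density profile.

Builds a synthetic two-domain membrane protein (boundary planted at the
midpoint of its inter-domain linker, residue 60) with a realistically
noisy predicted contact map, computes the smoothed spanning-count
profile and reports its minima.
"""

import warnings

from reentrant_scope import density, synthetic as syn

warnings.filterwarnings("ignore", message="requested top")

protein = syn.build_protein(syn.two_domain_spec(seed=42))
result = density.density_profile(protein.noisy_map)

print(f"chain length        : {protein.L}")
print(f"planted boundary    : {protein.truth.boundaries[0]}")
print(f"density minima      : {result.minima}")
print(f"top boundary call   : {result.boundary}")
print()
print("The top-ranked minimum of the contact-density profile marks the")
print("position spanned by the fewest high-confidence contacts - the")
print("inter-domain linker. A call within a few residues of the planted")
print("boundary is a correct recovery.")
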