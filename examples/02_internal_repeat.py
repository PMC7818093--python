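"""Detect a cryptic internal tandem repeat from the contact map alone.

Builds a protein of two identical 60-residue units, corrupts its contact
map (85% true-positive retention), and runs the Jaccard-over-offsets
repeat test with a separation-preserving permutation null.
"""

from reentrant_scope import repeats, synthetic as syn

protein = syn.build_protein(syn.tandem_repeat_spec(seed=42))
hit = repeats.detect_repeat(protein.noisy_map, splits=range(50, 71, 5),
                            n_perm=199, seed=1)

print(f"chain length        : {protein.L}")
print(f"planted unit length : 60")
print(f"best split / offset : {hit.split} / {hit.delta}")
print(f"canonical period    : {hit.period}")
print(f"half-map Jaccard    : {hit.score:.3f}")
print(f"permutation p-value : {hit.p_value:.4f}  ({hit.n_permutations} draws)")
print()
print("The period (split + offset) estimates the repeat unit length; a")
print("p-value at the 1/(n_perm+1) floor means no permuted map matched")
print("the observed half-map similarity.")
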