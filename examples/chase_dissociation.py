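"""Dissociation rates by chase: preformed labelled complexes are mixed with
excess unlabelled nucleotide, so the fluorescence decay rate equals k-1.

Compares mant-ATPgS release from the two isolated cassettes; the
N-terminal cassette releases the nucleotide ~800-fold faster.
"""

from brr2allo.kinetics.recovery import recover_chase_rate

nc = recover_chase_rate("hBrr2-NC", "mant-ATPgS", "NC", n_seeds=10, base_seed=0)
cc = recover_chase_rate("hBrr2-CC", "mant-ATPgS", "CC", n_seeds=10, base_seed=0)

print(f"NC k-1 = {nc.median:.4g} 1/s  (truth {nc.generating_value})")
print(f"CC k-1 = {cc.median:.4g} 1/s  (truth {cc.generating_value})")
print(f"NC/CC dissociation fold = {nc.median / cc.median:.0f}  (truth 800)")
print("\nSlow release from the C-terminal cassette makes it a stable")
print("nucleotide-binding scaffold rather than a turnover site.")
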