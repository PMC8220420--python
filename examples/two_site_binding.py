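"""Biphasic nucleotide binding to a dual-cassette Brr2 construct.

Simulates mant-ADP association with hBrr2-T1 (both cassettes active),
shows that the phase-count test selects a double exponential, assigns the
fast phase to the N-terminal cassette, and derives per-cassette rate
constants and the affinity table with fold ratios.
"""

from brr2allo.pipeline import KineticsRunConfig, run_kinetics

summary = run_kinetics(
    KineticsRunConfig(construct="hBrr2-T1", nucleotide="mant-ADP", seed=2),
    "scratch/two_site_demo",
)

print(f"selected phase count: {summary['n_phases']} (biphasic -> two pockets)\n")
print(summary["rate_constants"][
    ["cassette", "k1", "k1_se", "k_minus1", "provenance"]
].to_string(index=False))
print()
print(summary["affinity"][["cassette", "kd_uM", "kd_se_uM"]].to_string(index=False))
print()
print(summary["folds"].to_string(index=False))
print("\nThe fast phase (NC) binds and releases nucleotide quickly; the slow")
print("phase (CC) releases ~1000x slower, giving it a far higher affinity.")
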