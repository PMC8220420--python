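"""Recover association/dissociation rate constants from a simulated
stopped-flow titration of the isolated C-terminal cassette with mant-ADP.

Simulates the standard design (five nucleotide concentrations, seven
replicate traces each, 1% noise), fits a single exponential per averaged
trace, and regresses the apparent rates against concentration: the slope
is the association rate constant k1, the intercept estimates the
dissociation rate constant k-1, and Kd = k-1/k1.
"""

from brr2allo.kinetics.fit import TitrationSeries, fit_exponentials, \
    normalize_and_average, regress_kapp
from brr2allo.synthetic import KineticsDesign, generate_kinetics_dataset

design = KineticsDesign(construct="hBrr2-CC", nucleotide="mant-ADP", seed=42)
dataset = generate_kinetics_dataset(design, include_chase=False)

points = []
for conc in design.association_concs:
    trace = normalize_and_average(dataset.association[conc])
    fit = fit_exponentials(trace, n_phases=1)
    points.append((conc, fit.k_app[0], 0.0, 1))
    print(f"[{conc:5.1f} uM]  k_app = {fit.k_app[0]:.4f} 1/s")

reg = regress_kapp(TitrationSeries(points, "CC"))
kd_nM = reg.k_minus1 / reg.k1 * 1e3
print(f"\nslope     k1  = {reg.k1:.4f} +/- {reg.k1_se:.4f} 1/(uM s)   (truth 0.5)")
print(f"intercept k-1 = {reg.k_minus1:.4f} +/- {reg.k_minus1_se:.4f} 1/s  (truth 0.002)")
print(f"Kd = k-1/k1 = {kd_nM:.1f} nM")
print("\nThe slope recovers how fast mant-ADP binds the C-terminal cassette;")
print("the tiny intercept reflects its very slow nucleotide release.")
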