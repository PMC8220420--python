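# brr2allo

Nucleotide-binding kinetics and allosteric-communication analysis for the
two-cassette spliceosomal RNA helicase Brr2.

Brr2 is a Ski2-like helicase built from two structurally similar helicase
cassettes: a catalytically active N-terminal cassette (NC) that hydrolyses
ATP and unwinds RNA, and an inactive C-terminal cassette (CC) that still
binds adenine nucleotides and regulates the NC from ~70 Å away.  This
package implements, as one tested pipeline, the two computational analyses
used to characterise that system:

1. **Pre-steady-state binding kinetics** (stopped-flow FRET with
   mant-nucleotides).  Binding at each pocket is a one-step reversible
   reaction P + N ⇌ PN.  Under pseudo-first-order conditions every site
   contributes one exponential phase,

   F(t) = F<sub>∞</sub> + Σ<sub>i</sub> F<sub>i</sub> exp(−k<sub>app,i</sub> t),   k<sub>app</sub> = k₁[N] + k₋₁,

   so association titrations give k₁ from the slope of k_app versus [N],
   chase experiments against excess unlabelled nucleotide give k₋₁ directly
   from the decay rate, and K_d = k₋₁/k₁.  The package simulates
   realistic trace sets, averages replicates (normalised to F₀), fits 1–2
   exponentials with an extra-sum-of-squares F-test for phase count,
   assigns the fast phase to the NC, and derives rate-constant / affinity /
   fold-ratio tables.

2. **Hydrogen-bond communication graphs** from MD trajectories.  Hydrogen
   bonds are detected geometrically (donor–acceptor distance ≤ 3.2 Å,
   deviation from D–H···A linearity ≤ 42°), aggregated into residue-pair
   occurrence probabilities HB<sub>ij</sub> over an analysis window, and converted
   to communication costs C<sub>ij</sub> = −ln HB<sub>ij</sub> (covalently consecutive
   residues cost 0).  The k-shortest loopless paths between the two
   nucleotide-binding pockets (Dijkstra/Yen) trace candidate allosteric
   routes; participation frequencies, interface-crossing tallies and
   block-averaged path lengths summarise them.  RMSF with block-averaged
   SEM, dynamic cross-correlation maps, and pocket-width distance series
   (G506–G854 for the NC pocket, G1353–G1689 for the CC) cover the
   flexibility side.

Because the original 200-ns trajectories are not publicly deposited, the
structural arm ships a synthetic-trajectory generator that plants
hydrogen-bond communication structure with known ground truth; the graph
machinery is validated by exhaustive-enumeration oracles and
planted-path-recovery experiments rather than by re-deriving the original
path tables.

## Worked example

`examples/kinetics_titration.py` simulates a titration of the isolated CC
with mant-ADP (five concentrations, seven replicates, 1% noise), fits each
averaged trace with one exponential and regresses k_app on concentration:

```
[  1.0 uM]  k_app = 0.5017 1/s
[  2.5 uM]  k_app = 1.2531 1/s
[  5.0 uM]  k_app = 2.5024 1/s
[ 10.0 uM]  k_app = 5.0074 1/s
[ 20.0 uM]  k_app = 10.0018 1/s

slope     k1  = 0.5000 +/- 0.0002 1/(uM s)   (truth 0.5)
intercept k-1 = 0.0031 +/- 0.0018 1/s  (truth 0.002)
Kd = k-1/k1 = 6.2 nM
```

The slope recovers the generating association rate constant to four
digits.  The intercept is statistically consistent with the generating
k₋₁ = 0.002 s⁻¹ but, being ~1000-fold smaller than the largest k_app in
the series, is poorly determined by the titration alone — which is why
dissociation rates are measured by chase experiments
(`examples/chase_dissociation.py`):

```
NC k-1 = 1.601 1/s  (truth 1.6)
CC k-1 = 0.002006 1/s  (truth 0.002)
NC/CC dissociation fold = 798  (truth 800)
```

The other examples cover biphasic two-site fitting with automatic phase
selection (`two_site_binding.py`), planted communication-path recovery
(`communication_paths.py`) and trajectory flexibility metrics
(`trajectory_flexibility.py`).  A thin CLI wraps the same pipeline:
`brr2allo demo --seed 1 --out demo/` runs both arms end to end.

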