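# Methods

This note documents the models, numerical choices and known limitations of
the two analysis arms.

## Binding model and simulator

Each nucleotide-binding pocket is a single reversible site, P + N ⇌ PN with
association rate constant k₁ (µM⁻¹ s⁻¹) and dissociation rate constant
k₋₁ (s⁻¹).  Dual-cassette constructs are modelled as two fully independent
sites: no thermodynamic coupling term is included, because the measured
traces are fitted as sums of independent exponentials and the allosteric
effects of interest appear as *changes in the fitted rate constants between
constructs*, not as deviations from exponentiality within one trace.

Signals follow the stopped-flow FRET convention: association traces rise to
the final signal F∞ (phase amplitudes enter negatively), chase traces decay
to F∞.  Phase amplitudes are free experimental parameters; the default
NC:CC amplitude split is 0.45:0.55, reflecting the one-versus-two nearby
tryptophan FRET donors at the two pockets — a qualitative, not quantitative,
motivation, so no analysis depends on the exact split.

`model_association_ode` integrates the full mass-action system (shared
free-nucleotide pool, LSODA, rtol 1e-9) as a fidelity check of the
pseudo-first-order closed form; the two agree to <2% of amplitude whenever
nucleotide exceeds protein ≥20-fold, and the package warns (not errors)
below 10-fold excess.

The synthetic kinetics generator reproduces the experimental design:
association titrations at {1, 2.5, 5, 10, 20} µM labelled nucleotide with
0.2–0.4 µM protein, chase of a 5 µM labelled complex against 100 µM
unlabelled competitor, 1000 points in logarithmic time sampling, seven
replicates per condition, and additive i.i.d. Gaussian noise with σ = 1% of
the total amplitude.  The noise level is a package choice (no instrumental
noise spec exists for these data); at 1%, seven-replicate averages visually
match published trace quality, and all recovery results below are reported
under exactly these conditions.  Time windows are derived from the
generating constants — t_max = 7/k_slowest (≈3500 s for the CC chase, whose
k₋₁ = 2×10⁻³ s⁻¹), t_min ≤ 0.02/k_fastest — so every phase is sampled from
~2% to ~99.9% completion.

What the generator does *not* emulate: instrument dead time, photobleaching,
baseline drift, inner-filter effects, and heteroscedastic shot noise.
Passing recovery tests therefore demonstrate identifiability of the rate
constants under the stated design and noise model, not robustness to every
instrumental artefact.

## Exponential fitting and model selection

Fits minimise least squares with lmfit (Levenberg–Marquardt, xtol = ftol =
1e-10, ≤10⁴ evaluations; settings recorded in the fit object), making every
fit deterministic given the trace.  Initialisation: F∞ from the mean of the
last 5% of points; a single-phase rate seed from a log-linear regression of
|F − F∞|; two-phase seeds both from that value split ×10 / ÷10 and from the
times at which the residual amplitude crosses 60% and 10% of its initial
value (t ≈ ln 5 / k for near-equal amplitudes).  Both two-phase seedings are
fitted and the lower-χ² solution kept — rate pairs separated by three
orders of magnitude (NC vs CC dissociation) otherwise trap the optimiser in
a one-phase-like local minimum.  Phases are always reported fast → slow;
rates are bounded positive, and hitting a bound flags the fit.

Phase count: the published criterion ("best fits, lowest SEMs") is
informal, so the package uses an extra-sum-of-squares F-test at α = 0.01
*plus* a ≥3-fold rate-separation guard; both statistics are retained.  On
pure-noise traces the 1-phase model survives in ≥95% of seeds.

k₁ comes from ordinary least squares of mean k_app on concentration
(optional 1/SD² weighting); the intercept estimates k₋₁ but chase-derived
decay rates are authoritative whenever available, because the intercept of
a titration dominated by large k_app values carries little information
about a small k₋₁ (see the worked example in the README).  Negative
intercepts are flagged, not rejected.  K_d = k₋₁/k₁ with standard errors
propagated in quadrature.  Uncertainty over replicates follows the
mean ± SD convention of the source experiments.

The published rate-constant and affinity tables bundled in
`kinetics.reference` serve as generating truths and calibration.  Note the
printed K_d values were computed from unrounded rates: for three entries
(isolated-NC ATPγS, isolated-CC ATPγS, full-length CC ADP) recomputing
k₋₁/k₁ from the rounded printed rates deviates from the printed K_d.
Fold-ratio arithmetic on printed affinities therefore uses the printed K_d
table directly.

## Hydrogen-bond occupancy and communication graphs

A hydrogen bond D–H···A is scored when dist(D, A) ≤ 3.2 Å **and** the
deviation from linearity — defined as 180° minus the angle at H between
H→D and H→A — is ≤ 42°.  Both cutoffs are inclusive ("maximal"/"maximum").
Donors are N/O heavy atoms with a covalently bound hydrogen (sulfur
optional, off by default); acceptors are all N/O heavy atoms.  No
periodic-boundary imaging is applied; inputs are assumed whole (solvated
monomeric protein).  Water-mediated bridges and non-protein nodes
(nucleotides, ions) are excluded from the graph by default because the
path endpoints of interest are protein residues; this is a modelling
choice, exposed as a flag.

Occupancy aggregation over a window is `frame-union` by default (a frame
counts if *any* bond bridges the residue pair) with `max-single-bond`
(highest per-(D,H,A)-triplet occupancy) as the alternative; union ≥ max
always holds.

The communication graph is undirected: nodes are residues, hydrogen-bond
edges cost −ln HB_ij, covalently consecutive residues cost 0, and a pair
with both keeps the zero cost.  HB_ij = 0 yields no edge; probabilities are
never clamped, so zero-cost hydrogen-bond edges (HB = 1) are legal.
k-shortest loopless paths are generated by Yen's deviation search
(networkx `shortest_simple_paths`); because zero-cost covalent edges create
cost ties, generation continues past the k-th path while costs tie and the
final ranking is by (cost rounded at 1e-9, path length in residues,
lexicographic residue sequence), which makes the output deterministic and
lets tests compare it against exhaustive simple-path enumeration.  Block
statistics build one occupancy matrix and graph per contiguous temporal
block (canonically five 20-ns blocks over the final 100 ns) and report
mean ± SEM of the per-block average path length; pathless blocks are
excluded and reported.

## Flexibility metrics

Global motion is removed by least-squares rigid-body superposition
(proper rotations only, via quaternion alignment), referenced to the first
frame or an iterated mean structure.  RMSF_i = √⟨|r_i − ⟨r_i⟩|²⟩ is
computed per block with each block's own mean as fluctuation reference
(default), so the between-block SEM measures sampling error of a
stationary process; a whole-window-mean reference is available by flag.
Cross-correlation uses the standard 3D dynamic cross-correlation
definition C_ij = ⟨Δr_i·Δr_j⟩/√(⟨|Δr_i|²⟩⟨|Δr_j|²⟩); zero-variance atoms
are flagged undefined rather than silently zeroed.  Pocket widths are
per-frame Cα–Cα distances (NC: G506–G854; CC: G1353–G1689 on
Brr2-numbered structures) with block SEMs.

## Synthetic trajectories and planted networks

The structural-arm generator builds a toy two-cassette pseudo-protein
(default 30 + 30 residues, numbered 401… and 1301… so the standard
NC/CC partition at residue 1282 applies).  Each residue carries CA, an
N–H donor and an O acceptor on a 20 Å grid, so no accidental contacts
occur.  One interface hydrogen bond is planted at occupancy p_path
(default 0.95); decoy interface bonds and random intra-cassette bonds form
a background at occupancy ≤ p_bg (default 0.3).  In trajectory mode the
planted bonds toggle between a bonded geometry (D–A = 2.9 Å, linear) and
a broken one (6.5 Å) per frame as Bernoulli(p) draws, plus Gaussian
positional jitter (default 0.05 Å; capped at 0.3 Å to keep planted
geometry inside the detection criterion).  The fast occupancy-network mode
skips geometry and emits binomially sampled occurrence frequencies
directly — which also makes the negative control honest: at
p_path = p_bg the planted crossing wins only at chance level against the
decoys.

Because covalent edges cost zero, the planted communication chain is the
backbone route from source to the planted interface pair to target; its
recovery as the rank-1 path tests exactly the property that matters —
that the cheapest interface crossing determines the communication route.

These toys exercise detection geometry, occupancy estimation, graph
construction and path ranking with known truth.  They do not emulate
force-field physics, correlated bond dynamics, side-chain chemistry or
solvent, so planted-recovery results say nothing about whether real MD
sampling was sufficient — only that the analysis chain is correct.

## Problem sizes

Recovery experiments use 50 seeds × 7 replicates × 1000-point traces;
graph property suites use 100 random graphs of ≤8 nodes (exhaustive
oracle) and 100 planted networks of 60 residues.  These sizes give
sub-percent medians and binomial error bars of a few percent while the
full test suite and the acceptance script each complete in well under a
minute of CPU.
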