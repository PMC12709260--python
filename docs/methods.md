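# Methods

This note documents the models, estimators and numerical choices behind
`idplens`, and what its synthetic data do and do not establish about real
ensembles.

## Scope and data model

The package analyses conformer ensembles of a single peptide chain. The
in-memory currency is an `Ensemble`: a stack of coordinate frames
(Angstrom) over a shared reduced topology of backbone atoms N, H(amide),
Cα, C, O plus a Cβ pseudo-atom per non-glycine residue. Side-chain mass
beyond Cβ (and the α-hydrogen and terminal extras) is lumped onto the Cβ
(Cα for Gly) so the topology's total mass equals the peptide molecular
weight; the SAXS module performs the analogous lumping in electrons.
Full-atom topologies read from PDB are also accepted by the observable
modules, which key radii and form factors on elements.

Physical units are explicit throughout and in config keys (`trim_ns`,
`cutoff_nm`, `rg_target_A`) because the field conventionally mixes
Angstrom (Rg, SAXS q) and nanometres (RMSD, SASA, cluster cutoffs).

## Sequence annotation

Hydropathy uses the Kyte–Doolittle scale; charges are the integer
neutral-pH assignment (Asp/Glu −1, Lys/Arg +1, His neutral by default,
+1 behind a flag; +1/−1 for charged N/C termini). No fractional titration
is attempted — the model mirrors classical MD protonation choices. The
packaged 35-mer AICD fixture carries net charge −2e with YENPTY at
residues 22–27. Average (not monoisotopic) residue masses are the default
because the mean residue weight MRW = MW/(L−1) feeds the CD concentration
normalization.

## Synthetic conformer generator

The generator replaces an MD engine. Chains are built from per-residue
(φ, ψ) by natural-extension-reference-frame placement with ideal geometry
(N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å; ω = 180°; amide H and carbonyl
O in the peptide plane, anti to one another; Cβ at the tetrahedral
L-position). An ideal α-helix built this way shows i→i+4 O···H ≈ 2.1 Å
and a fully extended chain grows ≈3.65 Å per residue.

Sampling is a per-replica Markov chain: single-residue (φ, ψ) redraws
from a four-basin Gaussian mixture — αR (−63, −43) weight 0.30, β
(−120, 130) 0.35, PPII (−75, 150) 0.25, αL (60, 45) 0.10, σ = 15° —
rejected when any heavy-atom pair ≥2 residues apart comes within 2.8 Å,
with an optional Metropolis factor exp(−k(Rg−Rg₀)²) (k in kBT/Å²). The
stationary distribution is therefore the basin mixture restricted to
clash-free chains and tilted by the Rg bias. Frames are recorded every 2
accepted moves after 300 moves of burn-in, so the series is autocorrelated
by construction (lag-1 Rg autocorrelation ≈ 0.3), which is what the
time-lagged analyses require. Replica r uses the stream `seed + r`:
replicas are independent but the ensemble is bit-reproducible.

Defaults (5 replicas, the basin mixture above, 10 ps pseudo-time per
frame) emulate the study conditions of a five-replica disordered-peptide
simulation with transient secondary structure. What the generator does
*not* emulate: side-chain packing, solvent, electrostatics, realistic
kinetics. Tests passing on synthetic ensembles validate the estimators
and bookkeeping, not force-field accuracy.

Two measured consequences of the excluded-volume term worth knowing:
compact basins are suppressed relative to their proposal weights (αR
marginal drops by ≈0.08 at default settings), and the Rg distribution of
the unbiased chain centres near 17 Å for the 35-mer.

## Trimming and decomposition

Replica trimming discards frames with pseudo-time strictly below the
cutoff (a frame exactly at 300 ns is kept); survivors concatenate in
replica order. At full scale, 5 replicas × 100,000 frames at 10 ps minus
300 ns each gives exactly 350,000 frames. Frames are binned to the
nearest integer-Angstrom Rg (half-up at .5); index files are written
1-based in GROMACS NDX form while all in-memory numbering is 0-based. Rg
is mass-weighted over all atoms (gmx-gyrate convention); a Cα-only
selection is available. The RMSD reference defaults to the first
post-trim frame — the natural choice when no external reference exists.

## SAXS

The Debye sum uses Cromer–Mann form factors with an excluded-volume term
f_eff = f_CM(q) − ρ_s V exp(−q²V^(2/3)/4π), ρ_s = 0.334 e/Å³, Fraser
volumes; hydration-shell contrast is fixed at zero (no shell model exists
in this package). Missing side-chain atoms of the reduced topology are
absorbed into the Cβ scatterer by summing the Cromer–Mann factors and
volumes of the absent atoms, so the lumped f(0) equals the residue's
missing electron count plus carbon's; charged-termini extras (2 H, 1 O)
go to the first/last residue. A `vacuum` flag disables the
excluded-volume term (used by closed-form tests) and a
`constant_contrast` flag freezes every atom at f(0) — the point-scatterer
model under which I(q) and P(r) are exact Fourier mates.

The default q grid is 100 log-spaced points on 0.0078–0.495 Å⁻¹,
mirroring a typical measurement re-binned to 100 points. Guinier fits
iterate on the window qRg < 1.3 starting from the low-q decade (starting
from the full range can lock onto a spurious fixed point when the curve
has wide-angle structure); for strongly anisotropic scatterers such as a
two-point dumbbell the regime is qRg < 1. χ² is implemented literally
with the simulated-intensity denominator, Σ(Eᵢ−Sᵢ)²/Sᵢ², with an optional
least-squares scale factor c = ΣES/ΣS² applied to S first; a
conventional σ-weighted reduced χ² is a separate function.

P(r): the indirect transform expands P in sines vanishing at 0 and Dmax,
solves a ridge system with an analytic curvature penalty (coefficient
`alpha`), and optionally re-solves on the r-grid under non-negativity
(NNLS). A free q-independent column absorbs atomic self-scattering — a
delta at r = 0 that no basis vanishing there can carry; without it the
fit rings at small r. P is returned in fit units (not area-normalized) so
that `alpha → ∞` sends P → 0 identically. The direct route histograms all
interatomic distances weighted by f(0)f(0) and normalizes to unit area.
Cross-validation of the two routes is performed at constant contrast on a
compact ensemble: with q-dependent form factors the indirect peak shifts
by 2–3 Å (contrast decay that P(r) theory does not model), and a broad
disordered P(r) has a nearly flat top on which an argmax comparison is
ill-conditioned.

## SASA, contacts, hydrogen bonds, secondary structure

Shrake–Rupley with 960 golden-spiral sphere points, probe 1.4 Å, Bondi
radii; outputs in nm². Agreement with an independent implementation
(mdtraj) is within 0.2% on 35-residue frames; the isolated-sphere
analytic case is exact to discretization (<0.5%). Rotating a frame
changes values only through the fixed orientation of the point set
(≤ a few %); translations are exact. Group summaries subtract the
unweighted mean over group means ("each Rg group counts once"); a
frame-weighted variant is behind a flag.

H-bond maps use the geometric criterion donor–acceptor(N···O) ≤ 3.5 Å and
H–N···O angle ≤ 30° (GROMACS hbond defaults), occupancy per residue pair.
Secondary structure uses the Kabsch–Sander electrostatic energy
E = 27.888(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond if
E < −0.5, and collapses to five classes: helix (two consecutive n-turns,
n = 3, 4, 5 folded together), strand (parallel/antiparallel bridges,
isolated bridges included), turn (residues spanned by isolated n-turns),
bend (>70° Cα-trace direction change), coil. Priority helix > strand >
turn > bend. On ideal helix and hairpin fixtures the labels match a full
DSSP implementation exactly after collapsing its eight classes the same
way.

## Ramachandran fractions and J-couplings

Ramachandran statistics use interior residues (both dihedrals defined) on
a 72×72 (5°) grid; region fractions count raw points inside named
rectangles. The default rectangles are narrow literature-style regions
(αR [−100,−30]×[−67,−7], β [−180,−90]×[90,180], PPII [−90,−20]×[120,180],
αL [30,100]×[7,67]) and are configuration — not measurement — choices:
with σ = 15° basins leak outside them, and β/PPII overlap intrinsically,
so *parameter-recovery* experiments instead use rectangles that partition
the basin supports (β/PPII split at φ = −97.5°) and sample with the
hard-core radius at a negligible value, recovering the configured weights
within 0.03 at 10⁴ dihedrals.

Karplus equations are evaluated literally as printed coefficients
(³J: A=6.4, B=−1.4, C=1.9; ²J: A′=2.0, B′=−0.5, C′=0.5 Hz) with an
angle-offset parameter defaulting to 0; the conventional ³J(HN–Hα)
relation uses θ = φ − 60°, so the offset is exposed for sensitivity
analyses. With defaults, ³J ranges over [1.823, 9.7] Hz.

## CD

Δε = CD(mdeg)·MRW/(32980·l·c) exactly, with the constant as printed.
Ensemble spectra are fraction-weighted sums of per-class basis curves;
because the model is linear, frame-wise and mean-fraction averaging are
identical. The packaged basis curves are synthetic parametric band shapes
(Gaussian sums reproducing helix 192+/208−/222−, strand 195+/217−, coil
198−), declared as such in the module; they support exact linear-algebra
round-trips and qualitative ensemble spectra, not quantitative
deconvolution of measured data. Decomposition is non-negative least
squares with fractions constrained to sum ≤ 1. The five structure classes
map onto the four-class basis by folding bend into coil.

## tICA, landscapes, clustering

Features default to sin/cos of backbone dihedrals: interior residues
contribute all four terms (4(L−2) features); the two chain-end singleton
angles (ψ₁, φ_L) enter as cosines only, giving 4(L−2)+2 — a documented
convention keeping the end angles at half weight. A Cα-distance scheme
(|i−j| ≥ 2) is the alternative. Lagged pairs never straddle replica
boundaries. The estimator symmetrizes the lagged covariance,
C_τ = (C(τ)+C(τ)ᵀ)/2, and solves C_τ v = λ(C₀+εI)v, so eigenvalues are
real and bounded by 1 up to numerical noise and eigenvectors are
C₀-orthonormal — a deliberate estimator choice accepting a small downward
bias for guaranteed spectral sanity. On AR(1) fixtures the leading
eigenvalue recovers the lag-τ autocorrelation a^τ within sampling error.
Default lag: 100 frames, reported in all outputs.

Free-energy surfaces are −ln(ρ/ρ_max) in kBT over 2D histograms; empty
bins are undefined (NaN), never infinite, and the occupied minimum is
exactly 0. GROMOS (Daura) clustering computes the full superposed-RMSD
matrix (batched 3×3 SVD Kabsch, memory-chunked), repeatedly takes the
frame with the most neighbours within the cutoff (0.9 nm default; ties to
the lowest frame index) and removes the cluster. It is O(n²), so
ensembles beyond `max_frames` (20,000 library default; 2,000 in the
pipeline) are strided, and the stride is recorded in the result.

## Pipeline and reproducibility

`run_pipeline` executes thirteen stages (sequence profile, generate,
trim/concat, decompose, SAXS, P(r), SASA, contact+H-bond maps, secondary
structure, Ramachandran+J-couplings, CD, tICA/FES, clustering) and writes
a manifest with the verbatim config, its hash, the seed, library versions
and per-stage frame counts — sufficient to re-run bit-identically. A
stage failure halts the run naming the stage, preserving earlier outputs.
Observable stages stride the trimmed ensemble (defaults: every 10th frame
for SASA/secondary structure, every 10th for the global SAXS average) —
problem sizes chosen so the 5×2000-frame desk-scale fixture completes in
a few minutes on one CPU; strides are configuration and appear in the
manifest.

## Known limitations

- The reduced topology has no rotameric side chains; SASA variance and
  hydrophobic-burial effects at side-chain resolution are out of reach.
- The SAXS model has no hydration shell; comparisons to measured curves
  of hydrated proteins will be biased at mid-q.
- CD basis curves are synthetic shapes; decomposition of experimental
  spectra is qualitative.
- Generator kinetics are Monte-Carlo artifacts: autocorrelation is
  controlled, but timescales carry no physical meaning, so tICA
  eigenvalues on synthetic data characterize the chain, not a molecule.
- The χ² statistic with the simulated-intensity denominator is not the
  σ-weighted reduced χ² of standard SAXS practice; both are provided and
  must not be compared across definitions.
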