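# Methods

## The measurement being modelled

Off-resonance R1ρ relaxation dispersion detects sparsely populated,
short-lived ("excited") conformational states in exchange with an
observable ground state. A spin-lock field of amplitude ω₁ = 2π·power is
applied at an offset Ω = ω_obs − ω_rf from the observed resonance;
magnetization prepared along the tilted effective field (angle
θ = atan2(ω₁, Ω) from +z) decays mono-exponentially at the rotating-frame
rate R1ρ. Exchange with an unseen state of population p_ES, exchange rate
k_ex = k₁ + k₋₁ and chemical-shift difference Δω = ω_ES − ω_GS adds an
Rex contribution whose dependence on power and offset encodes all three
parameters. Profiles are displayed as
(R2 + Rex) = (R1ρ − R1·cos²θ)/sin²θ against Ω/2π.

The application here is the wobble G·T mismatch in DNA duplexes: the
ground-state wobble exchanges with Watson–Crick-like tautomeric and (at
high pH) anionic species, and base carbons/imino nitrogens can also
passively sense Watson–Crick→Hoogsteen flipping of a neighboring G-C pair
("Hoogsteen blowback"), which enters the model as a second excited state
in a star topology.

## Bloch–McConnell engine

Magnetization of n exchanging states (n = 2 or 3) evolves under
dM/dt = Γ M with Γ = blockdiag(Lᵢ) + K ⊗ I₃. Each 3×3 block Lᵢ carries
−R2 on the x,y diagonal, −R1 on z, the state-specific offset
Ωᵢ = Ω_GS + 2π·Δωᵢ·ν_larmor·10⁻⁶ coupling x↔y, and ω₁ coupling y↔z
(spin-lock along +x; positive Ω rotates x into y). K is the exchange rate
matrix built from detailed balance: for each connected pair,
k_{i→j} = p_j/(p_i+p_j)·k_ex, which reduces to k₁ = p_B·k_ex for two-state
exchange and has the model populations as its stationary vector for every
topology (for the triangular B–C edge the two involved populations are
renormalized over that pair, adding no parameters).

The homogeneous form (no thermal-recovery constant) is used: dispersion
experiments measure relative decay of magnetization prepared at exchange
equilibrium — the experimental 5 ms equilibration delay is modelled by
starting from the equilibrium population vector tilted along the effective
field, pᵢ·(sinθ, 0, cosθ).

R1ρ is computed by two independent routes:

* **eigenvalue** (default, used inside fitting): expand the tilted initial
  condition in the eigenbasis of Γ and take −Re(λ) of the mode carrying
  the largest amplitude along the detection axis. Selecting by overlap
  rather than by smallest |Re(λ)| avoids latching onto spurious slow modes
  in three-state systems. The grid version stacks all conditions into one
  batched eigendecomposition.
* **decay-fit**: propagate (via eigendecomposition of Γ, equivalent to the
  matrix exponential to ~1e-14), project onto the initial effective-field
  axis at each delay, and fit a mono-exponential — mirroring how real data
  are reduced. Non-monotonic projections (oscillatory regime) raise a
  warning.

The two routes agree within 1% over standard grids; the engine also
matches the algebraic Laguerre second-order expression (implemented
independently in `approximations.py`) within 2% in fast exchange, and the
no-exchange identity R1ρ = R1cos²θ + R2sin²θ to 1e-6 at effective fields
of a few kHz (the identity itself carries O(((R2−R1)/2ω_eff)²)
corrections, visible below ~1 kHz).

Alignment of the tilt/detection axis: `gs` (ground-state offset), `avg`
(population-weighted offset), or `auto`, which selects `avg` when
k_exAB ≥ |Δω_AB| in rad/s. The exact criterion used in the original
protocol is not published; the threshold is configurable and both explicit
modes are available for sensitivity checks. For the sparse excited states
studied here (p ≤ 8%) the two references differ by a few Hz at most.

## Decay reduction and σ_R1ρ

Peak intensities at 3–10 delays are fit to I(t) = I₀·exp(−R1ρ·t)
(negative rates are kept, with a warning — dropping them would bias flat
profiles). σ_R1ρ comes from a seeded Monte-Carlo scheme: noisy replicas of
the best-fit curve are refit and σ is the SD of the replica rates.

The noise amplitude can be estimated three ways, in decreasing order of
reliability: passed explicitly (as from spectral baseline or duplicate
scans), pooled over the mono-exponential residuals of a nucleus's whole
grid (default in `reduce_dataset` — thermal noise is a property of the
spectrum series, not of one condition; pooling gives the estimate hundreds
of degrees of freedom), or taken from the residuals of the single series.
The last option carries only n−2 ≈ 6 degrees of freedom, which makes
(R1ρ−truth)/σ t-distributed rather than normal and drops the 1.96σ
coverage from 95% to ≈90% — a small-sample effect users should be aware of
when only single short series are available. The coverage calibration
experiment (500 synthetic decays) uses the known-amplitude route and
measures ≈95%.

## Dispersion fitting

χ² = Σ ((R1ρ,meas − R1ρ,calc)/σ)² over all power/offset combinations of
all nuclei. Populations and exchange rates are global (shared across
nuclei); R1, R2 and per-nucleus Δω are local; any parameter may be fixed —
the blowback state is typically pinned (p_C, k_exAC) from an upstream
two-state fit of a reporter nucleus, with its Δω_AC left free per nucleus
(both fixed and shared-free modes are supported).

These objectives are multimodal (Δω sign, the p·Δω² trade-off, and for
the star topology an exact B↔C label permutation), so:

* fits run from 10 seeded starts — the user/default initial plus
  Latin-hypercube samples (log-scale for populations and rates) — in two
  stages: a cheap probe per start (250 evaluations) and a full polish
  (5000 evaluations, ftol 1e-8) of the best two endpoints;
* the optimizer is trust-region least squares with jacobian-based
  parameter scaling and finite-difference step 1e-5 (parameters span six
  decades);
* after convergence a refit with all Δω_AB signs flipped is run; the fit
  is flagged `dw_sign_degenerate` when |χ²(+) − χ²(−)| < 1;
* the star label permutation is broken, when the two excited states have
  known identities, by ordering bounds — in the high-pH application slot B
  is the sparse fast tautomer (p ≤ 1%, k_ex ≥ 1000/s) and slot C the
  populous slower anion — and by starting Δω at the values known from
  prior characterization of the trapped species. Without such priors a
  16-parameter three-state fit can settle in chimeric basins that mix the
  two states' signatures.

Default bounds: populations (1e-7, 0.499) — the excited state is by
definition minor, which also prevents label swap with the ground state;
rates (1, 5e4)/s; Δω ±30 ppm (¹³C) / ±100 ppm (¹⁵N); R1 (0.01, 50)/s,
R2 (0.1, 500)/s. The published analysis does not state bounds; these are
design choices wide enough not to bind in the studied regimes.

**Monte-Carlo uncertainties**: n_mc parametric replicas (each point ~
Normal(back-calculated value, σ); measured-centered replicas optional) are
refit from the best-fit start; the uncertainty is the SD of replica
parameters. Parameters whose 95% interval includes zero are listed as
poorly determined — in the high-pH regime this flags the tautomer Δω of
the sugar ¹³C probe, whose ~0.5 s⁻¹ peak contribution at p = 0.075% and
k_ex ≈ 4000/s is buried in the noise, reproducing the identifiability
limit seen experimentally.

**Model selection**: with per-point σ known, AIC = χ² + 2k and
BIC = χ² + k·ln N (constant terms cancel); weights
wᵢ = exp(−Δᵢ/2)/Σexp(−Δⱼ/2). Small-sample AICc is not applied (not stated
in the source analysis). A triangular fit on star-generated data converges
to the star optimum with kex_BC at its lower bound and loses on parsimony.

**pKa**: computed post hoc from the fitted anionic population at the
measurement pH via Henderson–Hasselbalch, pKa = pH − log₁₀(p/(1−p));
8.019% at pH 8.8 gives 9.86 ≈ 9.9.

## Synthetic data and the experiments

The generator emulates the acquisition rules: delays equally spaced from 0
to min(−ln(1−0.70)/R1ρ, cap) with caps of 60 ms (¹³C) and 120 ms (¹⁵N);
default spin-lock grids of 5–6 powers spanning more than a decade
(¹³C 150–3600 Hz, ¹⁵N 100–1600 Hz) with 13 offsets per power out to
±3.5×power, denser near resonance. The real measurements used
instrument-specific grids that are not published in the main text; the
defaults are config-overridable so real tables can be dropped in. Noise is
Gaussian on intensities at 2% of I₀ by default — constant amplitude
("additive", thermal peak-height noise; a multiplicative option exists).
Forward R1ρ for generation uses the eigenvalue route while reduction goes
through decay fitting, keeping the round trip cross-method.

Preset truths define the three study regimes at 700 MHz:

1. **two-state tautomer**: p_B = 0.2%, k_ex = 1000/s, Δω = 2 ppm ¹³C;
2. **star + blowback**: shared wobble→WC-like process (0.2%, 1600/s) and a
   fixed blowback state (0.4%, 3000/s) sensed by two imino ¹⁵N probes
   (Δω_AB 35–40 ppm) and one sugar ¹³C. The ¹⁵N probes are essential:
   with ¹³C-only probes at ~2 ppm the (p_B, k_ex) likelihood ridge is
   nearly flat at 2% noise (noiseless model separation Δχ² ≈ 34 over 234
   points between basins) and no optimizer can recover the truth;
3. **high-pH star**: tautomer 0.075%/4029 s⁻¹ and anion 8.019%/500 s⁻¹,
   ¹⁵N Δω up to ±56 ppm, one ¹³C probe with weak tautomer signal.

Recovery experiments score each parameter as z = (estimate − truth)/MC-SD;
acceptance gates the shared global parameters at |z| ≤ 3. The topology-
selection experiment uses a triangular truth with p_B = 0.5% and
k_ex,BC = 4000/s — at the high-pH populations a direct B↔C rate is
invisible (the star model fits triangular data at reduced χ² ≈ 1), so
resolvability requires a non-negligible minor-state flux.

What the generator does not emulate: Hartmann-Hahn transfer efficiency,
¹H decoupling imperfections, solvent-exchange broadening, peak overlap,
temperature/field drift, and non-Gaussian spectral artifacts. Passing
recovery tests therefore demonstrates correctness of the estimation chain
under its own statistical assumptions, not robustness to systematic
experimental error.

## Structure survey

Torsions use the standard atom definitions (ε C4′-C3′-O3′-P₊₁,
ζ C3′-O3′-P₊₁-O5′₊₁, γ O5′-C5′-C4′-C3′, χ O4′-C1′-N9-C4 for purines /
O4′-C1′-N1-C2 for pyrimidines, ring ν0–ν4) with an alias map for old-style
names (O3* etc.); missing-atom torsions are NaN, never zero — terminal
residues simply lack ε/ζ. The dihedral follows the IUPAC sign convention
and is computed with the atan2 formulation; it is invariant under chain
reversal and changes sign under mirror reflection (tested as such).

Sugar pucker uses the ν₂ = ν_max·cos(P) convention, recovered by
least-squares projection of the five ring torsions onto the cosine basis —
exact on ideal sugars, stable to ±2–3° under 0.01 Å coordinate jitter.
BI/BII: both ε and ζ are wrapped to [0°, 360°), the difference ε−ζ is
wrapped to [0°, 360°), and the phosphate is BII iff the difference lies in
the closed window [20°, 200°] (the endpoints are measure-zero in real
data). The flanked-mismatch filter takes a DSSR-style annotation table
(pair classes are consumed, never computed here), applies an optional
resolution ≤ 3 Å cut, and returns wobble G·T/T·G pairs with ≥2 consecutive
Watson–Crick pairs on both sides. Superposition is Kabsch
(scipy Rotation.align_vectors); the default atom set for triplet
superposition is the ribose heavy atoms of the four flanking residues
(the exact subset used originally is not enumerated; it is configurable).

`idealized.py` provides the idealized reference geometry as a generator
rather than a static file: nucleotides are built from internal coordinates
(NeRF), the furanose ring as a pentagon with out-of-plane displacements
calibrated against the package's own pseudorotation convention, and
strands are chained through exact three-point placement of each
phosphodiester junction so that every ε/ζ/α/γ/χ/pucker value is a known
construction parameter. The complementary strand is positioned by
least-squares so the central pair's C1′–C1′ distance is exactly 10.5 Å
(flanking pairs land at 9.2/11.9 Å). This synthetic geometry is
B-form-like, not a refined structure; it exists to validate the survey
code end to end, PDB I/O included.

## Problem sizes and runtimes

Defaults were chosen so a full run completes on a single CPU in minutes:
recovery experiments use 65–78 grid points per nucleus, 60 Monte-Carlo
replicas per reduced point, 10 fit starts and 25–40 parameter-MC replicas
(SD estimates then carry ~15% sampling error, which the |z| ≤ 3 gate
absorbs); the coverage calibration uses 500 decays × 80 replicas. All
randomness flows from explicit integer seeds; rerunning any experiment or
CLI command with the same seed is bit-reproducible at the report level.
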