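# Methods

## Observables and corrections

The primary observable throughout is the proximity ratio
P = I_A / (I_A + I_D): the fraction of photons detected in the acceptor
channel, uncorrected for the detection factor γ. P is a monotone proxy
for the FRET efficiency E = 1/(1 + (R/R₀)⁶); the two are related by
P = γ/(γ − 1 + 1/E) with γ = (η_A φ_A)/(η_D φ_D). γ defaults to 1
because P, not E, is the stability readout — absolute dye distances are
never needed for c₁/₂ extraction or subpopulation fractions.

Ensemble intensities are corrected in the standard composition:
background is subtracted per channel first, crosstalk α is applied to
the *background-subtracted* donor signal, and the direct-excitation term
δ uses the background-subtracted acceptor-excitation signal:

    I_D,corr = I_D^Dex − bkg_D
    I_A,corr = I_A^Dex − bkg_A − α·I_D,corr − δ·(I_A^Aex − bkg_AA)

Corrected intensities are deliberately **not clamped** at zero; the
proximity-ratio histogram therefore spans [−0.1, 1.1) so that
correction-induced values outside [0, 1] remain visible rather than
piling up at the edges. α and δ are configuration inputs; when a plate
contains control wells they are estimated from them (buffer wells →
backgrounds, donor-only wells → α, acceptor-only wells → δ).

## Burst search

Bursts are maximal clusters of photons — donor and acceptor channels
merged — in which every consecutive inter-photon gap is strictly less
than 120 µs; clusters of at least 50 photons become bursts. "Mutual
separation" is interpreted as consecutive gaps in the merged sequence,
and the inequality is strict (a gap of exactly 120 µs splits). Per-burst
background subtraction uses expected counts = channel background rate ×
burst duration; crosstalk removes α times the corrected donor counts
from the acceptor channel. Each burst contributes exactly one P value to
the histogram (no size weighting), and bursts with P outside [0, 1] are
retained. Bins are half-open, left-closed, width 0.02.

## Mixture decomposition

Histograms are decomposed by least-squares fitting of a sum of three
Gaussians to the binned frequency curve at bin centers — matching the
histogram-fitting convention of the measurement — rather than by
per-burst likelihood. Subpopulation fractions are relative **areas**
(amplitude × σ√(2π)), not amplitudes. Bounds: means in [−0.1, 1.1],
σ in [0.01, 0.3]; initialisation at the canonical subpopulation
positions (0.12, 0.39, 0.64). Components are labeled LF < MF < HF by
ascending fitted mean; a component whose area falls below 10⁻³ of the
total is reported with fraction 0, labeled by its initialisation
position (its fitted mean is unconstrained in that regime), and a
two-component robustness re-fit is run and flagged — never substituted.
Two means closer than 0.02 set a degeneracy flag. Each salt condition is
fit independently; σ is not shared across conditions. The disassembly
statistic is HF/(MF+HF): the share of partially disassembled nucleosomes
among those not yet fully dissociated (LF excluded by construction).

## Salt titration

Replicate-level tables are aggregated per concentration, normalised by
the mean P over points at ≤ 100 mM NaCl (low-salt plateau ≡ 1 — the
normalisation reference is a package choice), and fitted with the
four-parameter logistic

    P(x) = P(0) + (P(∞) − P(0)) / (1 + exp((c₁/₂ − x)/b)).

The sign convention is resolved after fitting so that P(0) is always the
low-salt plateau and c₁/₂ the midpoint regardless of the optimiser's
parameterisation; c₁/₂ falling outside the fitted span sets an
`extrapolated` flag. Initial values come from the data (end-point
plateaus, span midpoint, b = span/20).

**Weighting.** The fit is unweighted by default. Weighting residuals by
1/sd² of the replicates is available (`weighting="1/sd2"`, with a 10⁻³
SD floor), but with three replicates the SD estimates are so noisy that
weighting by them inflates the spread of recovered c₁/₂ roughly
six-fold on the reference simulation protocol and makes the reported SE
anti-conservative; under homoscedastic replicate noise the unweighted
fit is the correct estimator. Both the single-fit covariance SE and, in
workflows with replicate series, the SEM over replicate fits can be
reported; construct comparisons use pairwise z = Δc₁/₂ / √(SE₁² + SE₂²)
with |z| < 2 flagged "coinciding".

## MD geometry operators

Coordinates are nm, times ps. The hydrogen-bond criterion is the
GROMACS-conventional geometric one — donor–acceptor heavy-atom distance
≤ 0.35 nm **and** hydrogen–donor–acceptor angle ≤ 30° — since analyses
of this kind rarely state it explicitly; both cutoffs are configurable.
Hydrogens are associated with their donor geometrically (same residue,
< 0.12 nm). Occupancy is the fraction of frames in the inclusive
analysis window (default 20–150 ns, the production segment after
equilibration) in which *any* qualifying bond exists for a
donor–acceptor residue pair. Contacts are heavy-atom pairs strictly
below 0.35 nm. DNA-arm segments are 5-bp windows (1–5, 6–10, 11–15,
16–20) counted 1-based from each terminus inward; bp i pairs residue i
(5′→3′) of strand 1 with residue N+1−i of strand 2, and each segment's
center of mass includes all atoms of both strands' residues (heavy-only
is an option). Running averages are trailing means over the preceding
200 ps, output on the input time base. Trajectories are assumed whole
and unwrapped; an orthorhombic box can be supplied for minimum-image
distances. Frames are weighted uniformly.

## Synthetic generators

The generators define the reference conditions under which the pipeline
is validated:

* **Photon streams** — per burst: species drawn by weight, size uniform
  on [50, 150] photons, true P drawn from a normal truncated to [0, 1]
  (extra width 0 by default, i.e. pure shot noise), photons assigned to
  the acceptor channel as Bernoulli trials at that P. Intra-burst gaps
  are exponential with mean 10 µs and inter-burst gaps exponential with
  mean 10 ms, so the two time scales bracket the 120 µs threshold by an
  order of magnitude on each side; specs whose mean intra-burst gap
  reaches the threshold are refused. Background photons are superposed
  Poisson processes (rate 0 by default). The generator emulates burst
  statistics only — not diffusion paths, optics, or dye photophysics
  (blinking/bleaching), so passing recovery tests demonstrates
  correctness of the analysis chain, not robustness to photophysical
  artifacts in real data. With these rates ~1% of burst pairs merge
  (inter-burst gap < 120 µs) and a few per 10⁵ split, which perturbs the
  recovered means by well under the 0.01 validation tolerance.
* **Titrations** — the logistic evaluated at 13 concentrations
  (5, 100, 200, …, 1200 mM) plus N(0, 0.02) noise per replicate, 3
  replicates: the reference measurement design.
* **Toy trajectories** — ≤ 200-atom scripted systems: an H-bond triad
  bonded in a known random subset of frames, a mock 20-bp duplex whose
  base-pair positions coincide so segment COM distances are exact by
  construction (4.0 nm and 2.0 nm pairs), and seeded random walks for
  brute-force contact comparisons.

## Validation sizes and numerical choices

Recovery checks use 200 simulated titrations per construct parameter
set (60 in the faster unit-test variant), 30 000 bursts for the
full-pipeline mixture recovery, and 50 seeded random streams of up to
10⁴ photons for exact equivalence with an independent double-loop burst
finder. Mixture and titration fits use Levenberg–Marquardt
(`lmfit`); non-convergence is reported as a flag with the last iterate,
never raised. Empty histograms carry NaN frequencies and an `is_empty`
flag. Degenerate inputs (flat titrations, < 5 concentrations, < 3
nonzero bins, unsorted photon streams) are rejected with explicit
validation errors.

## Known limitations

* The burst search is the gap-threshold method only; sliding-window
  variants and ALEX-based sorting are out of scope.
* Mixture fitting is fixed at three components (with the two-component
  robustness check); no model selection over component counts.
* No thermodynamic interpretation (ΔG) of c₁/₂ values.
* The H-bond criterion is geometric; energetic definitions are not
  implemented.
* PDB parsing of real trajectories relies on MDAnalysis and expects
  models with consistent atom counts.
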