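# nucfret

Quantitative analysis of salt-induced nucleosome disassembly from FRET
experiments and molecular-dynamics trajectories.

Nucleosomes — ~147 bp of DNA wrapped around a histone octamer (two
H2A-H2B dimers plus one (H3-H4)₂ tetramer) — can be driven apart *in
vitro* by raising the NaCl concentration, and the process followed by
Förster resonance energy transfer between dyes attached to the DNA
and/or the histones. `nucfret` implements the full analysis chain for
such experiments, for researchers studying chromatin stability:

* **Ensemble (microplate) FRET** — intensity corrections for background,
  donor crosstalk (α) and direct acceptor excitation (δ), and the
  proximity ratio *P* = I_A / (I_A + I_D).
* **Single-pair FRET** — burst search in photon-arrival streams (bursts
  = ≥ 50 photons with consecutive gaps < 120 µs), per-burst
  *P* = N_A / (N_A + N_D), and 0.02-bin histograms over [−0.1, 1.1).
* **Subpopulation decomposition** — three-Gaussian fits resolving the
  low-FRET (LF, *P* ≈ 0.12, open nucleosomes / free DNA), mid-FRET
  (MF, *P* ≈ 0.39, intact) and high-FRET (HF, *P* ≈ 0.64, partially
  disassembled) states, and the disassembly statistic HF / (MF + HF).
* **Salt titrations** — the four-parameter logistic
  *P*(x) = *P*(0) + (*P*(∞) − *P*(0)) / (1 + e^((c₁/₂ − x)/b)),
  whose inflection point c₁/₂ is the stability readout, with pairwise
  z-score comparison across nucleosome constructs.
* **FRET arithmetic** — E = N_A/(N_A + γN_D) = 1/(1 + (R/R₀)⁶),
  P = γ/(γ − 1 + 1/E), γ = (η_A φ_A)/(η_D φ_D).
* **MD trajectory geometry** — hydrogen-bond occupancy (d ≤ 0.35 nm,
  H-donor-acceptor angle ≤ 30°) over an analysis window, heavy-atom
  contact counts (d < 0.35 nm, strict), and center-of-mass distances
  between 5-bp DNA-arm segments and their counterparts on the opposite
  arm, with 200-ps running averages.

A synthetic-data module generates photon streams, titration tables and
toy trajectories with known ground truth, so every stage is validated by
parameter recovery.

## Worked example

Simulate a three-species spFRET measurement, run the pipeline, and
decompose the histogram:

```python
import nucfret as nf
from nucfret.synthetic import SpeciesMixtureSpec, simulate_photon_stream

spec = SpeciesMixtureSpec()                      # equal-weight LF/MF/HF mix
stream, truth = simulate_photon_stream(spec, 10_000, seed=42)
bursts, ps = nf.process_stream(stream)           # burst search + per-burst P
fit = nf.fit_three_gaussians(nf.build_histogram(ps))
print(fit.summary())
```

```
Three-Gaussian proximity-ratio mixture
==============================================
comp      mean   sigma      area  fraction
LF       0.118   0.033    0.0066     0.333
MF       0.390   0.051    0.0068     0.341
HF       0.641   0.048    0.0064     0.325
----------------------------------------------
HF/(MF+HF): 0.488   SSE: 2.057e-04   converged: True
```

The fitted means recover the generating species (0.12 / 0.39 / 0.64)
to within ~0.002, the fractions recover the equal weights, and
HF/(MF+HF) ≈ 0.49 reflects the equal MF and HF populations. The widths
are pure photon shot noise (σ ≈ √(P(1−P)/N) for N ≈ 50–150 photons).

Fitting a simulated wild-type salt titration (truth c₁/₂ = 800 mM):

```python
from nucfret.synthetic import TitrationTruth, simulate_titration
from nucfret import SaltTitrationModel

_, plate = simulate_titration(TitrationTruth(c_half_mm=800.0), seed=42)
fit = SaltTitrationModel.from_dataframe(plate).fit()
print(fit.summary())
```

```
Salt-titration sigmoidal fit
============================================
P(0)          1.0074
P(inf)        0.1006
c1/2 (mM)     801.06 +/- 2.40
b (mM)         61.03
SSE        7.821e-04
converged True
```

The same pipelines are exposed as a CLI (`nucfret simulate-photons`,
`bursts`, `histogram`, `fitmix`, `titrate`, `compare`, `md-hbonds`,
`md-contacts`, `md-armdist`, …); run `nucfret --help`.

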