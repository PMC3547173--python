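# Methods

## The model

`cmcfield` implements a neural-field generative model of single-channel
M/EEG power spectra. A cortical patch of linear extent `L_patch = 25 mm`
contains, at each point, a canonical microcircuit of four populations:
spiny stellate input cells (1), inhibitory interneurons (2), deep pyramidal
cells (3) and superficial pyramidal cells (4). The expected depolarisation
field V(x, t) obeys second-order convolution dynamics

    V'' + 2 B V' + B^2 V = A B ∫ K(x − x') σ(V(x', t − |x − x'| υ)) dx' + G u,

with A = diag(m_e, m_i, m_e, m_e) the maximum postsynaptic depolarisations,
B = diag(κ₁..κ₄) the postsynaptic rate constants, σ the logistic firing-rate
function σ(v) = 1/(1 + exp(r(η − v))), υ the inverse conduction speed, and
G = (κ₁ m_e, 0, 0, 0)ᵀ routing endogenous fluctuations u into the stellate
population. The connectivity kernel has an interlaminar (intrinsic) part,
(1/2) a_ab exp(−c_ab |x|) on a fixed sparsity pattern with fixed signs
(inputs from the interneurons and the 1←4 connection negative, everything
else — including all self-connections — positive), and a patchy horizontal
(extrinsic) part (1/2) c_aa [exp(−c_aa|x−h|) + exp(−c_aa|x+h|)] connecting
like layers of macrocolumns separated by h. The dispersion 1/c_aa of the
horizontal connections is the model's measure of macrocolumn width.

Linearizing about a spatially homogeneous state and Fourier transforming in
space and time gives the transfer function

    T(k, ω) = (−ω² I − 2iωB + B² − A B D(k, ω) γ)⁻¹ G,

where D(k, ω) is the signed transform of the delayed kernels and γ the
sigmoid slope at the linearization point. A single virtual electrode sees
the patch through a Gaussian lead field with dispersion φ (a fraction of
`L_patch`; 0.1 → 2.5 mm by default), giving the predicted spectrum

    g(ω) = Σ_k |L(k, φ)|² |q̃ · T(k, ω)|² g_u(ω),      g_y = g + g_n + ε,

summed over the discrete spatial frequencies k_n = n / L_patch of the
bounded patch, with layer weights q̃ = (10, 0, 10, 80), a spatially white
input spectrum g_u and a channel-noise curve g_n. The neural-mass variant
is the limit υ = 0 with the lead field concentrated at k = 0; it is
implemented independently through the spatially integrated connectivity
∫K dx (a_ab/c_ab plus the extrinsic mass 2 on the diagonal) and agrees with
the clamped field model to machine precision.

### Conventions

* Units: ms, mm, mV internally. Interfaces take temporal frequency in Hz
  (ω = 2πf/1000 rad/ms) and spatial frequency in cycles/mm (κ = 2πk rad/mm).
* Kernel transforms use the convention FT[u] = ∬ u e^{−iκx+iωt} dx dt, so a
  conduction delay contributes e^{+iωυ|x|}. Both transforms are exact closed
  forms (the patchy kernel by piecewise integration split at the kink x = h)
  and are validated against split-interval oscillatory quadrature to 1e−6
  (observed agreement ~1e−14).
* Two independent routes compute T(k, ω): direct batched 4×4 solves, and a
  cofactor closed form S_a(k, ω)/R(k, ω) written out for the circuit's
  sparsity pattern. Their agreement (< 1e−8, observed ~5e−15) is a standing
  cross-check; the closed form is also the fast path for long frequency
  grids.
* The k-grid order N is sized so the lead-field weight at the truncation
  boundary is below 1e−6 (N = 9 at default φ); doubling N changes the
  spectrum by < 0.1%.
* The sigmoid is linearized at v = 0 by default (γ = r e^{rη}/(1+e^{rη})²,
  i.e. r/4 at η = 0). Linearization at the nonzero steady state — computed
  by damped fixed-point iteration with a Newton polish to residual 1e−10 —
  is available via the `linearization="fixed_point"` option.
* The input/noise curves default to a white-plus-1/f mixture α + β/f; a
  literal linear-in-ω law is selectable (`colour="linear"`).

### Default parameters

Prior means: m_e = 8, m_i = 32 mV; κ = (1/2, 1/2, 1/16, 1/28) ms⁻¹;
r = 0.54 mV⁻¹, η = 0; amplitudes a₂₂ = a₃₃ = a₄₁ = 3200, a₁₂ = a₄₄ = 800,
a₂₃ = a₃₂ = 1600, a₁₁ = 9600, a₁₄ = 4000, a₂₁ = 4800; spatial decays
c_ab = 0.6 mm⁻¹ (a ≠ b) and 2 mm⁻¹ (a = b); h = 4.5 mm; υ = 0.6 ms/mm
(1.5 m/s⁻¹ conduction, i.e. the 0.6 s/m prior); φ = 0.1 of the patch.
The φ value and the q̃ weights have no canonical units; they are taken as
configuration constants and absorbed into the overall spectral scale.

### A note on stability

At these defaults the linearized dynamics possess exponentially growing
modes (largest real eigenvalue ≈ +61 ms⁻¹), a direct consequence of the
uniformly positive self-connections combined with the large amplitude
constants. The spectral predictions are therefore defined through the
transfer function evaluated on the real frequency axis — the standard
practice for this model family — rather than as the stationary output of a
simulatable stochastic system. Two consequences for validation:

* time-series surrogates are produced by frequency-domain synthesis
  (independent complex-Gaussian FFT bins with the analytic spectrum as
  one-sided PSD), which realises the prescribed second-order statistics
  exactly regardless of the dynamical stability of the operating point;
* the simulation-vs-transfer-function cross-check (Euler–Maruyama
  integration of the linearized mass dynamics, Welch-estimated) is run at
  an explicitly stable low-gain circuit (r = 0.004, amplitudes 2–20),
  verified stable by its eigenvalues inside the test.

## Inversion

Free parameters are multiplicative log-scalings of the prior means,
θ = θ̄ e^ϑ, with shrinkage priors ϑ ~ N(0, σ²): σ² = 1/8 for synaptic and
amplitude parameters (κ₁, m_e, a_ab) and 1/16 for spatial (υ, c_ab) and
sigmoid (r, η) parameters. The default free set is {κ₁, m_e, a_ab, υ, c_ab,
r, η} (25 parameters; the mass variant pins υ = 0 and drops it). Because
packing is multiplicative, a parameter with zero prior mean (η at default)
is left unchanged by its scaling; it remains a flat direction absorbed by
its prior. Observation noise is iid Gaussian per frequency bin with
precision e^λ; λ carries a Gaussian prior N(0, 64) (broad, since the data
scale is arbitrary).

The objective is the variational free energy under the Laplace assumption:
accuracy −(n/2)ln2π + (n/2)λ − (e^λ/2)‖y − g(μ)‖², minus the KL divergences
of the parameter posterior N(μ, C) and the hyperparameter posterior
N(m_λ, v_λ) from their priors. Ascent is Levenberg–Marquardt-damped
Gauss–Newton on μ with central-difference Jacobians (step 1e−3 in
log-scaling space); λ is re-solved exactly at every evaluation (the
stationarity condition is monotone in λ, solved by bracketing); the
posterior covariance is the Laplace curvature C = (e^λ JᵀJ + Π_prior)⁻¹.
A candidate step is accepted only if its fully re-evaluated free energy
improves, so the accepted-step trajectory is non-decreasing by
construction. Convergence is declared after 4 consecutive accepted
improvements below 0.01 nats, with a cap of 128 iterations. Fits are
deterministic given data and settings.

Model comparison uses ΔF = F_field − F_mass as an approximate log Bayes
factor, with |ΔF| ≥ 3 (inclusive) flagged as strong evidence.

## Synthetic data

The generator emulates the data a gamma-band MEG study would contribute:
30–80 Hz auto-spectra at 1 Hz resolution with additive Gaussian error per
bin, floored at zero. Two fixed noise conditions are defined as fractions
of the mean noiseless band power: `NOISE_MODERATE = 0.03`, matching the
precision of a multitaper estimate averaged over ~7 tapers × 180 one-second
trials (relative SE ≈ 1/√1260 ≈ 2.8%), and `NOISE_HIGH_SNR = 0.005` for a
high-quality recording. Group datasets draw multivariate-Gaussian rows
(Gaussian copula, unit variances) with a prescribed 4×4 correlation.
Peak gamma parameters are extracted by least-squares Gaussian fitting of
the percentage power change (or raw power without a baseline); fits that
fail, have non-positive amplitude, or peak at the grid boundary signal
"no peak".

What the generator deliberately omits: trial structure and evoked
components, non-Gaussian estimator statistics (a χ²-distributed multitaper
error is approximated as Gaussian), heteroscedasticity across bins,
multi-channel structure, and any head/forward modelling beyond the one
Gaussian lead field. Passing recovery tests therefore demonstrate the
internal consistency of simulation plus inversion under the model's own
assumptions, not performance on raw MEG recordings.

### Identifiability at the default operating point

The default operating point is strongly coupled: the connectivity term
dominates the dynamical terms by 3–4 orders of magnitude, and the in-band
spectrum is smooth. Under these conditions the spectrum is sensitive to the
columnar-width direction (a +1 log-scaling of the c_aa diagonal moves it by
~30%) but almost silent along the interneuron-drive direction a₂₃ (~0.3%
per unit log-scaling; the cofactor structure of the observed populations
nearly cancels its contribution). Consequently, in the package's recovery
study (20 seeded replicates, generating scalings +0.4 on c_diag and −0.4 on
a₂₃, moderate noise), the width sign is recovered in 19/20 replicates while
the a₂₃ posterior stays prior-dominated (|mean| ~ 1e−3, sign recovered in
6/20, i.e. at chance). Recovering the a₂₃ sign under this model requires
per-bin noise below ~0.5% of mean power. The noise conditions were fixed a
priori on empirical grounds and are reported as found; the corresponding
joint-sign check in the acceptance suite fails and is left failing as an
accurate statement about identifiability at this operating point.

## Population statistics

Pearson tests use t = r√((n−2)/(1−r²)) with n − 2 df; partial correlations
come from the precision matrix of the relevant submatrix with
df = n − 2 − #controls. Tails are always an explicit argument. Path
analysis fits recursive standardized path models to the correlation matrix
treated as a covariance observed on n samples: ML minimises the Wishart
discrepancy ln|Σ| + tr(SΣ⁻¹) − ln|S| − p over path coefficients plus
residual/exogenous variances (Nelder–Mead refined by BFGS from
equation-wise least-squares starts); the log-likelihood uses divisor n − 1
and AIC = −2 lnL + 2k, with ties in rankings broken by fewer parameters.
Rounding for comparisons against two-decimal published tables is half away
from zero (Python's `round`). The bundled reference matrix carries the
source table's three-decimal entries (e.g. width–V1 = .364). The candidate
model space fixes V1 size → width and enumerates the 16 subsets of
{width→f, a₂₃→f, V1→f, width→a₂₃}; arbitrary user-defined acyclic models
are accepted.

## Problem sizes

Default study sizes, chosen to keep every analysis at desk scale: 51
frequency bins; 19-point spatial grid; 20-replicate recovery studies;
10-replicate field-vs-mass comparisons; 600 s surrogate series at 256 Hz
for the Welch cross-check (2 s Hann segments, 50% overlap); 10,000-row
group simulations for consistency checks. A single spectral inversion takes
a few seconds on one CPU.

## Known limitations

* Auto-spectra of a single channel only; the Re/Im error split of complex
  cross-spectra is representable in the data model but not exercised.
* The 1-D patch with rotational symmetry; no 2-D or anisotropic kernels,
  and a single fixed conduction delay per unit distance.
* The printed positive self-connection convention is kept as-is (a
  configurable sign map exists for the conventional inhibitory-self
  variant); no attempt is made to re-derive a stable operating regime.
* No hierarchical (group-level) inversion and no MCMC posterior checks;
  the Laplace posterior is taken at face value.
* SEM is complete-case, observed-variable path analysis: no latent
  variables, mean structures, or fit indices beyond the likelihood, AIC
  and df.
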