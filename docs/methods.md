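# Methods

## The quantity of interest

Organelle DNA (oDNA — mitochondrial or plastid genomes) is present in
hundreds to thousands of copies per cell. The *heteroplasmy* h of a cell is
the fraction of its oDNA molecules carrying a variant. Because purifying
selection between generations acts on cell-to-cell *differences* in h, the
evolutionarily useful statistic is the normalised heteroplasmy variance

    V'(h) = V(h) / (E(h)(1 − E(h))),

bounded by 1 (every cell homoplasmic). Its reciprocal N_b = 1/V'(h) is the
effective bottleneck size: the number of independently segregating units
that would produce the same variance under one binomial sampling step.

## The additive first-order theory

To first order the contributions of the five variance-generating cellular
mechanisms sum:

| mechanism | contribution | parameters |
|---|---|---|
| (i) cell division | n_c / n | n copy number before division; n_c homoplasmic cluster size |
| (ii) turnover | (1 + n_d) ν f t / n | ν degradation rate (day⁻¹), f fragmented fraction, n_d molecules per autophagy event |
| (iii) gene conversion | 2 (κ/n_comp) (1 − f)² t | κ conversion rate (day⁻¹); n_comp separate gene pools (plastid picture) |
| (iv) subsampling | n_c (1/n₂ − 1/n₁) | hypergeometric, without replacement |
| (v) reamplification | 1/n₁ − 1/n₂ | Pólya urn (beta-binomial) |

Everything except gene conversion is suppressed by copy number; gene
conversion adds 2κ per unit time *independent of n*, which is why highly
fused organelle networks (low f) can segregate oDNA without any physical
copy-number bottleneck.

Additivity is a linear-noise approximation. The package reports uncapped
sums but warns above V' = 0.5 and hard-warns (and caps the summary object)
above 1.0, where the theory has saturated. The exact sampling laws differ
from the first-order terms by finite-size factors — hypergeometric halving
of n molecules gives exactly 1/(n−1) rather than 1/n, and Pólya growth
n₁→n₂ gives exactly (n₂−n₁)/(n₂(n₁+1)) rather than 1/n₁−1/n₂ — negligible
above a few hundred molecules and exposed through `exact=True` flags and
the enumeration oracles in the test suite.

## Division/regrowth cascades

When copy number moves from N₀ to N_k across k cell cycles, each cycle is
modelled as amplification by a constant factor a = 2(N_k/N₀)^{1/k}
(replication during the cycle) followed by a halving division, so the
post-division profile is geometric, N₀(a/2)^i. Summing terms (i) and (v)
along this profile gives the closed form

    V' = (a + n_c − 1)/(a N₀) · ((2/a)^k − 1)/((2/a) − 1),

with the a→2 limit k(a + n_c − 1)/(a N₀). The closed form equals the
brute-force per-cycle sum to machine precision (tested at 1e−12 relative).
It requires a ≥ 1 — depletion no faster than halving per cycle — which all
schedules used here satisfy; faster depletion would make the within-cycle
step a subsample and is rejected with a domain error.

## Selection theory

Selection enters as a scaled replicative difference ρ (day⁻¹) between the
two oDNA types. The mean follows the logistic trajectory whose logit is
logit(h₀) + ρt. For the variance we solve the linear-noise moment
equations, treating copy number N and fragmentation f as equilibrated
constants and ignoring recombination:

    dE/dt = ρ E(1 − E),
    dV/dt = 2ρ(1 − 2E) V + 2 ν f E(1 − E)/N,

whose closed-form solution at reference h₀ = 1/2 is

    V'(t) = (2νf/N) · [2t + 2 sinh(ρt)/ρ] · x/(1 + x)²,   x = e^{ρt}.

This reduces to the neutral 2νft/N as ρ→0 (the implementation dispatches to
that limit for |ρt| < 1e−9) and is verified against direct ODE integration
and against simulation ensembles. For founders h₀ ≠ 1/2 the normalised
variance (h₀-free at this order) is rescaled by E(1−E) along the founder's
own logistic mean.

Because the stochastic model's replication feedback holds N near its set
point, the analytic map from the microscopic replicative advantage δ to ρ
degenerates there; ρ is therefore calibrated empirically
(`ssa.effective_rho`): fit the through-origin slope of the transformed mean
trajectory z(t) = logit(E(h)) − logit(h₀), which under logistic dynamics is
exactly ρ (empirically ρ ≈ δν at the default rates). Comparisons between
theory and simulation under selection evaluate the closed form at the
ensemble's *equilibrated* mean copy number, which under selection sits a
few percent above the set point — that is the constant the derivation
assumes.

## The stochastic simulator

State is (W_f, W_s, M_f, M_s): wild-type/mutant molecules in fused vs
singleton organelles; N their sum, h the mutant fraction, f the singleton
fraction. Exact Gillespie simulation (numba-compiled; bitwise reproducible
per seed) of:

* **replication** — per-molecule rate r(N) = max(0, ν + (λ−ν)(1−αN)). This
  law equals λ at N = 0 and exactly ν at the set point N = 1/α, so birth
  balances death there for any (λ, ν); defaults λ = 2, ν = 1, α = 1/1000.
  Mutants replicate at r(N)(1+δ). For λ < ν the feedback is destabilising
  above the set point; the constructor warns.
* **autophagy** — only singleton molecules are degradable; events occur at
  rate ν·pool/n_d and remove min(n_d, pool) same-type molecules (a
  homoplasmic cluster), preserving the per-molecule rate ν and producing
  the (1+n_d) factor in term (ii).
* **gene conversion** — restricted to the fused pool, mass-action in
  discordant pairs: toward mutant at κ(1+ε)W_f M_f and toward wild type at
  κ(1−ε)W_f M_f. This is the unique scaling for which dV'/dt = 2κ(1−f)²
  independent of N. Sign convention: ε > 0 favours conversion *toward the
  mutant* type (aA → AA weighted (1+ε)/2).
* **fission–fusion** — independent per-molecule switching at α_s
  (fused→singleton) and α_f (singleton→fused); equilibrium
  f = α_s/(α_s+α_f). This is the simplest coarse-grained representation of
  network state; the variance results are insensitive to that choice.

Extinct cells (N = 0) carry no heteroplasmy; ensembles exclude them from
h statistics and report the extinct fraction. The standard error of V'
across m surviving replicates is V'·sqrt(2/(m−1)).

Division is delegated to the partitioning module so simulated lineages can
execute event schedules: hypergeometric (each daughter exactly N/2
molecules, cluster-wise for n_c > 1), perfect (each pool halved, odd
remainders by fair coin), or per-molecule binomial assignment. The
separate `partition_binomial` of the partitioning module instead implements
the with-replacement comparison model (daughter compositions drawn from
parent fractions), which adds 2/n per halving and deliberately does not
conserve molecular identity — the unphysical feature that motivates the
hypergeometric choice.

## Spatial partitioning toy

Organelles are placed uniformly in the unit square; in `repulsive` mode
positions relax by inverse-distance pair repulsion with reflecting
boundaries (damped iterations, per-step displacement capped at 0.05, until
the maximum displacement is below 1e−4 or 400 iterations); the cell is
bisected at x = 1/2. Genotypes are assigned independently of position, so
spreading narrows daughter copy-number variance (below the binomial n/4)
while leaving heteroplasmy variance untouched. No interaction potential is
asserted quantitatively — only this ordering and invariance.

## Mouse germline schedules and inference

Development: copy number falls 1e5 → b (the physical bottleneck, always a
fitted parameter) over 29 divisions of period 7 h, regrows b → 5,000 over 7
divisions of period 16 h, then reamplifies to 1e5 in the mature oocyte (36
divisions in all). After development, oocyte turnover adds
(1+n_d)(νf/n)·age to V'; only the compound νf/n (day⁻¹) is identifiable
from oocyte data, and n_d = 1 is fixed for mouse predictions. Ages are
treated as days post conception with the ~13-day development itself
contributing negligibly to the ageing term.

Candidate mechanisms are schedule variants: divisions+turnover+
reamplification (the reference model); a single discrete oogenesis
subsampling followed by reamplification (free parameter: the subsample
size, giving a constant V'); clustered divisions (free n_c, no ageing
term); and the reference model plus selection ρ.

**Likelihood.** Each oocyte record (mother, age, founder h₀, measured h) is
transformed to z = logit(h) − logit(h₀). On this scale the selection mean
is exactly ρ·age and, by the delta method (g'(h) = 1/(h(1−h))), the
variance is V'(age)/(E(1−E)) with E the record's own logistic mean (h₀
itself when neutral). The likelihood is Gaussian in z. Fixated records
(h ∈ {0,1}) cannot be transformed and are excluded with a reported count;
no censoring correction is attempted. This Gaussian-in-z construction is
first-order: at large V' (≳ 0.1) the true sampling distributions are
beta-like and the logit-scale variance exceeds V'/(E(1−E)) by O(V')
relative — visible when comparing the molecule-level generator backend to
the transformed-Gaussian backend outside the moderate-variance regime.

**Fitting.** Nelder–Mead simplex maximisation with positive parameters (b,
νf/n, subsample size, n_c) on log scale; out-of-domain proposals are
penalised. Default init b = 1000, νf/n = 1e−4, ρ = 0; optional jittered
multistarts (log-scale s.d. 0.3). Convergence tolerances xatol 1e−6,
fatol 1e−9. Uncertainty by nonparametric bootstrap: oocytes resampled with
replacement within each mother (preserving the per-mother founder design;
resampling whole mothers is available as `bootstrap_unit="individual"`),
each resample refitted from the full-data point estimate, 95% percentile
intervals; refit failures counted and warned above 10%. Model comparison
by AIC = 2k − 2ℓ and by R² between per-age-group empirical V'(h) and the
model curve.

**Empirical V'.** The raw per-age-group estimator uses sample moments of h
(appropriate when cells share a founder). When founders differ across
mothers, the founder-referenced estimator is used: V̂' =
Σ(z_i − z̄)² h₀ᵢ(1−h₀ᵢ)/(m−1), which is delta-method-consistent and reduces
to the raw estimator for a common h₀. Groups of fewer than two records are
dropped with a warning; SE is V'·sqrt(2/(m−1)).

## Synthetic data

The generator emulates the published oocyte study design: four age groups
(25, 120, 250, 400 days), 40 mothers round-robin across ages, 30 oocytes
per mother, founder heteroplasmy uniform on (0.2, 0.8), truth at the
canonical neutral estimates b = 670 and νf/n = 1.4e−4 day⁻¹. These defaults
keep both parameters identifiable at roughly the published data scale while
remaining desk-scale to fit.

Two backends: `gaussian_transformed` draws z from exactly the model the
likelihood assumes (the inverse of the inference construction — any
parameter scale, selection supported); `full_ssa` pushes each oocyte's
molecule population through the actual stochastic machinery (Pólya
amplification and hypergeometric partitioning along the schedule, then an
exact-SSA turnover epoch with all molecules fragmented and ν chosen to
realise the target νf/n at the oocyte copy number). The molecule-level
backend is neutral-only and intended for desk-scale schedules (copy
numbers of order 10³); at mouse scale (10⁵ copies for hundreds of days) the
event count is prohibitive, and at large V' the two backends part ways for
the delta-method reason above. What the generator does *not* emulate:
sequencing/measurement error in heteroplasmy calls, mother-level random
effects beyond the founder offset, oocyte atresia, and de novo mutation.
Passing recovery tests therefore demonstrate correctness of the inference
machinery under its own assumptions, not robustness to those real-data
features.

`recovery_experiment` is the calibration harness: generate many datasets,
refit, and tabulate bias, RMSE, bootstrap coverage and model-selection
outcomes. At the default scale the median fitted b is within a few percent
of truth and 95% bootstrap intervals (100 resamples in the harness; the
single-fit default is 1000) cover the truth at roughly nominal rate.

## Problem sizes and numerical choices

Simulation checks use 10⁴ replicates (SE on V' about 1.4%); recovery
experiments use 100 datasets of 1,200 oocytes with 100 bootstrap resamples
each; model-selection checks use 10 datasets per condition with ρ = 5e−3
day⁻¹ for the selection truth. Selection-theory checks use δ = 0.05, the
weak-selection regime where the equilibrated-constant assumption holds
(empirical ρ ≈ 0.048 day⁻¹, within the range inferred from real germline
data). Gillespie kernels are numba-compiled and seeded per replicate from
a `SeedSequence`; identical seeds give bitwise-identical trajectories.

## Known limitations

* First-order additivity: accuracy degrades as V' grows toward 1; no
  saturating (full Kimura-type) distribution is implemented.
* No de novo mutation converting one type into the other.
* The selection closed form assumes weak selection and equilibrated N, f;
  strong selection (δ ≳ 0.1) shows visible O(δ) deviations.
* The fission–fusion representation is per-molecule state switching, not a
  physical network model; n_c/n_d clustering is the only substructure.
* The replication feedback law is one of several satisfying the stated
  constraints (value λ at N = 0, set point 1/α); results shown are robust
  to this choice at the level of the variance terms.
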