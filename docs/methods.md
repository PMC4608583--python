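# Methods

## Model

A gene product (mRNA or, in the bursty-synthesis limit, protein) is produced
in i.i.d. batches on a renewal event stream and each copy is degraded
independently at a first-order rate. This maps the copy-number process onto
the infinite-server batch queue GI^X/M/∞: arrivals are batches of random
size `X`, "service" is exponential degradation, and the number "in service"
is the copy number. The only structural assumptions are (i) renewal arrivals
— interarrival times are i.i.d., which holds exactly for any promoter scheme
that returns to a fixed state after each production event (multi-step
activation chains with backslips included) — and (ii) independent decay.
History-dependent (non-renewal) arrival processes are out of scope for the
moment formulas, though the simulator accepts any irreducible promoter CTMC;
Little's law for the mean holds regardless.

## Steady-state moments

All moments derive from one triangular recursion. Writing
`t_j = f_L(jμ)/(1 − f_L(jμ))`, `b_k` for the batch factorial moments and
`k_b` for the arrival rate:

```
e_0 = 1
e_j = t_j Σ_{i<j} C(j,i) b_{j−i} e_i
m_k = (k_b/(kμ)) Σ_{j<k} C(k,j) b_{k−j} e_j        (k-th factorial moment)
```

implemented to order 4. Orders 1–3 reproduce algebraically the familiar
mean/Fano/skewness forms written with the gestation factor
`K_g(μ) = 1 + 2[f_L(μ)/(1−f_L(μ)) − k_b/μ]`; the tests assert this
equivalence exactly, in rational arithmetic. The engine is arithmetic-generic:
`fractions.Fraction` inputs propagate unchanged, which is how the signature
closed forms are verified to machine precision without floating-point
cancellation arguments.

Numerical stability near `s = 0` matters because `f_L(μ)/(1 − f_L(μ))` and
`k_b/μ` both diverge while their difference stays finite. Both are therefore
evaluated through exact polynomial divisions of the rational transform:
`1 − f_L(s) = s·Q(s)/D(s)` and `f_L(s)/(1−f_L(s)) − k_b/s = R(s)/(s·...)`
reduce to ratios of polynomials whose constant terms cancel identically, so
`K_g` is computable down to `μ = 0` (needed for burst-limit protein
statistics).

Protein moments use the compound burst: the per-burst protein output is the
sum over the burst's mRNAs of i.i.d. per-mRNA bursts, and its factorial
moments `A_k` follow from the Bell-polynomial chain rule on the generating
functions. In the burst limit (`μ_m ≫ μ_p`) the recursion applies verbatim
with batch `A_k` and rate `μ_p`. Beyond the burst limit the finite mRNA
lifetime is absorbed by scaling: the excess noise `CV² − 1/⟨p_s⟩` by
`1/(1 + μ_p/μ_m)`, and inside the third-moment formula
`A_2 → A_2/(1+μ_p/μ_m)`, `A_3 → A_3/[(1+μ_p/μ_m)(1+2μ_p/μ_m)]`. This
reproduces the exact constitutive two-stage results; for promoter-switching
schemes it is an approximation whose error grows with `μ_p` relative to the
promoter switching rates. We quantified it against an exact moment-ODE
solution of the telegraph batch scheme: at the protocol parameters used here
(`μ_p = 0.01`, switching rates ~0.25–1) the variance error is ≲ 0.6% across
lifetime ratios 1–50, but it reaches ~5–10% when `μ_p` is comparable to the
switching rates. The scaled mode is the default; `mode="burst_limit"` gives
the uncorrected forms.

Two geometric-burst conventions appear in this literature and both are
first-class: `geometric_from_mean` (support 0,1,2,…; variance m(1+m)) and
`conditional_geometric_from_mean` (support ≥ 1; variance m(m−1); at mean 1
it degenerates to exactly one mRNA per event, unifying constitutive and
bursty expression). The constructors are explicit so no bare "mean burst
size" ever crosses an interface without its convention. The telegraph
protocols in this package fire conditional-geometric batches; that choice is
what makes the analytic pipeline agree exactly with the telegraph
closed-form signatures.

## Sequence-size analysis

`φ(τ) = 1/(1 − ∫₀^τ f)` is computed from the survival function, which for a
rational `f_L` is inverted exactly by partial fractions of `Q(s)/D(s)`
(companion-matrix root finding; repeated poles detected with a clustering
tolerance of 1e−8 and handled with higher-order terms). Curvature is then
analytic, so the inflexion is refined by bracketed root finding; the
inflexion is the first sign change of `φ''` after the initial convex region,
matching the single-crossing structure of bursty kinetics (convex on the
within-burst scale, concave at the plateau, convex again on the between-burst
scale).

The empirical route (waiting-time samples) uses the empirical CDF on a
log-spaced grid starting near the median gap: below that, the second
derivative of an ECDF is noise (its sampling error grows like `τ^{−3/2}`).
`log φ` is smoothed with a centred moving average (default window: grid
size/20, forced odd), monotonicity is enforced, curvature is taken by
non-uniform three-point central differences and smoothed the same way, and a
sign change only counts if the curvature stays non-positive for longer than
the smoothing window. With 6×10⁴ recorded waiting times this estimates a
true burst size of 11 to within ~10%; the analytic route is exact.

## Moment fitting

`fit_arrival_model` matches analytic to measured central moments (mean,
variance, third, fourth as needed) by least squares in log-parameters
(positivity by construction), Levenberg–Marquardt from 16 seeded random
starts spanning ±3 decades around moment-implied scales, convergence
tolerance 1e−12. Residuals are weighted by inverse bootstrap standard errors
when the moment set carries them, else by inverse magnitudes (relative
residuals); higher moments are noisier and this keeps them from dominating.
The parameter count of `g^m_n` is `n + m + 2`, and the fit refuses
under-determined problems by name. Moment sets measured at different mRNA
degradation rates may be supplied jointly for extra constraints. Identifiable
combinations are recovered exactly from noise-free moments (`g^1_0` and
`g^2_0` recovery tests); with sampled moments the absolute scale of
`(k_m, β)` can drift along a ridge at nearly fixed `k_m/β` — the implied
burst size, which is what the procedure is for, is stable, and it is always
reported via sequence-size analysis of the fitted `f_L`. A fit whose
gestation factor is within 1e−3 of 1 is flagged `no_gestation` (no evidence
against Poisson arrivals).

## Simulator and sampling protocol

The Gillespie core (numba-compiled) simulates an arbitrary promoter CTMC
with one production-competent state (single or batch production; geometric,
conditional-geometric, negative-binomial or unit batches), translation and
decay. Burn-in is 10× the slowest timescale among `1/μ_m`, `1/μ_p` (when
proteins are on) and the reciprocal of the smallest promoter rate; samples
are taken at 5× that timescale by default. Both are overridable, and the
bundled protein-moment protocol deliberately samples at 1.5 protein
lifetimes instead (autocorrelation e^{−1.5} ≈ 0.22), trading mild sample
dependence for a fourfold larger sample count at a fixed event budget; its
acceptance margins account for that. A single integer seed is expanded into
per-replicate streams by `numpy.random.SeedSequence`, making every output
bit-reproducible. Extrinsic noise redraws the transcription rate once per
replicate ("cell") from a log-normal law — the static cell-to-cell
interpretation — never per event.

What the simulator emulates, it emulates exactly; what it does not include
— cell division and dilution, replication-dependent gene dosage, measurement
noise of smFISH counting, time-lapse readouts — bounds what the validation
shows: agreement of formulas with the model's own dynamics, not with any
particular experiment.

## Study protocols (workflows)

* **Protein-moment sweep** (`two_stage_sweep`): telegraph α = 0.5, β = 0.25,
  k_m = 2, ⟨m_b⟩ = 5, k_p = 0.5; `μ_p = 0.01` fixed, `μ_m/μ_p ∈
  {1,5,10,50}`; 25,000 samples per ratio (10⁵ across the sweep), 300
  bootstrap resamples. The decay scale is the same slow-protein value used in
  the signature protocol; it also keeps the finite-lifetime scaling within
  its accurate regime (see above).
* **Burst-size table** (`burst_size_table`): activation chain with forward
  rates 1, 0.5, 0.25, 0.75, backslips 0.1, 0.2, 0.5, k_m = 500,
  β ∈ {50, 100, 200}; exact burst sizes 1 + k_m/β = 11, 6, 3.5.
* **Extrinsic-noise study** (`extrinsic_noise_table`): two-step activation
  (1, 0.5), β = 50, ⟨k_m⟩ = 500, μ_m = 1; σ_km/⟨k_m⟩ ∈ {0, 0.2, 0.5, 1};
  25,000 cells × 4 samples; `g^2_0` fit on four mRNA moments; Δ_σ =
  (⟨m_b⟩_0 − ⟨m_b⟩_σ)/⟨m_b⟩_0 with cell-level bootstrap refits for errors.
  Extrinsic noise inflates the higher moments, which the fit reads as
  stronger gestation and hence a larger burst size, so Δ_σ is negative and
  its magnitude grows monotonically with σ — the monotone-deviation property
  the validation asserts.
* **Signature table** (`telegraph_signature_table`): α = 0.25, k_m = 2,
  ⟨m_b⟩ = 5, k_p = 0.5, μ_m = 1, μ_p = 0.01, β swept; closed forms vs the
  analytic pipeline vs simulation with bootstrap CIs.

## Signatures: numerical notes

`D_m`, `D_p` and `G_m` need third moments; their denominators can vanish or
change sign for sub-Poissonian data, in which case the statistic is reported
as undefined (a flag in the report), never silently dropped. `G_m`'s
factor-of-two degradation-rate protocol is enforced through metadata — the
two means must be consistent with a halved lifetime (10% relative band) or a
`RatePairingWarning` is raised; the data themselves cannot identify the
pairing. Empirical uncertainty is nonparametric bootstrap (default 2000
resamples, seeded, percentile CIs); mRNA and protein vectors are resampled
independently. The telegraph closed forms are evaluated with rates in units
of `μ_m` (`D_m`, and `D_p` additionally in the `μ_p → 0` burst limit), while
`D_mp` is exact at arbitrary rates and equals
`[K_g(μ_m) − K_g(μ_p)]/(2k_b)`; the consistency tests drive the exact
rational pipeline against all three, using `μ_p = 10⁻³⁰` (exact arithmetic)
for the burst-limit comparison.

For negative-binomial bursts with `r > 1` the `G_m` combination deviates
from 1 as required, but its value depends on the mean expression level as
well as `(r, p)`; the package therefore reports `G_m` by direct substitution
of moments and makes no closed-form claim beyond the geometric null.

## Known limitations

* The finite-lifetime scaling for protein moments is exact only for
  constitutive expression; its error for switching promoters is documented
  above and bounded empirically by the exact-ODE cross-check.
* Moment-based fitting needs accurate third and fourth moments; sampling
  error in the fourth moment is the dominant noise source in burst-size
  recovery (the ~10⁵-sample protocols here keep it a few percent). Skewness
  accuracy at realistic smFISH sample sizes (~10²–10³ cells) is far poorer,
  so the estimators target large-sample data.
* Non-renewal arrival processes (e.g. production from multiple promoter
  states) violate the moment formulas' premise; the simulator can generate
  them, the analytics will not match.
* The `G_m` protocol assumes the burst process is unchanged when the
  degradation rate is doubled; only the mean-halving consistency check
  guards this experimentally.
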