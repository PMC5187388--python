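# adaptivesr

Adaptive stochastic resonance (SR) model of a single auditory frequency
channel, for computational neuroscientists studying how internal noise
interacts with elevated hearing thresholds — and, by extension, how a
noise-tuning feedback loop in the auditory brainstem could relate to
tinnitus-like hyperactivity after cochlear damage.

## The model

A channel consists of three stages in a closed loop:

1. **Acoustic environment.** Sound-intensity levels *I(t)* (dB SPL)
   follow an Ornstein–Uhlenbeck process with stationary law
   *N*(μ_I, σ_I²), defaults μ_I = 40 dB, σ_I = 25 dB, and
   autocorrelation e^(−τ) in model time units. An i.i.d. Gaussian series
   with the same marginal serves as the uncorrelated control.
2. **Sensor.** The inner-hair-cell synapse / auditory-nerve stage maps
   intensity to firing rate by an infomax rate–intensity function with
   threshold *I_θ*, spontaneous rate *f*_sp = 50 Hz and maximum rate
   *f*_max = 250 Hz:

       f(I) = f_sp                                                  I < I_θ
       f(I) = f_sp + (f_max − f_sp) · (Φ_I(I) − P_sp)/(1 − P_sp)    I ≥ I_θ

   where Φ_I is the CDF of the adapted intensity distribution and
   P_sp = Φ_I(I_θ). Hearing loss is modelled purely as an elevation of
   *I_θ*. Internal noise *n* ~ *N*(0, σ_n²) is added to the intensity
   before thresholding: the noisy response is *f(I + n)*.
3. **Information detector and noise generator.** The detector evaluates
   the mean autocorrelation of the output, AC = (1/N) Σ_{τ=1..N} AC(τ)
   — an input-agnostic proxy for transmitted information — and steers
   the noise variance toward the value σ²_{n,opt} that maximises it
   (equivalently locatable by grid search over a resonance curve; a
   histogram mutual-information estimator is provided as the
   information-theoretic cross-check).

Two estimators quantify the hearing-threshold **benefit** of the
optimal noise at a given hearing loss: the shift of the 50 %-detection
point of a simulated psychometric function, and the horizontal (iso-AC)
shift between the with-SR and without-SR autocorrelation-versus-threshold
curves.

A separate module generates synthetic pure-tone audiogram cohorts with
tinnitus / non-tinnitus group structure on the clinical 5-dB lattice
and compares the groups per frequency with a two-sample
Kolmogorov–Smirnov test (permutation null by default, which stays
calibrated on heavily tied data).

## Worked example

```python
from adaptivesr import (
    EnvironmentConfig, SensorParams, resonance_curve, run_feedback_loop,
)

env = EnvironmentConfig(mu_I=40.0, sigma_I=25.0, dt=0.1, n_samples=200_000, seed=0)
lossy = SensorParams(I_theta=40.0)  # 40 dB of hearing loss

slow = resonance_curve(env, lossy, seed=0)
print(f"instantaneous noise : optimum sigma_n^2 = {slow.optimum_sigma_n_sq:6.1f} dB^2, "
      f"peak mean AC = {slow.optimum_value:.3f} (zero-noise AC = {slow.mean_ac[0]:.3f})")

fast = resonance_curve(env, lossy, seed=0, noise_draws_per_sample=10)
print(f"band-limited noise  : optimum sigma_n^2 = {fast.optimum_sigma_n_sq:6.1f} dB^2, "
      f"peak mean AC = {fast.optimum_value:.3f} (zero-noise AC = {fast.mean_ac[0]:.3f})")

traj = run_feedback_loop(env, lossy, seed=0, noise_draws_per_sample=10)
print(f"feedback controller : settles at sigma_n^2 = {traj.terminal_sigma_n_sq:6.1f} dB^2 "
      f"after {traj.n_iter} iterations")
```

prints

```
instantaneous noise : optimum sigma_n^2 =    0.0 dB^2, peak mean AC = 0.164 (zero-noise AC = 0.164)
band-limited noise  : optimum sigma_n^2 =  161.6 dB^2, peak mean AC = 0.168 (zero-noise AC = 0.164)
feedback controller : settles at sigma_n^2 =  194.9 dB^2 after 60 iterations
```

Reading: with one independent noise value per intensity sample
(`noise_draws_per_sample=1`, the default), the mean-autocorrelation
objective is maximal at **zero** injected noise even at 40 dB of
hearing loss — every dB² of dither variance costs the output
autocorrelation more than the recovered sub-threshold signal is worth,
so no SR benefit arises in this regime (see `docs/methods.md` for the
analysis). When the internal noise fluctuates faster than the signal
(here 10 draws per sample, i.e. the rate averages over the noise within
each intensity sample), the classic interior resonance peak appears:
injecting noise of variance ≈ 160 dB² raises the mean output
autocorrelation from 0.164 to 0.168, and the closed-loop controller
finds the same broad optimum without ever seeing the input.

## Command line

`adaptivesr simulate-env | resonance | feedback | benefit | sweep |
cohort | cohort-compare` expose the same operations as shell commands
writing CSV; see `adaptivesr --help`.

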