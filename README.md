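# aspull — adaptive stochastic pulling protocols for PMF reconstruction

Reconstructing a molecule's potential of mean force (PMF) from steered
pulling experiments or simulations is expensive: the Jarzynski equality

```
exp(-β ΔG) = ⟨ exp(-β W) ⟩
```

is exact for any pulling speed, but with a finite number of work samples
and fast (dissipative) pulling the exponential average is dominated by
rare low-work trajectories and the estimate acquires a large systematic
bias. `aspull` implements a family of *adaptive stochastic perturbation
protocols* that attack this problem by deliberately jittering the pulling
point: broadening the work distribution in a controlled way raises the
probability of sampling low-dissipation trajectories and dramatically
accelerates convergence at fixed computational cost.

The toolkit is aimed at people analysing constant-velocity pulling data
(SMD, AFM, optical tweezers) or prototyping pulling protocols, and
contains:

* **estimators** — PMF reconstruction by the Hummer–Szabo
  weighted-histogram form of the Jarzynski equality, the stiff-spring
  shortcut `G₀(x_j) = -β⁻¹ ln⟨e^{-βW(t_j)}⟩`, the second-order cumulant
  expansion `G₀ = ⟨W⟩ - (β/2) Var W`, and the mean-work profile;
* **bias_analysis** — the fluctuation–bias relation `B = β σ²/2`:
  maximum-bias prediction from the low-pass-filtered (5th-order
  Butterworth, zero-phase) fluctuations of a reconstruction, and the
  normalised guiding curve `V_noise(r)` extracted from pilot runs;
* **protocols** — the pulling-point laws: plain constant velocity,
  constant-variance noise, amplitude modulation (noise SD scaled by
  `V_noise`, energy ∝ `V_noise²`) and frequency modulation (full-amplitude
  noise gated with probability `V_noise`, energy ∝ `V_noise`), with
  Gaussian or work-Gaussianising ("chi-inducing", rejection-sampled)
  jitter distributions;
* **calibration** — the noise amplitude `m` (jitter SD in units of the
  thermal displacement `σ_r = √(2DΔt)`) that matches the injected work
  fluctuation to a target bias, for both averaging schemes, including the
  `√n` sampling-interval reduction, amplitude-modulation factor, decade
  rounding and the `n^{1/4}` velocity-scaling rule;
* **simulator** — a vectorised overdamped Brownian-dynamics engine that
  pulls a particle across 1-D model potentials (flat, harmonic, rugged
  double wells, splines) through a Hookean spring, with exact bookkeeping
  of the external work on the sampling grid;
* **metrics / io / cli** — relative RMSD in percent of the barrier
  height, delimited-text formats for ensembles, profiles and curves, and
  a `simulate / reconstruct / bias / calibrate / compare` command line.

## Worked example

The built-in surrogate study pulls a particle across a rugged double well
(20 k_BT barrier over 16 Å, 2 k_BT corrugation) at 25 m/s with the
standard stiff pulling spring (500 pN/Å).  The adaptive pipeline runs a
cheap pilot stage, predicts the mean-work bias, builds the guiding curve,
calibrates the noise amplitude and compares frequency-modulated pulling
against plain pulling at equal cost:

```python
from aspull import surrogate, jarzynski_pmf, relative_rmsd

pilot = surrogate.pilot_analysis(seed=7)
print(f"predicted mean-work bias : {pilot.mean_work_bias:.1f} k_BT")
print(f"guiding-curve average    : {pilot.v_noise.average():.2f}")
print(f"calibrated amplitude m   : {pilot.amplitude:.0f}")

ref = surrogate.reference_profile()
for kind in ("normal", "fm"):
    ens = surrogate.run_protocol(kind, seed=1007, pilot=pilot)
    est = jarzynski_pmf(ens, mode="stiff_spring")
    print(f"{kind:>7s} pulling: end bias {est.values[-1] - ref[-1]:6.2f} k_BT, "
          f"relative RMSD {relative_rmsd(est, ref):5.1f} %")
```

prints

```
predicted mean-work bias : 14.9 k_BT
guiding-curve average    : 0.46
calibrated amplitude m   : 341
 normal pulling: end bias   8.94 k_BT, relative RMSD  23.2 %
     fm pulling: end bias   4.17 k_BT, relative RMSD  13.2 %
```

With 200 trajectories each, frequency-modulated noise cuts the end-point
Jarzynski bias by half and the relative RMSD from 23% to 13% of the
barrier height — the same trajectory budget, a substantially better
profile.

The calibration arithmetic is also available directly from the shell; for
example, the amplitude that cancels a 37 k_BT mean-work bias under the
cumulant-expansion scheme:

```
$ aspull calibrate --bias 37 --mode cumulant --n 200 --round-decade
mode              cumulant
target_bias_kbt   37
m                 100
...
```

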