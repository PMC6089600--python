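# ktflim

Quantitative machinery for measuring NDC80 kinetochore–microtubule binding in
live cells by FLIM-FRET, and for explaining its tension dependence with a
three-step Aurora B model — implemented as a tested, reusable Python package
exercised end-to-end on synthetic data with known ground truth.

## The scientific problem

During mitosis the NDC80 complex couples kinetochores to spindle microtubules
(kMTs). Labeling NDC80 with a donor fluorophore (mTurquoise2) and the
β-tubulin C-terminus with a tetracysteine/FlAsH acceptor makes bound NDC80
molecules undergo FRET, shortening the donor fluorescence lifetime. A
time-correlated single-photon-counting (TCSPC) histogram from one kinetochore
holds only a few hundred photons, so this package infers the FRET fraction
with a Bayesian two-exponential decay model

    g(t) = (1 − f_FRET) exp(−t/τ_D) + f_FRET exp(−t/τ_FRET),

convolved with the instrument response function, under a multinomial
likelihood and uniform prior. Posteriors from kinetochores in a group are
multiplied and marginalized to give the group mean and SEM, and the FRET
fraction is converted to a bound fraction through the calibration slope
*f*_FRET = 0.42 · *f*_bound obtained from a geometric Monte-Carlo model of the
donor and its labeled acceptor lattice (lifetime mixing
τ = τ_D / (1 + Σᵢ Iᵢ (R₀/rᵢ)⁶), Förster radius R₀ = 5.90 nm, labeled fraction
26.1%).

The tension dependence is modeled in three closed-form steps: Aurora B
autoactivation in trans gives the active kinase concentration
[A_active] = [A] − K above a threshold A\* (and A\* − K below it); active
Aurora B sets the phosphorylated fraction of the Hec1 tail,
f_phos = (1 + K_phos/[A_active])⁻¹; and phosphorylation weakens binding,
f_bound = (1 + K₀ + K₀′ f_phos)⁻¹. The package fits these relations
(K₀ = 1.43, K₀′ = 18, K = 3.5 µM, K_phos = 19 µM, A\* = 4.6 µM) and
cross-checks every closed form against a forward ODE integration.

Supporting pipelines cover kinetochore detection/tracking/pairing from image
stacks (sub-pixel centroids, drift correction, five-point velocities,
sister-pair classification), FCS calibration of the focal volume and
molecular brightness, and the labeling-fraction arithmetic.

## Worked example

Run the full synthetic pipeline — simulate a metaphase movie plus
per-kinetochore decays whose true FRET fraction rises linearly with the
sister-kinetochore (K-K) distance, track and pair the kinetochores, infer
per-kinetochore posteriors, group by K-K distance, and fit the trend:

```python
from ktflim.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(outdir="run", seed=5))
print(report.metrics)
```

```
{'tau_d_ns': 3.804981934832956, 'tau_fret_ns': 0.7518830189816077,
 'kk_trend_slope': 0.24345935231145227, 'kk_trend_p': 0.00043334965598262876}
```

The donor lifetime recovered from the no-acceptor control (3.80 ns) and the
FRET lifetime from the aggregated decays (0.75 ns) match the generating
values (3.75/0.75 ns); the positive FRET-fraction vs K-K-distance slope is
significant (p ≈ 4×10⁻⁴), recovering the injected tension trend. The grouped
table (`run/groups.csv`) shows the binding gradient after the 0.42
conversion:

```
 group  kk_mean_um   f_fret      sem  n  f_bound
     0    0.861020 0.078890 0.005031 90 0.187833
     1    0.989432 0.108222 0.005112 90 0.257670
     2    1.108091 0.136997 0.005167 90 0.326184
     3    1.237938 0.170682 0.005225 90 0.406386
```

i.e. kinetochores under the least centromere tension have ~19% of NDC80
bound, rising to ~41% at the highest tension — the same ~13%→31%-style
conversion used for the cell measurements
(`ktflim.flim.fret_to_binding(0.13)` → 0.31).

The same stages are available from the shell:

```bash
ktflim simulate --out run --seed 5
ktflim fit-flim --hist run/decays/d_0_a_0.csv --irf run/irf.csv \
    --fix tauD=3.75 --fix tauF=0.75 --fix A=1.0
ktflim calibrate --flabel 0.261 --r0 5.90 --reps 30 --seed 7
```

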