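# sifi — stacking-induced fluorescence increase analysis

A covalently attached Cy3 dye brightens strongly — up to ~2.5-fold — when it
stacks into a nick, gap or single-strand overhang of duplex DNA, because
stacking sterically suppresses the excited-state *trans* → *cis*
photoisomerization that otherwise quenches the dye. This stacking-induced
fluorescence increase (SIFI) turns a single dye into a probe of DNA
structure and dynamics: hairpin opening/closing can be followed molecule by
molecule, and moving a single abasic site along the duplex modulates the
dye–DNA interaction with the ~10 bp period of the B-form helix, a signature
of through-backbone allostery.

`sifi` implements the computational side of such experiments for
biophysicists working with time-resolved and single-molecule fluorescence:

* **TCSPC reconvolution** (`sifi.tcspc`) — iterative reconvolution fitting
  of photon-count decays against a measured instrument response (IRF),
  with model selection by reduced χ² and a runs test on the residuals.
  A fit `F(t) = IRF(t−s) ∗ Σᵢ αᵢ e^{−t/τᵢ} + b` (circular over the pulse
  period) is summarised by the amplitude-weighted average lifetime
  ⟨τ⟩ = Σαᵢτᵢ/Σαᵢ, the intensity-weighted average τ̄ = Σαᵢτᵢ²/Σαᵢτᵢ, and
  the fractional intensities fᵢ = αᵢτᵢ/Σαⱼτⱼ.
* **Single-molecule kinetics** (`sifi.smkinetics`) — Gaussian-mixture
  thresholding of intensity traces into open/closed states, dwell-time
  extraction with censoring flags, rate estimation from the frame-sampled
  two-state chain (discretisation- and missed-event-corrected), and the
  closed/open enhancement factor.
* **Accessible volume** (`sifi.av`) — the geometric cloud of positions a
  linker-tethered dye can reach on an idealised B-form duplex
  (grid search with exact-geodesic seeding), plus axial-reach and
  junction-stacking metrics.
* **Allostery periodicity** (`sifi.allostery`) — aggregation of per-decay
  lifetime summaries into position profiles (mean ± SEM), a damped-cosine
  fit `τ(x) = b + A cos(2πx/P − φ) e^{−x/λ}` for the modulation period, and
  the stacked/unstacked fractional-intensity anticorrelation.
* **Synthetic data** (`sifi.simulate`) — generators for every input the
  lab instruments would produce (IRFs, decays, traces, abasic-position
  datasets) with known ground truth, so every analysis stage is verifiable
  by parameter recovery.

Fitting follows a statsmodels-like pattern: a model object built from data
(`ReconvolutionModel`, `DwellTimeModel`, `PeriodicProfileModel`) whose
`fit()` returns a results object with estimates, standard errors and a
`summary()`.

## Worked example

Simulate one decay at the abasic-hairpin conditions (stacked 2.65 ns,
intermediate 1.3 ns, unstacked 0.3 ns at populations 0.25/0.25/0.5; 8 ps
channels, 120 ps FWHM IRF, 20 000 peak counts) and fit it:

```python
from sifi import (ABASIC_HAIRPIN, InstrumentConfig, simulate_irf,
                  simulate_decay, fit_reconvolution, select_n_components)

cfg = InstrumentConfig()
irf = simulate_irf(cfg, seed=1)
decay = simulate_decay(ABASIC_HAIRPIN, cfg, irf, seed=2)
n = select_n_components(decay, irf)     # -> 3
fit = fit_reconvolution(decay, irf, n_components=n)
print(fit.summary())
```

```
Multi-exponential reconvolution fit
===================================
components: 3    weighting: neyman
fit range: channels [64, 1804)
reduced chi-square: 1.0205
background: 0.467 counts/channel   IRF shift: +0.016 channels

comp   tau (ns)        alpha    f_int
   1     2.6196 +/- 0.044       0.2599   0.5995
   2     1.2660 +/- 0.058       0.2424   0.2702
   3     0.2975 +/- 0.005       0.4976   0.1303

<tau> (amplitude-weighted):  1.1359 ns
tau_bar (intensity-weighted): 1.9512 ns
```

All three lifetimes and populations are recovered within a few percent, the
reduced χ² is close to 1 (an acceptable fit by the conventional criterion),
and the summaries show the stacked conformer carrying ~60% of the
steady-state emission. The same objects drive the command line:

```sh
sifi simulate-decay --preset abasic --seed 3
sifi fit-decay decay.txt irf.txt
sifi run-all --seed 7 --out-dir out   # decay fit + rates + position profile
```

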