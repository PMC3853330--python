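# msabm — agent-based Teff/Treg cross-regulation in relapsing-remitting MS

`msabm` is a stochastic lattice simulation of the immune dynamics behind
relapsing-remitting multiple sclerosis (RRMS).  A small patch of white
matter is a 51 × 51 toroidal grid of myelinated patches on which three
kinds of agents interact:

* autoreactive **effector T cells (Teff)** that, once activated, strip
  myelin from the patch they occupy and duplicate while food lasts;
* **regulatory T cells (Treg)** that hunt and suppress activated Teff and
  duplicate on success — a predator–prey loop;
* an **EBV-like viral trigger** whose contact activates resting T cells
  through molecular mimicry.

Patches that lose all myelin never recover (permanent lesions); partial
damage regrows each step.  A random seed is a *virtual patient*: the whole
trajectory is a deterministic function of (parameters, seed).  The model's
core experiment contrasts **healthy** individuals, whose Teff and Treg
share the same maximum duplication rate (`eff_dup = p_t = 0.1` per
2.4-hour step), with **"hill"** individuals whose Treg duplication is
impaired (`p_t = 0.025`), breaking the cross-balance.

The Teff duplication probability per eligible attack is

```
p_e = eff_dup · (myelin / init_mye)² · mean_Tregs / (Treg_here + mean_Tregs)
```

with `Treg_here` the number of active Tregs within `treg_radius`; Treg
duplication on successful suppression is Bernoulli with constant `p_t`.
See `docs/methods.md` for the full rule set, the parameters (with units
and defaults), and the calibration of the constants that have no
published value.

The package is aimed at computational immunologists and systems-biology
modelers who want a reproducible, scriptable reimplementation of this
class of NetLogo-style models — with a compiled fast engine, a
transparent pure-Python reference engine, and cohort statistics
(medians, two-sample Kolmogorov–Smirnov comparison, relapse-episode
extraction) built in.

## Worked example

Simulate one hill patient and one healthy patient for 5 years
(18250 steps) each:

```bash
$ msabm run --seed 7 --scenario hill --out run7
seed 7 (hill): final damage recoverable=22 unrecoverable=80900 total=80922 myelin units

$ msabm run --seed 7 --scenario healthy --out run7h
seed 7 (healthy): final damage recoverable=2 unrecoverable=500 total=502 myelin units
```

The same genetic predisposition and the same viral exposure (same seed)
end in 809 permanently demyelinated patches when Treg duplication is
impaired, versus 5 when regulation is intact — damage is measured in
myelin units, where one destroyed patch contributes `init_mye` = 100.
Each output directory holds `timeseries.csv` (per-step populations and
recoverable/unrecoverable/total damage), `myelin.csv` (final lattice),
`snapshot.png` (one pixel per patch: light = intact, dark = recovering,
black = lesion), and `provenance.json` (the fully resolved
configuration).

The same from Python:

```python
from msabm import Params, HILL, run_cohort, ks_two_sample

params = Params()                      # published defaults
cohort = run_cohort(params, HILL, n=20, base_seed=100, steps=18250)
print(cohort.median)                   # ≈ 77215 myelin units
```

`msabm cohort` runs one arm from the shell; `msabm compare` runs both
arms and writes a JSON report with the two medians and the KS statistic.

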