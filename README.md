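# repairkinetics

Kinetic modelling of DNA strand-break repair in a ~172 kb circular
minichromosome (the chromatinised Epstein–Barr virus episome), for
researchers quantifying repair from pulsed-field gel electrophoresis
(PFGE) band time courses.

After ~50 Gy of ionising radiation essentially every minichromosome copy is
linearised by one double-strand break (DSB) and carries ~8–9 single-strand
breaks (SSBs). Repair returns molecules to the supercoiled form through
four compartments — linear with SSBs (`LSSB`), clean linear (`L`), nicked
circular (`CSSB`), supercoiled (`S`) — with first-order transfer rates
(fractions of molecules moved per hour):

```
dS/dt    =  k_d·L + k_s·CSSB          k_sd : LSSB → L     (SSB repair)
dL/dt    =  k_sd·LSSB − k_d·L         k_ds : LSSB → CSSB  (DSB repair)
dLSSB/dt = −(k_sd + k_ds)·LSSB        k_d  : L → S        (DSB repair)
dCSSB/dt =  k_ds·LSSB − k_s·CSSB      k_s  : CSSB → S     (SSB repair)
```

with `k_d`, `k_ds` multiplied by a binary switch `s_inh` (0 when DSB repair
is arrested by a DNA-PKcs inhibitor such as NU7441) and an `hr_factor`
≤ 1 for partial homologous-recombination impairment. The gel observes two
bands — `linear_total = L + LSSB` and `supercoiled = S` — and the model is
fitted to both conditions jointly by multistart bounded least squares with
the tied-rate constraint `k_s = k_sd`, `k_d = k_ds` (the four-rate model is
not practically identifiable from two bands). The package provides the
exact and numerical solvers, the fitting machinery with bootstrap
confidence intervals and identifiability diagnostics, molecule-level
break/fragmentation simulation, a synthetic-data generator, and a CLI.

See `docs/methods.md` for assumptions, parameter conventions and
limitations.

## Worked example

```python
from repairkinetics import (
    StrandBreakRepairModel, generate_dataset, reference_config,
    estimate_ssb_count, per_break_repair_time,
)

# synthetic two-condition time course at the reference parameters
table = generate_dataset(reference_config(seed=8, noise_sd=0.03))
res = StrandBreakRepairModel(table, tie_rates=True).fit(n_starts=20, seed=0)
res.conf_int(n_boot=200, seed=0)
print(res.summary())
```

```
Strand-break repair kinetics: least-squares fit
========================================================
Conditions:        control, NU7441
Observations:      60
Tied rates:        True   Shared init: True
Multistart:        20 starts (seed 0)
SSR:               0.053722
Residual scale:    0.03125
--------------------------------------------------------
parameter       estimate      2.5%     97.5%  t1/2 (min)
k_s               0.2392    0.1725    0.2647       173.9
k_d               0.7542    0.7076    0.7911        55.1
S0                0.0128    0.0076    0.0221
L0                0.0000    0.0000    0.1074
LSSB0             0.9872    0.8771    0.9908
CSSB0             0.0000    0.0000    0.0126
========================================================
```

The fitted `k_s` ≈ 0.24/h and `k_d` ≈ 0.75/h recover the generating values
(0.21 and 0.74 per hour) within the bootstrap intervals: about 21% of
SSB-carrying molecules and 74% of DSB-carrying molecules are repaired per
hour, i.e. first-order half-times of roughly 3 h and 1 h. The fitted
initial state is almost entirely `LSSB`, as expected immediately after
irradiation.

Break-burden arithmetic from the fragmentation assay:

```python
est = estimate_ssb_count(mean_fragment=20.0, genome_length=172.0)
print(est.integer_pair, est.midpoint)                  # (8, 9) 8.5
print(per_break_repair_time(140.0, est.midpoint))      # 16.5 min per break
```

Command-line equivalents:

```bash
repairkin simulate --seed 1 --out data.csv
repairkin fit --data data.csv --n-starts 100 --seed 1 --boot 200 --out fit.json
repairkin predict --inhibitor NU7441 --horizon 20 --out trajectory.csv
repairkin breaks --mean-fragment 20 --genome 172
repairkin compare --data-a a.csv --data-b b.csv --condition-a control \
    --condition-b NU7441 --observable supercoiled --time 2
```

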