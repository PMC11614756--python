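# qdtherm

Analysis pipeline for quantum-dot (QD) nanothermometry of myosin ATPase
activity: from raw microplate fluorescence kinetics to per-animal myosin
efficiency indices and a between-group comparison.

## The problem

CdTe quantum dots adsorbed to extracted myosin act as nanoscale
thermometers: their fluorescence intensity falls as the microenvironment
warms during ATP hydrolysis. The steeper the decay of relative
fluorescence, the more chemical energy is dissipated as heat per unit
myosin — i.e. the **lower** the motor's mechanochemical efficiency. This
package implements the complete analysis for such an assay, as used to
compare soleus-muscle myosin from control rats (CON) against rats exposed
to five days of an experimental ICU condition (EXP):

1. each well's fluorescence trace F(t), read every 5 s for 2 min, is
   normalised to its starting value, F(t)/F(0);
2. a polynomial (default degree 2) is fitted by OLS over the window and
   the **initial rate** is taken as the magnitude of the t = 0 slope,
   r = −c₁;
3. the mean rate of the preparation's blank wells (0 mM ATP) is
   subtracted and the result is normalised by the effective myosin
   concentration in the well (A280 total protein, blank- and
   BSA-controlled, divided by the dilution factor):

   index = (r_ATP − r̄_blank) / c   [s⁻¹ per mg·mL⁻¹]

4. sextuplicate replicates are QC'd — negative indices (null reactions)
   are excluded first, then a single-pass band of one sample SD around
   the remaining mean;
5. surviving replicates aggregate preparation → animal → group, with
   group mean ± SD computed over animal means (n = animals);
6. preparations with an elevated fast type IIa MyHC fraction
   (> 10 % by gel densitometry) form a separate stratum, since fast
   isoforms run the reaction with less heat; the main-stratum groups are
   compared with the pooled-variance unpaired Student t-test, two-sided.

A synthetic-study generator draws complete, ground-truthed datasets from
a hierarchical model matched to the study conditions, so every stage is
testable without lab data.

## Worked example

```python
from qdtherm import SyntheticConfig, ThermometryAssay, generate_study

dataset = generate_study(SyntheticConfig(seed=3))      # 5 CON vs 5 EXP rats
results = ThermometryAssay.from_synthetic(dataset).fit()
print(results.summary())
```

prints

```
Quantum-dot thermometry: myosin efficiency index
============================================================
polynomial degree 2, window [0, 120] s, QC band 1 SD
replicates: 60 (39 included, 3 negative, 18 outside SD band)
------------------------------------------------------------
group   stratum    n animals    mean index        SD
CON     main               5        0.5543     0.161
EXP     main               5         1.687     0.472
------------------------------------------------------------
Student (pooled) unpaired t-test, main stratum: t = -5.079, df = 8, two-sided p = 0.0009542
larger index = steeper fluorescence decay = more heat = lower myosin efficiency
```

The EXP group's mean index is about three times the CON group's: ICU-like
exposure makes the fluorescence decay steeper, i.e. myosin releases more
heat per ATP and works less efficiently. `results.records` holds every
replicate with its QC verdict, `results.to_tsv("results.tsv")` writes the
full report, and `results.plot_indices()` reproduces the dot-plot view
(solid dots = qualified preparations, open circles = animal means).

The same steps run from the shell:

```bash
qdtherm simulate --seed 3 --out-dir study/
qdtherm run --data-dir study/ --out results.tsv
qdtherm compare --mean-a 0.47 --sd-a 0.25 --n-a 5 \
                --mean-b 1.47 --sd-b 0.44 --n-b 5
```

Input formats are plain CSV: a wide kinetics table (`time_s` + one column
per well), and long tables for plate layout, sample metadata, A280
readings and MyHC band volumes — see `docs/methods.md`.

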