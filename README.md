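# lectinquench

Analysis toolkit for characterising lectin–carbohydrate binding from
intrinsic-fluorescence quenching titrations, with companion modules for
urea-denaturation state assignment and protein-sequence consistency checks.
It was built around the study of cMoL, the 101-residue cationic coagulant
lectin from *Moringa oleifera* seeds, whose glucose/galactose binding is
mediated by the protein dimer — but every stage is generic.

## What it computes

Given emission spectra of a protein titrated with a quenching ligand at one
or more temperatures:

* **Stern–Volmer analysis** — F₀/F = 1 + K_SV·[Q], fitted by OLS with a free
  intercept (deviation from 1 is reported as a diagnostic).
* **Mechanism classification** — static vs dynamic quenching from the sign
  and significance (z = slope/SE) of the K_SV-vs-T trend: ground-state
  complexes dissociate on heating (K_SV falls ⇒ static), collisional
  quenching intensifies (K_SV rises ⇒ dynamic).
* **Binding constants** — modified Stern–Volmer double-log fit
  log₁₀((F₀−F)/F) = log₁₀ K_a + n·log₁₀[Q].
* **Van 't Hoff thermodynamics** — ln K_a vs 1/T gives ΔH and ΔS; ΔG is
  reported by *both* routes, −RT·ln K_a and ΔH − TΔS, with a consistency
  report that flags disagreements instead of merging them.
* **Hill cooperativity** — (F₀−F)/F₀ = B_max·[Q]ʰ/(K_dʰ + [Q]ʰ) by
  multistart nonlinear least squares; h ≈ 2 indicates all-or-none binding to
  a functional dimer.
* **Denaturation analysis** — replicated λ_max/I_max statistics (one-way
  ANOVA + Tukey HSD, α = 0.1 by default), CD218 comparison, a three-state
  verdict per denaturant concentration (native / intermediate monomer /
  unfolded), and hemagglutination titers with loss classification.
* **Sequence checks** — composition, simple pH-7 net charge,
  Needleman–Wunsch global percent identity, solvated-box molarity
  arithmetic.

A seeded synthetic-data generator (`lectinquench.synthetic_data`) produces
titration, denaturation, CD and hemagglutination datasets with known ground
truth, so the whole pipeline is testable without instrument data.

## Worked example

```python
import lectinquench as lq
from lectinquench.binding import (quench_points, stern_volmer_fit,
                                  modified_sv_fit, hill_fit, classify_mechanism)

cfg = lq.GeneratorConfig(noise_rel=0.01, seed=42)   # static quencher, 3 temperatures
ests, ka_by_t = [], {}
for series in lq.gen_titration(cfg):
    pts = quench_points(series, f_mode="integral")
    est = stern_volmer_fit(pts, temperature_K=series.temperature_K)
    bf = modified_sv_fit(pts, temperature_K=series.temperature_K)
    ests.append(est); ka_by_t[series.temperature_K] = bf.ka_per_M
    print(f"T={series.temperature_K:.0f} K  Ksv={est.ksv_per_M:6.2f} 1/M  "
          f"Ka={bf.ka_per_M:6.2f} 1/M  n={bf.n_sites:5.3f}")
call = classify_mechanism(ests)
print(f"mechanism: {call.verdict} (z = {call.z_score:.1f})")
p = lq.vant_hoff_fit(ka_by_t)
print(f"dH = {p.dH_J_mol/1000:.1f} kJ/mol, dS = {p.dS_J_K_mol:.1f} J/(K mol)")
```

prints

```
T=298 K  Ksv= 28.37 1/M  Ka= 26.66 1/M  n=0.986
T=303 K  Ksv= 19.77 1/M  Ka= 18.46 1/M  n=0.981
T=308 K  Ksv= 14.39 1/M  Ka= 16.91 1/M  n=1.037
mechanism: static (z = -53.9)
dH = -34.9 kJ/mol, dS = -90.1 J/(K mol)
```

The falling K_SV marks static quenching (ground-state complex formation);
K_a ~ 10¹–10² M⁻¹ is the weak, reversible affinity typical of
lectin–monosaccharide interactions, and the negative ΔG values confirm the
binding is spontaneous.  Fitting the Hill isotherm to a cooperative
(concerted two-site) dataset recovers `h = 1.99, Kd = 6.02 mM, Bmax = 1.00`.

The same analyses are available from the shell:

```sh
lectinquench simulate --out bundle --seed 42 --noise-rel 0.01
lectinquench run --bundle bundle --out report.json
lectinquench quench classify --bundle bundle
lectinquench seq charge QARRPAIQR...   # or a FASTA path
```

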