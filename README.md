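# thermotraits

Thermal-physiology trait analysis for microbial isolates: derive growth,
respiration and ATP traits from raw culture assays, fit Sharpe–Schoolfield
thermal performance curves, quantify the phylogenetic signal of thermal
optima, and run community-level trait statistics — with a synthetic-data
generator that replaces wet-lab inputs by simulations with known ground
truth.

## Who this is for

Microbial ecologists studying how temperature structures bacterial
communities — in particular *species sorting* experiments in which
replicate communities are incubated across a temperature gradient and the
thermal preferences and life-history strategies (r- vs. K-selection) of
the emerging isolates are compared.

## The models at the core

**Trait derivation.** An assay tracks a culture growing exponentially for
`t` hours. With carbon biomass `C` obtained from flow-cytometry cell
counts and diameters (spherical cells; carbon per cell
`fgC = 133.754 · V^0.438`, `V` in µm³):

- growth rate `µ = ln(C_tot/C_0) / t` (h⁻¹),
- respiration rate `R = µ·R_tot / (C_0·e^{µt} − C_0)` (h⁻¹), which
  accounts for biomass changing while carbon accumulates,
- ATP from the peak luminescence reading via
  `log10(nM ATP) = 1.21·log10(RLU) − 4.69`.

**Thermal performance curves.** The four-parameter Sharpe–Schoolfield
model with explicit peak temperature,

```
B(T) = B0 · exp(−E/k · (1/T − 1/Tref)) /
       (1 + E/(ED − E) · exp(ED/k · (1/Tpk − 1/T)))
```

with activation energy `E` (eV), deactivation energy `ED > E`, Boltzmann
constant `k = 8.617e−5 eV/K`, is fitted by multi-start nonlinear least
squares. It yields the thermal optimum `Topt = Tpk − 273.15`, the peak
rate `B(Tpk)` in closed form, and the operational niche width (`Topt`
minus the temperature below the peak where the rate halves).

**Phylogenetic signal.** Pagel's λ (maximum likelihood on [0, 1],
likelihood-ratio test) and Blomberg's K (permutation test) quantify
whether closely related isolates share similar `log(Topt)`; ancestral
optima are reconstructed at internal nodes by GLS under Brownian motion.

**Community statistics.** A nested F-test compares quadratic vs. straight-
line regressions of `Topt` on sorting temperature; PCA (variables scaled
to mean 0, SD 1) exposes r/K trait structure; log–log OLS estimates the
ATP–respiration scaling exponent per phylum; Wilcoxon rank-sum tests
contrast (optionally Arrhenius-corrected, default `E = 0.61 eV` to 20 °C)
rates between phyla.

## Worked example

```python
from thermotraits import synthetic_data as synth, tpc_fitting as tpc, phylo_signal as ps
from thermotraits.community_stats import quadratic_vs_linear

# fit a thermal performance curve to noisy simulated rates
params = tpc.SSParameters(b0=0.08, e=0.65, ed=3.0, tpk=303.15)
obs = synth.generate_tpc_observations(synth.SyntheticTPCTruth(
    isolate_id="iso1", params=params, noise_cv=0.05, replicates=4, seed=11))
fit = tpc.fit_ss(obs)
print(f"Topt = {fit.topt:.2f} C, peak rate = {fit.peak_rate:.3f} /h, "
      f"niche width = {fit.niche_width:.2f} C, E = {fit.params.e:.3f} eV")

# a full community sorting scenario
table, tree = synth.generate_community_scenario(synth.ScenarioConfig(seed=1))
sorting = table[table.isolation_mode == "sorting"]
cmp = quadratic_vs_linear(sorting.incubation_temp, sorting.topt)
print(f"quadratic vs linear: F = {cmp.f_statistic:.1f}, p = {cmp.p_value:.2e}")
lam = ps.estimate_lambda(tree, table.topt, transform="log")
print(f"Pagel's lambda on log(Topt): {lam.value:.3f} (p = {lam.p_value:.1e})")
```

prints

```
Topt = 30.06 C, peak rate = 0.946 /h, niche width = 11.14 C, E = 0.636 eV
quadratic vs linear: F = 118.0, p = 1.95e-12
Pagel's lambda on log(Topt): 1.000 (p = 1.1e-34)
```

The true curve peaked at 30 °C (`Tpk = 303.15 K`) with `E = 0.65 eV`, so
the fit recovered both within the 5% measurement noise. In the scenario,
isolates' optima track their sorting temperature but sit above it at the
cold end, so the quadratic model wins decisively; optima cluster in
clades, giving λ at the Brownian ceiling.

A command-line interface mirrors the library
(`thermotraits run-all --out demo --seed 1`, plus per-stage subcommands
`simulate`, `derive-traits`, `fit-tpc`, `phylo-signal`,
`community-stats`).

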