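# cpim — a contact-process Ising model of growing bacterial colonies

`cpim` simulates and analyzes spatial patterns of gene expression in
growing bacterial colonies whose cells carry two-state, chemically
coupled gene networks.  It is aimed at researchers studying how
short-range cell-cell coupling (e.g. quorum-sensing signals linking
toggle-switch states) produces long-range spatial correlations,
critical-like patterns and power-law cluster statistics in colonies.

## The model

Cells live on an L x L lattice in four states
S = {vacant, undifferentiated `*`, +1, -1} and evolve by

* **contact-process demography** — colonization of a vacant site with
  probability 1-(1-b)^k per attempt (k occupied neighbours), death with
  probability d, differentiation `*` -> +/-1 with probability g;
* **Ising dynamics** — differentiated cells interact through
  H = -J Σ_⟨ij⟩ σ_i σ_j (pairs of differentiated cells only) and flip
  by the Metropolis rule with acceptance min(1, e^(-ΔH/T)), k_B = 1.

J = +1 (ferromagnetic coupling) favours homogeneous expression
domains; J = -1 (anti-ferromagnetic) favours checkerboard order.  The
control parameter T sets the coupling strength; near the Ising
critical point T_c ≈ 2.27 the colonies self-organize into long-range
correlated, power-law patterns.

The analysis stack quantifies those patterns:

* magnetization m = M/n_occ, susceptibility per occupied site
  χ^N = ⟨n⟩(⟨m²⟩-⟨|m|⟩²)/T, temperature scans and finite-size scaling
  (peak height/location vs L, T_c extrapolation);
* radial spatial autocorrelation C(r) of the signed state field under
  arbitrary masks, with the exponential-decay fit
  y0·e^(-r/b)+C (length constant b = mean domain size) and the
  critical form C(r) = A·e^(-r/B)/r^η;
* connected same-state cluster sizes and the power-law exponent of
  P(S) ~ S^(-γ) by discrete maximum likelihood (automatic low-end
  cutoff) and log-binned least squares;
* rotation-minimized Hamming distance between binary patterns
  (24 orientations in 15° steps);
* the two-state thermodynamic promoter model
  P_on = (1 + [(1+L/Kd_off)/(1+L/Kd_on)]^n · e^(-nβΔE))^(-1)
  with fitting and a synthetic two-channel dose-response generator.

## Worked example

Grow a ferromagnetic population at the critical coupling and
characterize its pattern:

```python
import cpim
from cpim import spatial

p = cpim.CPIMParams(L=96, T=2.27, J=1, b=0.03, d=1e-5, sweeps=1500, seed=7)
res = cpim.run_simulation(p, stop_at_edge=False)
last = res.series.iloc[-1]
print(f"occupied sites: {int(last.n_occupied)} of {96*96}")
print(f"magnetization per occupied site m = {last.m_per_occupied:+.4f}")

acf = spatial.radial_autocorrelation(res.lattice.grid, r_max=48.0)
exp_fit = spatial.fit_exponential_decay(acf, r_max=32.0)
print(f"sACF length constant b = {exp_fit.b:.2f} lattice units")

clusters = spatial.label_clusters(res.lattice.grid)
mle = spatial.fit_powerlaw_mle(clusters.sizes)
print(f"cluster-size exponent gamma = {mle.gamma:.2f} (x_min = {mle.x_min})")
```

Output:

```
occupied sites: 9215 of 9216
magnetization per occupied site m = +0.2576
sACF length constant b = 5.85 lattice units
cluster-size exponent gamma = 1.84 (x_min = 1)
```

The colony has filled the lattice; its net magnetization is small (no
state dominates), same-state domains have a mean size of about six
lattice units, and the cluster-size distribution is scale-free with an
exponent near the critical value — one colony's worth of the ensemble
statistics computed by the acceptance pipeline below.

The same operations are available from the shell:

```bash
cpim simulate --L 96 --T 2.27 --J 1 --b 0.03 --d 1e-5 --sweeps 1500 \
     --seed 7 --no-stop-at-edge --out-dir run/
cpim sacf run/grid_final.txt --out-dir run/acf
cpim clusters run/grid_final.txt --out-dir run/cl
cpim fitpl run/cl/clusters.csv --out-dir run/pl
```

Every command writes a `manifest.json` (parameters, seed, version)
beside its outputs, so each artifact is reproducible from its manifest
alone.

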