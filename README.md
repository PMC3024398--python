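# qqcr — quantity-quality consumer-resource dynamics

`qqcr` simulates and analyses *metaphysiological* consumer-resource models in
which every population carries two states: its abundance X (biomass density)
and its average quality Q ∈ (0, 1].  Extracted resources are converted to
biomass and split by an allocation proportion u between growing the
population (u) and raising its average quality (1 − u); low-quality
populations senesce faster.  The framework is aimed at theoretical
ecologists studying how quality dynamics, seasonal forcing, and adaptive
allocation switching shape the stability and oscillation periods of
consumer-resource interactions — from ungulate-vegetation systems to
microbial growth curves.

In log variables x = ln X, q = ln Q the consumer core is

    dx/dt = u·I − µ + α·q
    dq/dt = a·(−q)·(1 − u)·I − c·µ − b·α·q

with converted intake
I = κ(Q_R)·sech(w(u − v))·δ·ρ/(1 + ρ + (X/K)^γ), ρ = R/β
(a Beddington–DeAngelis extraction law with interference abruptness γ,
quality-dependent conversion κ(Q_R) = λ·Q_R^(1/(1+c)), and a sech efficiency
penalty for allocations away from the set point v).  Three variants are
provided: a consumer on a fixed resource background, a consumer coupled to a
logistic resource with seasonally forced carrying capacity S(t) and resource
quality Q_R(t), and a full four-state system in which the resource is itself
a quantity-quality population.

The library covers:

* hybrid trajectory integration in log coordinates, with event-detected
  threshold allocation switching, sliding-mode (Filippov) regulation, and an
  extinction cutoff;
* the closed-form optimal constant allocation v*± (from the singular-arc
  conditions of maximising ∫ ln X dt) and its numerical co-verification by
  an equilibrium sweep over u;
* equilibria, Jacobian spectra and stability classification, oscillation
  period estimation (inter-peak and spectral), windowed statistics, and
  growth-phase segmentation (lag / LogEx / RegEx / inhibition / stationary /
  decline);
* parameter sweeps, scenario presets, and a command-line interface.

## Worked example

```python
from qqcr import (AllocationPolicy, baseline, estimate_period, simulate,
                  summary_stats, v_star)

p = baseline()

vs = v_star(p)
print(f"optimal allocation: v+ = {vs.v_plus:.6f}, v- = {vs.v_minus:.6f}")

traj = simulate("cr3", p, 0.5, None, (0.0, 300.0))
print(f"baseline 300 mo: X = {traj.X[-1]:.0f}, R = {traj['R'][-1]:.0f}, "
      f"Q_X = {traj['Q_X'][-1]:.3f}")

slow = simulate("cr3", p.with_(r=0.3), 0.5, None, (0.0, 2400.0))
est = estimate_period(slow, (1200.0, 2400.0), min_distance_months=18.0)
print(f"r = 0.3: period ~{est.rounded} years ({est.n_peaks} peaks)")

pf = p.with_(delta=7.0, d_r=0.45, d_s=0.45)
pol = AllocationPolicy.threshold(0.0, 1.0, 4000.0, "grow_below")
reg = simulate("cr3", pf, pol, None, (0.0, 1200.0))
st = summary_stats(reg, (960.0, 1200.0))
print(f"switching at X_switch = 4000: min {st.min:.0f}, max {st.max:.0f}, "
      f"mean {st.mean:.0f}, sigma {st.sigma:.1f}")
```

prints

```
optimal allocation: v+ = 0.704124, v- = 0.295876
baseline 300 mo: X = 50409, R = 650661, Q_X = 0.439
r = 0.3: period ~11.4 years (9 peaks)
switching at X_switch = 4000: min 4000, max 4000, mean 4000, sigma 0.0
```

Reading the output: the closed-form singular-arc roots bracket the baseline
set point; the unforced coupled system settles to a stable equilibrium within
25 years; slowing the resource's regrowth rate to r = 0.3 destabilises the
interaction into a multi-year consumer-resource cycle; and under strong
seasonal forcing the threshold allocation rule pins the consumer exactly at
the switching abundance by sliding-mode regulation — the allocation control
chatters between its bounds while abundance holds a narrow band.

The same computations are available from the shell:

```sh
qqcr vstar
qqcr simulate --variant cr3 --months 300 --out run
qqcr period --set r=0.3 --months 2400 --window 1200
qqcr scenario fig3d --out out/fig3d
```

Presets `fig1`, `fig2a`–`fig2f`, `fig3a`–`fig3f`, `fig4a`–`fig4f`, `fig5`,
`table3a`, `table3b` reproduce the framework's standard numerical studies;
`qqcr scenario <id> --out DIR` writes trajectory/sweep CSVs plus a
`summary.json` echoing every effective setting.

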