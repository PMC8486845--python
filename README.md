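# zipperjunction

Analysis and simulation toolkit for single-molecule junctions formed by a
DNA duplex in the **zipper configuration**: both thiol linkers at the same
duplex end, the helix perpendicular to the electrode gap, so that the
junction fails by *unzipping* base pairs rather than by breaking an Au–S
bond — and can spontaneously restore itself when the partially unzipped
duplex reanneals.

It is written for people who work with STM break-junction (BJ) data and
coarse-grained pulling simulations, and it covers the full computational
chain of such a study:

* **`synthetic_data`** — seeded generators for every input: two-segment
  exponentially decaying conductance–displacement (G–z) traces with a
  molecular plateau, bimodal current–voltage sweep ensembles,
  consecutive-trace series with persistent or independent junction
  formation, and random DNA sequences.
* **`trace_analysis`** — displacement origin convention (z = 0 where G
  first drops below 50 mG₀), per-trace-histogram plateau filtering, 1D/2D
  conductance histograms with Gaussian peak fitting, and two-segment
  tunnelling decay constants: G ∝ exp(−βz) fitted during (β₁) and after
  (β₂) the plateau, in Å⁻¹.
* **`tvs`** — transition voltage spectroscopy: high/low conductance state
  classification, the Fowler–Nordheim representation log₁₀(I/V²) vs 1/V,
  and V_trans at its interior minimum.
* **`restoration`** — dwell length of each trace inside a conductance
  band, formation judgement against a plateau-length threshold, longest
  success runs, and a joint-probability test (p_joint/p_form², permutation
  null) separating repeated from random junction formation.
* **`zipper_sim`** — a sequence-dependent 1D zipper model: fork coordinate
  n_open over nearest-neighbour opening free energies, freely-jointed-chain
  ssDNA elasticity, two 8.5 N/m tether springs, and Metropolis kinetic
  Monte Carlo under a pull–hold–return (or release) tip protocol. It
  reproduces partial unzipping under a 30 nm pull, unzip forces of tens of
  pN (far below the 1–2 nN Au–S rupture scale), and complete spontaneous
  reannealing.

See `docs/methods.md` for the models, defaults, and numerical choices.

## Worked example

```python
import numpy as np
from zipperjunction.synthetic_data import preset_trace, gen_bj_ensemble, gen_sequence
from zipperjunction.trace_analysis import (set_displacement_origin,
    filter_plateau_traces, conductance_peak, fit_decay_constants)
from zipperjunction.zipper_sim import (Duplex, ZipperParams, Protocol,
    kmc_run, unzip_force_plateau)

# 500 synthetic 90-mer BJ traces -> filter -> plateau peak and betas
ens = [set_displacement_origin(t)
       for t in gen_bj_ensemble(preset_trace("90mer"), 500, seed=1)]
retained, report = filter_plateau_traces(ens)
peak = conductance_peak(retained, (-3.1, -2.35))
fits = [fit_decay_constants(t, r) for t, r in zip(ens, report)
        if r.present and r.z_end > r.z_start]
print(f"retained {len(retained)}/{len(ens)} traces")
print(f"plateau peak: {peak.center:.2f} mG0")
print(f"median beta1: {np.median([f.beta1 for f in fits]):.3f} A^-1, "
      f"median beta2: {np.median([f.beta2 for f in fits]):.2f} A^-1")

# pull a tethered 90-bp duplex 30 nm, hold, return
dup = Duplex.from_sequence(gen_sequence(90, 0.5, seed=1))
traj = kmc_run(dup, ZipperParams(), Protocol(), seed=1)
print(f"max open pairs: {traj.n_open.max()}, final intact pairs: {traj.n_duplex[-1]}")
print(f"unzip force plateau: {unzip_force_plateau(traj):.1f} pN, "
      f"max force: {traj.force.max():.1f} pN")
```

prints

```
retained 381/500 traces
plateau peak: 1.99 mG0
median beta1: 0.260 A^-1, median beta2: 1.99 A^-1
max open pairs: 28, final intact pairs: 90
unzip force plateau: 14.4 pN, max force: 20.3 pN
```

The filter keeps the ~80 % of approaches on which a junction formed; the
Gaussian-fitted plateau sits at the 1.9 mG₀ preset (the one-sided decay
background biases it ~5 % high); the noisy-ensemble β medians recover the
generator's 0.27 and 2.0 Å⁻¹. The 30 nm pull unzips only 28 of 90 pairs
at a ~14 pN force plateau — three orders of magnitude below Au–S rupture —
and the duplex reanneals completely after the tip returns, the mechanism
behind the junction's self-restoring behaviour.

A thin CLI mirrors the library:

```bash
zipperjunction generate traces --preset 90mer --n 500 --seed 1 --out traces/
zipperjunction analyze --in traces/ --out analysis/
zipperjunction simulate --n-bp 90 --protocol pull-hold-return --pull 30 --seed 1 --out sim/
```

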