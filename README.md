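# antisync

Anticipating spike synchronization in unidirectionally coupled
Hindmarsh–Rose neuron networks: chaotic network simulation, per-spike
anticipation analysis, and a causal-window synaptic-plasticity rule driven
by it.

## The problem

When a chaotic "slave" neuron is driven by a "master" neuron and is
intrinsically slightly faster than its driver, the pair can synchronize with
the slave firing *before* the master — anticipating synchronization. This
package simulates that phenomenon in networks of Hindmarsh–Rose (HR)
neurons and quantifies its functional consequences:

- how a chain of intermediary relay neurons between master and slave
  enhances the per-spike anticipation;
- how anticipation reshapes the firing regime (tonic, phasic bursting, fast
  spiking in slow bursts) of a convergent neuron X receiving excitatory
  master input and inhibitory slave input;
- how each spike's anticipation correlates with its preceding interspike
  interval (ISI), discriminating burst-initiating, intra-burst and
  burst-ending spikes;
- how a causal plasticity window (potentiate the slave→X synapse when the
  slave-origin spike precedes the master-origin spike within a half-width
  `w`, depress otherwise) converts that structure into net potentiation or
  depression.

It is aimed at computational neuroscientists studying synchronization,
spike-train structure and timing-based plasticity in small model circuits.

## The model

Each neuron follows the Hindmarsh–Rose equations with a capacitance-like
time-scale factor `C` on the fast variable; diffusive coupling enters the
fast equation of the driven neuron:

    C ẋ = y + x²(b − a x) − z + J₀ + Σₖ k (x_pre − x)
      ẏ = c − d x² − y
      ż = r (s (x − x_st) − z)

with a = 1, b = 3, c = 1, d = 5, s = 4, r = 0.005, x_st = −1.6, J₀ = 3.25.
The chain sets C_master = 1 > C₁ > … > C_n > C_slave = 0.7 (equispaced) so
every driven neuron is slightly faster than its driver — the precondition
for anticipation — with all couplings k = 1.7. Per-spike anticipation is
`t_master − t_slave` for the nearest pair of spike maxima (positive when
the slave leads).

Integration uses an adaptive explicit Runge–Kutta 4(5) scheme at tolerance
1e-10 from zero initial conditions, discarding a 300-time-unit transient
and sampling the dense output at step 0.01 over a window of `T = 5 × 10⁴`
(a compiled Dormand–Prince loop by default; `scipy.integrate.solve_ivp`
RK45 and fixed-step RK4 as cross-check backends).

## Worked example

```python
from antisync import run_basic_chain, anticipation_enhancement
from antisync.spikes import anticipation_vs_isi, principal_clusters
from antisync.plasticity import PlasticityParams, window_sweep

n3 = run_basic_chain(3)   # master -> 3 intermediaries -> slave, T = 5e4
n0 = run_basic_chain(0)   # direct master -> slave coupling

print(len(n3.table), n3.table["anticipation"].median())
print(anticipation_enhancement(n3.table, n0.table, statistic="max"))

clusters = principal_clusters(anticipation_vs_isi(n3.table))
print(clusters[["count", "isi_mean", "anticipation_mean"]].round(3))

print(window_sweep(n3.table, [0.3, 0.4, 0.5], PlasticityParams(g0=3.0)))
```

prints (chaotic trajectories differ across platforms at the last digits;
these statistics are stable):

```
1549 0.48851395260862773
3.044607899061722
   count  isi_mean  anticipation_mean
0    333    13.406              0.706
1    604    18.456              0.483
2    195    28.659              0.125
3     32    29.616              0.540
4     40    59.449              0.257
5    294    78.751              0.438
```

Reading: over 5 × 10⁴ time units the slave fires 1549 spikes, each leading
its master partner (median lead 0.49 time units); the peak anticipation is
about 3× the direct-coupling peak. The ISI–anticipation diagram splits into
clusters: the fastest intra-burst spikes (mean ISI 13.4) lead by ~0.71, the
bulk by ~0.48, the burst-ending spikes by only ~0.13, and the
burst-initiating spikes (preceding ISI ~79, the inter-burst gap) by ~0.44.
The plasticity sweep returns the net change of the slave→X weight for
window half-widths 0.3/0.4/0.5:

```
{0.3: 1.768571428571624, 0.4: 3.7800000000001113, 0.5: 16.282857142856738}
```

— wider windows capture more of the anticipation distribution, ordering the
net change monotonically in `w`.

## Command line

```sh
antisync run-chain --n 3 --out runs/n3         # trajectory + anticipation CSV
antisync run-preset fig3_anticipation --out runs/f3a   # X-neuron presets
antisync analyze --traj runs/n3/trajectory.h5 --out runs/n3-analysis
antisync plasticity --table runs/n3/anticipation.csv --w 0.5 --w 0.4 --w 0.3 --out runs/pl
antisync fixtures --seed 1 --out runs/fx       # synthetic ground-truth pair
```

Every output directory contains a `provenance.json` (resolved configuration
plus package version) sufficient to re-run the identical computation.

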