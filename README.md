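# neuraltube

Gene-regulatory modelling of rostrocaudal and dorsoventral neural-tube
patterning: a minimal tristable-switch ODE model of forebrain/midbrain/
hindbrain fate under GSK3 control, data-driven selection of its network
topology, in-silico knockdown and overexpression screening, and a combined
rostrocaudal + dorsoventral network simulated with diffusing WNT and SHH
morphogens on a 3D voxel neural tube.

**Who it is for.** Computational and systems biologists studying neural
patterning or stem-cell regionalisation protocols: the in-vitro layer
models dose–response experiments in which pluripotent-cell cultures are
caudalised by a GSK3 inhibitor (CT, µM), and the 3D layer asks which
features of the embryonic neural-tube pattern a minimal circuit plus
realistic morphogen geometry can reproduce.

## The model

Brain-region fates form a tristable switch controlled by GSK3 activity,
which the inhibitor CT shuts down (high CT ≈ strong WNT). Production terms
follow the Hill formalism — activators contribute `c·x^n` to numerator and
denominator, repressors to the denominator only — e.g. for the forebrain
node:

    d[FB]/dt = c1·GSK3^n1 / (1 + c1·GSK3^n1 + c2·MB^n2 + c3·HB^n3) − δ1·FB

Topology selection enumerates all 4096 activation/repression assignments of
the twelve free interactions and fits each to data by L-BFGS-B minimisation
of the squared deviation `Ed(p) = Σ_CT Σ_i (d_i − r_i(p))²`. The 3D layer
couples the same circuit (driven by a WNT-buffer node) with the minimal
Gli/Pax6/Olig2/Nkx2.2 dorsoventral circuit; WNT and SHH diffuse by the
discrete Fick law from anatomical source voxels (roof plate, floor plate,
zona limitans, isthmic organiser, ventral midbrain) with clamped source
levels. See `docs/methods.md` for the full account.

## Worked example: knockdown screening of the fitted model

```python
import numpy as np
import neuraltube as nt

params = nt.published_defaults()            # published parameter set
topo = nt.Topology.consensus()          # data-selected tristable switch
grid = np.round(np.arange(0, 1.0001, 0.05), 3)

for spec in (nt.PerturbationSpec(),                 # wildtype
             nt.PerturbationSpec.kd("HB"),          # hindbrain knockdown
             nt.PerturbationSpec.kd("FB")):         # forebrain knockdown
    dr = nt.dose_response(params, topo, grid, spec)
    width, bounds = nt.mb_window(dr)                # strong-MB CT window
    print(f"{dr.condition:10s} MB window {width:.2f} uM  {bounds}")
```

prints

```
wildtype   MB window 0.10 uM  (0.2, 0.25)
HB-kd      MB window 0.85 uM  (0.2, 1.0)
FB-kd      MB window 0.15 uM  (0.15, 0.25)
```

Reading: in the wildtype, only a narrow band of inhibitor concentrations
(0.20–0.25 µM) commits the culture to midbrain fate — the regime relevant
for dopaminergic-neuron protocols. Knocking down the hindbrain node widens
that window more than five-fold (every concentration from 0.2 µM upward
stays midbrain), whereas knocking down the forebrain node helps far less.
Repressing hindbrain fate is therefore the robust protocol-engineering
strategy.

The same screening is available from the shell:

```bash
neuraltube dose-response --kd HB --out out/hbkd
neuraltube synth-data --seed 1 --out out/data
neuraltube select-topology out/data/expression.csv \
    --edges "FB<-FB,MB<-MB" --restarts 2 --out out/sel
neuraltube simulate3d --wnt-oex --out out/wntoex
```

Every run writes a `manifest.json` (arguments, version, seed) next to its
outputs.

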