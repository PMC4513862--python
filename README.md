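# hpk — hairpins and the kinetics of DNA duplex formation

`hpk` is a simulation package for a question from DNA nanotechnology and
biophysics: when two complementary strands carry stable hairpins, does the
lost duplex stability show up as slower hybridization or as faster melting?
For a second-order association reaction the two rate constants are tied to
the standard free-energy change of duplex formation by detailed balance,

    k+ / k- = exp(-ΔG⁰ / k_B T) / c⁰ ,      c⁰ = 1 M,

so measuring k+ (by forward flux sampling) and ΔG⁰ (from equilibrium
free-energy landscapes) determines k- without ever simulating a melting
event. The package implements, end to end:

- a secondary-structure-level state space (sets of Watson-Crick base pairs
  over one or two strands) with a nearest-neighbor ΔH/ΔS energy model,
  loop/initiation terms, a pseudoknot penalty and a box-to-standard-state
  translational term;
- exact enumeration of small systems (partition functions, landscapes,
  melting curves, mean first-passage times) as the ground truth for every
  stochastic component;
- umbrella-sampled Monte Carlo with adaptive bias learning, window
  stitching and single-histogram temperature reweighting, giving 2D
  free-energy landscapes over (inter-strand, intra-strand) base pairs,
  hairpin melting curves and ΔG⁰/Keq;
- kinetic Monte Carlo with forward flux sampling over interfaces on the
  inter-strand pair count, decomposing k+ into the first-contact rate r+
  and the success probability P+, with attachment-site statistics and
  association-pathway classification;
- detailed-balance inference of relative melting rates and a per-system
  rate table against a hairpin-free reference.

It ships the six experimental 25-mers studied in the reference systems
(probes P0/P3/P4 and complementary targets T0/T3/T4: negligible secondary
structure, a stable 3-bp hairpin, and a stable 4-bp hairpin respectively),
plus generators for designed-hairpin strand pairs and for exactly solvable
toy systems. See `docs/methods.md` for the model, its assumptions, and its
known limitations.

## Worked example

Exact thermodynamics of a toy system (an 8-nt complementary pair whose
probe carries a 2-bp hairpin stem), printed as `n_inter,n_intra,dG_kT`:

```
$ hpk oracle --n-nt 8 --hairpin --seed 3 | head -6
n_inter,n_intra,dG_kT
0,0,-0.000000
0,1,5.526600
0,2,1.817138
0,3,8.035041
0,4,5.020618
```

The unbound bin (0,0) is the reference; the doubly-hairpinned state (0,4)
sits a few k_BT above it, and the full duplex (further down the table) is
the global minimum. Every umbrella-sampling and FFS result in the test
suite is checked against these exact numbers on systems like this one.

The experimental systems run through the pipeline:

```python
from hpk.pipeline import run_pipeline, default_config

bundle = run_pipeline(default_config(), outdir="out")
print(bundle["rate_table"]["P4T4"]["k_plus_ratio"],
      bundle["rate_table"]["P4T4"]["k_minus_ratio"])
```

With the default desk-scale budgets (seed 1) this prints a hybridization
slowdown `k⁰+/k+` of about 24 and an inferred melting acceleration
`k-/k-⁰` of about 8.4e3 for the 4-bp-hairpin system — the package's
central result: the hairpins' large equilibrium destabilization of the
duplex (Keq ratio ~2e5) is absorbed almost entirely by faster melting,
not slower hybridization. The bundle also carries, per system, the
hairpin melting curve (the 4-bp and 3-bp hairpin systems melt near 66 and
65 °C, the unstructured control near 18 °C), the hairpin yields at 20 °C
(99.9%, 100.0% and 45% respectively), the constrained and unconstrained
landscapes, the FFS decomposition (r+, P+), attachment-site maps showing
first contacts strongly excluded from the P4 stem bases, and pathway
classifications showing that 93% of P4T4 association events begin with at
least one intended hairpin intact (85% for P3T3). Absolute rates are in
reduced time units (the base attempt rate sets the clock); only relative
rates are physically meaningful.

The same run is available from the shell as
`hpk run --config run.cfg --out out/`, with a plain-text `key = value`
configuration; `hpk sequences --table1`, `hpk melt`, `hpk landscape` and
`hpk ffs` expose the individual stages.

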