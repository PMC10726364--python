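# ringdyn

Intramolecular aromatic ring alignment and switching dynamics for minimal
peptoid and peptide trajectory ensembles.

## The problem

Minimal aromatic peptoids (e.g. the benzyl-bearing dimer Ac-Nf-Nf or
tripeptoids like Nk-Nf-Nf) and their peptide analogues (FF, KFF, FKF)
self-assemble — or fail to — depending on how their two phenyl side chains
organize.  Because peptoid backbone amides populate both *cis* and *trans*
states, each sequence is really an ensemble of amide conformers (cc, ct,
tc, tt), and assembly propensity tracks whether side-chain motion is
*independent* of that backbone state.  `ringdyn` computes the descriptors
that make this quantitative from any multi-molecule trajectory:

* **ρ = r_ipso / r_para** — ratio of ipso–ipso to para–para carbon
  distances between the two rings; ρ = 1.0 is exact face-to-face stacking.
* **λ** — the para–ipso–ipso–para dihedral between the rings, wrapped to
  [0, 360) (360° is added to negative torsions); λ = ±180° is coplanar.
* **Δλ switches** — a frame-to-frame change of λ of at least 20° counts as
  one ring-reorganization event; **x̄_λ** is the mean switch count per
  molecule over the population (bootstrap-validated, n = 1000).
* **η = x̄_λmax / x̄_λmin** across a sequence's amide states — the
  homogeneity parameter.  η ≈ 1 means side-chain exploration is
  backbone-independent (correlated with well-defined assembly); η ≫ 1
  means the amide state gates the aromatic dynamics.
* **ρ–λ occupancy surfaces** (60 × 60 histograms) with a quantitative
  histogram-intersection overlap between states.

The package also implements the grid-search partial-charge parametrization
used to build force fields for such residues (0.05 e lattice enumeration,
1.2–1.5× dipole-overestimation filter, ±0.2 kcal/mol water-probe energy
scoring), and a synthetic trajectory generator whose switching ground
truth is exact, so the entire pipeline is testable without an MD engine.
See `docs/methods.md` for the model details and design choices.

## Worked example

Generate a four-amide-state synthetic family whose per-frame switch
probabilities are in ratio 7:4:5:4 (cc:ct:tc:tt), run the full pipeline,
and recover the inhomogeneity:

```python
from ringdyn.synthetic_data import SyntheticSpec, generate_state_family
from ringdyn.ring_descriptors import compute_series
from ringdyn.switching_stats import mean_switches, bootstrap_x_bar, compute_eta

family, eta_truth = generate_state_family(SyntheticSpec(seed=11))
x_bars = {}
for state, (ensemble, truth) in family.items():
    summary = mean_switches(compute_series(ensemble), convention="circular")
    boot = bootstrap_x_bar(summary.per_molecule_switches, seed=11)
    x_bars[state] = summary.x_bar
    print(f"{state}: x_bar = {summary.x_bar:.2f} +/- {boot.sd:.2f} (bootstrap sd, n=1000)")
print(f"eta = {compute_eta(x_bars).eta:.3f}")
```

prints

```
cc: x_bar = 68.40 +/- 1.52 (bootstrap sd, n=1000)
ct: x_bar = 40.52 +/- 1.37 (bootstrap sd, n=1000)
tc: x_bar = 50.52 +/- 1.49 (bootstrap sd, n=1000)
tt: x_bar = 40.84 +/- 1.33 (bootstrap sd, n=1000)
eta = 1.688
```

Each of the 25 molecules per state switched its ring arrangement ~40–70
times over 2500 frames; the cc state explores λ ~1.7× faster than the
slowest states, close to the generating ratio 0.028/0.016 = 1.75 (η is
estimated from finite counts, hence the small deviation; the bootstrap 99%
interval brackets 1.75).

Real trajectories enter the same way — `read_ensemble("traj.pdb",
label="ct")` accepts multi-model PDB or XYZ (one chain or fixed atom block
per molecule), resolves the ipso/para carbons from built-in residue
templates (Phe-style `CG`/`CZ`, overridable), and feeds the identical
analysis.  The `ringdyn` CLI (`analyze`, `synthesize`, `chargefit`,
`report`) orchestrates full runs from one YAML config, writing descriptor
tables, surfaces, switch summaries, and a reproducibility manifest.

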