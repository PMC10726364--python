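# Methods

## The descriptors

`ringdyn` quantifies the *intramolecular* organization of the two phenyl
side chains carried by minimal peptoids (e.g. Ac-Nf-Nf, Nk-Nf-Nf) and their
peptide analogues (FF, KFF, FKF) across trajectory ensembles.  Two numbers
summarize one molecule in one frame:

* **ρ = r_ipso / r_para**, the ratio of the ipso–ipso to para–para carbon
  distances between the two rings.  ρ = 1 is an exact face-to-face stack;
  ρ > 1 means the para carbons approach closer than the ipso carbons
  (a "scissored" arrangement).  The ratio orientation (ipso over para) is
  fixed so that ρ > 1 ⇔ r_para < r_ipso.
* **λ**, the para1–ipso1–ipso2–para2 dihedral about the ipso–ipso axis.
  The signed torsion follows the IUPAC convention (positive clockwise
  looking from ring 1's ipso towards ring 2's); negative values have 360°
  added, so λ ∈ [0, 360).  λ = 180° is the coplanar anti (zig-zag)
  arrangement; a display-only remap to (−180, 180] is provided for plots.

Ring 1 is always the ring nearer the N-terminus.  By the dihedral reversal
identity (torsion(A,B,C,D) = torsion(D,C,B,A)) the descriptors do not
actually depend on which ring is labeled first — relabeling leaves both ρ
and λ unchanged; only a mirror reflection flips λ's sign.  The ring-order
rule is kept because it fixes the convention for molecules read from files.

## Switching statistics

The frame-to-frame change Δλ is compared between frame *i* and frame
*i* + 1; a **switch** is a step with Δλ ≥ 20° (inclusive).  Two conventions
are implemented:

* `literal` (default): |λ_{i+1} − λ_i| on the wrapped values.  This is the
  procedure as commonly stated, but it records a spurious switch when a
  small torsional drift crosses the 0/360 seam (e.g. 355° → 5° reads as
  350°).
* `circular`: min(d, 360 − d), the true angular distance, immune to the
  seam.  Recovery tests against the synthetic generator use this
  convention because the generator's ground truth is exact under it.

Every report names the convention used.  The population mean **x̄_λ** is
the arithmetic mean of per-molecule switch counts (default population: 25
molecules, 2500 frames, matching the ensemble layout the pipeline is built
for).  Bootstrap uncertainty (default n = 1000) resamples *molecules* with
replacement, because x̄_λ is defined as a mean over molecules; a frame-level
variant (`bootstrap_x_bar_steps`) that resamples per-step Δλ values is
provided since the statistic can be read either way, but the molecule-level
resampling is the default throughout.

The homogeneity parameter **η = x̄_λmax / x̄_λmin** across a sequence's
amide states (cc/ct/tc/tt) measures whether side-chain torsional
exploration is independent of the backbone amide configuration: η ≈ 1 is
homogeneous, η ≫ 1 inhomogeneous.  x̄_λmin = 0 yields η = +∞ with a warning
flag rather than an exception — degenerate but representable.  `bootstrap_eta`
resamples every state's counts independently (split from one seed) to give
a percentile interval on η.

## ρ–λ occupancy surfaces

Raw 2D histograms (default 60 bins per axis; ρ on [0, 2], λ on [0, 360))
of every (ρ, λ) pair across all molecules and frames.  Points with ρ
outside the range are tallied separately, never silently dropped, so
in-range + out-of-range always equals the input point count.  The
sampled/unsampled mask is `counts > 0`; rendering paints unsampled bins
beige.  Surface similarity is the histogram intersection of the
count-normalized surfaces, Σ_b min(â_b, b̂_b) ∈ [0, 1] — symmetric, 1 on
identical occupancy, 0 on disjoint support.  No −kT ln P transform and no
smoothing: the surface is the occupancy itself.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes — a
population of M molecules (default 25) observed over F frames (default
2500), each carrying exactly two rigid benzene rings — with *exactly known*
ground truth:

* λ(t) per molecule: uniform random start, then per step a jump of
  magnitude U[25°, 120°] with probability *p* (random sign), otherwise
  jitter U[0°, 5°].  Jump support sits at or above the 20° threshold and
  jitter strictly below it, so the number of jump events equals the
  circular-convention switch count exactly; literal-convention counts can
  differ only at seam crossings, which the ground truth tallies.
* Geometry: both para carbons lean towards the opposite ring by a template
  angle (default 60°, i.e. an axial lean of 2.78 sin 60° Å); λ is realized
  as the azimuth of ring 2's para carbon about the ipso–ipso axis, and the
  ipso separation d is solved per frame from the quadratic
  (1 − ρ²) d² + 4mρ² d − ρ²(4m² + k) = 0, k = 2q²(1 − cos λ), so that
  ρ = d / r_para matches the program exactly.  When two positive roots
  exist (ρ > 1) the smaller (compact) one is taken, deterministically.
  An exact "rotate ring 2 about the axis without moving ρ" construction is
  impossible (it would require para1 to sit on the torsion axis, which
  degenerates the torsion), so the solver keeps the two descriptors
  independently and exactly programmable instead.  Infeasible ρ programs
  (no positive real root, e.g. ρ ≫ 1 with this template) raise a
  generation error.
* Placement: a seeded random rigid rotation plus a 20 Å translation grid
  per molecule.  Descriptors are rigid-motion invariant, so the programs
  survive placement to ~1e-13°.

The per-state defaults of `generate_state_family` use switch probabilities
(cc, ct, tc, tt) = (0.028, 0.016, 0.020, 0.016) — ratio 7:4:5:4, ground
truth η = 1.75 — a four-state family with one fast and one repeated slow
state, the inhomogeneity pattern of interest at a realistic per-frame
switching rate (tens of switches per 2500-frame trajectory).

**What the generator does not emulate:** force-field energetics, solvent,
realistic amide isomerization kinetics, autocorrelated torsional diffusion,
or coupling between ρ and λ.  Passing recovery tests therefore demonstrates
that the *pipeline* measures what it claims on data with known truth — not
that any particular chemical system behaves this way.

## Charge-fit protocol

Grid search over per-atom partial charges on a 0.05 e lattice: every
combination summing to the molecular charge is enumerated (symmetry groups
tie chemically equivalent atoms to one variable; backbone atoms can be
frozen), filtered by requiring the classical dipole to overestimate the
quantum-reference magnitude by 1.2–1.5× (both edges inclusive — the band's
boundary semantics are a documented choice), then scored against reference
TIP3P water-probe interaction energies: pass iff every probe is reproduced
within ±0.2 kcal/mol.  Energies are Coulomb (332.0636 kcal·Å·mol⁻¹·e⁻²)
plus Lennard-Jones with CHARMM combining rules; 1 e·Å = 4.80320 D.
Reference dipoles and energies are *inputs* — no quantum chemistry is
performed.  Candidates are ranked by RMS deviation over probes (ties: max
|deviation|, then lexicographic charges), a deterministic replacement for
a by-hand final selection.  Enumeration is exponential in the number of
free groups; a cap (default 10⁷ lattice points) refuses oversized problems
with the computed bound.

## Numerical choices

* Coordinates in Å; angles in degrees everywhere user-facing.
* Collinear torsion atoms and coincident para carbons raise
  `DegenerateGeometryError` — they indicate corrupt input, never
  legitimate ring chemistry.
* Multi-model PDB round-trips to 1e-3 Å (format columns); XYZ to ~1e-4 Å
  (library writer precision).  No periodic-boundary unwrapping: inputs
  must be molecule-whole, and a validation pass flags any ring with
  ipso–para distance > 3 Å (an intact ring has 2.78 Å) as broken.
* "60 bins" for the surfaces is read as 60 per axis (consistent with the
  resolution of published occupancy plots).
* All randomness flows through `numpy.random.default_rng(seed)`; family
  generation splits seeds via `SeedSequence.spawn`, and every stochastic
  result records its seed.

## Problem sizes used in the checks

Recovery and conservation checks run at the native population scale
(25 molecules × 2500 frames per state; 10-seed sweeps for the η-recovery
check), which completes in seconds thanks to vectorized generation and
descriptor evaluation.  Unit tests use smaller ensembles (≤ 10 molecules,
≤ 500 frames) where the full scale adds nothing.

## Known limitations

* The literal Δλ convention's seam artifact slightly inflates switch
  counts for slowly drifting torsions; use the circular convention when
  exactness matters and report which was used.
* η is an upward-biased estimator (max/min of noisy means); the bootstrap
  interval, not the point value, should be quoted for small populations.
* The charge-fit evaluator supports rigid probe poses only; probe-pose
  generation and any bonded-parameter refinement are out of scope.
* Trajectory ingestion assumes exactly two phenyl rings per molecule;
  sequences with more rings are rejected at selection time.
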