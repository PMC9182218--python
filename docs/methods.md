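# Methods

This note documents the models implemented in `dyescreen`, the choices made
where the procedure was genuinely open, and what the synthetic fixtures do
and do not emulate.

## Units and constants

External I/O uses the field's units — nm, ps/ns, Debye, meV, M⁻¹cm⁻¹ —
and all physics is evaluated in SI behind a single conversion boundary
(`dyescreen.geometry.CONSTANTS`): ε₀ = 8.8541878128×10⁻¹² C²J⁻¹m⁻¹,
1 D = 3.3356409519×10⁻³⁰ C·m, 1 meV = 1.602176634×10⁻²² J. The gas
constant defaults to the rounded 8.31 J mol⁻¹K⁻¹ conventionally quoted
with the partitioning formula (CODATA 8.314463 is available by parameter);
the partitioning temperature defaults to 273.15 K, also by convention, and
is exposed as a parameter for users who prefer 298.15 K. The refractive
index default is water, n = 1.33.

## Exciton coupling

**Orientation factor.** κ = û_m·û_n − 3(R̂·û_m)(R̂·û_n) with û taken along
each dye's long axis (endpoint r → endpoint s as supplied). No sign
convention exists for a transition dipole axis, so κ and J are computed
signed and reported as absolute values by default; reversing one axis
flips both signs and leaves |κ|, |J| unchanged (property-tested).

**Extended dipole model.** Each transition dipole is two opposite point
charges at the dye's endpoints; the coupling is the four-term Coulomb sum
scaled by J₀ = μ_m μ_n /(4π ε₀ n² l_m l_n). For μ = 15.35 D, l = 1 nm,
n = 1.33, J₀ = 83.14 meV·nm. Degenerate inputs raise rather than return
junk: dipoles shorter than 10⁻⁶ nm are rejected at construction, and any
inter-dye endpoint pair closer than 10⁻³ nm raises a singularity error
naming the pair (overlapping charges are physically meaningless).

**Point-dipole cross-check.** J = κ μ_m μ_n /(4π ε₀ n² R³) is implemented
independently and the extended-dipole result converges to it as dye length
shrinks: measured relative difference is < 0.5% at max(l)/R = 0.01 and
< 10⁻⁴ at 0.001, excluding the null neighbourhood |κ| ≤ 0.01 where a
relative comparison is meaningless (the point-dipole coupling vanishes
while the extended−point gap stays O((l/R)²) on the dipolar energy scale,
so the ratio diverges there for any implementation).

**Aggregate classification.** |κ| near 0, 1, 1.5, 2 maps to stacked
oblique, H, tail-to-tail oblique, and J aggregates. MD distributions are
continuous, so classification uses a band half-width (default 0.1; values
outside every band are "intermediate" with the nearest canonical class
reported). The default deliberately under-claims: an intercalated dimer at
|κ| ≈ 1.35 is reported as intermediate/J-like, not forced into a class.

## Trajectory analysis

Endpoints are the unweighted geometric centroids of the two terminal
aryl-group atom selections per dye (mass weighting is an option; "center"
without weighting is the conventional choice). Coordinates are read with
MDAnalysis (GRO+XTC, multi-frame PDB) and converted Å → nm; a plain CSV
endpoint table is an equivalent entry point and round-trips bit-exactly.

Numerical/procedural choices:

* **Equilibration.** Frames before the cutoff (default 100 ns) are dropped
  before any statistic; tests verify pre-cutoff frames cannot influence
  summaries or heatmaps.
* **Periodic images.** The analyzer refuses frames in which any selected
  atom group spans > 1.5 nm — a molecule split across the periodic
  boundary — instead of guessing an unwrapping convention; re-image the
  trajectory first.
* **Intercalation states.** O2 (intercalated) iff R < 2.0 nm by default,
  midway between the observed non-intercalated (≈ 2.5–3.0 nm) and
  intercalated (≈ 0.9–1.5 nm) distance ranges; configurable.
* **Dispersion.** Summaries report the population standard deviation.
* **Heatmaps.** Default bins 0.05 nm in R, 0.05 in |κ|, 2 meV in |J|;
  edges cover the data range and counts always sum to the frame count.
* **Stride.** Times need not be exactly uniform; the stride recorded on a
  table (default 10 ps in fixtures) is advisory metadata.

## Synthetic trajectory fixtures

The generator emulates the two-state structure of dye–DNA dimer
trajectories: a non-intercalated state (large R, oblique/H-like κ) and an
intercalated state (small R, J-like κ), switched block-wise by default
(one transition, like a single intercalation event) or i.i.d. Each state
prescribes means and standard deviations for |κ| and R directly in
observable space; per frame the pair is sampled from truncated normals
(|κ| on [0, 2], R > 0.3 nm) and realized *exactly* by a coplanar geometry
family — parallel dipoles tilted at cos²θ = (1−|κ|)/3 for |κ| ≤ 1, and
mirrored "splayed head-to-tail" dipoles at cos²α = |κ|−1 for |κ| > 1 —
followed by a random rigid motion (which leaves κ, R, J invariant).
Isotropic Gaussian endpoint jitter (0.05 nm scale) is a separate
instrument-noise knob for exercising the extraction pipeline; it is not
stacked on top of prescribed dispersions by default, since that would
double-count variance.

What the fixture does **not** emulate: the joint (κ, R) structure of real
trajectories. Marginals are sampled independently, so a small fraction of
frames realize geometries with inter-dye endpoint charges near contact,
giving the per-frame |J| distribution a heavy upper tail that real,
sterically constrained dimers do not show. An opt-in excluded-volume floor
(`min_contact_nm`) resamples such frames, but it is off by default because
enforcing it cuts visibly into the prescribed marginals (≈ 18% of frames
for the intercalated-Cy5 prescription) and biases the recovered means.
Consequently: passing recovery tests demonstrate that the analysis
pipeline faithfully measures |κ| and R distributions and segments states —
they do not validate |J| statistics of real trajectories, whose
consistency with the reported coupling band is checked separately at the
mean intercalated geometry.

Recovery tests compare pooled sample means (20 seeds × 1,000 frames)
against the exact truncated-normal expectation (scipy `truncnorm`) at
three standard errors — problem sizes chosen so sampling error, not
runtime, dominates the check.

## Hydrophobicity

ΔG_solv = E_solvated − E_vacuum per solvent, with one declared energy unit
per table (kcal/mol default, the quantum-chemistry convention; kJ/mol and
J/mol accepted) and separate vacuum columns for the water and octanol
workflows, since the two solvent calculations need not share a vacuum
reference. log(P_o/w) uses the conventional factor 2.3 rather than
ln 10 = 2.3026 (difference < 0.2%; exact value available by parameter).
Ranking is most-hydrophobic-first with ties broken by dye id.

## Extinction-coefficient ML

**Features.** A versioned registry (`registry_version` recorded in every
model artifact): four named structural counts — maximum carbon chain
length (longest simple path through carbon atoms), aromatic ring, amide
and ester group counts — followed by the standard RDKit 2-D descriptor
battery, ~214 features total. Featurization is pure; descriptors that fail
or return non-finite values are imputed as 0 with a logged count.

**Hygiene and split.** Records with ε strictly above 800,000 M⁻¹cm⁻¹ are
excluded (gross outliers relative to the screening threshold); ε exactly
at a boundary is kept, and ε exactly at 150,000 labels *high*. The
development set holds round(0.9·N) records, stratified on the high/low
label (class fractions within one record of global); the split seed is
mandatory and recorded.

**Models.** Random-forest Classifier and Regressor with 5-fold CV
hyperparameter selection on the development set. Default search grids:
max depth {8, 16, 32, ∞}, max features {√p, 0.3, 0.5}, class weight
{none, balanced} (classifier) / split criterion {squared error, absolute
error} (regressor); 100 trees. Tests and example runs pass reduced grids —
the package's own desk-scale choice; the library default remains the full
grid. A constant-target regression reports R² = 0 by convention with a
warning. The "always low" baseline (accuracy = low-class fraction) anchors
classifier performance on imbalanced data; the imbalance sweep subsamples
to requested low fractions (using as many records as the limiting class
allows), retrains, and reports classifier vs baseline accuracy per point.

**What the synthetic molecule fixture shows.** Generated ε is a documented
monotone function of structural features (max carbon chain + 3 × aromatic
rings + 0.05 × MolWt, exponentiated around the class threshold) over a
combinatorial scaffold family (substituted biphenyl/naphthyl/pyridyl
polyenes, thousands of distinct canonical SMILES), plus optional Gaussian
noise, with the achieved low-class count exact by construction. Regressor
R² ≥ 0.95 on this fixture demonstrates that the featurization exposes the
structure the target depends on and the training loop works — it says
nothing about accuracy on experimental dye corpora, whose ε depends on
measurement conditions and chemistry the fixture does not model.

## Screening funnel

Candidates are ranked by predicted ε (descending, ties by molecule id,
unparseable SMILES skipped with a warning). Where TD-DFT μ values and
solvation tables are supplied, candidates are flagged: predicted ε above
threshold, μ within 50% of the Cy5 reference (15.35 D) by
|μ−μ_ref|/μ_ref ≤ 0.5, and log(P_o/w) > 0; "promising" requires every
evaluable flag. Missing join keys leave flags null rather than dropping
candidates. Criteria that need spectra or chemist judgment (visible-range
absorption, π-network size) are left to a free-text annotation column.

## Known limitations

* Transition dipole magnitudes, solvation energies and trajectories are
  external inputs; the package performs no quantum chemistry or MD.
* The descriptor registry is a standard 2-D battery, not a reproduction of
  any particular published feature set; counts may differ.
* The fixture trajectory is endpoint kinematics only — no DNA, no
  excluded volume (see above), no kinetics beyond block/i.i.d. switching.
* Signed κ/J are retained internally but every user-facing default reports
  absolute values; users needing interference-sensitive quantities should
  take the signed fields from `CouplingResult` / `FrameSeries`.
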