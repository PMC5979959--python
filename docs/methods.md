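# Methods

This note documents the models, numerical choices and limitations behind
each module, in the order data flows through the pipeline.

## Mass arithmetic (`chem`)

Neutral monoisotopic masses are the canonical representation; m/z appears
only at I/O boundaries via `(M + z·m_p)/z` with the proton mass
1.00727646688 Da. Residue masses and per-residue nitrogen counts are frozen
textbook constants (the unit tests cross-check them against an independent
elemental-composition summation).

Crosslinker constants are derived from the reagent chemistry rather than
transcribed from any software: an NHS-ester crosslinker that has reacted at
both ends adds its diacid minus two waters (BS3/DSS: C₈H₁₀O₂ = 138.06808 Da;
BS2G/DSG: C₅H₄O₂ = 96.02113 Da); a hydrolyzed deadend retains one water
(+18.01056 Da); a Tris-quenched deadend (+bridge + 121.07389 Da) is
supported but disabled unless configured. No fixed modifications are applied
by default — in particular no cysteine carbamidomethylation, matching the
experimental protocol the pipeline emulates. Custom linkers load from a
plain-text table (name, bridge, deadend, span).

¹⁵N metabolic labelling shifts each protein-derived nitrogen by 0.997035 Da;
labelling is treated as 100% efficient. Real ¹⁵N media carry ~2% residual
¹⁴N, which broadens isotope envelopes and complicates precursor picking;
that instrument-level effect is out of scope here and does not enter the
mass arithmetic.

## Digestion and search (`xlsearch`)

Cleavage is C-terminal to K/R (trypsin) and F/W/Y/L/M (low-specificity
chymotrypsin), never before proline, with 0–2 missed cleavages by default.
The chymotrypsin residue set was chosen to cover the C-termini of the
observed peptides in the reference crosslink tables (e.g. …W, …M, …Y, …L).
Two digestion-adjacent rules matter for candidate enumeration:

* a lysine carrying the crosslinker is not cleaved, so a lysine at a
  peptide's C-terminus (a cleavage product) is never a link site;
* the protein N-terminal α-amine is reactive, but peptide N-termini created
  by digestion are not — crosslinking precedes digestion in the protocol.

Candidates are all peptide pairs with one reactive amine each (including a
peptide paired with a second copy of itself — in homo-oligomers such
same-to-same links are diagnostic of inter-subunit contacts), all
single-peptide hydrolyzed deadends, and internal looplinks for peptides
with ≥2 reactive amines, respecting the ≤3 modifications-per-peptide cap.

Matching is two-stage. Precursor: neutral mass within 10 ppm, considering
all four isotope states (14/14, 14/15, 15/14, 15/15) when labelling is
enabled; spectra below charge 3+ are skipped because crosslinked peptides
rarely ionize at 2+. Fragments: b/y ions at charges 1–2, where an ion
spanning the linked residue carries the intact partner peptide plus bridge
(CID does not cleave the crosslink). Looplink fragments between the two
bridged sites are treated as carrying the intact bridge — a deliberate
simplification of ring-opening chemistry, consistent between the simulator
and the matcher.

The fragment score is this package's own: (matched fraction of theoretical
fragments) × (matched fraction of total peak intensity). Both factors
shrink monotonically as the tolerance tightens, and the score is not
comparable to any external search engine's. The manual-validation criteria
are deliberately kept as separate boolean flags rather than folded into the
score: matched intensity above a floor (default 1000), fragment ions from
both peptides, and at most 30% of the top-20 peaks unexplained. Ranking
ties break by smaller |ppm|, then candidate id, for determinism.

Hybrid detection takes the top-ranked accepted match per spectrum (a
spectrum's identification is its best explanation; lower-ranked candidates
whose nitrogen count happens to compensate an isotope shift would otherwise
masquerade as hybrids) and reports exchange = hybrids present in the
mixed-before-crosslinking sample and absent in the crosslinked-then-mixed
control.

Out of scope: decoy-database FDR, retention-time modelling,
isotope-envelope deconvolution, raw-file conversion.

## Constraint mapping and model ranking (`structmap`)

Distances are Cα–Cα throughout (matching how the reference distance tables
were computed), read from standard PDBs with author residue numbering
assumed to equal 1-based sequence positions. Thresholds: satisfied ≤ 30 Å
(inclusive — the crosslinker spacer plus side-chain and backbone dynamics
reach about 30 Å), violated > 40 Å (strict), ambiguous between.

On multi-chain homo-oligomer models a constraint is evaluated as the
minimum over all chain assignments, and the realization (intra-chain vs
which chain pair) is recorded. Same-to-same-residue constraints are
evaluated only across distinct chains; on a monomer they are marked
"inter-only, unevaluable" rather than failing.

Ranking: models with zero violating crosslinks above any model with
violations; within a tier more satisfied constraints win; remaining ties
break by fewer violations, lower mean distance, then model id. The
zero-violation-first rule is the substantive criterion; the rest of the
chain is a deterministic tie-break of this package's own choosing.
`rank_models_from_distances` accepts a precomputed constraint × model
distance table for the case where only published distances, not
coordinates, are available.

Restraint export writes both a TSV (pairs + 30 Å upper bound) and CNS-style
ambiguous `assign` statements between Cα atoms with allowed range 0–30 Å
(`30.0 30.0 0.0`), the format information-driven docking engines consume.

Default domain map: NTD 1–71, middle 72–189, CTD 190–241. Note K189 falls
in the middle domain by these boundaries even though it sits one residue
from the CTD edge; the map is configurable.

## Elastic network model (`enm`)

A full anisotropic network model with one node per Cα: uniform springs
γ (default 1, arbitrary units) between all pairs within 10 Å, Hessian
super-element −γ/d²·Δr Δrᵀ. The 1/d² normalization is one of several ANM
conventions; eigenvalues are therefore meaningful only relatively (the
spring-constant scaling test pins the γ-linearity). The
rotation-translation-block method with one Cα per block, which the
reference analysis used, reduces to this all-atom-block limit.

Mode numbering is 1-based with modes 1–6 the rigid-body null space of a
connected network; mode 7 is the first internal mode. Fluctuation profiles
are per-residue eigenvector magnitudes; a mode range is combined as a
1/λ-weighted mean, because thermal amplitudes of harmonic modes scale with
1/λ. Flexible-region calls use a sliding-window mean (default 11 residues)
with ties resolved toward lower residue numbers. Conformers are ±amplitude
× eigenvector; contact-deviation maps are |d⁺(i,j) − d⁻(i,j)|.

Degenerate inputs: a disconnected network (isolated nodes) warns and yields
more than six near-zero modes; requesting rigid-body modes for fluctuation
or animation is an error. Eigendecomposition is dense (`scipy.linalg.eigh`),
adequate up to a few thousand residues.

## SAXS (`saxs`)

The q unit is declared on the curve (`nm^-1` or `A^-1`, factor 10); lengths
and volumes come out in the matching unit. The empirical mass conversions
expect nm³.

**Guinier.** The fit window grows from the lowest usable q and iterates its
upper edge to self-consistency with qmax·Rg ≤ 1.3. Leading points whose
studentized residuals exceed 2.5 are dropped; a positive leading excess (a
steep rise above the Guinier line) raises the aggregation flag. Because the
Guinier law is only the q→0 limit, a smooth particle contributes real
curvature over the window that biases the straight-line slope by ~2% on a
sphere; when that curvature is statistically resolved (quadratic
coefficient beyond 2 SE) the slope is de-leveraged, which is algebraically
the quadratic fit's linear coefficient. Noise-level curvature is left
untouched, so the estimator stays a plain linear fit on noisy data.

**Kratky.** (qRg)²·I/I₀ vs qRg with the peak located on a cubic-spline
interpolant refined by bounded scalar minimization; an ideal Guinier
globule peaks at exactly (√3, 3/e ≈ 1.104), a compact sphere slightly
above 1.1, flexible chains plateau without returning to baseline.

**Porod.** Q = ∫q²[I−B] dq with three segments: Guinier extrapolation from
0 to the first data point, trapezoid integration over the data, and an
ideal K/q⁴ tail beyond. The Porod constant K is estimated by regressing the
running integral of q²I on −1/q over a tail window starting at
min(qRg ≈ 4, 60% of the q range) — the cumulative form averages out
form-factor oscillations that bias a plain mean of q⁴I, and the wide window
spans several oscillation periods. The default background is 0
(buffer-subtracted data); `background="auto"` fits a flat constant on the
tail and rejects a negative estimate larger than the tail intensity.
Vp = 2π²I₀/Q; on noiseless spheres across R = 20–50 Å the volume is within
a few percent, and truncating the curve at qRg = 8 moves it by under 5%.

**P(r).** Indirect transform with P parameterized by its values on an
interior r grid (P(0)=P(Dmax)=0 built in), solved by non-negative least
squares with a second-difference smoothness penalty — so P(r) ≥ 0 holds by
construction. The penalty weight comes from a fixed 9-point L-curve-style
grid: the largest α whose misfit stays within 10% of the best. Dmax is
scanned over a trial grid; below the true dimension the misfit rises
steeply, above it the solution pads with near-zero tail, so the chosen Dmax
is the smallest trial whose misfit is within a factor 2 of the scan minimum
and whose P(r) decays into the endpoint (mean of the last 5% of the grid
below 5% of the peak). Everything is deterministic and seedless. Rg is the
second moment, Rg² = ∫r²P dr / 2∫P dr.

**Sizing.** MWp[kDa] = Vp[nm³]/1.6 and MWa[kDa] = Va[nm³]/2 are empirical
calibrations taken as given; masses are reported rounded to the nearest
kDa as conventional for them, and the subunit count is
round(MWp/monomer), ties away from zero, with the monomer mass (default
26.9 kDa for DNAJB6) a supplied constant, not computed. Concentration-based
I(0) mass calibration is out of scope (inapplicable after online SEC
dilution), as is ab initio bead modelling — only the ÷2 excluded-volume
mass rule from such models is implemented.

## Synthetic data (`synth`)

Every generator is a pure function of its arguments; the seed is recorded
in every truth table. Defaults reflect the study conditions the pipeline
emulates: 1:1 ¹⁴N/¹⁵N pools for exchange experiments, crosslinks sampled
below 25 Å (comfortably inside the 30 Å plausibility bound), decoys at
≥15 Å RMSD (clearly wrong folds), ≤50 noise peaks per spectrum with
exponential intensities, 3 ppm precursor and 0.01 Da fragment jitter
(inside the 10 ppm / 0.05 Da tolerances), 2% multiplicative Gaussian noise
on scattering curves. The noise models are this package's own
parameterizations — the emulated experiments publish no noise
characterization.

Structures: ideal α-helix (1.5 Å rise, 100°/residue, 2.3 Å radius), a
hairpin hinged at its midpoint, and a compact self-avoiding walk confined
to protein-like density (radius ≈ 3·n^⅓ + 2 Å) so its elastic network is
globular and well connected — an unconfined random coil can be genuinely
floppy (near-zero internal modes), which is physics, not a bug, but makes
a poor stand-in for a folded protein. Lysines sit at every 5th residue so
crosslink sampling always has reactive sites. Cn oligomers place copies
about the z axis and reject radii that clash below 2 Å inter-chain.

What the simulations do not emulate: isotope envelopes, charge-state
distributions, LC elution and co-elution, detector response; SEC
heterogeneity within one curve; real decoy ensembles from homology
modelling (Gaussian perturbations have no secondary-structure realism).
Passing the recovery tests therefore demonstrates the correctness of the
arithmetic and the ranking logic under controlled conditions, not
performance on real LC-MS/MS or beamline data.

## Problem sizes

The test suite and the reproduction script run at desk scale by design:
200 seeded structures (10–35 residues) for the rigid-body-mode property,
100 simulated spectra for search recovery, 100 decoy-ranking replicates
(80-residue structures, 8 crosslinks, 4 decoys), 100 noisy curves for
Guinier calibration, spheres of 20–50 Å for the scattering ground truths.

## Known limitations

* The published precursor masses in the reference crosslink tables cannot
  be unambiguously decomposed from the table notation (the deadend/looplink
  content of the footnote marks is not stated), so they are carried as data
  and never asserted as expected values.
* Scores from the original search software are not reproducible (its score
  function is unpublished) and are excluded from all comparisons.
* The supplementary monomer/dimer coordinate files are not redistributed;
  the tests and the reproduction script that measure distances and
  flexibility on them activate only when the files are placed under
  `data/supplementary/`.
* One reference constraint label ("K296" for a peptide spanning residues
  27–30) is treated as a typographical error for K29.
* The dimer K232–K232 distance is printed inconsistently in the source
  material (30.6 / 20.6 / 31.3 Å); only K189–K189 = 23.5 Å is used as a
  reference value.
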