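# Methods

This note documents the models implemented in `gtmdock`, the conventions
chosen where the procedure left genuine freedom, what the synthetic
generators do and do not emulate, and the known limitations.

## Contact fingerprints

A pose is described from the binding site's perspective. Key atoms — the
site atoms within 4.0 Å (closed cutoff) of any overlaid reference ligand
that expose more than 5% (strict) of their surface to solvent in the
ligand-free site — anchor the descriptor slots; their ascending-index
order is frozen once selected, because it defines the vector layout.

Solvent exposure is computed by the Shrake–Rupley method with a 1.4 Å
water probe and a 960-point Fibonacci lattice (deterministic; both
config-exposed). The exposed *fraction* divides accessible points by the
total lattice size, i.e. by the full probe-expanded sphere area, making it
an accessible solid-angle fraction independent of the atom's radius. Van
der Waals radii are the Bondi set with 1.2 Å for hydrogen. Hydrogen-bond
typing is deliberately simple and testable: the donor flag sits on an H
bound to N/O/S; acceptors are N/O with non-positive formal charge, except
N atoms that themselves carry an H.

Each (key atom *i*, ligand atom *j*) pair receives a sigmoidal association
score `1/(1 + exp(k(d − c)))` with inflexion at the contact cutoff
c = r_i + r_j + 0.5 Å; the long-range list adds one water radius (1.4 Å)
to the cutoff and *includes* the direct contacts (it extends the direct
list; channels are computed over the full long-range scores, not the
increment). The steepness default k = 5 Å⁻¹ places the 8%–92% transition
band at ±0.5 Å around the cutoff, matching the tolerance scale; it is
config-exposed because only the inflexion point is fixed by the method's
definition. Hydrogens participate as ligand contact atoms — donor counting
requires them. The two charge channels weight signed and absolute partial
charges by the association scores (the alternative, hard-gating charges at
the cutoff, is noted as an open reading; weighting is implemented).

## Fragments and Hybrid vectors

Circular fragments are radius-bounded rooted environments on the
H-suppressed bond graph, counted per canonical name. Names are
radius-tagged canonical rooted-subtree strings (children sorted
lexicographically), e.g. `r2:C(C(O))`. This in-package canonicalization
was chosen over rooted canonical SMILES because the synthetic toy species
are not guaranteed to pass a full valence model, and because tagging the
radius keeps fragments from different spheres distinct even when the
subgraph is exhausted early. Three atom-label modes exist: element,
element with a formal-charge flag (the scheme class selected as best in
the original optimization), and a pharmacophore typing (donor/acceptor/
charge/hydrophobe). The candidate pool for map optimization is a 12-scheme
grid (sphere ranges 1–1, 1–2, 2–2, 1–3 × three label modes).

Hybrid vectors concatenate the CF block with vocabulary-aligned fragment
counts; the vocabulary is frozen on the training ligands before any map
fitting, and out-of-vocabulary fragments of new ligands are dropped with a
logged count. No inter-block scaling is applied at concatenation;
unit-variance column scaling is available as a map-level option (default
off, also unstated in the source procedure).

## Pose-pool bookkeeping

Pools are filtered to an energy window of 50 kcal/mol above the pool
minimum (a pose exactly at the boundary is kept). The diverse-subset
selector greedily accepts the energetically best remaining pose and
discards everything within a dissimilarity threshold of an accepted pose,
until 200 poses (default) are accepted; energy ties break on conformer-id
lexicographic order for determinism. The default pose dissimilarity is a
CF-vector Euclidean distance, since CF is the in-scope pose descriptor.
The energy convergence criterion (ECC) holds when at least five
simulations exist and those ranked 2–5 lie within 1 kcal/mol of the best
minimum (at most 20 simulations). RMSD is computed index-matched over
heavy atoms in the common site frame — no superposition, no
graph-automorphism symmetry correction — capped at 6.0 Å for landscape
modelling; "native-like" means RMSD strictly below 2.0 Å everywhere. The
docking score is ΔE = min bound energy − min free-ligand energy.

## GTM

The map is a K-component isotropic Gaussian mixture constrained to an RBF
manifold: nodes and RBF centres sit on square grids spanning [−1, 1]²; the
RBF width is `rbf_width_factor ×` the centre spacing (the conventional
reading of a "width factor"); the basis carries a constant bias column, so
affine planes are exactly representable — the property the planar
reconstruction test exploits. Initialization is deterministic PCA (sign
convention: largest-magnitude loading positive), with the initial noise
variance the larger of the third principal variance and half the mean
nearest-neighbour node-image spacing squared. EM alternates
responsibilities (log-domain softmax, overflow-safe) with a penalized
least-squares weight update `(ΦᵀGΦ + (λ/β)I)W = ΦᵀRT` (weight decay
excludes the bias row) and the closed-form β update. The monitored
objective is the penalized log-likelihood, which EM guarantees
non-decreasing; at λ = 0 it equals the plain likelihood. Training data are
centred on training means (optional unit-variance scaling recorded in the
model). Maps serialize to a JSON archive.

The published hyper-parameter values for the two map families
(29×29 nodes / 144 RBFs / width 1.8 / λ 6.61, and 46×46 / 441 / 0.3 /
0.012) are honoured as nameable configurations, not as reproducible
outcomes: the exact width and regularization conventions of the original
implementation are unpublished, so those numbers parameterize *this*
package's conventions when used.

## Landscapes and map selection

Node values are responsibility-weighted property means over nodes whose
density exceeds ε (default 1e−6·N/K); class landscapes store per-class
cumulated responsibilities, the winner per node (ties to the lower class
index, flagged) and, for numeric labels, the fuzzy mean value.
Predictions are density-aware weighted means over defined nodes; the
summed responsibility on defined nodes is the coverage, and predictions
below `coverage_min` (default 0.1) are returned undefined — the
"white-spot" applicability-domain behaviour.

Cross-validation is repeated stratified k-fold (3×3 default), stratifying
regression folds by property quartile to stabilize Q² on skewed RMSD
distributions. Q² = 1 − SSE/SST with SST around the *training* mean (the
convention chosen where the source is ambiguous); undefined predictions
are imputed with the training mean and counted. The manifold is fixed
during CV by default (folds re-colour only), with full refit behind a
flag. Map fitness is the mean of all Q² values minus one SD; the
hyper-parameter search is a small elitist tournament GA (population 20,
tournament 3, mutation 0.2, crossover 0.5, ≤200 evaluations by default),
deterministic under its seed, with the descriptor/fragment-scheme choice
as one more categorical gene.

In the Q/R/M/F cross-prediction verdicts, the "determination coefficient"
is the prediction-quality form 1 − SSE/SST (consistent with Q²), not
squared Pearson correlation; balanced accuracy uses the fixed 2 Å cut on
both axes; ROC ranks by ascending predicted RMSD. Labels are evaluated in
the order Q (all three > 0.75), R (AUC > 0.8), F (none > 0.6), else M; on
degenerate single-class test sets the undefined criteria simply never
exceed a threshold and the verdict is flagged.

IRI(p): with per-node densities D_k summed over both runs and run-A
fraction f_k, a node is irreproducible when max(f_k, 1−f_k) > p (default
p = 0.85); IRI is the density-weighted fraction of irreproducible nodes.
Empty nodes are excluded; p ≤ 0.5 is rejected as ill-defined dominance.

AR vectors weight pose responsibilities by exp(−β(E−E_min)) (shifted for
overflow safety); β = 0 is plain averaging, β → ∞ selects the most stable
pose. The default β grid {0, 0.1, 0.3, 1, 3} (kcal/mol)⁻¹ spans the
regimes of interest. In screening, compounds with undefined predictions
are excluded from the ROC (not imputed) and counted; colour/test splits
are seeded random halves stratified by activity class; decoys are assigned
pK 3.

## Synthetic generators

The generators emulate the *structure* of docking outputs, not their
physics:

* **Toy site** — ~150 typed atoms on an 8 Å spherical shell around an
  empty cavity, with two designated hot-spot atoms (an acceptor
  carbonyl-like O and a donor amide-like H ≈ 4 Å apart near the cavity
  bottom, mimicking a kinase-hinge anchoring pair); the shell is locally
  thinned around them so both stay solvent-exposed. The 7-atom ligand
  docks natively with its donor H 2.6 Å from the hot-spot O and its
  acceptor O 2.8 Å from the hot-spot H.
* **Pose ensembles** — rigid rotation about the heavy-atom centroid plus a
  translation whose magnitude is solved so the heavy-atom RMSD hits an
  exactly sampled target (the rotation/translation cross-term vanishes),
  plus 0.02 Å per-atom jitter. Targets come from a two-band mixture
  (U(0.2, 1.8) with the native fraction's probability, else U(2.3, 7.5)),
  so the realized native-like fraction is controlled to binomial accuracy.
  Energies follow the funnel E = E₀ + a·RMSD + N(0, σ²) with defaults
  a = 1.5 kcal/mol/Å, σ = 1 kcal/mol.
* **Paired runs** — both runs sample around 8 of 16 pre-built mode
  centres; the overlap parameter sets how many modes the runs share. Mode
  magnitudes stay within the contact-informative 1.0–4.5 Å band and mode
  directions are spread on a Fibonacci sphere: poses far past the site rim
  all share a near-empty fingerprint, so nominally distinct remote modes
  would otherwise collapse onto one map node and a disjoint pair of runs
  would not read as disjoint.
* **Screening sets** — 100 top (pK ∈ U(7.2, 9.0)), 91 weak (U(4.7, 5.5))
  and 101 decoy (pK = 3) compounds, each a small element/charge variant of
  the toy ligand with an intact anchoring motif. The class effect enters
  through the native-pose fraction of each compound's ensemble
  (0.70/0.45/0.05 at effect size 1; all equal at 0). Compound-level energy
  offsets (σ = 2 kcal/mol) model the limited cross-compound comparability
  of raw docking scores — the documented weakness that makes
  interaction-pattern rescoring attractive — so the ΔE baseline is
  informative but beatable, as in practice.

What passing tests on these generators show: the descriptor, map,
landscape and screening machinery are internally correct and behave as the
method intends under controlled signal. What they do not show: performance
on real force-field energies, real chemistry (tautomers, protonation,
symmetry), or induced-fit sites.

## Numerical choices and degenerate inputs

Sigmoid exponents are clipped at ±500 before `exp`; responsibilities and
likelihoods are computed in the log domain; the M-step falls back to
least squares on singular systems (warning); β is floored away from
division by zero on noiseless data. Empty responsibility subsets give zero
vectors with a warning; empty pose files give empty lists with a warning;
a missing energy tag or an atom-count mismatch across records of one
ligand is a hard error. Mol2 charges are re-read from the text at float64
so file round-trips are bit-exact; node tables are written at %.17g for
the same reason.

The noise-precision recovery experiment generates from a planar 10×10
known map with unit-normalized plane axes: an isotropic generating grid
keeps the fitted square node grid within the model class. With strongly
anisotropic generators EM lands in quantization local optima and the
recovered precision biases low — a property of EM, not of the estimator's
definition.

## Limitations

RMSD has no symmetry correction; acceptor/donor typing is rule-based, not
quantum-informed; the original 100-scheme fragmentation pool is
represented by a 12-scheme grid containing the winning scheme class; maps
are batch-fitted (no minibatch mode); landscape rendering is limited to
CSV node tables (plotting is intentionally out of the tested contract).
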