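# Methods

This note documents the models, parameter choices and numerical decisions
behind `nullelab`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Molecular states and the action space

A state is a canonical SMILES string (RDKit canonical aromatic writer,
fixed per run) plus an episode step counter.  Actions are single edits:

* **atom addition** — attach one atom of an allowed element (default
  C/N/O; libraries also use F/S) to any atom with free valence, by a
  single, double or triple bond permitted by both partners' free valence;
* **bond addition / order increment** — between any two atoms with free
  valence; creating a bond between already-connected atoms closes a ring
  and can be disabled (`allow_ring_formation`);
* **bond removal** — decrement the order or delete the bond; deletions
  that disconnect the graph are rejected (single-fragment policy);
* **no modification** — a legal action so the agent can stop early.

Aromatic bonds are never created directly; edits operate on the kekulized
graph and aromaticity is re-perceived by sanitization afterwards.  Charged
species and explicit hydrogens are excluded; notably, RDKit's sanitizer
charge-separates some pentavalent-N motifs (nitro/azoxy-like N=O), and such
products are filtered out rather than admitted as zwitterions.  Free
valence is the implicit hydrogen count, which for neutral organics agrees
with sanitization.  The enumeration is verified exhaustively against a
blind try-everything-and-sanitize oracle over all 571 connected neutral
molecules with ≤ 4 heavy atoms over {C, N, O}.

## CNS MPO score

The CNS multiparameter-optimization score is the sum of six desirability
functions, each in [0, 1]: molecular weight (Da), ClogP, ClogD at pH 7.4,
TPSA (Å²), hydrogen-bond-donor count (donor hydrogens on N/O: water counts
2) and the most basic pKa.  Five are monotone-decreasing
plateau–ramp–plateau functions; TPSA is a trapezoidal hump (too little
polar surface is as undesirable as too much).  The default breakpoints
(`src/nullelab/data/cns_mpo.yaml`) follow the published six-parameter CNS
desirability scheme — MW 360/500, ClogP 3/5, ClogD 2/4, TPSA 20/40/90/120,
HBD 0.5/3.5, pKa 8/10 — and are shipped as editable data because absolute
scores depend entirely on these constants.  Desirability is continuous
everywhere, so the total is continuous and bounded in [0, 6]; ≥ 4 is the
conventional CNS-penetrant cutoff.

ClogP/ClogD/pKa are predictor-dependent, so they come from a pluggable
provider.  The built-in default uses the Crippen atom-contribution ClogP, a
SMARTS-rule basic-pKa estimate (aliphatic amine 10.0, pyridine 5.2, aniline
4.6, amidine/guanidine 12.0; no basic nitrogen → 0), and the
Henderson–Hasselbalch correction for a monoprotic base,
ClogD = ClogP − log10(1 + 10^(pKa − 7.4)).  A CSV lookup provider supports
externally computed values; a missing value is a loud error, never a
default.  Absolute CNS MPO values from the built-in provider are estimates;
rank orderings and the [0, 6] bound are what the tests guarantee.

## Synthetic accessibility

An Ertl-style score: the mean log relative frequency of the molecule's
radius-≤2 circular substructures in a shipped frequency table (common
fragments = easy), minus penalties for size (n^1.005 − n), ring
bridgeheads/spiro atoms and fused bonds, stereocenters, and macrocycles,
affinely mapped to roughly 1 (easy) – 10 (hard) with a floor at 1.  The
frequency table is built once from a seeded 400-molecule synthetic library
(`scripts/build_sa_table.py`) and shipped as JSON; unseen fragments score
0.5 below the rarest tabulated fragment.  Because the table derives from
the fixture distribution rather than a reaction corpus, only orderings
(simple acyclic < fused polycyclic; adding a fusion never eases synthesis)
are meaningful, and those are what the tests assert — including a
cross-check of easy-vs-hard ordering against RDKit's independent
contributed SA implementation.

## Composite reward

Each component is mapped to a [0, 1] benefit over a configured range before
weighting: potency benefit rises linearly with predicted normalized
half-time over (1, 3); MPO benefit is score/6; SA benefit falls with the
score over (1, 10); binding benefit rises as the predicted energy drops
over (−12, 0) kcal/mol.  The reward is Σ wᵢ·benefitᵢ with non-negative
weights — monotone in every component by construction.  The ranges are
declared defaults, not fitted values.  Binding energies enter only through
a provider interface; the shipped default is a deterministic
descriptor-based *synthetic* surrogate with the shape of a docking score
and no structural basis, present so the reward component is exercised.

## QSAR

Featurizers share one contract (molecules → fixed-width matrix): folded
Morgan fingerprints (default, ECFP4), a physicochemical descriptor block,
and a dense substructure embedding obtained by truncated SVD of the
log-damped substructure co-occurrence matrix of a training library — a
self-contained stand-in for pretrained structural embeddings.  Molecules
are canonicalized before featurization, so SMILES aliases predict
identically.

Families: ordinary least squares, unrestricted decision tree (train MSE 0
by memorization), 100-tree random forest, and a feed-forward network.  The
network is a NumPy MLP with Adam and He initialization; per-endpoint
defaults are 256/256/32 ReLU with a range-scaled sigmoid output at learning
rate 1e-3 for the binding endpoint, 256/256/32 ReLU6 at 1e-3 for CNS MPO,
and 128/128/128/32 at 5e-4 for the aggregation endpoint, 1000 epochs.
Inputs are standardized inside the model wrapper.  The aggregation target
(normalized half-time) is log-transformed before fitting and
back-transformed on prediction, since half-time ratios are positive and
right-skewed.

Benchmarking is k-fold cross-validation (default k = 5; the pipeline demo
uses k = 3 at its small fixture sizes) with shuffled, seeded folds shared
across families, reporting mean train and test MSE per (family, endpoint)
in a 4 × 3 × {train, test} matrix.  On fixture data the *pattern* of the
matrix (tree memorization, forest/network generalization) is meaningful;
absolute MSEs reflect the surrogate labels, not any experimental dataset.

## Q-learning generator

The value network scores candidate *next states* (action ≡ resulting
molecule): input is the state fingerprint concatenated with normalized
steps-remaining.  Selection is epsilon-greedy with a deterministic
lowest-canonical-SMILES tie-break (reproducibility under ties).  The
per-step reward is the composite reward of the new state discounted by
γ^(steps remaining), so improvements near episode end dominate; learning is
TD regression on uniformly replayed transitions with the double-Q target
(online argmax, target-network evaluation) and periodic target sync.

Defaults: γ = 0.9, epsilon 1.0 → 0.01 linearly over the first half of
episodes, replay 5000, batch 128, target sync every 20 episodes, max 10
steps per episode.  QSAR oracles are frozen during generation.  Episode
counts are problem-sized: the optimality benchmark uses 2000 episodes on
the two-step micro-space from methane, where greedy rollouts reach the
exhaustively enumerated optimum in ≥ 4/5 seeds; the demo pipeline uses 300
episodes with 512-bit fingerprints and a 64/32 hidden stack, which is
enough for the small fixture space.  A reward failure aborts the episode,
is counted, and the run continues.

## Similarity screen

Queries and catalog entries are compared by Tanimoto similarity of ECFP4
fingerprints (2048 bits, radius 2).  Catalog duplicates are collapsed by
canonical structure (aliases are common in vendor files); the threshold is
inclusive (≥ 0.40 by default), every query's best hit is flagged, and
results are sorted by descending similarity.  The potency filter retains
hits whose QSAR-predicted normalized half-time is ≥ 1.5 — the 50%-increase
notion that also defines KIC50 — with the cutoff configurable because no
canonical value exists.  Raising either the threshold or the cutoff can
only shrink the result set; both monotonicities are tested, and the search
agrees exactly with a brute-force pairwise oracle.

## Kinetics and KIC50

Traces are normalized between the means of head and tail windows (5% of
points each, minimum 3); a plateau difference below 3× the head-window
noise flags "no transition".  The half-time is the first upward 0.5
crossing by linear interpolation between bracketing samples — robust to
asymmetric curves; a global sigmoid fit is deliberately not the default.
Traces that start above 0.5 or never cross are censored and excluded from
dose–response assembly.  Window-based plateau estimation assumes the
sampling grid covers both plateaus; transitions very close to either end of
the grid bias the baseline, which is why the recovery tests place planted
crossings at ≥ 5 h on a 60 h grid (worst-case error there is ≈ 0.02 h).

Replicate traces at a concentration are reduced to the mean t½ (spread
reported).  The approximate rate is (1/t½)/(1/t½,control) × 100, anchoring
the control at exactly 100 — this makes the KIC50 definition internally
consistent (rate ⅔ of control ⇔ t½ up 50%) rather than depending on a
plate-maximum normalization.  The Hill fit is bounded least squares
(`scipy.optimize.curve_fit`): top initialized at 100, bottom free but ≥ 0,
slope in [0.05, 20]; a rate spread under 1 unit is a degenerate
"no dose effect" fit that downstream KIC50 refuses.  KIC50 inverts the
*fitted* curve at R = 200/3 by bracketed root-finding (`brentq`, 1e-12
tolerances); for bottom = 0, top = 100 this equals m·2^(−1/h) analytically,
which the tests verify to better than 1e-6 relative.  Solutions outside the
tested concentration range are flagged extrapolated; curves that never
reach ⅔ of control yield an explicit "no inhibition" result.

## Synthetic data: what it emulates and what it does not

Molecule libraries are seeded random action walks (≤ 20 heavy atoms,
C/N/O/F/S) — chemically valid but not distributed like any vendor catalog.
Surrogate labels are exact functions of descriptors (affine, smooth
nonlinear, or motif-lifted with a planted sulfur motif raising the
half-time label from 1.0 to 2.0) plus seeded Gaussian noise: they make
recovery tests *definitionally* answerable, which real assay data never is.
Kinetic traces are symmetric logistics with the normalized 0.5 crossing at
the planted t½ and multiplicative Gaussian noise (default 3–5%); real ThT
curves are asymmetric, baseline-drifting and heteroscedastic.  The dose
series plants t½(c) = t½,control·(1 + 0.5·(c/KIC50)^h), chosen precisely so
the KIC50 definition holds by construction; equivalently the rate curve is
Hill-shaped with midpoint KIC50·2^(1/h).  Passing tests therefore
demonstrate correctness of the *machinery* — enumeration, scoring, fitting,
inversion, learning dynamics — not predictive validity on experimental
chemistry, which requires external datasets and predictors out of scope
here.

## Numerical and design choices

* Canonicalization dialect fixed to RDKit's default; recorded per run.
* Fingerprint length/radius fixed per run; generator and screen default to
  2048/2 (benchmarks use shorter folds where speed matters; width is
  configuration, not semantics).
* Epsilon-greedy ties break to the lowest canonical SMILES; k-fold splits
  are shuffled with a recorded seed; the pipeline derives per-stage seeds
  from the global seed by fixed offsets.
* Degenerate inputs are explicit: empty datasets, k > n folds, empty
  candidate sets, censored half-times, flat dose-responses and
  non-converged fits all raise or flag rather than returning silent
  defaults.
* The pipeline resumes from existing stage outputs; the manifest records
  config, version, checksums and timings.

## Known limitations

* The built-in ClogP/ClogD/pKa estimators are crude; absolute CNS MPO
  values shift with the provider (the provider name is recorded per run).
* The SA fragment table reflects the synthetic library's chemistry only.
* The generator is desk-scale: hundreds to thousands of episodes on spaces
  with ≤ ~10 edit steps; no GPU path, no policy transfer between runs.
* Kinetic half-time extraction assumes both plateaus are sampled; strongly
  censored designs need the censoring flags downstream.
* Stereochemistry-aware actions, 3D conformers, reaction-based enumeration
  and live catalog queries are out of scope.
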