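# Methods

This note records the modeling choices behind `ugtsom`, what the synthetic
benchmarks do and do not show, and the numerical conventions a user should
know before trusting or extending the results.

## Scope and chemistry

Glucuronidation is modeled as a single graph edit: an SN2-type transfer in
which a substrate nucleophile attacks the anomeric carbon (C1) of the
glucuronosyl group, forming one new bond. Only O- and N-glucuronidation
are supported; reactions whose formed bond touches any other element are
rejected. UDP is never modeled: reactions are written as
`substrate.glucuronosyl-donor >> glucuronide`, with the donor's anomeric
hydroxyl omitted (the anomeric carbon appears as CH2 on the reactant
side) so the heavy-atom equation balances exactly. Glucuronosyl
recognition uses a pyranose-uronic-acid substructure that ignores
anomeric stereochemistry, because input data mixes α/β depictions.
Hydrogens are implicit throughout (heavy-atom graphs and heavy-atom-only
atom maps). Atom maps are 1-based; every atom index exposed by the API is
0-based, and the conversion is confined to `chem_io`.

### Candidate sites

Candidate sites of metabolism are every hydroxyl oxygen, classified with
precedence COOH > ArOH > AlOH (a carboxyl hydroxyl is never counted as an
aliphatic hydroxyl), plus nucleophilic nitrogens. The nitrogen rule —
neutral N with at least one hydrogen, or an aromatic/sp2 nitrogen with a
free lone pair; quaternary and nitro nitrogens excluded — is this
package's own definition, chosen to match known N-glucuronidation
chemotypes (anilines, aliphatic amines, pyridine-type ring nitrogens,
imines). Tertiary sp3 amines without hydrogens are *not* enumerated, so
quaternary-ammonium glucuronides are outside the candidate space; a true
SOM missing from the enumeration counts as a ranking error, never as a
silent exclusion. The candidate set is also the denominator for top-k
accuracy, so changing the nitrogen rule changes the difficulty of the
ranking task.

### Carboxylic-acid SOM convention

The COOH label sits on the hydroxyl oxygen — the atom that actually forms
the glycosidic (acyl-glucuronide) bond — not on the carbonyl oxygen or
the carbon.

## Substrate classifiers

Five traditional learners (RF, SVM, LR, NN, ET; scikit-learn) run on
binary fingerprints or on a 2D physicochemical descriptor vector; two
graph networks (a GCN with a concat(weighted-sum, max-pool) readout, and
a two-level attention network that attends first over each atom's
neighborhood and then over the whole molecule) run on one-hot featurized
molecular graphs. GAT, Weave and MPNN are registered extension names that
raise `NotImplementedError` rather than silently aliasing GCN.

Descriptors come from RDKit's 2D descriptor set (~210 features); the
ordered name manifest is stored with every trained model so vectors are
reproducible. Standardization (median imputation, then z-scaling) is fit
on training folds only. MACCS keys are exposed as exactly 166 bits
(RDKit's placeholder bit 0 is dropped). Morgan radius is fixed at 2;
folded fingerprints support 512/1024/2048 bits.

The graph networks are implemented on a small reverse-mode automatic
differentiation core over NumPy (`ugtsom.autodiff`) — double precision,
single-threaded, fully deterministic under a seed. This keeps the package
dependency-light and makes retraining bit-reproducible; the cost is that
very large training sets would be slower than on a GPU framework.

Model selection: ten-fold stratified cross-validation (stratification is
this package's choice; with near-balanced classes it is benign and
stabilizes SE/SP), ranking by pooled out-of-fold MCC with ties broken by
AUC then by spec name. Hyperparameters use documented defaults plus an
optional small seeded grid search; there is no Bayesian optimization, so
absolute metric values on real data are not expected to match any
externally tuned system.

### Consensus convention

The consensus family over the top-10 models is **every non-empty member
subset: 2¹⁰ − 1 = 1023 committees**. A single-member committee votes
identically to its model, so the genuinely multi-member combinations
number 2¹⁰ − 10 − 1 = 1013; `enumerate_consensus(..., min_size=2)`
restricts to those. The 1023 total is the package's reporting convention
for "the consensus family built from ten models". Soft voting averages
member class-1 probabilities; the substrate threshold 0.5 is boundary
**inclusive**. A failed member prediction fails the committee — members
are never silently dropped.

## The WL network

Default configuration: 1 WL iteration, hidden width 300, learning rate
0.001, batch size 20, maximum 500 epochs, patience 10 (training loss) /
15 (validation top-1). One iteration means an atom's local feature
depends only on its immediate neighborhood before attention — deliberate,
since the nucleophile's first shell (aromatic ring, carbonyl, alkyl
carbon) already separates the four site classes. The hidden width and the
pair-head architecture (one ReLU layer on the concatenated local+context
features of the site atom and the anomeric carbon, then a linear score)
are this package's defaults, exposed in `WLNConfig`.

Pair scoring is restricted to (candidate site, anomeric carbon) pairs:
every glucuronidation forms exactly one bond to C1, so scoring all atom
pairs would only add noise; an `all_atoms` option scores every substrate
heavy atom for diagnostic heat-maps. Negatives are the substrate's other
candidate sites — no cross-substrate negatives — matching the
per-molecule ranking objective that top-k accuracy measures. If every
training reaction has a single candidate site, training warns and samples
non-candidate atoms as negatives so the score scale stays anchored.

Prediction canonicalizes the substrate, so ranked sites use canonical
atom indices; equal scores break ties by ascending atom index. The
forward pass is permutation-equivariant by construction (sum aggregation,
softmax attention), verified to ~1e-16 in the tests. Reactions sharing a
substrate are always placed in the same split partition.

## Evaluation conventions

MCC uses the zero-denominator convention MCC = 0. AUC is the rank-based
Mann–Whitney statistic (ties count one half) — equivalent to trapezoidal
ROC integration and robust to tied scores. Top-k counts a substrate as
correct if *any* of its observed SOMs ranks ≤ k among its candidate
sites; per-class tables restrict to substrates whose observed SOM carries
the class, and an empty class is reported as absent rather than 0.
Site-level AUC/MCC for SOM models treat every enumerated candidate as one
binary case scored by its reactivity logit, with predicted-positive
meaning logit ≥ 0; this is one reasonable site-level reading, stated here
because others exist.

## Synthetic benchmarks — what they show and what they don't

The generator decorates benzene, naphthalene and cyclohexane cores with
substituent menus (hydroxyl, alkanol, carboxyl, amine groups plus neutral
decoys including methoxy, nitro, nitrile and halogens), guaranteeing
validity, uniqueness and exact ground truth. Substrate labels follow the
planted rule "contains ArOH or COOH", generated class-balanced, with
optional label noise drawn from an independent RNG stream (so the same
seed yields the same molecules at any noise level). Reaction sets plant
the SOM by the preference rule ArOH > COOH > AlOH > Nitrogen (lowest
atom index with a transferable hydrogen within the winning class) and
attach the glucuronosyl group by dropping one H from the nucleophile and
bonding it to C1.

Sizes used by the shipped tests and the acceptance script — 250–500
reactions, 300–1,000 labeled molecules, hold-outs of 20 % — mirror the
scale of curated glucuronidation datasets (a few hundred reactions, ~1.2k
labeled compounds).

In multi-site mode each non-nitrogen reaction carries exactly one
distractor site of strictly lower priority. Nitrogen is the
lowest-priority class, so a nitrogen SOM cannot receive a lower-priority
distractor, and a same-class second nitrogen would make the planted
answer an unlearnable index tie; nitrogen-SOM reactions are therefore
emitted single-site even in multi-site mode. This is the one asymmetry of
the benchmark and is visible in per-class tables (nitrogen top-1 is
trivially 1.0 there).

Passing these benchmarks shows that the pipeline's plumbing, objectives
and rankings are correct and that the networks can recover a clean
structural preference from a few hundred examples. It does **not** show
real-world predictive accuracy: the planted rules are noiseless and
first-shell-local, whereas experimental glucuronidation preferences
depend on steric environment, electronics beyond the first shell, and
isoform availability. Metrics near 1.0 on the synthetic sets are
expected and are a correctness statement, not a performance claim.

## Numerical and reproducibility notes

- All training is single-threaded double precision; retraining with the
  same data, config and seed reproduces parameters bitwise.
- Descriptor calculation canonicalizes the molecule first because a few
  descriptors (BCUT eigenvalues, logP sums) are atom-order sensitive at
  machine epsilon.
- The CLI derives one sub-seed per stage by hashing the stage name with
  the global `--seed`, so stages can be rerun independently yet
  reproducibly; derived seeds stay below 2³¹.
- Degenerate inputs have defined behavior: molecules with no candidate
  sites yield an explicit empty prediction (and an explicit output row at
  the CLI); empty training sets, single-class labels, unbalanced SMIRKS
  and zero-formed-bond reactions raise typed errors.

## Known limitations

- S- and C-glucuronidation, tautomer enumeration, protonation states and
  conformer-dependent (3D) effects are out of scope.
- The glucuronidation-specific atom mapper requires the product to
  contain exactly one glucuronosyl moiety whose excised aglycone matches
  the substrate; diglucuronides and rearranged aglycones are rejected.
- UGT isoform selectivity and reaction kinetics are not modeled; the
  reactivity score is a ranking signal, not a rate.
- The substrate/nonsubstrate and SOM stages are trained independently;
  gating simply suppresses SOM output for predicted nonsubstrates.
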