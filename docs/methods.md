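# Methods

## Scope and model

`multicellfba` builds condition-specific, multi-cell-population
constraint-based models. The underlying assumptions are those of flux
balance analysis: the system is at metabolic steady state (`S v = 0`),
fluxes live in arbitrary units bounded by `[lb, ub]`, and cellular
objectives are linear. Two extensions structure the model:

* **Population structure.** Every retained cell type gets a namespaced
  copy of the generic reconstruction. Copies never share internal
  metabolites; the only coupling is through a single medium compartment
  (tag `u`). Each generic boundary exchange is rewritten as per-type
  transports plus one shared environment exchange per medium species,
  making the medium the single point of truth for uptake bounds and
  the natural place to read inter-cellular exchange.
* **Transcriptome context.** Which reactions a cell type's sub-model
  may contain is decided by expression evidence (core reactions) plus
  the minimal completions required for flux consistency — not by flux
  optimality. Reactions without GPR rules are never core; they enter
  only as completions.

## Discretization

Per (condition, cell type) stratum, counts are normalised per cell to
counts-per-10k, transformed `log2(x+1)`, and averaged over the
stratum's cells (pseudobulk). Averaging after the per-cell transform
damps outliers; doing it per stratum rather than per cell mitigates
dropout, which single-cell UMI data exhibit heavily.

The nonzero pseudobulk values are modelled as a two-component 1-D
Gaussian mixture (deterministically initialised EM, so the result is
invariant to gene and cell order). The upper threshold is the smallest
value whose posterior probability of the high component reaches
`p_core` (default 0.9); the lower threshold mirrors it for the low
component (`p_inactive`, default 0.9). Genes above the upper threshold
are core, genes below the lower threshold or at zero are inactive, the
rest are unknown and do not influence model building. When the mixture
is degenerate (fewer than 8 distinct nonzero values, component
separation below 1 pooled SD, or a vanishing component) the scheme
falls back to percentile thresholds (66th/33rd of nonzero values) and
warns. Posterior thresholds rather than density-peak positions were
chosen because they classify essentially the entire high-expression
component as core once the components are a few SDs apart, which is
what a core-gene call should mean; both thresholds are recorded in the
run metadata and can be overridden explicitly.

## Consistency and extraction

`find_consistent_subnetwork` is an LP-based scan in the FASTCC family:
blocked reactions (unable to carry |flux| ≥ ε at steady state within
bounds) are identified with a small number of LPs that maximise the
number of simultaneously active reactions, flipping reversible
candidates before declaring them blocked. ε defaults to 1e-4 a.u. —
far above solver feasibility noise (1e-9) and far below the bound
magnitude (1000 a.u.). Because a blocked reaction carries zero flux in
*every* steady state, one per-reaction flux-range pass over the full
network is an exact oracle; the test suite checks the scan against it
on randomized networks.

`extract_core_subnetwork` follows the FASTCORE scheme: alternate an LP
that pushes flux through pending core reactions and a weighted 1-norm
LP that activates them while penalising non-core flux, flipping
reversible cores that only run backwards. Two deviations are
deliberate:

* **Deterministic order.** Pending sets are iterated in lexicographic
  reaction-id order and all LPs use dual simplex, so extraction is
  bit-reproducible.
* **Pruning pass.** The 1-norm surrogate measures flux magnitude, not
  support size, so it can prefer a flux-dense detour (e.g. a
  high-ATP-yield oxidative chain at ε-scale flux) over a
  support-sparse one. A greedy post-pass therefore removes, in
  lexicographic order, every non-core addition whose removal keeps the
  core (and the protected boundary exchanges) flux-consistent. On all
  enumerable toys this lands on a minimal consistent superset of the
  core; in general it guarantees inclusion-wise compactness, not
  global minimality.

Environment exchanges of the declared medium components are added to
the extraction core (available nutrients should be representable);
other environment exchanges are available as completions and are
protected from pruning, since they define the model's boundary rather
than its context.

## FBA with maintenance floors and minimal cardinality

Stage 1 maximises each type's biomass-maintenance flux alone, giving
per-type solo maxima. Stage 2 fixes floors at 10% of each solo maximum
and maximises the cell-count-weighted biomass sum; the floors guarantee
every population a minimal maintenance while the weights distribute the
remaining medium across cell types in proportion to abundance. Floors
are computed from solo maxima, not from the weighted optimum, so a rare
cell type's guarantee does not shrink when a dominant type saturates
the medium.

Among flux vectors attaining the stage-2 optimum (within relative
tolerance 1e-6 — tight enough to stay on the optimal face, loose
enough not to cut it off numerically) the solver returns one with
minimal support. Models with ≤ 400 reactions use an exact big-M MILP
whose objective carries tiny (1e-7-scale) lexicographic tie-break
weights; larger models use 5 rounds of iteratively reweighted 1-norm
minimisation followed by a support-verification LP. Zero-norm minima
are not unique in general; uniqueness is claimed only as run-to-run
reproducibility. A solution checker asserts `|S v| ≤ 1e-6`, bound and
floor satisfaction on every solve exercised by the tests.

Medium handling: listed concentrations map *directly* to maximal
uptake bounds (no volumetric rescaling); unlisted species are closed
for uptake but free to be secreted; the oxygen bound always equals
`o2_glucose_ratio` × glucose bound (default 2, the tissue-culture
setting; 5 approximates the physiological brain ratio); thymidine and
linoleate default to a trace bound of 1 so biomass maintenance is
possible on defined media.

## Readouts

FluxSum of a metabolite is its producing flux sum
`Σ_j max(S_ij v_j, 0)`; at steady state it equals the consuming sum
and estimates turnover. Pathway FluxSum sums key metabolites (defaults
for the toy network: glycolysis g6p/pyr/lactate, TCA
citrate/α-ketoglutarate/succinate, OXPHOS mitochondrial NADH + ATP,
FAO cytosolic + mitochondrial acetyl-CoA; user-supplied keys for real
reconstructions). The two exchange tables use the conventions of the
figures they emulate and intentionally differ: medium tables count
uptake as positive; inter-cellular tables count release as negative,
with a medium-accumulation row closing the balance to zero.

## Synthetic data

The toy reconstruction covers glucose uptake, lumped glycolysis
(2 ATP + 2 cytosolic NADH per glucose), lactate dehydrogenase and
monocarboxylate transport, pyruvate oxidation and a four-step TCA
lump, oxidative phosphorylation at 5 ATP per O2 (2 NADH), β-oxidation
of linoleate, acetate and 3-hydroxybutyrate exchange, and a
biomass-maintenance reaction consuming 10 ATP plus trace
thymidine/linoleate. Coefficients are fixed constants chosen for clean
hand-verifiable optima rather than literature P/O ratios: with glucose
bound 10 and the default oxygen rule the aerobic optimum is exactly
12 biomass units, the fermentative optimum exactly 2, and the minimal
oxygen requirement at the aerobic optimum exactly 2× the glucose
bound.

The count simulator draws gamma-Poisson (negative binomial, dispersion
2) UMI counts per gene and cell, scaled by lognormal per-cell library
factors (σ = 0.2) and thinned by 10% dropout. The shuttle scenario
simulates 2 × 300 cells over ~60 genes: a glycolytic astrocyte-like
program (high GLUT1/HK2/PKM/LDHA/MCT1) and an oxidative neuron-like
program (high MCT2/LDHA plus the mitochondrial axis), with shared
housekeeping genes and low-expressed fillers. High and low modes (60
vs 0.4 expected counts) are separated by many SDs on the pseudobulk
log scale, so core-gene recovery — and hence shuttle recovery — is
stable across seeds; the scenario checks directionality, not effect
sizes. The "disrupted" variant silences the neuron's oxidative
program; the pipeline then reconstructs a glycolytic fallback neuron,
which the tests detect as a rise of the neuron's glucose-
phosphorylation (g6p) FluxSum from zero. The g6p-only key is used for
that check because the full glycolysis key already scores
lactate-derived pyruvate turnover in the healthy neuron, masking the
direction of the change.

What the synthetic data do **not** emulate: realistic genome-scale
network size (Recon3D has ~10^4 reactions vs ~30 here), more than two
cell types, ambient RNA, batch effects, cell-type-specific biomass
compositions, or quantitatively realistic exchange rates. Passing
tests therefore demonstrate correctness of the machinery and
recoverability of a designed cross-feeding signal — not quantitative
accuracy on real tissue data.

## Numerical choices and limitations

* LP/MILP engine: HiGHS through scipy (`linprog` dual simplex,
  `milp`); feasibility tolerance 1e-9, activation ε 1e-4, support
  tolerance 1e-6 a.u.
* Ties: lexicographic reaction-id order everywhere (extraction
  iteration, pruning, MILP tie-break weights).
* Degenerate inputs: empty strata raise; degenerate expression
  distributions fall back to percentiles with a warning; infeasible
  maintenance floors raise naming the stage.
* The extraction is a heuristic: on large models it may keep a few
  more reactions than a global minimum; the pruning pass bounds this
  on small networks only.
* Flux variability, flux sampling and knockout analysis are out of
  scope, as are upstream QC, clustering and cell-type annotation
  (labels are an input).
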