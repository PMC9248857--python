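# Methods

`organsort` implements an end-to-end analysis for organelle-fractionation
("spatial") proteomics: from a protein × sample quantification table it
selects marker proteins, discovers profile clusters, annotates them with
subcellular compartments, trains SVM classifiers whose probability outputs
are thresholded by precision-floor calibration, and derives domain- and
complex-level colocalization statistics. Because no public quantification
accompanies the design it implements, the package ships a first-class
synthetic-data generator that reproduces the statistical structure the
analysis assumes, with full ground truth for every simulated protein.

## The experimental design being modeled

Six membrane-bound organelle fractions (plasma membrane, ER, endosome,
lysosome, Golgi, mitochondria) are differentially enriched from two cell
lines (a parental line and a knockout) in technical triplicate, giving
12 abundance measurements per protein. Fractions are *enrichments*, not pure
isolates: every protein leaves a signal in every fraction. A protein's
relative distribution over fractions — its fractionation profile — encodes
its subcellular localization.

## Synthetic data generator (`synthetic_data`)

Each of the default 18 clusters has a characteristic profile supported on
one or two dominant fractions (a Dirichlet draw over the dominant set;
dominant sets are distinct across clusters, so all clusters are separable
while clusters sharing a fraction remain adjacent). Clusters map onto five
neighborhoods (secretory, mitochondria, nuclear, cytosol, ribosome) by a
configurable map (default 3/5/3/6/1).

Nuisance structure, in the generator's fixed sampling order (every stage has
its own seeded stream, so stages can be replayed independently):

- **Contamination** (default 5% of signal) is redistributed over all six
  fractions according to a per-protein background profile that is uniform in
  expectation (Dirichlet, concentration 15) but fixed across replicates and
  conditions. Reproducibility of the background matters: with exactly
  uniform contamination, off-dominant entries are exact ties whose
  cross-condition ranks are pure noise, and the Spearman filter would reject
  perfect markers.
- **Biological scatter** (Dirichlet, concentration 200, disable with
  `scatter_concentration=None`): every protein gets a small individual
  perturbation of its cluster profile, fixed across replicates and
  conditions. Real datasets contain no two identical profiles; without this
  term the t-SNE embedding degenerates on near-duplicate points and
  fragments tight clusters into artificial islands.
- **Replicate noise**: multiplicative lognormal, σ = `noise_sd` (default
  0.1) for marker candidates — the planted low-noise population — and
  `nonmarker_noise_multiplier` (default 3) times that for everyone else.
- **Condition-unstable proteins** (default 10%) get an independent dominant
  set in the knockout condition; they are replicate-stable within each
  condition, so only the cross-condition filter can catch them (≈3% slip
  through, well under the 5% contaminant budget the tests enforce).
- **Multi-localized proteins** (default 10%) blend two cluster profiles from
  different neighborhoods with a mixing weight re-drawn per replicate around
  1/2 (Beta(5,5)): a dual-localized protein's partition ratio fluctuates, so
  most fail the reproducibility filter, and the consistent minority are
  exactly the ambiguous cases the probability thresholds must reject.
- **Missingness** is intensity-dependent (left-censoring, as in MS data):
  per entry p ∝ (1 − relative intensity)⁴, renormalized within each
  six-fraction profile so the mean per-entry rate equals `missing_rate`
  (default 5%). Uniform missingness would knock out dominant-fraction
  entries and make the correlation filters reject genuine markers.

Three reference-annotation sources (UniProt-like, GO-like, mouse-marker-like)
label each protein's true compartment with per-source coverage (0.7/0.7/0.5)
and error (5%). The domain table carries ~40 background Pfam-style
accessions (Poisson(0.8) per protein) plus three planted domains enriched in
compact neighborhoods (carrier rate 0.4 vs 0.01 background); planting is
restricted to neighborhoods holding ≤20% of clusters because fold change
(b/n)/(B/N) is bounded above by 1/f for a class containing a fraction f of
the proteome — an association planted into a 33% class could never clear a
4-fold cutoff. Complexes (default 40, sizes 2–6) are sampled from marker
candidates of one cluster (colocalized, default 80%) or of several clusters.

What the generator does **not** emulate: peptide-level inference, shared
peptides, batch effects, abundance-dependent noise heteroscedasticity beyond
censoring, annotation biases that correlate between sources, and
inter-protein correlation beyond cluster membership. Passing tests therefore
demonstrate correctness and calibration of the *pipeline logic* under the
assumed structure, not performance on real MS data.

## Marker selection (`markers`)

Four conjunctive stages on the median-normalized table (each sample column
divided by its median over present values; the direction — every sample
median becomes 1 — is a recorded convention, and the operation is
idempotent): (1) normalization; (2) quantified in both conditions; (3)
minimum pairwise Pearson correlation among the three replicate profiles
(six fraction values, per condition; both conditions must pass) ≥ 0.8;
(4) Pearson ≥ 0.8 **and** Spearman ≥ 0.6 between the two conditions'
replicate-mean profiles. Correlations use pairwise-complete present entries
(the convention of R's `cor`); zero-variance or <3 shared entries fail
conservatively. Stage order does not affect the final set (the filter is
conjunctive), and raising any threshold can only shrink it.

## Cluster discovery and annotation (`cluster_annotate`)

Replicate-averaged marker profiles are embedded in 3-D by Barnes-Hut t-SNE
(perplexity 50, theta 0.5, PCA initialization, fixed seed). Gaussian
mixtures with full covariances are fitted for k = 1…25 (5 k-means-seeded
restarts each); the k with the lowest BIC wins, ties toward fewer
components. On the default simulation BIC typically lands a few components
above the 18 planted clusters — t-SNE islands are not Gaussian, and the
extra components are either pure sub-splits of one planted cluster or small
residual groups; downstream calibration handles them (see "closed" classes
below).

Annotation tests every (cluster, compartment) pair for enrichment of
reference-annotated markers: fold change FC = (b/n)/(B/N) and the upper-tail
hypergeometric probability P(X ≥ b), BH-corrected within each of five
annotation strategies (UniProt only; GO only; union of both, conflicts
dropped; intersection requiring agreement; union ∩ mouse marker set
requiring agreement). A compartment is assigned when FC ≥ 2 (inclusive) and
q < 0.05 (strict) in at least 3 of 5 strategies; a strategy with no
annotated markers is skipped without shrinking the denominator. Compartments
collapse to neighborhoods by a fixed dictionary (ER/Golgi/endosome/lysosome/
plasma membrane/peroxisome → secretory; mitochondrion → mitochondria;
nucleus → nuclear; cytosol/cytoskeleton → cytosol; ribosome → ribosome).
A cluster whose assigned compartments span two neighborhoods is an error at
the operation level; the pipeline resolves such clusters (and unannotated
ones) by the majority neighborhood of their members' union annotations,
logged as an override. A second annotation round reuses the same
hypergeometric machinery on arbitrary term tables per cluster
(target-vs-background); its results are supplementary and never feed the
neighborhood map.

## Classification and calibration (`classify`)

Markers (labeled by their discovered cluster) are split 2/3 train : 1/3
test, stratified by cluster. Per replicate, an RBF-kernel SVM is selected by
10-fold cross-validated accuracy over log-spaced grids spanning cost
10⁻¹⁰…10¹⁰ (11 points) and gamma 10⁻¹⁰…10 (7 points) — CV ties are broken
toward the least extreme pair, since on separable synthetic data many grid
points tie at perfect accuracy — then refitted with the SVM's
pairwise-coupling probability model and applied to every protein with a
profile in that replicate. Replicates are merged: the cluster call is kept
only when at least two of three replicates agree on the argmax; probability
vectors are averaged.

Per-class probability cutoffs are calibrated on the held-out markers. For a
class, a protein is *predicted* when the class has its unique maximal
averaged probability and that probability reaches the threshold. Candidate
thresholds are the observed probabilities plus {0, 1} (PR curves are step
functions, so this search is exact; it is verified against a quadratic-time
brute-force oracle in the tests). The selected threshold maximizes recall
subject to precision ≥ 0.9 (cluster level) or ≥ 0.95 (neighborhood level);
if the floor is unattainable, the F1-maximizing threshold is used instead
("F1-max" mode). If even the best F1 is zero — no threshold produces a
single true positive, which happens for residual mixture components the
profile-space SVM cannot learn — the class is *closed*: it gets no
threshold and emits only unclassified calls, like a class absent from the
test set.

Neighborhood probabilities are the sums of member-cluster probabilities
(probability mass is conserved), thresholded by the same calibration at the
0.95 floor. Finally the two levels are reconciled: a protein whose cluster
call maps to a different neighborhood than its neighborhood call — or that
has a cluster call but no neighborhood call — becomes unclassified at both
levels; a protein without a cluster call keeps a neighborhood-only call.
Consequently the classified fraction at neighborhood level is always at
least the cluster-level fraction.

## Evaluation, domains, complexes

`evaluate` maps external single-localization references to neighborhoods
through the same fixed dictionary and reports the agreement fraction over
proteins classified to a single neighborhood, overall, per neighborhood and
per stratum. Marker metrics report accuracy before thresholding (unique
argmax over all test markers) and after (over retained calls), with both
denominators, plus per-class precision/recall/F1.

`domains_complexes` tests every (domain, class) pair with the same
enrichment machinery (BH across all tests; default cutoffs log₂FC ≥ 2,
q < 0.05, ≥3 carriers in the class; a flag switches the cutoff to the raw
fold-change scale). Complex colocalization computes pairwise Pearson
correlations of members' averaged 12-dim profiles, prefilters members whose
mean correlation to co-members is < 0.8, classes coverage (full = all
members identified and surviving), and calls a complex colocalized when its
≥2 retained members share one neighborhood call. The random-pair null
samples non-co-member pairs (seeded, rejection sampling) and reports the
two-sample KS statistic against member correlations.

## Numerical and design choices

- Classifier features: 12-dim per-replicate vectors concatenating both
  conditions (markers are condition-stable, so the two blocks are
  near-duplicates that damp noise); configurable to 6-dim per condition.
  Missing entries are zero before renormalization — absence from a fraction
  is informative in enrichment designs.
- Modal-vote ties (all replicates distinct) and exact argmax ties are
  unclassified (conservative).
- GMM degeneracies are handled by a covariance ridge (1e-6) and k-means
  restarts; BIC ties break toward smaller k.
- The pipeline drops clusters with fewer than 3 markers from
  training/calibration and lowers CV folds to the smallest training class
  when needed (both logged); the library-level operations keep strict error
  contracts instead.
- Default problem sizes (2000 proteins, 18 planted clusters, ≈1500 retained
  markers) keep a full pipeline run around five minutes on one CPU while
  leaving every stage's statistics well-populated (≥15 markers per planted
  cluster).

## Known limitations

- BIC on t-SNE coordinates over-estimates k when islands are non-Gaussian;
  the pipeline tolerates this (closed classes, neighborhood reconciliation)
  rather than correcting it.
- Threshold calibration and evaluation share the held-out marker set, as in
  the original procedure; reported post-threshold precision is therefore an
  in-sample property of the test markers, not an unbiased estimate for new
  proteins.
- The agreement computation treats references as single-label; genuinely
  multi-localized proteins depress agreement by construction.
- Sequence-level steps (domain scanning, sequence clustering) are consumed
  as precomputed tables; the package never touches sequences.
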