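# Methods

## Scope and model

`mycoderep` implements the computational core of a two-strain fungal
co-culture differential-metabolomics screen on unit-resolution (ion-trap)
LC-PDA-MS/MS data: cross-group feature alignment, fold-change trend
classification, MS/MS molecular networking, chlorine isotope-envelope
classification, and multi-criteria dereplication against a local
natural-product catalog. Wet-lab stages (cultivation, TLC, bioassays) and
live database queries are out of scope; catalogs are local CSV files.

The experimental design is fixed at seven groups: two axenic references
(G1 = first strain alone, G2 = second strain alone) and five co-culture
regimes (G3–G7) varying inoculation order and heat inactivation. All fold
statistics are ratios of integrated extracted-ion areas against the
producing strain's axenic reference; node sizes in the molecular network
are *not* used for quantification, because precursor-based node clustering
can pool isomers and is less reliable than EIC integration.

## Chlorine isotope envelopes

A molecule with *n* chlorines shows n+1 isotopologue peaks spaced ~2 Da
(exactly 1.99705 Da, the ³⁷Cl–³⁵Cl mass difference), with intensities
binomial over ³⁷Cl incorporations. Defaults:

* **Abundance ratio 3:1** (0.75/0.25) rather than the exact natural
  0.7576/0.2424. The simplified ratio makes the smallest-integer cluster
  ratios exact (Cl₂ → 9:6:1, Cl₃ → 27:27:9:1), which is how such clusters
  are reported and eyeballed in practice; the exact abundances are one
  parameter away.
* **Isotopes of C/H/N/O ignored** in the templates. At unit resolution and
  the 9:6:1 intensity level their perturbation of the M+2 ratios is below
  the instrument's intensity precision. This is a documented limitation:
  for large molecules (>60 carbons) the ¹³C₂ contribution to M+2 starts to
  matter.
* **Score: square-root-weighted cosine** between the observed and template
  intensity vectors, zero-padded to a common length. A raw-intensity cosine
  lets the base peak dominate the norm and leaves the Cl₂/Cl₃ templates
  only ~0.03 apart; under multiplicative log-normal noise at CV 0.10 it
  misassigns ~3% of clusters, while the square-root weighting (the same
  convention as the networking cosine) recovers the true count in 100% of
  2000 trials per class at that noise level and still scores exact
  templates at 1.0. Ties break toward fewer chlorines.
* **Spacing tolerance ±0.3 Da** around 2.0 Da, matching unit-resolution
  centroid scatter. Clusters violating it are refused by
  `classify_halogenation` (they are not M+2 halogen satellites);
  `regularize_envelope` can first trim an off-grid *trailing* satellite —
  weak M+2n peaks near the noise floor often carry unreliable centroids —
  so the dominant prefix still classifies. `annotate_peak` applies this
  trimming automatically.
* **n_max = 4** chlorines by default, covering the chlorination states
  reported for depsidone-producing *Aspergillus* species; bromine templates
  are computable from the same machinery but joint Cl/Br inference is a
  non-goal.
* The score threshold at which a call should be trusted is genuinely
  unconstrained by published practice; the classifier therefore reports the
  full ranked alternative list and leaves thresholding (default 0.95 in
  configuration) to the caller.

## Feature alignment and trends

Greedy nearest-neighbour alignment merges features across groups when both
|Δm/z| ≤ 0.3 Da and |Δrt| ≤ 0.5 min against the row consensus
(area-weighted means); ties break by smallest |Δm/z| then |Δrt|; a row
accepts at most one feature per group, so co-eluting same-group features
stay distinct. Tolerances reflect unit-resolution data and are
config-overridable. Group areas can be rescaled by a total-extract
proportionality factor (1 when unknown), mirroring extract-proportional
sample preparation.

Fold changes are rounded to two decimals. The trend legend is an inclusive
step function: fold ≤ 0.2 → decreased fivefold-and-more; fold ≥ 5 →
increased fivefold-and-more; fold = 1 → unchanged; fold 0 (eliminated) is
accepted as a fivefold-and-more decrease. A feature above the detection
floor in a test group but absent from the reference is NEW, split into
major/minor at a configurable abundance threshold (default: the median
non-zero area, since "large quantities" is not otherwise quantified). The
default detection floor is 3× the median of the bottom intensity decile
per group — a blank-free proxy chosen because no instrumental threshold
generalises across instruments.

Differential selection takes a peak whose trend in ≥1 co-culture group is
NEW, ≥ min_fold (default 2), or ≤ 1/min_fold, under any axenic reference
the peak is attributable to. Attribution is by axenic presence: a peak
detected in one axenic group is compared against that group, one detected
in both against both (reported twice, counted once), one detected in
neither against both (where it is NEW).

## Molecular networking

The modified cosine pairs fragments when |Δm/z| ≤ 0.3 Da, or additionally
when the difference offset by the precursor mass delta is within
tolerance. Intensities are square-root weighted (tames base-peak
dominance), and the one-to-one pairing maximising the summed products is
found **exactly** via `scipy.optimize.linear_sum_assignment` rather than
greedily — this makes the score equal, by construction, to the exhaustive
maximum over all pairings, a property the test suite verifies against a
brute-force enumerator on ≤6-peak spectra. Edges require cosine ≥ 0.7 and
≥4 matched fragments; components smaller than 2 nodes are removed;
positive- and negative-mode networks are built separately. No top-K edge
pruning is applied (a documented divergence knob from platform defaults).
The fragment m/z tolerance and the node-merge cosine (0.95) are exposed in
configuration since platform values for unit-resolution data are not
standardised.

`split_nodes_by_rt` re-clusters the member spectra of any node spanning
more than rt_tol minutes (1-D single linkage, break at gaps > rt_tol),
then re-scores edges between sub-nodes. Total node intensity is conserved;
per-group intensity shares always sum to the node total.

## Dereplication

Neutral masses use 5-decimal adduct constants and are reported at 2
decimals. MW comparisons use **average masses on both sides** (the
instrument is unit-resolution and catalogs list average MWs); the window
is ±1 Da, ±2 Da when the observed cluster classifies as chlorinated,
because the average mass of a polychlorinated species sits ~1 Da per Cl₂
above the monoisotopic ion actually measured.

UV compatibility: "end absorption" is a distinguished token, not an empty
list — a trace with no maxima above the solvent cutoff is *exclusionary*
evidence against candidates with genuine maxima >250 nm, and must not be
conflated with missing data (verdict `unknown`). When both sides carry
maxima, the two lists are matched within 15 nm in both directions and the
mean of the two matched fractions must reach 1/2. The symmetric score is
deliberate: a candidate with one lucky coincident band among many measured
maxima fails, while a candidate whose few bands all find counterparts
passes even if the measured trace has extra bands (mixtures, instrument
baseline). The 15 nm tolerance absorbs solvatochromic shifts between
literature solvents and the mobile phase.

Taxonomic scoping is two-staged: genus members first; if no genus-level
hit earns a star, the search widens to the fungal kingdom (the widening
trigger is this package's operationalisation of "expand when necessary",
exposed in configuration). Abbreviated binomials ("A. terreus") match the
queried genus.

A hit is **starred** when the MW match is corroborated by ≥1 further line
of evidence: an MS/MS library cosine, compatible UV, a consistent chlorine
count, or genus-level taxonomy. UV *incompatibility* excludes a hit —
unless an MS/MS match exists, which is treated as stronger evidence than
literature UV values recorded under different conditions. This hierarchy
(spectral > UV > taxonomy) reproduces published practice, where
UV-only conflicts are used to rule candidates out but a good spectral
match survives divergent literature UV. Duplicate records across source
databases are retained; halogenation-by-taxon percentages therefore count
per source.

## Cyclic-peptide fragments

A protonated cyclic peptide ring-opens at any amide bond under low-energy
CID and sheds residues as b-type acylium ions, so the theoretical set is
{Σ(contiguous run) + proton} over all openings and run lengths 1…n−1,
plus the intact [M+H]⁺ (= Σ residues + 1.00728; cyclic peptides carry no
terminal water). Masses within 1e-4 Da merge, bounding the set at
n(n−1)+1 compositions. Only the b series is modelled — y/a series and
modification localisation are non-goals. Residue masses are supplied by
the caller; no sequence is hard-coded. Matching reports
composition-coverage: matched distinct compositions / total.

## Synthetic data

The generator emulates the seven-group design with a planted metabolite
panel exercising every trend class: a suppressed diketopiperazine-like
metabolite (strong decreases when its producer is inoculated late), an
induced statin-like metabolite (8–10× increases in three regimes), a
cyclopeptide-like shared-and-shifting metabolite, a trichlorinated
main metabolite that declines, a dichlorinated metabolite present ONLY in
co-culture (NEW; major in one regime), an isomer pair sharing precursor
and fragment template at rt 4 vs 12 min, and near-stable backgrounds.

Noise model: multiplicative log-normal intensity noise (CV 0.10 default —
typical of integrated areas from replicate fermentations), Gaussian m/z
jitter (σ 0.02 Da) and rt jitter (σ 0.05 min) well inside the alignment
tolerances, and 10% MS/MS peak dropout. Multipliers are drawn from the
categorical fold magnitudes such screens report (0.01–0.14 strong
suppression, 1.6–10.5 induction) and deliberately avoid the 0.2/1/5
category boundaries so the stated noise cannot flip a true class;
backgrounds sit at ~0.7/1.4, halfway (log scale) between neutrality and
the twofold selection boundary. Fragment templates are derived per
metabolite from a CRC32-keyed generator, so they are stable across runs
and independent of the experiment seed; the isomer pair shares one
template key. Everything else derives from a single integer seed; fixed
(config, seed) reproduces byte-identical CSV/MGF/catalog outputs.

What the generator does **not** emulate: chromatographic peak shapes,
adduct coexistence per metabolite, ion suppression, replicate-level
variance structure, retention drift between groups, or catalog errors.
Passing recovery tests therefore demonstrates correctness of the
*analysis logic* under the stated noise model, not robustness to every
artifact of real LC-MS data.

## Problem sizes and numerical choices

The default synthetic scenario is 12 metabolites × 7 groups; the recovery
suites run 20 seeds (trend categories, ≥95% required) and ≥1000 generated
isotope clusters (chlorine counts, ≥99% required), which completes in
seconds. Brute-force cosine oracles are exercised on spectra of ≤6 peaks,
where exhaustive enumeration over all one-to-one pairings is tractable.
Fold values are compared after the same 2-decimal rounding the reports
use. Tie-breaks: alignment prefers smallest |Δm/z| then |Δrt|; halogen
calls prefer fewer chlorines at equal score; candidate lists sort by
|ΔMW| then name. Degenerate inputs: empty spectra cannot be scored
(error), empty networks and catalogs flow through as empty results, a
zero-area reference yields NEW or undefined rather than a division error.

## Known limitations

* Halogen calling is chlorine-only by default; bromine and mixed Cl/Br
  envelopes are out of scope.
* The UV score treats literature maxima as point values; bandwidths and
  relative absorbances are ignored.
* Average-mass MW windows are appropriate for unit-resolution data only;
  high-resolution workflows should compare monoisotopic masses with ppm
  windows, which this package does not implement.
* The bundled demo catalog is a small curated fixture for the worked
  example and regression tests, not a substitute for real database
  coverage.
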