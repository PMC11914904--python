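# Methods

## Flux-balance auxotrophy prediction

A genome-scale metabolic model is a stoichiometric matrix `S` over two
compartments (cytosol, extracellular) with per-reaction flux bounds and
a biomass pseudo-reaction. FBA maximizes biomass flux over
`{v : S v = 0, l ≤ v ≤ u}`; the LP is solved with HiGHS (via
`scipy.optimize.linprog`) at 1e-9 feasibility tolerances. Flux units are
abstract but mutually consistent; no unit conversion is performed.

The growth medium sets each exchange reaction's lower bound to minus its
uptake rate (absent metabolites: 0); secretion is always allowed up to
the model's own upper bound. Exchange reactions follow the standard
convention — one extracellular metabolite, coefficient −1, negative flux
= uptake.

The auxotrophy screen solves the model on the full medium and then once
per amino acid with only that amino acid's exchange entry removed. A
genome is auxotrophic for *a* iff growth without *a* falls below
`zero_tol` (default 1e-6 flux units, configurable) while full-medium
growth is at least `zero_tol`. An absolute threshold was chosen over a
relative one as the simplest reproducible reading of "no growth";
because the screen's models either grow at the biomass cap or exactly at
0, any tolerance in (0, cap) gives identical calls on synthetic data.
Amino acids with no exchange reaction in a model are
prototroph-by-absence (one cannot starve a model of a metabolite it
cannot import); models that do not grow on the full medium are flagged
non-growing and excluded with a reason. Peptide/dipeptide carriers, if a
model has them, are deliberately not removed during leave-one-out (only
the free amino acid's exchange entry is); all 20 amino acids are
screened, with an optional analysis-level subset. Genomes below 85%
assembly completeness (inclusive gate: 85.0 passes) are excluded before
screening.

Only the LP objective value is used, so alternate optima are irrelevant
and the screen is deterministic.

## Template model

The synthetic template has 64 reactions: carbon exchange + transport +
precursor synthesis (3), per amino acid an exchange, a transporter and a
biosynthesis reaction `precursor → aa` (3·20), and a biomass reaction
consuming the precursor plus all 20 cytosolic amino acids. The biomass
upper bound (10) sits below the carbon-limited optimum, so a full
prototroph grows at exactly the same rate (10) on the full medium and on
carbon alone — amino-acid uptake cannot raise growth, which makes the
"growth is independent of supplied amino acids" signature of a
prototroph exact rather than approximate. Knockouts delete biosynthesis
reactions; a knocked-out model still grows at 10 on the full medium
(import) and at exactly 0 without the focal amino acid, so planted
auxotrophy recovery is noiseless by construction. The full medium allows
carbon uptake 1000 and 20 flux units of each amino acid.

## ASV mapping

Each ASV is aligned semi-globally (ASV end-to-end, free end gaps on the
reference) against every 16S gene in the catalog, in both orientations;
scoring is match +1 / mismatch −1 / gap −2, identity = matches /
alignment columns spanning the ASV, query coverage = ASV positions
aligned to a reference base / ASV length. A genome's identity is the
maximum over its 16S genes and orientations. Thresholds (97% identity,
95% coverage) are inclusive; per ASV only hits at the maximum passing
identity are kept, so ties across genomes survive. A shared-12-mer
prefilter skips hopeless pairs; a test asserts it never changes results.
The kernels are numba-compiled dynamic programming with fixed
tie-breaking (diagonal > up > left), verified against an
alignment-enumeration oracle on short sequences.

Abundance assignment splits each mapped ASV's counts equally among its
tied genomes (configurable to drop ambiguous ASVs instead), sums per
genome and normalizes by the sample's mapped reads. Samples with no
mapped reads keep an empty abundance map and are flagged. IUPAC
ambiguity codes are accepted but never match (they score as mismatches);
non-IUPAC characters are input errors.

## Peptidase calling

Every scan sequence (query) is aligned locally (Gotoh affine gaps,
BLOSUM62, gap of length L costs 11 + L, X scores 0 against everything)
against every protein of a genome. Raw scores are converted with the
Karlin–Altschul transformation at the gapped BLOSUM62 defaults
λ = 0.267, K = 0.041 — `bits = (λ·raw − ln K)/ln 2`,
`E = m·n·2^(−bits)` with m the scan length and n the total residue count
of the proteome being searched — which makes scores reproducible without
an external search tool. Four filters apply conjunctively in one pass:
E < 0.01, query coverage > 85% (strict), bitscore > 100 (strict), and
coverage of the annotated peptidase unit ≥ 95% (inclusive); coverages
are computed from the query span of the optimal local alignment.
MEROPS identifiers are validated as family (letter + 2 digits) '.'
member (3 alphanumerics, letter allowed first, e.g. S09.A41).

Extracellular flagging keeps hits on signal-peptide-positive proteins
(annotation table is an input; missing proteins count negative and are
logged) and aggregates per genome: gene copies = distinct
(protein, MEROPS id) pairs; distinct mode counts MEROPS ids. The
weighted community average defaults to gene copies, with distinct-ID
mode as an option.

For synthetic data a documented toy signal-peptide rule stands in for a
trained predictor: positive iff residues 2–4 contain a K/R and residues
5–25 contain a run of ≥ 8 residues from {L, A, V, I, F}. It emulates
only the n-region charge + h-region hydrophobicity architecture; it has
no relationship to real predictor accuracy, so passing tests say nothing
about signal-peptide prediction quality on real proteomes — on real data
the table should come from a dedicated predictor.

## Community metrics

Genomes present in a sample but absent from a profile (e.g. below the
completeness gate) are dropped and weights renormalized over profiled
genomes; the dropped fraction is reported per sample. Auxotrophy
abundance, presence-based peptidase abundance and both weighted averages
follow the formulas in the README; by construction the weighted
auxotrophy average equals the sum of the 20 per-amino-acid abundances,
an identity asserted in tests. Bray–Curtis uses the union of keys with
absent = 0 and raises on two all-zero profiles; distance matrices for
ordination use per-sample peptidase abundance vectors over all observed
extracellular MEROPS ids. Range scaling maps a constant vector to all
zeros. Median dissimilarity to a reference set uses the midpoint
convention for even counts.

## Statistics

* Kendall tau-b (ordered regions coded 1–4) with midrank tie
  correction; two-sided p by exhaustive permutation of the value vector
  for n ≤ 8, otherwise the tie-corrected normal approximation.
* Wilcoxon rank-sum: exact enumeration when n₁+n₂ ≤ 12 without ties,
  else normal approximation with continuity and tie correction.
  Signed-rank analogously (zeros dropped first; all-zero input returns
  p = 1 flagged degenerate). Random tie-breaking is never used.
* BH step-up FDR (statsmodels), input order preserved, capped at 1.
* Spearman matrix: rho per (amino acid, peptidase) pair over shared
  samples, constant columns flagged, BH applied jointly across the
  whole matrix.
* PCoA: double-centering of −D²/2, symmetric eigendecomposition,
  coordinates from positive-eigenvalue axes; negative eigenvalues are
  reported, not corrected.
* PERMANOVA (one-way, free permutation of labels): pseudo-F from
  `SS_total = Σ_{i<j} d²/N` and within-group analogues; p by the
  add-one convention `(1 + #{F* ≥ F}) / (1 + n_perm)` — never exactly
  zero, floor 0.001 at the default 999 permutations — or by full
  enumeration of distinct label arrangements when there are ≤ 10,000
  (the observed arrangement is then part of the null set). Seeded and
  bit-reproducible.
* Differential peptidase screen: prevalence filter (median relative
  abundance ≥ 1% in either group), signed-rank (paired, matched sample
  ids required) or rank-sum per retained peptidase, BH adjustment, and
  significance at adjusted p < α (default 0.001); a config flag
  thresholds on raw p instead, since adjusted-versus-raw thresholding
  is a genuine analysis choice. Direction is the sign of the median
  difference.

## Synthetic study design

`make_catalog` draws, per genome: a 16S gene as a 300-nt shared
ancestor with 8–15 substitutions (pairwise identities ≥ 90%); an
auxotrophy set (each amino acid independently at rate 0.10 — auxotrophy
is common among gut bacteria, and 0.10 yields the 0–5 auxotrophies per
genome typical of catalog-scale screens); planted peptidase domains
(each of 12 scan sequences carried extracellularly with probability
0.35, as an intracellular copy with probability 0.175, mutated at 1% per
residue by default), one scrambled decoy per genome, and background
proteins; completeness cycles deterministically over {100, 90, 80} so
the 85% gate always has work to do. All generators are pure functions of
(parameters, seed).

`make_samples` plants one mappable ASV per genome (identities cycling
100 / 98.5 / 97.0 — the last sitting exactly on the inclusive mapping
threshold) and, for every fourth genome, an unmappable ASV at 96 or 95%.
Sample composition is Dirichlet with concentration
`base · exp(aux_tilt·z_aux + pep_tilt·z_pep)`, where z are standardized
per-genome trait covariates, followed by multinomial reads at depth
10,000 (seconds-scale tests at realistic sparsity). The default region
design tilts small-intestine samples toward auxotrophic genomes
(decreasing along duodenum → jejunum → farthest distance, reversed in
the large intestine) and large-intestine samples toward peptidase-rich
genomes; the SIBO design reverses both tilts in the overgrowth group.
When focal amino acids are configured, the auxotrophy covariate combines
the standardized total count with the standardized indicator "carries at
least one focal auxotrophy": the aggregate weighted-average contrasts
are then robust across seeds, while individual focal amino-acid trends
remain subject to sampling variability (an unlucky catalog draw can
leave one focal amino acid's carriers anti-correlated with the composite
covariate) — the expected behaviour of a compositional simulation, and
the reason stage-level truth scoring uses aggregate recall/precision.

What the generator does not emulate: chimeras, sequencing error
profiles, realistic sequence evolution, gapped 16S variation, copy-number
variation of the 16S gene, or correlated auxotrophy/peptidase traits.
Passing tests therefore demonstrate correctness of the computations and
recoverability of planted effects, not performance on real amplicon
data.

## Numerical choices and problem sizes

Solver tolerances 1e-9 (LP), symmetric-matrix checks at 1e-9,
permutation-test comparisons at 1e-12 slack. Alignment kernels are
integer-scored, so oracle equality is exact. Test problem sizes — 200
random LPs against a vertex-enumeration oracle, 100-genome screens,
enumeration oracles at n ≤ 8, a 40-genome / 180-sample end-to-end study
with 999 permutations, 1,000-replicate null calibration — were chosen so
the whole suite completes in about a minute on one CPU while each check
still exercises the property at meaningful scale.

## Known limitations

* The FBA layer assumes models are curated inputs; no gap-filling or
  medium inference is attempted, and an unbounded LP is reported as a
  model error rather than repaired.
* The peptidase stage is homology calling, not activity prediction, and
  the hand-rolled aligner lacks BLAST's composition-based statistics; λ
  and K are fixed constants, so bitscores match BLAST only in spirit.
* SBML import covers Level 3 FBC-style and kinetic-law-parameter bound
  conventions; exotic compartment layouts map to cytosol with a warning.
* PERMANOVA is one-way with free permutations (no strata, no
  dispersion test); unbalanced tiny groups (n = 1) are rejected.
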