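# Methods

## The measurement model

Each LC-MS run carries four isotopically labeled samples: two control and
two treated biological replicates, tagged with the D0/D3/D6/D9 variants of
the trimethylammoniumbutyryl (TMAB) amine label so they co-elute and are
read off as four monoisotopic peaks per peptide.  The label deltas
(+128.1075 Da for D0; +3/+6/+9 × 1.00628 Da for the deuterated forms) are
exposed as constants (`core.TMAB_LABEL_MONO`) for users validating raw
peaks, but peptide masses in all tables are *unlabeled* monoisotopic
masses — residue masses plus one water, +42.01057 Da per N-terminal acetyl
and +15.99491 Da per oxidized Met, all derived from elemental monoisotopic
masses via pyteomics.

Quantification proceeds in three deterministic steps:

1. **Charge-state averaging.** A peptide observed at several charge states
   contributes, per channel, the arithmetic mean over the states in which
   that channel was detected.  A channel absent everywhere stays "not
   detected" (ND) and never becomes a zero.
2. **Control-mean normalization.** Within a run, every detected channel is
   divided by the arithmetic mean of the *detected* control channels.
   When both controls are present their ratios average exactly 1 — an
   algebraic identity the tests assert to 1e-12 — and all ratios are
   invariant to rescaling the run.  A peptide with no detected control
   channel is unquantifiable in that run and is excluded with a warning.
3. **Pooling and testing.** Ratios are pooled across runs (the pooled
   control n is the total number of control replicates in which the
   peptide appeared, e.g. 6 or 8 for 3–4 runs).  Control vs treated is
   compared with a two-sided two-sample Student's t-test with pooled
   variance and df = n₁ + n₂ − 2, tiered at p < 0.05 / 0.01 / 0.001.
   Fold-change calls use the pooled treated mean with *strict*
   thresholds: > 2 is up, < 0.5 is down, exactly 2 (or 0.5) is within.
   Only peptides found in at least `min_runs` runs (default 3) enter the
   pooled table; per-run ratios remain available for rank plots.

Degenerate inputs: two zero-variance groups with equal means take the
t = 0 / not-significant convention; zero variance with unequal means is
flagged `degenerate` with no p-value, avoiding infinite statistics on toy
fixtures.  Fewer than two ratios in either group is flagged
`insufficient`.  No multiple-testing correction is applied to the tiers —
they mirror the raw-p convention of the source tables — but a
Benjamini–Hochberg q-value column is emitted alongside for modern use.

A known property of this design, quantified during validation: because the
per-run control ratios are constrained (their mean is exactly 1, variance
≈ σ²/2) while treated ratios are not (variance ≈ 1.5 σ²), the pooled
t-test's true type-I rate at CV 20%, 2 runs × 2 replicates, is ≈ 6.0%
rather than 5.0%.  This mild anti-conservatism is inherent to
normalize-then-test pipelines with few replicates and is within the 3-SE
acceptance band used by the calibration test, which averages the call rate
over five replicate 1000-peptide simulations to keep Monte Carlo noise
well below the band width.

## Peptide-to-protein mapping and classification

Coordinates are 1-based and inclusive throughout; residue 1 is the
initiator Met.  Mapping is exact substring search over the proteome (I and
L are distinct — identifications come from a search engine that committed
to one).  All occurrences are returned; when the identification table
annotates a gene, matches to that gene are marked canonical and drive the
census (paralogous matches, e.g. identical peptides shared by two
glyceraldehyde-3-phosphate dehydrogenase genes, are retained but not
double-counted).  Nonstandard residue codes (B, Z, X, U) are rejected
outright: silently skipping them would corrupt composition statistics.

Terminal classes are mutually exclusive, N-terminal rules first: start 1
(initiator Met present); start 2 of a Met-initiated protein (Met
excised — still an N-terminal peptide); start at an annotated mature-form
N-terminus; end at the last residue (C-terminal); otherwise internal.  A
peptide spanning the whole protein is therefore classified N-terminal;
none was observed in the motivating data, so the choice of precedence is
essentially cosmetic but is fixed for reproducibility.

Cleavage sites are the bonds that *produced* the peptide: the N-side bond
(P1 = upstream flanking residue) exists unless the peptide starts at
residue 1, the C-side bond (P1 = the peptide's last residue) unless it
ends at the protein's C-terminus.  P1 categories: acidic {D, E}, basic
{K, R}, hydrophobic {L, M, V, A, F, Y, W}, Pro, other.  Because published
percentages mix two denominators, the census reports both: per-site
(every bond counted once) and per-peptide (a peptide counts once in each
category in which it has at least one bond).

Census conventions: composition and terminal tallies deduplicate on bare
sequence (the same sequence in several modification states counts once;
configurable); composition percentages are printed to one decimal,
terminal and location percentages to the nearest integer, matching the
conventions of the tables they emulate.  The packaged background
composition (intracellular and nuclear yeast proteins) is survey data from
Cedano et al., J Mol Biol 266:594–600 (1997), shipped as a fixture rather
than recomputed.

## The terminal-fraction null model

With W = L − k + 1 windows of length k on an L-residue protein, at most
two touch a terminus, so a uniformly drawn window is terminal with
probability min(2, W)/W.  For L in 300–400 and k = 15 this stays below
1%, the benchmark against which the observed ~30–43% terminal excess is
judged.  The simulation reproduces this limit exactly at θ = 0 (below).

## Abundance, half-life, and coverage

Abundance tables are ranked by descending value with stable tie order
(no tie rule exists upstream, so input order is preserved and documented);
bin i covers ranks (i−1)·size+1 … i·size, hits absent from the table or
beyond the last bin fall into an overflow bucket, and binning is invariant
under any strictly monotone transform of the values.  Gene joining is
exact string match after optional upper-casing — aliasing is data
preparation, not analysis.  Half-lives are clamped to 100 h at load (the
convention of the upstream turnover dataset, which caps its estimates
there), with the clamp count logged; summaries report the median, the
fractions at ≤ 3 h and ≥ 100 h, and a percentile curve at 1% steps.
`min_proteins_covering` returns the smallest m such that the m most
peptide-rich proteins account for *strictly more* than the threshold
fraction, ties broken by descending count then protein id.

## Alignment and conservation

`global_align` is a Gotoh affine-gap global aligner: a gap of length g
costs open + g·extend, and the traceback breaks ties diagonal → up → left
so outputs are bit-reproducible.  Its scores are verified two independent
ways: exhaustive enumeration of all alignments for short sequences, and
Bio.Align.PairwiseAligner under the same parameterization for longer
random pairs.  The default scheme is BLOSUM62 with gap open 10 / extend
0.5 — ordinary practice, recorded in every report's metadata, because the
alignments behind the published identity percentages were produced by an
unspecified external tool; identity comparisons against those numbers are
approximate by construction.

`progressive_align` covers the 2–3 sequence use case (e.g.
yeast/mouse/human triples): the highest-scoring pair is aligned first and
the third sequence is aligned to the two-row profile (column score =
mean substitution score, gaps in a column contributing −extend), with new
gap columns propagated to both rows.  Larger sets are out of scope; an
externally computed gapped-FASTA alignment can be imported instead.

Identity uses the reference's residues as denominator: a column counts as
identical only when *every* row carries the same residue, so a gap in any
ortholog counts against identity.  Peptide regions are merged (overlap
and adjacency) before mapping into alignment columns; "identity within
peptides" is the same statistic restricted to columns whose reference
residue lies in a merged region, and equals whole-protein identity when
the region is the whole protein (asserted as an invariant).

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with defaults describing a realistic small study, chosen once:

| parameter | default | rationale |
|---|---|---|
| n_proteins / lengths | 500; N(480, 300), min 60 | yeast-scale proteome slice; mean length near the proteome-wide ~480 aa |
| residue frequencies | intracellular-proteome survey means | realistic background composition |
| n_peptides / lengths | 300; N(15, 4) in [7, 30] | a few hundred identified peptides, masses ≈ 1.6 kDa |
| abundance | log-normal(0, 1.5) | strongly skewed, so a handful of precursors dominates the peptidome |
| terminal enrichment θ | 0.28 | that probability mass forced onto terminal windows reproduces the observed ~30% terminal excess |
| P1 weights | hydrophobic 0.50, basic 0.22, acidic 0.11, Pro 0.005, other 0.165 | proteasome-like cleavage preferences |
| acetylation of N-terminal peptides | 0.57 | the fraction of yeast proteins that are N-terminally acetylated; with ~15% N-terminal peptides this yields the observed ~9% acetylated peptides |
| Met oxidation | 0.05 per Met | a low, typical in-source oxidation rate |
| design / noise | 3 runs × (2 control + 2 treated), charges {2, 3}, CV 20% | the 4-plex design; CV matches between-replicate scatter of control ratios |

Peptide windows: the precursor is drawn abundance-weighted; with
probability θ the window is forced onto a terminus (N or C, equal odds),
otherwise the start is uniform over all W windows — so θ = 0 reproduces
min(2, W)/W exactly and θ = 1 is fully terminal, with monotone behaviour
in between.  Non-N-terminal windows are accepted by rejection sampling of
the upstream (P1) residue against the category weights; uniform or absent
weights disable the preference (and are used in the terminal-fraction
checks so the two dials do not interact).  Real identification tables list
unique sequences, so the generator deduplicates by default;
`unique_sequences=False` switches to pure i.i.d. draws for large
statistical simulations where uniqueness is impossible (10,000 draws from
336 windows) and irrelevant.  Intensities: base level = precursor
abundance on an arbitrary ion-count scale; treated channels multiply in
the peptide's true fold change; every measurement carries independent
unit-mean log-normal noise of the configured CV per run, channel and
charge state.  Masses in emitted tables are computed, never simulated.

Randomness: one root seed spawns independent child streams (proteome,
peptidome, noise) via `numpy.random.SeedSequence`, so identical
(seed, config) produce byte-identical files and stages can be regenerated
independently.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: missing channels and run-to-run
detection dropout (every simulated peptide appears in every run), the
small-precursor bias of real peptidomes (simulated precursor selection is
abundance-only, so simulated precursor lengths track the proteome),
retention-time or charge-state dependence of intensities, missed or
non-proteasomal cleavage chemistry, and correlated noise between channels
of one run.  Conclusions about those behaviours need real data.

## Problem sizes and validation scale

The statistical validations run at sizes chosen to put Monte Carlo error
well inside the tolerances they check: fold-change recovery over 500
simulated peptides (tolerance 10% of truth; observed error < 2%), null
calibration over 5 × 1000 peptides against a 3-SE(1000) band,
terminal-fraction recovery over 10,000 draws against a 3-binomial-SE band,
and the aligner oracle as a complete sweep of all 7,056 ordered pairs of
length ≤ 3 over a 4-letter alphabet plus 200 seeded random pairs at
lengths 4–6 (the exhaustive-enumeration oracle grows as the Delannoy
numbers, so the complete sweep is run where enumeration is cheap and
sampled where it is not).

## Known limitations

* Identity percentages depend on alignment parameters that upstream
  analyses left unstated; reports record the scheme used and comparisons
  to externally produced figures should expect small deviations.
* The pooled t-test is anti-conservative by ~1 percentage point under the
  default design (see above); the emitted BH q-values are the safer
  quantity for screening.
* Summary statistics tied to third-party datasets (external abundance,
  half-life, and ortholog tables) are recomputed only when users supply
  those tables in the documented dialects; the package ships no download
  clients.
* Progressive alignment is restricted to three sequences by design; the
  profile scoring is a mean-score heuristic, adequate for close triples,
  not a general MSA method.
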