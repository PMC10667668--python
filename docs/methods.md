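# Methods

## Scope and data model

The package analyses a protein × sample table of LC–MS/MS spectral counts
with sample metadata (strain, sugar, fraction ∈ {supernatant, cytosol}),
classifies proteins as secreted or not, visualizes the secretome as a
clustered heatmap, screens genomes for TrmB-family binding motifs, and
computes ΔΔCt relative expression and exponential growth rates. A *condition*
is a strain × sugar pair containing at least one supernatant sample. The
default layout has seven conditions (wild type on none/maltose/
maltodextrin/pectin; the deletion mutant on all but pectin, which is not
assayed), each with one supernatant and one cytosol sample — a single-run
LC–MS/MS design without replicates; replicate counts are configurable.

## Normalization

Sample columns are rescaled to a common total of 10,000 spectra
(`total` parameter). Rescaling is linear per column, so within-sample
proportions and rank order are preserved and the operation is idempotent.
A zero-sum column is an error naming the sample rather than a silent NaN.
Normalized abundances are used for all ratio comparisons; *detection*
(presence/absence) is evaluated on the retained raw counts, because spectral
counts are integers and presence is a raw-count notion. The normalized
container therefore keeps a `raw` reference to its source counts.

## Secretion rule

Parameters (all exposed, defaults in parentheses): `ratio_threshold` (1.0),
`min_conditions` (2), `pseudocount` (0.5 normalized units),
`detection_floor` (1 raw spectrum).

Per locus and condition *c*:

* detected(c) — any supernatant sample of *c* has raw count ≥ floor;
* cytosol reference(c) — the mean normalized cytosol abundance of *c* when
  the locus is detected in *c*'s cytosol; otherwise the locus's matrix-wide
  mean normalized cytosol abundance floored at the pseudocount (a protein
  seen in the cytosol of other conditions is present at its typical level,
  not absent — a single stochastic zero must not create secretion evidence);
  the bare pseudocount when the locus is never detected in any cytosol
  sample ("found only in the supernatant", the maximal-evidence case);
* support(c) — detected(c) and normalized supernatant mean >
  `ratio_threshold` × cytosol reference.

With d detected and s supporting conditions, the discrete probability is
**1** when s = d ≥ `min_conditions` (consistent, broad evidence), **0.5**
when s = d < `min_conditions` (consistent but narrow, e.g. a protein seen in
a single sugar condition) or when partial support coincides with
supernatant-only status, and **0** otherwise — in particular, partial
support together with genuine cytosol presence is treated as cytosolic
contamination and removed, which mirrors how published secretome tables pair
every probability-0.5 entry with supernatant-only status. A locus is called
secreted iff probability ≥ 0.5. Verdicts are monotone in supernatant
abundance within already-detected conditions (raising supernatant counts
there can only switch support on); monotonicity cannot extend to conditions
where the locus was undetected, because newly detected conditions enter the
"all detected conditions must support" requirement. Ties in output ordering
are resolved lexicographically by locus tag.

The signal-peptide flag is an input annotation from an external predictor
and is carried through to the calls for reporting; it does not enter the
rule, since secreted proteins without predicted signal peptides (moonlighting
or vesicle-exported proteins) are an expected observation class.

## Clustered heatmap

Columns are centered (mean 0), so cell values are differences of normalized
spectra from the sample mean; centering removes constant column offsets, and
clustering after centering is invariant to global shifts. Row and column
trees use WPGMA ("weighted" linkage): at each step the closest pair merges
at height d(a,b), and the new cluster's distance to any third cluster is the
unweighted mean (d(a,k) + d(b,k))/2. The implementation is a direct O(n³)
agglomeration; ties on the minimal distance are broken toward the
lexicographically smallest cluster-id pair so trees are identical across
platforms. The distance metric is Euclidean by default (configurable); only
the linkage method is fixed by the analysis design, the metric being the
standard default of the seaborn clustermap approach used for the figure
style. Leaf order is the standard dendrogram order without optimal-leaf
reordering. Rendering is grayscale, white = lower and black = higher
abundance. Axes with a single element skip clustering on that axis.

## Motif screening

Patterns are consensus blocks with free spacers: `TACTN3AGTA` parses to
blocks (TACT, AGTA) with a 3-bp spacer (span 11); `N3-6` denotes a ranged
spacer, and a span is realized per hit. Mismatches are counted at block
positions only — the published site variants diverge within blocks, never in
the spacer — with a budget of `max_mismatches` (default 2, which covers the
reported site family, whose variants differ by at most two block positions).
Scanning is vectorized: the sequence is byte-encoded and per-offset
inequality counts are accumulated over block positions for every window, on
the forward sequence and its reverse complement. Coordinates are 1-based
inclusive on the forward strand (published site coordinates follow this
convention: each printed range width equals the pattern span, e.g.
1,439,024–1,439,040 = 17 = 6+5+6). Minus-strand hits report the forward
interval and the matched sequence in pattern orientation. When both strands
match at the same interval (spacer-palindromic patterns such as the TGM),
both hits are reported.

Gene context: upstream regions are strand-aware windows (default 300 bp —
not fixed by the study design; wide enough for archaeal promoter elements)
immediately 5′ of the gene start, clipped at contig bounds. A hit is
assigned to the gene whose upstream window fully contains it, the nearest
gene start winning when windows overlap. The per-gene report flags motif
presence per pattern.

## ΔΔCt expression

ΔCt = mean target Ct − mean of the reference genes' per-condition mean Cts
(arithmetic mean on the Ct scale, equivalent to a geometric mean of relative
quantities — the standard Livak extension for two internal controls such as
*pcna* and the 30S gene); ΔΔCt = ΔCt(condition) − ΔCt(control); fold change
= 2^(−ΔΔCt). Replicates are averaged on the Ct scale before differencing.
Spread is propagated as the root-sum-square of the standard errors of the
four mean terms; single-replicate terms contribute zero. Swapping condition
and control negates ΔΔCt exactly, and a global Ct shift cancels.

## Growth rate

Growth rate is expressed in doublings per hour and equals 1/G (G = generation
time). It is the least-squares slope of log2(density) on time. With an
explicit window the fit uses the points inside it; otherwise the contiguous
window of ≥ 3 points with the maximal slope is selected (ties favour longer,
then earlier windows) and reported for audit — an automatic stand-in for the
usual manual choice of the exponential phase. On noisy curves the
maximal-slope selection is upward-biased (it chases the steepest noisy
stretch); supplying an explicit window removes the bias, and the fitted
window is always reported so the choice is auditable. Estimates are invariant
to positive rescaling of density.

## Synthetic data generator

Counts are negative-binomial with mean m and variance m + αm² (dispersion
α, default 0.05, i.e. 26–31% CV at the simulated means — typical
overdispersion for spectral counts), followed by an independent dropout that
zeroes each count with probability 0.1, emulating detection limits that
produce "found only in the supernatant" rows. Secreted loci have expected
supernatant counts `baseline_mean × enrichment` (defaults 20 × 8) and
cytosol counts `baseline_mean`; the remaining loci are the reverse
(cytosol-enriched), so the cytosol control genuinely contains them. Exactly
`round(n_proteins × secreted_fraction)` loci are secreted; the defaults
(200 × 0.165) plant 33, matching the scale of the motivating study.
Signal-peptide flags are drawn at 90% true-positive and 5% false-positive
rates, reflecting the imperfect concordance between secretion and predicted
signal peptides in real tables. All generators are deterministic per seed
(bit-identical outputs).

What the generator does **not** emulate: peptide-level identification noise,
shared-peptide ambiguity, sample-carryover, condition-specific secretion
programs (planted secretion is global across conditions), compositional
coupling beyond the closure imposed by normalization, and pressure effects.
Passing recovery tests therefore demonstrates correctness of the scoring
logic under the stated noise model, not performance on real spectra.

Genome simulation plants realized motif instances (spacers filled randomly)
at non-overlapping 1-based coordinates on either strand of a random
background of configurable GC content, and places one gene per site 50 bp
downstream on the site's strand, so each site falls inside its gene's
upstream window. Ct tables plant ΔΔCt = −log2(fold) with
condition-independent reference genes and Gaussian per-well noise. Growth
curves follow N(t) = n0·2^(rate·t), optionally with mean-one multiplicative
lognormal noise of given CV.

## Numerical and design choices

* Detection floor inclusive (count ≥ 1 ⇒ detected), matching integer counts.
* Normalization tolerance for the "columns sum to total" invariant: 1e-6
  relative.
* WPGMA heights are exact merges of floating-point means; the brute-force
  oracle comparison uses allclose at default tolerances.
* The pipeline runner writes a manifest (parameters, seed, SHA-256 of every
  output); defaults that are methodological assumptions rather than
  data-driven values are logged with an "assumption" tag.
* Problem sizes used by the shipped acceptance computation: 14-sample /
  200-locus secretome, 100 random ≤7-leaf matrices for WPGMA, 200 random
  sequence/pattern/mismatch triples (50–260 bp) for the scanner, a 2.01-Mb
  synthetic genome for coordinate recovery, 200 Monte-Carlo ΔΔCt tables, and
  17-point growth curves — sizes chosen to exercise each method well past
  its asymptotic regime while completing in seconds.

## Known limitations

* The secretion rule is a documented interpretation of ratio-based
  secretion-probability scoring; the exact published formula behind archival
  supplementary tables is not restated in print, so constants
  (`ratio_threshold`, `min_conditions`, pseudocount) are exposed rather than
  hard-coded.
* Spectral counting is semi-quantitative; no peptide-level FDR or
  protein-inference modelling is attempted.
* Motif scanning is consensus-based by design (no PWM scores, no statistical
  enrichment); patterns with long ranged spacers enumerate all spacer
  lengths and may report overlapping realizations of the same site.
* ΔΔCt assumes equal amplification efficiency across genes (no Pfaffl
  correction).
* The automatic growth window targets clean exponential segments; strongly
  noisy curves warrant an explicit window.
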