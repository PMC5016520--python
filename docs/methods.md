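# Methods

## The comparison model

A repertoire set is a collection of clonotypes — unique V–(D)–J
rearrangements with a unique CDR3 amino-acid junction — each carrying
gene/allele calls and the count of sequencing reads assigned to it.
Two totals matter: *diversity* n = number of clonotypes (the test
denominator), and *expression* = total assigned sequences.  The two
sets are treated as independent samples, and the per-gene tests as
independent of each other; clonotypes are the sampling units.

For gene (or allele) k the null hypothesis is equality of the usage
proportions p₁ₖ = x₁ₖ/n₁ and p₂ₖ = x₂ₖ/n₂.  The test statistic is the
pooled-variance score z (pooled p̂ = (x₁+x₂)/(n₁+n₂)); the confidence
interval on the difference uses the unpooled Wald standard error at
level 1−α.  This pooled-z / unpooled-CI pairing is the standard one for
two-sample proportion comparisons; the two choices serve different
purposes (testing under the null vs. interval coverage under the
alternative) and are deliberately not unified.

**Small-count guard.**  The normal approximation is abandoned for
Fisher's exact test whenever *any* of the four expected counts n₁p₁ₖ,
n₁(1−p₁ₖ), n₂p₂ₖ, n₂(1−p₂ₖ) is below 5 — the classical validity rule.
Requiring all four to fail would essentially never trigger for the rare
genes the rule exists for.  The two-sided Fisher p follows the
probability-mass rule (sum of all tables with the observed margins
whose probability does not exceed the observed one), the convention of
the common exact-test implementations; the degenerate all-zero table
returns p = 1.  Fisher-tested items keep a Wald CI for display, with
the obvious caveat at such counts.

**Multiple testing.**  One run tests every gene of the requested groups
as a single family (a V+D+J human IGH run is a family of ~72), so each
raw p is adjusted by seven procedures computed from the closed
step-up/step-down formulas: Bonferroni, Šidák single-step, Holm, Šidák
step-down, Hochberg, Benjamini–Hochberg, Benjamini–Yekutieli.  All
seven are reported side by side; the package deliberately does not
choose among them.  The test suite cross-checks every procedure against
an independent reference implementation to < 1e−12.

**Allele follow-up.**  By default the allele-level family contains only
alleles of genes significant under *all* seven procedures (an override
tests every observed allele).  The family size for adjustment is the
number of such alleles across all groups.  Calls carrying a gene but no
allele are kept out of allele tables (in a "no-allele" remainder)
rather than inventing an allele; calls listing several alleles of one
gene count toward the gene at gene level but are ambiguous at allele
level.

**Interpretation and derived views.**  A difference is reported
significant "positive" when z > z₁₋α/₂ (set 1 enriched) and "negative"
when z < −z₁₋α/₂.  Rejection curves count adjusted p < α over an α grid
(default 0.001–0.25, step 0.001); scatter tables report −log₁₀ p
against z, capping p = 0 at −log₁₀ of the smallest positive double
(≈ 307.65) rather than infinity.  Normalised reports rescale counts per
10,000 clonotypes (or sequences).

## CDR analyses

CDR3-length filtering (inclusive bounds, default 4–45 AA) runs before
every analysis; excluded clonotypes are retained as a reported outlier
list.

CDR positions follow the IMGT unique numbering: CDR3 occupies 105–117
with the junction anchors (C 104, W/F 118) excluded.  A junction of L
residues assigns the first ⌈L/2⌉ residues to positions 105 upward and
the last ⌊L/2⌋ to positions ending at 117; L < 13 leaves gaps at the
loop top (111/112 outward), L > 13 inserts decimal labels there,
alternating 112.1, 111.1, 112.2, 111.2, … — so L = 13 is exactly
105–117, L = 12 lacks 111, and L = 15 reads 105–111, 111.1, 112.1,
112–117.  CDR1 (27–38) and CDR2 (56–65) use the same symmetric rule on
their own ranges.

Per-position profiles map each residue through one of the IMGT
amino-acid class schemes (hydropathy, volume, chemical, charge,
hydrogen donor/acceptor, polarity, or the identity over the 20 AA).
Memberships ship in an editable JSON data file
(`src/clonostat/data/imgt_aa_classes.json`) transcribed from the
published IMGT definitions, so corrections need no code change.  The
"physicochemical" scheme is currently the identity over the 20 amino
acids — the default residue-level display — pending curation of a
combined grouping; edit the data file to change that.  Profiles weight
one count per clonotype by default (diversity); expression weighting is
a flag, since either convention is defensible and the residue-level
display is usually about distinct junctions.

Three per-position variability indices are computed on the class
counts: Shannon entropy in bits (base 2, so the conventional
"conserved below 1, variable above 2" thresholds apply to ≤ 20
classes), Wu–Kabat k·N/n_max (1 for a monomorphic position, up to 400
for 20 equifrequent residues), and Simpson 1 − Σp² in [0, 1].

## Gene associations

V–J, V–D and D–J contingency tables count clonotypes (or sequences)
whose calls for both gene types are single; ambiguous calls are
excluded and their number reported, so matrix totals reconcile with the
per-gene count tables.  Optional double clustering applies Ward's
minimum-variance criterion on Euclidean distances independently to rows
and columns (the Ward.D2 update, the variant appropriate to raw
Euclidean input).  Ward admits no inversions, so merge heights are
non-decreasing; ties break by scipy's lowest-index convention, which
makes leaf orders deterministic.  Clustering operates on raw counts by
default (normalised per 10,000 on request); rows are not rescaled,
since the display is about occurrence structure, not profile shape.

## Synthetic study conditions

The generator emulates the statistical structure of an annotated human
IGH repertoire pair at the scale of a real memory-B-cell comparison:

* panels of 41 V, 25 D and 6 J genes (real IGH gene names, taken from
  the bundled locus-order file);
* long-tailed baseline usage (geometric decay, ratio 0.88), giving a
  few dominant genes and a rare tail that exercises the Fisher guard;
* allele mixtures: alternating genes are heterozygous-like
  (*01 at 0.7 / *02 at 0.3), the rest single-allele;
* CDR3 lengths on 4–45 AA, discretised Gaussian peaked at 15 AA
  (SD 3.5), the shape seen in IGH junction data;
* expression: 2% of clonotypes carry more than one assigned sequence
  (1 + geometric tail), matching the heavily one-copy profile of
  clonotype tables;
* 2% ambiguous ("several genes") calls; optional injected CDR3-length
  outliers (< 4 or > 45 AA) to exercise the filter.

Injected effects add δ to a gene's usage probability in set 2, with the
unshifted genes rescaled proportionally so probabilities still sum to
one.  Everything derives from one seed.

CDR3 strings are uniform random residues of the drawn length: the
generator reproduces the *counting* structure the statistics consume,
not junction biology — no V(D)J recombination machinery, no germline
junction content, no somatic hypermutation, no sequencing error.
Passing tests therefore validate the bookkeeping and the statistical
procedure under known truth; they say nothing about annotation quality
or junction-sequence realism in real data.

For replicated calibration studies a count-level shortcut draws the
per-gene multinomial counts directly (identical marginal distribution
at the gene level) instead of synthesising records; the type-I-error
and familywise-error checks use it to run 500 replicates of a
5,000-clonotype null pair in seconds.  Problem sizes used by the
benchmark runs: 20,000 clonotypes per set for power/recovery (the
injected ±0.05 shifts are tens of pooled standard errors there),
5,000 per set × 500 replicates for null calibration.

## Numerical and degenerate-input choices

* Adjusted p-values are clipped to [raw p, 1]; sorting is stable, so
  tied raw p-values adjust identically.
* A family of one returns adjusted = raw for every procedure.
* Empty inputs: filtering an empty record list yields an empty set;
  an empty count table is an error for testing; a single row/column
  matrix skips clustering with identity order.
* Exact ties x₁/n₁ = x₂/n₂ give z = 0, p = 1 — never NaN.
* Gene-count tables carry explicit remainders (several-calls,
  no-allele, no-call) so single + remainders always reconciles with the
  set totals; this conservation is property-tested.
* Parsing strips functionality annotations (F/ORF/P) from gene calls;
  records violating invariants (CDR3 length mismatch, non-standard
  residues, unparseable calls) go to a rejected-rows report, never
  silently dropped.

## Known limitations

* The exact-versus-normal agreement is scale-dependent: the
  probability-mass Fisher p exceeds the z p by up to ~0.05 when the
  smallest occurrence count is in the tens, falling below 0.01 only
  once the smallest cell reaches several hundred.  Borderline rare
  genes can therefore change significance class with the method, which
  is precisely why Fisher-guarded items are listed separately.
* The canonical input dialect is this package's own definition; real
  annotation exports with other column layouts need a `--dialect`
  column map.
* The bundled IGH locus order is a static approximation of the curated
  locus ordering; supply `--order-file` where exact display order
  matters.  D- and J-gene order especially should be checked against a
  current locus reference.
* Gene-level inference treats ambiguous multi-gene calls as their own
  excluded category; repertoires with high ambiguity rates lose power
  accordingly.
* No paired/dependent-sample design: the two sets must be independent.
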