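# Methods

## Events and classification

A skipped-exon event is an exon trio (upstream exon, cassette exon,
downstream exon) with replicate-level PSI values for two genotype groups and
an event-level p/FDR from an upstream differential-splicing caller. Tables
are consumed in an rMATS-like dialect: comma-separated replicate inclusion
levels (`NA` allowed and kept as missing), 0-based starts with end
coordinates that already act as half-open bounds (a 1-based-start dialect is
a flag). Internally all intervals are 0-based half-open; upstream/downstream
are transcript-direction, so on the minus strand the upstream exon lies
genomically right of the cassette.

Δψ = mean ψ(reference) − mean ψ(comparison) over non-missing replicates.
Sign convention: the reference group is the one expressing the regulator
(wild type), so regulator-enhanced exons have positive Δψ. Thresholds
(defaults): regulated at FDR < 0.05 and |Δψ| ≥ 0.05 (inclusive, matching a
"≥ 5%" rule); control at FDR > 0.5, every *group-mean* PSI strictly inside
(0.15, 0.85), and host-gene average FPKM > 5.0 in at least one group. The
PSI bound is applied to group means rather than individual replicates — the
between-group contrast is what the control set must lack; a replicate-level
bound would mostly re-test within-group noise. Events whose gene is missing
from the expression table are excluded from the control set only (the
regulated criteria never reference expression); they are warned about, not
errors, because joining two tools' outputs routinely drops identifiers.

## Region extraction

Enrichment regions: the exon body plus up to 250 nt of intron immediately
adjacent to the cassette exon on each side. Splice-site nucleotides are
*masked out* of the scanned string — 20 nt of intron at every 3′ splice site
and 6 nt at every 5′ splice site, whenever the window covers them (for
introns ≤ 250 nt this includes the far end). Masking (removing positions
from the window) was chosen over shifting the window outward because the
exclusion is a property of the splice sites, not of the window; shifting is
available via `RegionConfig(exclusion_mode="shift")`. Long-intron scanned
lengths are therefore 230 nt upstream (250 − 20) and 244 nt downstream
(250 − 6); an intron shorter than its exclusions yields an empty region with
a truncation flag, never an error.

Map segments: the five ordered segments (flanking exons whole, introns
truncated to the exon-proximal 250 nt, exon body) with **no** splice-site
exclusions — the map is meant to display, not test, so nothing is hidden.

Sequences are reported 5′→3′ in transcript direction (minus-strand slices
reverse-complemented), uppercased (soft-masked lowercase is scanned — the
analysis targets short degenerate motifs for which repeat-masking would
remove real sites), and transcribed T→U. `N` bases are retained and match no
motif position.

## Motif counting and enrichment

Motifs are literal or IUPAC-degenerate RNA strings compiled to overlapping
regex scans. by-NT counts every matching start position; by-Sequence is
0/1 per sequence, so by_seq = min(1, by_nt) holds by construction.

2×2 tables (regulated vs control):

- by-NT: occurrences vs remaining scannable start positions
  (Σ max(0, len − k + 1) − occurrences). An alternative construction using
  motif-covered vs uncovered nucleotides is available
  (`EnrichConfig(by_nt_table="coverage")`) and recorded in output metadata;
  the positions construction is the default because it matches the counting
  unit of the by-NT mode (match starts).
- by-Sequence: sequences with ≥ 1 hit vs without.

Both are tested with the right-tailed Fisher exact test (hypergeometric
P(X ≥ a); `scipy.stats.hypergeom`, verified in the test suite against exact
integer enumeration on every table with total ≤ 60 at 1e−12). BH correction
(`statsmodels`) is applied to by-NT p-values across motifs within each
(region, direction) family — the enhanced and silenced sets are independent
tests of different sequences, so they form separate families. by-Sequence
p-values are thresholded raw (p < 0.01); no BH is applied to them since the
dual criterion names an FDR only for by-NT. Enriched ⇔ FDR(by-NT) < 0.05 AND
p(by-Sequence) < 0.01.

With i.i.d. background sequences the by-NT test is approximately calibrated;
discreteness makes Fisher mildly conservative (measured type-I ≈ 0.04–0.06
at nominal 0.05 across seeds, inside the 99% binomial band — recomputed by
the acceptance script, never assumed). Self-overlapping motifs violate
positional independence slightly; the planted-recovery margin (~19-fold
occurrence excess at default planting) dwarfs this.

## RNA binding map

Coverage track: position i is 1 iff it lies inside ≥ 1 occurrence of any
motif in the set. Window score: mean of the track over a 50-nt window, 1-nt
step, emitted only for windows fully inside one segment (cross-boundary
windows would mix intron and exon signal and make segment attribution
ambiguous). Alignment for averaging across events: introns are anchored at
the exon-proximal boundary (position 0 = window flush against the exon);
exons, whose lengths vary, are anchored at both edges up to 100 windows per
edge with no rescaling — positions beyond a short exon simply contribute
nothing, and the per-position contributing-event count `n_events` is
reported so thin positions are visible. Percent-of-length rescaling was
rejected as the default because it blurs the fixed-distance positioning that
splice-site-proximal regulation exhibits. No smoothing beyond the window
itself.

The default map motif set is the bundled GU-rich 6-mer file: three 6-mers
established for Esrp1 (UGGUGG, GGUGGU, GUGGUG) plus nine further
UGG-containing 6-mers explicitly named `*_standin` — a documented synthetic
stand-in for a full in-vitro-selected top-12 list, not a published set.
Substitute a real list via `map_motifs` in the pipeline config. Likewise the
bundled RBP motif TSV is a small example set for testing and demonstration,
not a curated 115-motif literature collection.

## Expression filters

DEG ⇔ q < 0.05 AND fold > 2 (strict, per "greater than twofold") AND the
larger group-mean FPKM > 0.1. The floor is applied to the larger mean by
default — a gene silenced in one condition is a legitimate DEG; requiring
both means would exclude exactly the on/off genes of interest — with a
`both` option. A gene with one zero mean has infinite fold and passes the
fold criterion iff the nonzero mean clears the floor; a pseudocount option
exists. The RBP/splicing-factor panel filter keeps supplied panel members at
fold ≥ 1.5 (inclusive, per "at least 1.5-fold"), sorted by |log2 fold|; the
panel list itself is user configuration (empty default — panel composition
is study-specific curation, not something the package should invent).

## Quantitative statistics

PSI from gel bands: intensity is proportional to molar amount × product
length, so PSI = (I_inc/L_inc) / (I_inc/L_inc + I_skip/L_skip). The
mutually-exclusive-exon ratio is IIIb/(IIIb + IIIc) on molar amounts, and
composing it with band length-normalization equals the direct molar ratio.
Percent change = 100 (ref − test)/ref. The two-group test defaults to the
pooled-variance Student t (df n₁+n₂−2) treating "±" values as sample SDs:
on the group summaries (16.00 ± 2.37, n = 8) vs (12.25 ± 1.24, n = 6) this
reproduces p = 0.0043, which an SEM reading does not — that agreement is the
documented verification of the SD interpretation. Welch is a flag.
Concordance is the sample Pearson r with the t-transform p (n − 2 df);
zero-variance inputs raise rather than returning NaN.

## Synthetic data generator

What it emulates: replicate PSIs per group drawn from beta distributions
(mean μ per event set, concentration ν = 99 → within-group SD ≈ 0.05 at
μ = 0.5); effect size |Δψ| = 0.4 for regulated events (0.75 vs 0.35), or
per-event magnitudes from `delta_psi_range`; control events share a
per-event mean drawn from (0.35, 0.65) so group means stay inside the
control PSI window. Event counts default to 119 enhanced / 95 silenced /
500 control with 3 replicates per group. Event p/FDR are **computed** — a
two-sample t-test on the simulated replicates, BH across events — so the
FDR column behaves like real caller output; `fdr_mode="deterministic"`
instead places p/FDR strictly beyond thresholds for exact-recovery tests.
Geometry: exon trios with 400–800-nt introns laid non-overlapping on one
synthetic chromosome, random strand per event, i.i.d. bases (uniform by
default; a GU-rich composition can be set to stress-test false-positive
control, since the target motifs are themselves GU-rich). Planting:
Poisson(λ = 1.0) non-overlapping copies of UGGUGG per silenced upstream
intron and enhanced downstream intron, uniform within the scannable
(post-exclusion) window — ~19-fold over the uniform-background expectation
of ~0.055 occurrences per 230-nt window. Expression: control-event genes at
FPKM 10–30 (so they satisfy the control-gene expression criterion),
planted DEGs at fold 4 (178 up, 337 down), nulls at fold ≤ 1.25, plus
low-expression genes below the FPKM floor. Expression q-values are assigned
from planted truth because the emitted table carries no replicate-level
data to test on.

What it does **not** emulate — and hence what passing tests do not show
about real data: read-level noise and coverage-dependent PSI uncertainty,
correlated replicate structure, isoform complexity beyond a single exon
trio per gene, non-i.i.d. genomic sequence composition (repeats, GC
structure, conservation), motif clustering/co-occurrence between RBPs, and
any relationship between expression level and splicing measurement quality.

## Problem sizes and numerics

Default test and acceptance runs use the full default event counts
(714 events, ~1.3 Mb genome, ~1–2 s per pipeline run), 20-seed loops for
calibration/recovery properties, and exhaustive Fisher verification to
table total 60. All randomness flows from `numpy.random.default_rng` seeds;
identical seeds give byte-identical outputs. Degenerate inputs are defined,
not exceptional: empty scan regions (over-short introns) are flagged and
contribute nothing; motifs longer than a sequence count zero; the all-zero
Fisher table has p = 1; BH of an empty vector is empty.

## Known limitations

- The bundled motif files are example/stand-in sets (see above).
- The by-NT table construction for real published tables is not uniquely
  determined by prose descriptions; both plausible constructions are
  implemented and the choice is recorded in output metadata.
- Exon-segment alignment in the map (double-edge anchoring, no rescaling)
  is one reasonable convention among several; profiles near exon centers of
  variable-length exons should be read with the `n_events` column.
- No confidence bands on map profiles; no PWM scoring or motif discovery
  beyond literal/IUPAC k-mers (k-mer enumeration is provided).
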