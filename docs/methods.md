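# Methods

`polyedit` quantifies CRISPR/Cas9 indels at one amplicon target site with
four independent measurement models plus melt-curve analysis, and provides a
synthetic-data generator that plants exact ground truth for all of them.
This note records the models, the defaults and why they were chosen, and
what the synthetic tests do and do not demonstrate about real data.

## Allele-pool model

A line is a pool of amplicon alleles: one or more wild-type sequences with
relative abundances (multi-length WT variants arise in practice when primers
anneal in poorly conserved introns) and edited alleles, each a signed indel
planted at an offset from the Cas9 cut site with a pool frequency. The pool
frequency of an edited class is the quantity every method estimates — the
polyploid co-editing frequency, with reads or peak signal standing in for
gene copies. Frequencies must sum to one; allele labels travel in simulated
read identifiers so callers can be scored against exact truth.

## Sequencing error model

Reads are drawn from the pool by frequency, in the forward orientation only
(the anchor-based caller operates on forward reads; reverse-read assays are
handled by reverse-complementing the stream). Two error processes are
applied:

- per-base substitutions at `substitution_rate` (default 0.1%), and
- a per-read ±1–2 bp slippage indel at `read_indel_rate` (default 0.2%).

The defaults were fixed so that spurious length-deviation classes appear at
sub-1% frequencies, exercising both reporting filters the way real
background noise does. They are conventions for a plausible short-read
amplicon run, not measurements: the model has no quality scores, no
position-dependent error profile, no paired ends and no chimeric PCR
artifacts, so passing recovery tests demonstrates correctness of the
calling arithmetic under binomial sampling plus simple noise — not
robustness to every artifact of a real instrument.

## Conserved-sequence (CS) calling

Per read: exact primer match (first occurrence), then exact
conserved-sequence match downstream of the primer (first occurrence, warning
when repeated); indel size = (observed primer→CS distance) − (WT distance).
Reads missing either anchor are uncallable and leave the denominator.
Classes below `min_report_freq` (default 1% of callable reads) are excluded
from the breakdown but kept in the overall non-WT figure; consequently the
breakdown sums to at most the overall value, with equality exactly when no
sub-threshold class exists. Including sub-threshold deviations in the
overall figure is a deliberate choice: it preserves the identity between
"fraction of non-WT reads" and the denominator semantics, and the breakdown
remains the filtered view.

The conserved-sequence search starts after the primer match ends, since a
deletion large enough to pull the CS into the primer region would in
practice also destroy one of the anchors.

## Indicator-window calling

Two 12-nt indicators are taken from the WT amplicon immediately outside the
comparison range *R* (left indicator ends *R* bp left of the cut site, right
indicator starts *R* bp right of it), so re-deriving the assay at a
different *R* moves the anchors — the per-target indicator placement is
configuration, and this rule is the package's default geometry. A read
containing both indicators has its inter-indicator segment compared with the
WT segment:

- equal length and identical sequence → WT;
- equal length with mismatches → a substitution bucket, reported separately
  and never mixed into the indel breakdown (indel tables report indels;
  substitution calling is a sequencing-only capability);
- length difference `delta` with `|delta| <= R` → an indel call, with the
  inserted/deleted bases extracted by longest-common-prefix/suffix trimming
  (reported lower-case);
- `|delta| > R`, or an indicator destroyed by the indel → unmatched.

Calls aggregate into one class per indel size; a class's sequence column
lists its dominant extracted variants ("a or t" style: variants holding at
least 10% of the class, at most three shown). The reporting floor is 0.015%
of callable reads. Deletions whose deleted interval covers both cut sites
of a dual-target amplicon carry a `spans_both_sites` flag.

Large deletions invisible at the default *R* = 35 are recovered by a second
pass at `rerun_R` (default 70) restricted to reads the first pass could not
match; the newly callable reads join the denominator and all frequencies are
recomputed over the union, which raises the overall frequency whenever the
rerun reads are enriched for edits.

## Fragment analysis (CE)

The WT sample defines the WT peak-size set: every peak at least
`min_rel_height` (default 2%) of the tallest WT peak is a WT size, the
tallest is the main size. In mutant samples, any peak within
`match_tolerance` (default 0.5 bp — CE sizing scatter is sub-base-pair) of
any WT size is WT; other peaks get indel size = deviation from the **main**
WT size, rounded half away from zero (a 7.56 bp deviation reports as 8).
Peaks under 1% of total signal are baseline noise (configurable).
Frequencies are height fractions; the co-editing percentage is
100 × (total − WT height)/total and equals the sum of per-indel frequencies
exactly, because heights partition.

This reproduces the method's documented bias: when the WT amplicon itself
has a secondary variant one base below the main peak, a genuine −1 mutant
peak is absorbed into the WT class and the co-editing estimate can
undershoot by the full frequency of that allele. The bias is a property of
the WT-peak-set rule, not of the implementation, and the test suite pins it.

## RNP gel scoring

ΔGV = mean grey value of the cleaved product(s) − grey value of the
non-cleaved product; with two cleaved products their GVs are averaged, and
an absent band contributes 0. The categorical score is

| score | single-product ΔGV | dual-product ΔGV | band |
|-------|--------------------|------------------|------|
| 0 | < −90 | < −60 | 0% |
| 1 | −90 … −31 | −60 … −21 | <40% |
| 2 | −30 … 30 | −20 … 20 | ~50% |
| 3 | 31 … 90 | 21 … 60 | >60% |
| 4 | > 90 | > 60 | 100% |
| 5 | product at unexpected size | | 100%, large indel |

Real-valued ΔGV falling in the unit gaps between the printed integer ranges
resolves to the lower score. The dual-product cut points are the
single-product ones scaled to two thirds (averaging two cleaved bands
compresses ΔGV), and the suite checks that relation. The sign convention is
implemented exactly as stated — a fully cleaved (unedited) lane scores 0 at
ΔGV < −90 — which implies grey value decreases with band intensity; the
synthetic gel model therefore sets GV = scale × (1 − mass fraction), with
scale 150 (single) / 100 (dual) so that cleaved fractions
1.0/0.8/0.5/0.2/0.0 land exactly on scores 0–4 in the noiseless limit.
Score 5 fires when a lane shows bands matching neither expected product size
(±5%); an "extra" band that does match an expected size is an input error
and is reported as such rather than scored.

## HRMA

Melt curves are two-point normalized per replicate: an affine map sends the
mean fluorescence in a pre-melt window to 100 and in a post-melt window
to 0, which removes per-trace gain and offset exactly. Windows default to
the first and last 1 °C of the acquisition range and are configurable (real
instruments let the analyst place them per target). The per-sample curve is
the mean of its normalized replicates; the baseline is the mean over all WT
replicates (two WT samples in triplicate in the drivers); the difference
curve is sample minus baseline and the summary statistic is the maximum
**absolute** difference over the grid (the sign of a difference curve is not
meaningful across indel types). Melt peaks are maxima of −dF/dT after a
5-point centered moving average, requiring 5% prominence and 20% height
relative to the largest derivative — the height floor keeps replicate noise
on the flat shoulders from registering as transitions — and are reported to
0.1 °C.

The synthetic melt model is a frequency-weighted mixture of two-state
sigmoid transitions (width 0.6 °C) per allele, with per-replicate gain,
offset and additive noise. It makes the qualitative behaviors testable —
WT-vs-WT differences bounded by replicate noise, the difference statistic
monotone in mutant fraction for a fixed melt-temperature shift, two
well-separated transitions giving two derivative peaks — but it is not an
instrument model: real amplicons show sequence-dependent, multi-domain melt
behavior, SNP-driven WT variability, and saturation of the difference
statistic at large shifts, none of which the two-state mixture captures.

## Concordance, chimerism, cost

The concordance table reports each line's overall frequency per method and
compares reported indel sizes across methods within ±1 bp (observed CE/NGS
size drifts of 1–2 bp motivate the tolerance). Because the methods filter at
different floors, only classes at ≥1% enter the size comparison. Two
failure-mode flags are derived: a −1 class present in sequencing but absent
from CE (secondary-WT-peak absorption) and a sequencing class with no
window-caller partner; a large CS deletion explained by a window call
flagged as spanning both sites is reconciled, not flagged.

Chimerism: each vegetative progeny of an event is classified WT or mutant by
thresholding its overall frequency (default 5%, configurable — the
classification is qualitative); an event is chimeric iff its progenies
disagree, and a single progeny is insufficient evidence.

Cost: per-sample cost of a method is the sum over its components of pack
price divided by reactions per pack, multiplied by a per-sample replicate
count (3 for HRMA, which runs in triplicate). The drivers evaluate the model
on a synthetic price table with plausible magnitudes; no real quotes are
shipped.

## Problem sizes and numerical choices

The drivers and tests use 20,000 reads per line (5,000 for the progeny
screen), 0.1 °C melt grids over 70–95 °C, and 100-seed Monte Carlo for
noise-recovery checks; these sizes put binomial sampling error well below
the effects being measured while keeping everything fast. Stochastic
assertions use 3-SD bounds under fixed seeds. Frequencies are stored as
fractions everywhere in the library; only `co_editing_percent` returns the
percent scale, because that statistic is defined ×100.

## Known limitations

- Anchor matching is exact; a SNP inside an anchor silently removes a read
  from the denominator (mismatch-tolerant matching is exposed as a
  configuration hook but off by default, matching the exact-match
  definition of the method).
- The CS caller cannot attribute indels to individual sites of a
  dual-target amplicon; that is precisely the window caller's role, and the
  spanning-deletion flag is the bridge between the two.
- CE cannot see substitutions at all, and its −1/secondary-WT-peak bias is
  inherent.
- The RNP score is semi-quantitative (~25%-wide bins) and carries no size
  information; the gel-image-to-grey-value step is upstream of this package,
  which consumes the numeric table.
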