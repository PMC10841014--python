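# Methods

## The evidence chain

A miRNA–target module is supported by three independent readouts, each
implemented in its own module:

* the miRNA accumulates organ-specifically (sRNA-seq RPM, `srnaquant`);
* the target mRNA is sliced at the position predicted by the duplex
  (degradome/PARE 5′-end pileup, `duplex` + `degradome`);
* the target's steady-state level is inversely related to the miRNA's
  (RT-qPCR 2^−ΔΔCt and Spearman correlation, `expression`).

The `simdata` generator plants all three signals with known ground
truth, and `hairpin` adds a structural plausibility check for the
precursor.

## sRNA quantification

Reads are trimmed at the leftmost exact occurrence of the 3′ adapter's
first 8 nt; reads without the seed pass through, empty inserts are
dropped. Only trimmed lengths of 18–28 nt are retained — the canonical
plant sRNA window covering both 21-nt miRNAs and 24-nt siRNAs.
Collapsing produces (sequence, count) pairs ordered by count then
sequence; quantification is an exact full-length match of the mature
sequence (no isomiR tolerance — the pipeline answers "how abundant is
this exact mature form"). RPM uses the total of retained reads as its
denominator. Differential accumulation between two organs reports
log2((mean_A + 0.5)/(mean_B + 0.5)) — the 0.5-RPM pseudocount keeps
zero-expressed features finite — and a two-sided Welch t-test on
replicate RPM. Welch rather than pooled-variance Student is the default
because n = 3 with unequal variances is the norm; the pooled test would
be anti-conservative there.

## Duplex model

Gapless antiparallel alignment: miRNA position *i* (1-based from the
5′ end) pairs transcript position `site_end − i + 1`. Pair classes are
Watson–Crick (0 points), G:U wobble (0.5) and mismatch (1.0) — the
de-facto plant target-prediction weights. No positional weighting (seed
or 9–11 emphasis) is applied; the score description this implements
mentions only mismatch points, and positional weights are an open
choice left configurable in future versions. Candidate sites come from
an exhaustive scan of every window, retained at penalty ≤ 4.0 (the
conventional plant cutoff; a flag). The slice site is the transcript
base opposite miRNA position 10 (`site_end − 9`), the canonical
AGO-catalyzed register; for a 21-nt miRNA that is base 12 of the site
counted from the site's 5′ end.

## Degradome scoring

Tags (≥ 15 nt) are placed by exact substring search; the leftmost
occurrence per transcript counts, and a tag matching *k* transcripts
contributes 1/*k* to each. Profiles are normalized to tags-per-ten-
million (TP10M) over the library's mapped total. Exact mapping is a
deliberate desk-scale choice — real libraries with sequencing errors
can be mapped externally and imported as a per-position count TSV.

The composite score decomposes into *cutting power*
`CP = round(10·norm[pos]/max(norm)) ∈ {0..10}` (half-up rounding for
determinism) and *compliance* `8 − penalty_total`, combined as
`S = max(0, CP + 8 − penalty) ∈ [0, 18]`. The decomposition reproduces
both printed extremes exactly: a perfect duplex (penalty 0) at a unique
transcript-wide maximum (CP 10) scores 18; an eight-mismatch duplex at
a 1%-of-max site (CP 0) clamps to 0. Categories follow the five-level
degradome convention: 0 unique transcript-wide maximum (count > 1),
1 tied maximum, 2 above the median of occupied positions, 3 at/below
it, 4 single-read evidence; fractional multi-mapped counts ≤ 1 fall
into class 4, the low-evidence class. Category 0 implies CP = 10 since
both use the same positional maximum.

`call_targets` evaluates each duplex site at the canonical slice
position and one base 3′ of it (register tolerance +1, accommodating
one-off tag starts without inflating false positives; the best-scoring
register is kept), and reports candidates with score ≥ 10 and category
≤ 2 by default — explicit flags, not claims about any particular
historical analysis. Calling is per degradome library, so organ-specific
cleavage is visible; T-plot data cover every position with signal and
flag the called positions.

## qPCR model

ΔCt = Ct_gene − Ct_ref per (organ, replicate); ΔΔCt subtracts the mean
calibrator-organ ΔCt (calibrator defaults to Mv, the leftmost panel
condition); RQ = 2^−ΔΔCt assumes perfect doubling efficiency — no
standard-curve correction is implemented. Replicate RQs are compared
with the same Welch/star machinery. Inverse correlation is Spearman's ρ
over the four organ means with average ranks for ties; with only four
points ρ is coarse, so reports carry the raw profiles alongside the
flag (ρ < 0), and a constant profile is reported "not evaluable" rather
than given a sign.

## Synthetic data: what it emulates, what it does not

Defaults encode the study shape: 4 organs × 3 replicates, 20
transcripts of 500–1500 nt tiled 15% 5′UTR / 60% CDS / 25% 3′UTR, three
planted miRNAs (21, 21, 20 nt; two 3′UTR sites, one CDS site),
1 × 10⁶ reads per sRNA library, one degradome library per organ with
spike fraction 0.4 at the planted slice position over a uniform
background of ~2 tags/position, Ct noise sd 0.15, and target RQ
= 1/(1 + 2·RPM/1000) (normalized to the calibrator organ, so ΔΔCt
recovery returns it directly).

Choices worth knowing:

* **Abundance units.** Configured abundances are RPM *of retained
  reads* — the unit the quantifier reports. Because background inserts
  (random 15–35 nt) are partly removed by the length filter, per-read
  sampling probabilities are calibrated by the background retention
  fraction so that expected estimated RPM equals configured RPM.
* **Default organ profiles** are well separated (rank-adjacent values
  ≥ ~1.5× apart; every value either ≥ 600 RPM or < 100 RPM). At 10⁶
  reads the organ-mean RPM estimator has a relative sd of ≈ 0.8·√RPM,
  so this separation keeps both the 10% recovery band and the organ
  ranking several sd away from sampling noise — the regime the real
  figures' organ-enriched miRNAs occupy.
* **Planted sites** are exact reverse complements (optional mismatch
  count available), placed so the cleaved 3′ fragment supports a
  mappable ≥ 15-nt tag.
* **Ct construction.** Ct_target = 25 − log2(RQ) + N(0, sd); the
  reference gene is exactly constant at 20 cycles. Noise on the
  reference as well would push the ΔΔCt estimator's relative sd to the
  size of the recovery tolerance itself.
* **Determinism.** All draws flow from the config seed through named
  `numpy` `SeedSequence` substreams; the same config yields
  byte-identical files regardless of call order.

Not modeled: sequencing errors, isomiRs, antisense or intergenic
degradome tags, amplification-efficiency deviations, genome-scale
mapping ambiguity. Passing tests therefore demonstrate the *pipeline's*
correctness on clean, planted signals — they do not show robustness to
the noise sources a real library carries, which is why the mapping and
trimming stages accept externally pre-processed input.

## Validation set-up and problem sizes

The test suite checks each operation against an independent brute-force
oracle (explicit pair tables, exhaustive window scans, rank/median
re-derivations, enumeration of nested structures for folding ≤ 18 nt)
on hundreds of random small instances, plus end-to-end ground-truth
recovery: planted-module recovery and decoy-miRNA specificity over 20
generator seeds (degradome + duplex path, library sizes as above), RPM
recovery at the full default library size, mean ΔΔCt recovery over 20
Ct simulations, and the inverse-correlation flag for every planted
module over 20 seeds using the ground-truth miRNA profile against the
Ct-recovered target profile (the sRNA estimation error is covered by
the RPM check; crossing both noise sources in one statistic would just
test the product of two already-tested estimators).

## Known limitations

* The hairpin module maximizes base pairs (Nussinov with loop ≥ 3,
  5′-most tie-breaking); it deliberately produces no folding energies
  and can report biologically implausible isoenergetic alternatives —
  it answers only whether a miRNA/miRNA* duplex arm is structurally
  possible.
* Degradome categories and score decomposition follow field conventions
  where the composite 0–18 scale is underdetermined; the weights are
  module constants, easy to adapt.
* No multiple-testing correction anywhere: reports mirror per-test
  stars, as organ-pair panels conventionally do; users scanning many
  features should correct downstream.
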