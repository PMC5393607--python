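# Methods

## The screen

The pipeline classifies each gene promoter, in each of two conditions, into
one of four chromatin states from two histone-mark presence calls
(H3K4me3 = activating, H3K27me3 = repressive): *bivalent* (both),
*K4-monovalent*, *K27-monovalent*, *unmarked*. It retains genes whose
promoter resolves bivalent → K4-monovalent between the precursor and the
differentiated condition — the canonical fate of poised developmental
promoters that become active — and, of those, the genes with a
transcription-factor peak overlapping the promoter window. Expression
annotation is informational only and never filters.

Promoter = TSS ± flank. "Within 5 kb of the TSS" is read as distance ≤ 5 kb,
i.e. a symmetric ±5,000 bp window (10 kb total); the flank is a single
config key, so a 5-kb-total reading is one flag away. For multi-transcript
genes the canonical TSS is the 5′-most start site on the gene's strand — a
deterministic, annotation-version-robust tie-break. Windows are strand
symmetric. All coordinates are 0-based half-open (BED convention); a read
or peak "overlaps" a window iff they share ≥ 1 bp (no midpoint or fractional
rule), so boundary behaviour is exact and testable.

## Mark-presence model

Reads are modelled as a homogeneous Poisson process: the background
expectation of a window of length L is λ = N·L/G for library size N and
effective genome size G (default 1.87e9, mouse). This is a *global*,
whole-library λ in the MACS tradition: N counts every read in the file,
including reads sitting in enriched regions, which makes λ a slightly
conservative over-estimate of true background (by the library's enrichment
fraction, ~7–12 % per stratum for the packaged scenario). There is no input
track and no local λ — the screen's unit is the fixed promoter window, the
model stays closed-form, and every p-value is reproducible by direct pmf
summation.

Presence requires both practical effect size and significance:
count/λ ≥ `min_fold` (default 2) **and** BH-adjusted Poisson upper-tail
q < `alpha` (default 0.05), corrected within each (mark, condition) stratum
across all promoters, so the FDR refers to promoters — the unit being
selected. One read set per mark × condition; no replicate handling.
Presence is monotone in the count: raising a window's count can never turn
a present call absent. Tail p-values below the double-precision floor
(≈1e-308) underflow to exactly 0, which the BH step and the q < α
comparison handle correctly. A degenerate (empty) library is an error, not
a silent all-absent call.

## Synthetic data

The generator emulates what the screen consumes, not sequencing physics:

- **Genome / annotation.** 5 chromosomes × 4e7 bp; 2,000 genes placed
  round-robin at even spacing ≥ 2×flank, so promoter windows never overlap
  or clip; strands random.
- **Reads.** Background read starts are uniform at rate
  λ_bg/(2·flank + read_length − 1) per bp, which makes the expected number
  of background reads overlapping an interior window exactly
  `lambda_bg_per_window` (default 10, read length 36). Each planted-present
  window receives Poisson((fold−1)·λ_bg) additional reads uniform inside
  the window, bringing its expectation to fold·λ_bg (default fold 8).
  Enrichment is uniform — no peak shape — because the caller integrates
  counts over the window, so shape would add complexity without affecting
  the screen.
- **Planted states.** The `osteoclast` scenario plants exactly 49
  bivalent→K4-monovalent switch genes; 33 of them get a 400 bp TF peak
  centred on the TSS and carry the known candidate symbols; the 16
  remaining switch genes keep synthetic symbols. Distractors: 10 %
  bivalent→bivalent, 20 % K4→K4, 5 % bivalent→unmarked, remainder unmarked
  (all config keys). A `random` scenario draws state pairs i.i.d. from
  configurable proportions.
- **Expression.** Negative-binomial counts (shape r = 50, i.e. dispersion
  0.02, typical of well-expressed genes in bulk RNA-seq), lognormal
  baseline abundances, expected library total 1e6 per condition; switch
  genes carry a planted +3 log2FC. CPM-based fold changes carry the usual
  compositional bias (~−0.2 when 49/2000 genes rise 8-fold), which the
  ±0.5 recovery tolerance absorbs.
- **Determinism.** Every generator draws from named sub-streams of one
  `SeedSequence(seed)`, so identical configs give byte-identical files; the
  seed is echoed in every output header and in `config.yaml`.

What the simulator does *not* model: GC/mappability bias, duplicate reads,
fragment-length effects, input controls, replicate variability, peak shape.
Passing tests therefore demonstrate that the screen's logic and statistics
recover a planted signal at realistic depth — not that the thresholds are
optimal for any particular real ChIP-seq library.

## Numerical and design notes

- The Poisson tail is `scipy.stats.poisson.sf`; BH is
  `statsmodels.multipletests(method="fdr_bh")`. Both are cross-checked in
  the test suite against independent oracles (log-space pmf summation via
  `math.lgamma`; a quadratic textbook step-up).
- Overlap counting uses two sorted arrays per chromosome
  (count = n − #{end ≤ win.start} − #{start ≥ win.end}), verified against
  the naive scan on randomized instances.
- Missing mark-call cells degrade to "absent" with a logged warning rather
  than erroring (sparse peak files are normal); duplicated cells are an
  error.
- Readers reject malformed input with file and line number; writers are
  byte-deterministic; the candidate report is sorted by symbol.

## Calibration and known limitations

With the packaged conditions (λ_bg = 10, fold 8, min_fold 2, α 0.05,
2,000 genes), a background window needs ~2λ̂ ≈ 21–25 reads to be falsely
called present, which happens with probability ≈ 3e-4–7e-4 per window.
Per-cell call accuracy is therefore ≥ 99.9 %. Set-level perfection is
harder: ~550 windows sit one false call away from flipping a gene's switch
status (constitutive-K4 genes gaining a false K27-pre call, switch genes
gaining a false K27-post call, bivalent→unmarked genes gaining a false
K4-post call), giving ≈ 0.16 expected wrong genes per run and a measured
~0.8 probability that a run recovers *both* planted sets exactly; imperfect
runs are off by a single gene. Exact recovery on every reseed would require
either deeper background (λ_bg ≳ 20) or a stricter fold threshold, which
are deliberately left at their documented defaults. The TF-bound candidate
count is much more stable (the 33 planted candidates are recovered in
nearly every run) because false switch genes almost never carry a TF peak.
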