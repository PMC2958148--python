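# Methods

## Corpus model and file dialect

A corpus is three linked tables: libraries, expressed sequences, and
clusters. Each library carries six free-text source fields (`cell_line`,
`cell_type`, `description`, `lab_name`, `tissue_type`, `title`); each
sequence belongs to exactly one library and is either a single-pass EST or
a long cDNA (`mrna`); each cluster groups sequences putatively derived
from one locus, and no sequence may belong to two clusters. Unclustered
sequences are retained and counted rather than dropped — silent loss hides
ingestion bugs.

Historical public dumps of EST databases are not reproducible, so the
package defines its own line-oriented dialect (documented in
`est2tse.corpus`): blank-line-separated `LIBRARY`/`SEQ` records with
`key: value` lines, and a one-cluster-per-line TAB file. The dialect is
deterministic and human-writable; read ∘ write is the identity on every
valid corpus (property-tested).

**Terms.** The tissue vocabulary is built by splitting all six fields of
all libraries on non-alphanumeric runs, case-folding, and dropping pure
numbers. This makes "term" a reproducible notion: a lowercase word a
submitter used anywhere in the library annotation.

## The miner

Keyword matching has two modes because the original engine's semantics
are not published: `term` (exact token membership in the tokenized
fields — the default, stricter and insensitive to embedded words) and
`substring` (raw case-insensitive containment). Exclusivity is evaluated
over EST members only: a long cDNA inside a cluster neither vetoes nor
establishes exclusivity, because cDNA evidence from other tissues is
exactly what the later cross-source screen adjudicates. A cluster needs at
least one EST member to qualify.

The singleton filter defaults to `min_members = 2` (total members, EST +
cDNA). The cross-source screen consumes a precomputed table mapping
cluster IDs to external tissue labels; a cluster is removed if it has any
label outside the allowlist, and retained-with-flag if all its labels are
allowlisted. The allowlist defaults to `{testis, tumor}` — the
cancer/testis-antigen retention rule — and is configuration, not
hard-coded curation, so the behavior is reproducible and auditable.
Alignment itself (BLAST/BLAT) is out of scope; the screen's input is the
alignment summary.

## ORF scanning

Inputs are oriented transcripts, so only the sense strand is scanned (no
six-frame genomic mode). An ORF starts at any occurrence of a codon in
the configured start set and ends at the first in-frame stop, which is
included in its coordinates; nested in-frame starts each open their own
ORF. Start sets: canonical `{ATG}`, or the near-cognate set adding the
seven single-mismatch codons `{CTG, GTG, TTG, ACG, ATT, ATC, ATA}`, the
codons most commonly implicated in alternative initiation in mammals.
The initiating codon is translated as methionine regardless of identity
(initiator-tRNA convention); the remainder uses the standard genetic
code via Biopython. Coordinates are 0-based half-open; `U` is normalized
to `T`; `N` translates to `X` and never counts as a stop.

Open-ended ORFs (start codon with no downstream in-frame stop — relevant
for truncated ESTs) are reported only when `allow_open_end` is set,
truncated to whole codons. The default `min_aa = 20` keeps short products
visible (the interesting candidates here are 45–98 aa) while suppressing
the dense background of tiny ORFs; both knobs are explicit because no
published convention fixes them.

## Expression and clinical statistics

**2^-ΔΔCT.** Replicates are averaged at the Ct level (duplicate wells
estimate one quantity; averaging after exponentiation would bias RQ), then
ΔCt = mean Ct(gene) − mean Ct(control) per sample, ΔΔCt = ΔCt − reference
ΔCt, RQ = 2^−ΔΔCt. Reference modes: `"min"` (lowest normalized Ct, i.e.
highest expressor, giving RQ ≤ 1 everywhere and RQ = 1 at the reference)
or an explicit reference-sample group whose mean ΔCt is subtracted (the
group then has unit geometric mean RQ). Ct values must be positive and
finite; a sample lacking the control gene is a data error, not a silent
drop.

**G-test.** G = 2 Σ O ln(O/E) with expected counts from the margins and
0·ln 0 := 0 (the limit convention; required for tables with empty cells),
df = (r−1)(c−1), upper-tail χ² p-value. Degenerate tables (zero grand,
row, or column total) raise rather than returning NaN. The implementation
is direct; `scipy.stats.chi2_contingency(lambda_="log-likelihood")` is
used in the tests as an independent cross-check, never as the
implementation. On well-filled 2×2 tables the G and Pearson statistics
agree closely (property-tested band of 0.02 on the p-value).

**Kaplan–Meier.** Product-limit estimator per stratum; at tied times,
deaths precede censorings (a record censored at t is still at risk for the
events at t — the standard convention). With no censoring the curve equals
the empirical survivor function exactly.

**Breslow test.** Weighted log-rank machinery with weight w_i = n_i (total
at risk) at each distinct event time:
χ² = (Σ w_i (d_ai − e_ai))² / Σ w_i² v_i, with hypergeometric expectation
e_ai = d_i n_ai / n_i and variance
v_i = d_i (n_ai/n_i)(1 − n_ai/n_i)(n_i − d_i)/(n_i − 1), referred to χ²(1).
Unit weights reproduce the ordinary log-rank test (exposed as
`logrank_test` and verified against lifelines, including the Wilcoxon
weighting). A cohort with no events raises: the test is undefined. When
the variance term is zero the statistic is reported as 0 with p = 1 (no
information). ANOVA-on-log and Mann–Whitney group comparisons are thin
pass-throughs to scipy — standard plumbing, not reimplemented.

## Synthetic fixtures

`generate_corpus` builds a corpus from a `CorpusSpec` and returns it with
a cross-source match table and a truth table recording exactly which
clusters are exclusive / singleton / screened / allowlisted. Construction
guarantees the truth: planted exclusive clusters draw every EST from
keyword-matching libraries; every background cluster contains at least one
EST from a non-matching library; vocabularies are chosen so the keyword
appears in no non-matching library, as token or substring. Defaults
mirror the motivating study's structure at fixture scale: 12
target-tissue libraries, 215 exclusive clusters of which 177 singletons,
9 screened and 6 allowlisted multi-member clusters, 300 background
clusters. Multi-member cluster sizes follow a truncated geometric on
[2, 30] (p = 0.35) — EST cluster sizes are heavy-tailed small counts — and
~15% of multi-member clusters also gain a long-cDNA member.

What the generator does *not* emulate: real nucleotide content (sequences
are IDs and labels only), real annotation free text (vocabularies are
small word lists), library-size skew at database scale, and clusters that
straddle loci. Passing tests therefore demonstrate the algorithms'
correctness on well-formed corpora, not robustness to the noise of a real
submission history (misspelled tissue names, multi-tissue pools),
which would surface in the partition step.

`generate_cohort` draws exponential event times (unit baseline hazard;
second arm scaled by the hazard ratio) with independent exponential
censoring whose rate is solved so the expected censored fraction equals
`censor_rate`. `generate_ct_table` draws per-sample control Ct ~ N(25,
0.5), per-gene ΔCt ~ N(8, 2) and replicate noise SD 0.15 cycles —
a low-abundance target measured in duplicate. All generators take one
explicit seed and use a single `numpy` Generator stream per call.

## Validation strategy and problem sizes

Every pipeline stage is checked against an independent brute-force oracle
written by a different route (direct set comprehensions for the miner,
positional enumeration with an explicit codon dictionary for the ORF
scanner, a naive product loop for Kaplan–Meier), plus planted-truth
recovery over randomized generator specs, at 100 replicates each in the
end-to-end suite and smaller counts in the per-module tests. The Breslow
test's type-I error is estimated from 500 equal-hazard cohorts of 200 per
arm (nominal 0.05 within two Monte-Carlo standard errors) and its power
from three-fold-hazard cohorts at the same size. These sizes give exact
or tight stochastic checks while keeping the whole suite fast enough to
run on every change.

## Known limitations

- Keyword matching is lexical; synonyms and misspellings in library
  annotations are the user's problem (choose keywords from
  `build_tissue_term_list`).
- One library per sequence record is assumed; a sequence submitted under
  several libraries would need pre-deduplication.
- The cross-source screen trusts its input table; no alignment is
  performed.
- No primer-efficiency modeling in the qPCR path (the customary 90–110%
  efficiency acceptance is an upstream data filter) and no Cox
  regression; survival comparison is non-parametric only.
- p-values are asymptotic (χ²); for very sparse tables an exact test may
  be preferable.
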