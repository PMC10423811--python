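# Methods

## Composite signature score

The pathway-activity statistic is the unweighted mean of z-scored log2
expression over a gene set, per sample. Two conventions matter and are
fixed here:

- **z-scoring stratum.** Genes are standardized within each cohort ×
  compartment stratum over *all* its samples, cases and controls
  together. The case-control contrast needs a common reference;
  standardizing within group would erase it. A consequence is that scores
  are relative to the stratum mean: every set's scores sum to zero across
  the stratum (used as an exactness check, |sum| < 1e-10), and a shift
  injected into cases necessarily pushes controls the other way.
- **Standard deviation.** Sample sd (n−1 denominator), so results are
  bit-reproducible against the common convention. Rows whose sd is at
  floating-point rounding level (sd ≤ 1e-12·max|x|) are treated as
  constant and excluded — cancellation would otherwise turn rounding
  noise into O(1) z-scores.

Genes absent from a matrix reduce a set's *coverage* (fraction of members
present) instead of contributing zeros, which would shrink scores toward
null. Below 50% coverage (configurable) the score is flagged unusable
rather than silently reported. The score is exactly invariant to per-gene
affine rescaling of the input, which makes it robust to gene-wise
location/scale normalization differences but *not* to monotone nonlinear
transforms — hence the log-scale heuristic in ingest (maximum above 50 →
log2(x+1), refusing matrices that mix negative values with a linear-scale
maximum).

## Group comparisons

Per-group Shapiro–Wilk at α = 0.05 selects the test family: Student's
t (equal variances, mean ± sd summaries) when both groups pass, otherwise
two-sided Mann–Whitney U (median (range) summaries). The normality test
and its threshold are the most common convention; they are a package
choice, not an external prescription. Mann–Whitney p-values use the exact
null distribution when n₁+n₂ ≤ 12 without ties, a complete-enumeration
permutation when small with ties (so identical groups give p = 1
exactly), and the tie-corrected continuity-corrected normal approximation
otherwise; exact and asymptotic paths agree within 0.02 at 6 + 6. The
procedure's realized type-I error at a 14-vs-7 design is ≈ 0.047 (the
Shapiro gate routes ~10% of Gaussian null draws to the slightly
anticonservative small-sample U test).

Panels of comparisons (each grouping rule — LN vs LD, eGFR ≥ 90 vs < 90
within LN, treated vs untreated, class III/IV vs other classes — across
all sets and strata) report raw p alongside BH-adjusted p within the
panel, so either multiplicity convention can be read off. Sides with
n < 3 are skipped with a warning, never silently dropped.

## Moderated-t differential expression

Per gene, the two-group contrast gives log2FC = mean(case) − mean(control)
and the pooled variance s²_g on d_g = n₁+n₂−2 df. Variances are shrunk
toward a prior via the standard empirical-Bayes hierarchy
(s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g); t̃ on d₀+d_g df). The
hyperparameters are estimated by the method of moments on log s²_g using
digamma/trigamma identities, with the trigamma equation inverted by
Newton iteration; when it has no positive solution, d₀ = ∞ and every
posterior variance equals s₀². The implementation is verified against
Bioconductor limma to < 1e-8 on t, p, d₀ and s₀², and reduces exactly to
the ordinary pooled t at d₀ = 0. Zero-variance genes are retained — the
shrinkage regularizes them — and flagged. The design is a plain two-group
contrast (no covariates, no pairing); multi-factor models are out of
scope.

BH adjustment is the step-up rule q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j implemented
directly (and cross-checked against statsmodels). The DE screen is
log2FC beyond ±1 with adjusted p < 0.05; both thresholds are exposed
(`--lfc`, `--alpha`). DEG lists are ordered by adjusted p, then |log2FC|,
then gene name, so outputs are deterministic under ties.

## Candidate intersection

"Metabolism-related genes" is defined as the union of the eight metabolic
sets — the universe is not pinned down externally, so each candidate
carries the list of metabolic sets containing it, making alternative
universes auditable. A candidate must be screened in the *same direction
in every cohort*; genes up in one cohort and down in another are excluded
and logged. Venn-region counts are emitted for audit. The result is
invariant to cohort order.

## Gene-set registry

Fifteen lists in two categories (7 PCD, 8 metabolic) are built from
source sets by three rules: `extract` (copy one source), `intersect`
(set intersection, order-independent), `literature` (curated list passed
through). Symbols are uppercased and whitespace-stripped on ingest with
no alias mapping — determinism over recall. Expected sizes are checked
but mismatches *warn* rather than fail, because list sizes are tied to
unspecified upstream database versions. Genes are stored in alphabetical
canonical order so GMT round-trips are byte-identical.

The bundled `data/synthetic_sources.gmt` is a synthetic fixture: the
literature-derived lists live in supplementary materials not shipped
here, so sources are constructed (anchored on well-known real symbols
where membership is common knowledge — e.g. GPX4/ACSL4 for ferroptosis,
the ten-gene cuproptosis panel, CD163 in iron handling, PC in the TCA
cycle, ATP6V0A4 in oxidative phosphorylation) and padded with generated
symbols so that every recipe reproduces its published count exactly.
Real MSigDB GMTs are a drop-in replacement via `--gmt/--recipes`.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes —
two cohorts × two microdissected compartments, LN vs LD:

| knob | default | why |
|---|---|---|
| genes | 4000 (registry genes embedded + generated background) | enough multiplicity for FDR behaviour, fast |
| samples | 10 LN + 10 LD per cohort × compartment | typical microdissected-cohort scale |
| baseline | mean ~ U(4,12), sd ~ U(0.3,1.0) log2 units | range of normalized microarray intensities |
| pathway shifts | ferroptosis +1.0, iron +0.8, oxphos +0.6, glomerular LN only | the compartment-specific disease signal under study |
| DE effects | 30 up + 30 down background genes, &#124;log2FC&#124; ~ U(1.2,3) | realistic DEG load so BH ranks behave as in real cohorts |
| covariates | Spearman targets: eGFR −0.6; SCr/BUN +0.6; SLEDAI +0.5; C4 +0.4; C3 +0.2; HNE +0.7 | clinical directions of a severity axis; moderate strengths |
| LN classes | II/III/IV/V at 26/26/42/6% | class mix of a typical LN biopsy series |

Covariates are generated from the *realized* ferroptosis composite (the
latent severity axis), not from raw genes: the Pearson weight
r = 2·sin(πρ/6) on the rank-normalized latent hits the target Spearman ρ
in expectation, and unit mappings are monotone so ranks are preserved
(eGFR truncated at 0). Pathway shifts are uniform per gene by default; a
heterogeneous option (U(0.5δ, 1.5δ)) exists for robustness checks.

What the generator does **not** emulate: probe-level structure, batch and
platform effects, count noise, correlated gene-gene backgrounds, or
missing clinical data. Passing recovery tests therefore demonstrates
correctness of the statistical machinery under its stated model, not
robustness to real-data artefacts.

## Problem sizes in the test and acceptance runs

Monte Carlo budgets are chosen to finish in minutes on one CPU while
keeping binomial noise well inside the asserted bands: type-I error at
2000 replicates (se ≈ 0.005), signature power at 200 (the null arm at
1000, since a 200-rep estimate's noise would swamp the ±0.015 band), DE
recovery aggregated over 10 cohorts of 3000 genes, intersection shape
over 100 two-cohort replicates of 600 genes. All seeds are fixed (tests)
or derived from `--seed` (acceptance script).

## Known limitations

- Whole-kidney/glomerular/tubulointerstitial are the only recognized
  compartments; other stratifications need a registry-level extension.
- The eGFR 90 mL/min/1.73 m² split, class III/IV grouping and LN-vs-LD
  contrast are built-in grouping rules; arbitrary groupings require code.
- Probe collapsing keeps the max-mean probe (or mean); no sequence-level
  re-annotation.
- The moderated t assumes a common two-group design across all genes;
  surrogate-variable or weight-based extensions are out of scope.
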