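# Methods

## The assay and its data

The cytokinesis-block micronucleus (CBMN) test scores chromosome damage
in cells that have completed exactly one nuclear division: cytochalasin B
blocks cytokinesis, so once-divided cells appear binucleated (BNCs), and
a micronucleus (MN) in a BNC marks a chromosome fragment or whole
chromosome left out of a daughter nucleus. In organotypic airway
epithelium only a few percent of cells divide even under EGF stimulation,
so binucleation is rare (~4–10%), the MN denominator is scarce, and
cytotoxic doses deplete it further. The data unit is one tissue insert
(one slide): a nucleation-class tally over ~500 cells and an MN tally
over up to 667 BNCs, with triplicate inserts per dose group and a
solvent-control group per chemical.

Scoring rules enforced by the data model: cells are classed by nucleus
count (1 / 2 / ≥3) for the proliferation indices; MN eligibility is
restricted to binucleated cells that are neither mitotic nor apoptotic
(mitotic, apoptotic, and ≥4-nucleus cells are excluded from MN analysis,
but binucleated mitotic/apoptotic cells still count in the BNC class for
the indices, since the exclusion applies to MN scoring only); a candidate
MN body is accepted when its maximum diameter is ≤ half that of the main
nucleus, boundary included. A BNC with several micronuclei counts once in
the micronucleated-BNC tally; per-cell multiplicity is retained on the
annotation but enters no reported statistic. The 500-cell and 667-BNC
scoring targets are advisory configuration, not validation: real slides
fall short at cytotoxic doses, and the analysis must accept that.

## Indices

With per-group counts (pooled over inserts, i.e. inserts weighted by
cells scored): %BNC = 100·n_bi/N; CBPI = (n_mono + 2·n_bi + 3·n_multi)/N,
algebraically 1 + %BNC/100 + 2·(n_multi/N), hence bounded by [1, 3];
RI = 100·[(n_bi + 2·n_multi)/N]_T / [(n_bi + 2·n_multi)/N]_C. Relative
CBPI is the plain ratio 100·CBPI_T/CBPI_C — not the cytostasis transform
100 − 100·(CBPI_T−1)/(CBPI_C−1) — because only the plain ratio reproduces
the narrow 93–100% range the validation table reports; in low-proliferation
tissue the mononucleated majority pins CBPI near 1 and the ratio is
insensitive, which is exactly why %BNC and RI are the informative
cytotoxicity measures here. %BNC is exposed both absolute and
control-relative under distinct names (the published equation is the
ratio form, the published results quote absolute percentages).

%MN = 100·n_bnc_mn/n_bnc_scored is computed on counts pooled across
replicate inserts, not as a mean of per-insert frequencies. Internal
computation is unrounded; report formatting rounds half-up (2 decimals
for %MN, 1 for the others) to match the conventional table layout.

## The decision rule

A chemical is called genotoxic iff both, at the same α (default 0.05):

1. **Cochran–Armitage trend** over control + dose groups on the pooled
   micronucleated-BNC proportions: Z = Σ sᵢ(xᵢ − nᵢp̄) / √(p̄(1−p̄)[Σ nᵢsᵢ²
   − (Σ nᵢsᵢ)²/N]), asymptotic normal tail, no continuity correction.
   Scores default to the actual concentrations with control = 0 (rank and
   log-concentration scoring are available); the alternative defaults to
   one-sided increasing. With no outcome variation (p̄ = 0 or 1) the
   trend is degenerate and reported as z = 0, p = 1, flagged. A
   multivariate-hypergeometric permutation mode
   (`cochran_armitage_permutation`) is provided for sparse counts.
2. **Fisher's exact test**, each dose vs the concurrent control on the
   2×2 table (micronucleated vs not) × (treated vs control). Any
   significant dose satisfies this arm; no specific dose is required.

Fisher tails are computed natively by an exact integer recurrence over
the hypergeometric support — one-sided sums tables with at least the
observed treated MN count; two-sided sums all tables whose (integer)
point weight does not exceed the observed one's — so tail sums carry no
floating-point error and a table costs microseconds.

**Sidedness.** The package default for the pairwise test is two-sided.
The published starred-dose sets for all three reference chemicals are
reproduced exactly by two-sided testing (the convention of the JMP
software used for the original analysis), whereas a one-sided test would
additionally flag colchicine at 0.64 µg/mL (p = 0.033 one-sided, 0.065
two-sided). One-sided testing remains available (`--sided greater`), and
every published starred dose is significant under either choice. The
trend test stays one-sided increasing, the direction the assay asks
about; its verdicts are insensitive to this choice on the reference data
by dozens of orders of magnitude.

No multiplicity correction is applied across doses — per-dose tests at
raw α mirror the assay's published evaluation and are deliberate.
Pooling across inserts assumes a common within-group MN rate; each group
is therefore screened with a chi-square heterogeneity test on its
insert-level tables, and the call carries a warning when any group shows
p < 0.05, since pooled tests are anti-conservative under between-insert
overdispersion (quantified below). All assumption flags (sidedness,
score mode, any-dose rule, heterogeneity) are recorded on the
`GenotoxCall` and logged by the pipeline, so every verdict is auditable.

## Secondary endpoints

TEER: the voltohmmeter reading (Ω) times the insert membrane area
(default 0.6 cm²) gives Ω·cm²; group comparisons use Welch's t-test
(unequal variances, Satterthwaite df, two-sided). AK release:
ΔRLU = L_P − L_A per insert pair (treated-condition minus untreated
luminescence); negative deltas are kept with a warning rather than
clipped, so replicate averages stay unbiased. Differences are paired per
insert, not taken between per-condition means.

## Synthetic-data generator

One insert at dose d is drawn as:

- class counts ~ Multinomial(500; p_mono(d), p_bi(d), p_multi) with
  p_bi(d) = p_bi(0) / (1 + (d/EC50)^h) (log-logistic suppression) and the
  lost mass reallocated to mononucleated cells;
- BNCs scored = min(667, ⌊20000 · n_bi/500⌋): the classification-sample
  BNC fraction scaled to a slide-level pool of 20,000 cells (a free
  parameter; no slide-level census is published) and capped at the
  scoring target — this reproduces the BNC shortfalls real slides show
  at cytotoxic doses;
- MN count ~ BetaBinomial(n_scored, μ(d), ρ) with logit μ(d) =
  logit(μ₀) + β·d; ρ is the intra-insert correlation and ρ = 0 recovers
  the binomial exactly.

Defaults are the validated mitomycin-C condition: triplicate inserts,
p_bi(0) = 0.085, p_multi = 0.002, EC50 = 9 µg/mL, h = 2.3 (fit by hand to
the published relative-%BNC profile), μ₀ = 0.0028 (the 0.28% control
background), β = 0.43 per µg/mL (anchored to the 16.55% peak at
10 µg/mL), doses 1.25–20 µg/mL, ρ = 0. Seeding is counter-based: every
insert's stream derives from (master seed, group index, insert index), so
changing the insert count never shifts other inserts' draws, and
replicates in `operating_characteristics` derive per-replicate seeds the
same way.

What the generator emulates — and does not. It captures the count
structure, the scarcity of the MN denominator, dose-dependent
binucleation loss, and between-insert heterogeneity. It does not model
the high-dose %MN downturn (the logit-linear rate is monotone; the real
downturn reflects selection against heavily damaged cells), scorer
effects, within-slide spatial clustering, or TEER/AK dynamics beyond
optional constant-plus-noise columns. Passing calibration tests
therefore shows the decision rule behaves correctly under the assumed
sampling model, not that real slides satisfy that model.

## Operating characteristics

Computed by `operating_characteristics` (problem sizes chosen to keep
the standard runs light: 2,000 replicates for null calibration in the
acceptance checks, 300–500 elsewhere; Monte-Carlo SEs are reported):

- Under the null (flat dose–response, ρ = 0) the conjunction of two
  α = 0.05 tests rejects at ~0.01–0.02 — conservative, as the
  intersection of two correlated rejection events must be.
- At the validated mitomycin-C-scale effect the rule's power is ≈ 1.
- Under the null with overdispersion the pooled rule is badly
  anti-conservative: null rejection rises from ~0.013 (ρ = 0) to ~0.22
  at ρ = 0.02 and ~0.19 at ρ = 0.1 (1,500 replicates). The inflation is
  large but **saturates rather than growing monotonically in ρ**: at a
  rare-event baseline (μ₀ = 0.0028) a large ρ pushes insert-level rates
  toward all-or-nothing, and replicates increasingly lack the events a
  trend needs. This measured behaviour is why the pipeline emits the
  heterogeneity warning, and the test suite asserts the inflation (both
  ρ > 0 rates well above the binomial rate) rather than strict
  monotonicity.

## Numerical and degenerate-case choices

Half-up rounding (via `decimal`) for report values only. Welch's t with
two equal constant samples returns p = 1; unequal constant samples
return ±∞ with p = 0. Fisher requires both margins non-empty; the trend
test requires positive denominators everywhere. Relative indices raise
typed errors when the control baseline is zero rather than returning
infinities. The scoring-table reader reports 1-based line numbers on
every schema violation and requires a concentration-0 control per
chemical.

## Known limitations

- The bundled reference dataset's nucleation-class counts are
  reconstructed from published percentages (1,500 cells, no
  multinucleated cells) because raw per-insert class tallies were not
  published; recomputed relative indices are therefore approximate
  (published relatives came from unrounded replicate means), while MN
  counts, %MN, tests and verdicts are exact.
- The asymptotic trend p is anti-conservative for very sparse tables;
  the permutation mode exists for that case but is not the default.
- The conjunction rule's conservatism under the binomial null and its
  fragility under overdispersion are properties of the pooled design;
  insert-level mixed modelling is out of scope.
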