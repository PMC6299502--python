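# Methods

## Scope and data model

`cessmiss` performs single imputation on *aggregated* per-arm counts — no
individual-level variation enters the imputed quantities, so the method
quantifies how conclusions move under different missingness assumptions
rather than propagating imputation uncertainty (a multiple-imputation
extension is out of scope). All imputation is stratified by treatment
arm: each arm is imputed from its own observed cells only, and arms are
pooled into intervention contrasts afterwards. This is a deliberate
choice over treatment-adjusted imputation models; with strongly
differential missingness across arms the two strategies can differ.

An arm is eight numbers: the randomized total n, the survey triplet
(n¹¹ self-report abstinent, n¹² self-report failure, n²· survey missing)
and, among self-reported abstainers, the urine triplet (f¹¹⁽ᵒᵇˢ⁾
verified abstinent, f¹²⁽ᵒᵇˢ⁾ verified failure, v⁽ᵒᵇˢ⁾ urine missing).
Two accounting identities must close: the survey triplet sums to n and
the urine triplet sums to n¹¹. Urine cells may be fractional — provided
but untestable samples are redistributed in proportion to the tested
ones before any analysis (`redistribute_untested`), and every imputed
quantity downstream is kept as a real number; rounding is purely a
display concern. Identities on fractional cells are enforced to an
absolute tolerance of 1e-9.

The packaged Enhanced Quit & Win fixture stores the published per-arm
urine counts verbatim (38/6/21, 34/6/19, 35/6/20, 50/7/22) rather than
re-deriving the five-sample redistribution per arm, because the per-arm
assignment of those five samples is not recoverable from the published
summary; only the overall 86%/14% split is.

## Sensitivity parameters

| parameter | meaning | default | range |
|---|---|---|---|
| OR₁ | odds ratio between survey missingness and tobacco use | grid 1–5, +∞ | > 0, +∞ allowed |
| OR₂ | odds ratio between urine missingness and verified failure, among self-reported abstainers | grid 1–5, +∞ | > 0, +∞ allowed |
| λ | factor scaling the provided:missing urine odds of survey non-respondents relative to respondents | 1 | finite > 0 |
| η | factor scaling the verified-abstinent:failure odds of would-be urine samples relative to observed ones | 1 | finite > 0 |

All four are *assumed known* per scenario; the grid sweeps OR₁ (outer)
× OR₂ (inner) while λ and η are scalars per run (the CLI accepts lists
to grid them as well). OR = 1 at both stages reproduces the
complete-case rates exactly; OR = +∞ at both stages is the conservative
convention that counts every subject without a verified-abstinent result
as a failure. Values between 1 and 5 span what one would defend in an
incentivized-quit setting, where non-response plausibly signals failure;
values below 1 are admitted by the algebra and by the implementation
(they would describe settings where failures are *more* likely to
respond) but are not part of the default grid.

On λ: its defining relation scales the odds u/v of providing a urine
sample, which is how it is implemented. Describing it loosely as scaling
the "missing rate" is only odds-approximately true; the odds form is
taken as authoritative. η likewise scales the verified-abstinence odds.

## Numerical and degenerate-input choices

All four allocation steps share one primitive: split a pool T into two
cells with ratio `factor × (a/b)` for observed cells (a, b). Degenerate
cells resolve with a fixed precedence, chosen to keep the allocation
continuous in `factor` for fixed observed data:

1. a = b = 0 with T > 0 is an error — nothing observed anchors the split.
2. a = 0 sends the whole pool to the b-side cell **even when factor is
   +∞** (the observed zero odds win the 0·∞ indeterminacy). Concretely,
   an arm with no observed self-report failures imputes all its survey
   non-respondents as abstinent under every OR₁, including the
   missing = smoking limit.
3. b = 0, or factor = +∞, sends the whole pool to the a-side cell.

Infinity is a first-class parameter value with its own branch, not a
large float; `"inf"` (case-insensitive) is its textual form in configs,
CLI flags and CSV output. The finite path at OR = 1e9 agrees with the
infinity branch to within 1e-6 of a subject on the fixture.

Effects on pooled 2×2 tables use the uncorrected Pearson chi-square
statistic N(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)], valid as a formula for the
fractional counts imputation produces, with the p-value from the upper
tail of χ²(1). No continuity correction and no exact test are applied:
the uncorrected statistic reproduces both published complete-case
p-values (.058 and .291) and all published grid p-values, and sample
sizes here make small-sample corrections immaterial. A zero row or
column margin leaves the statistic undefined and raises. Display
formatting follows the published style — rates to one decimal percent,
odds ratios to two decimals, p-values to three decimals without the
leading zero.

## The synthetic-data generator

`synthdata` simulates individual-level trials and aggregates them to the
count schema, giving parameter-recovery tests a known latent truth. Per
subject it draws: true abstinence (per-arm probability, default 0.25 at
fixture scale); the self-report an abstainer would give (honest with
probability `self_report_honesty`, default 1; users always report use);
survey missingness, where users miss at `survey_miss_base` (default 0.2)
and abstainers at odds reduced by the factor `true_or1`; a latent
"confirmable" status (would a urine test verify the claim; default
probability 0.85); and urine missingness, where confirmable reporters
miss at `urine_miss_base` (default 0.3) and unconfirmable ones at odds
inflated by `true_or2`. Probabilities are moved on the odds scale,
p′ = r·p/(1−p+r·p). One seed drives the run; per-arm substreams derive
deterministically from (seed, arm index), so identical scenarios give
identical trials.

What the generator emulates: MNAR missingness at both stages whose
2×2-table odds ratios converge to `true_or1`/`true_or2` in large
samples, at the scale and missingness levels of a real four-arm
quit-contest trial. What it does not emulate: covariate-driven
missingness, dropout over repeated time points, misreporting in the
abstinent direction (users never claim abstinence), or assay error.
Consequently, passing recovery tests show that imputation at the true
odds ratios removes the bias this mechanism induces — they do not show
robustness to mechanisms outside this family. Note also that the
analysis odds ratios refer to self-report/verified *failure* while the
generator's act on latent truth; the two coincide under honest
reporting, which is why recovery tests fix `self_report_honesty = 1`.

The recovery experiment simulates independent replicates (replicate r
reuses the scenario with seed + r), imputes each at fixed analysis
parameters, and reports mean bias, its Monte-Carlo standard error, and
RMSE of the pooled rates against each replicate's latent truth. The test
suite uses 200 replicates of the fixture-scale scenario with
true OR₁ = OR₂ = 3: matched analysis must leave |mean bias| under three
Monte-Carlo standard errors in every pool, and the missing = smoking
analysis of the same replicates must underestimate every pooled verified
rate. These sizes keep the whole suite in the seconds range while the
standard error on a pooled rate bias is ≈ 0.0007, tight enough to detect
the ≈ 0.07 downward bias of the extreme assumption two orders of
magnitude above the noise.

## Known limitations

- Single imputation: imputed counts are treated as known when computing
  chi-square tests, so p-values understate the extra uncertainty of the
  imputation itself; interpret the grids as sensitivity displays, not as
  a combined inference.
- No confidence intervals for the odds ratios are produced.
- Aggregated input only; covariates cannot inform the imputation.
- λ and η are fixed known factors per scenario; no uncertainty in them
  is propagated.
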