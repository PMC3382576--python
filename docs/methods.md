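# Methods

This note documents the models and procedures implemented in `fossilcomp`,
the assumptions behind them, the parameters that matter, and the choices made
where the design was genuinely open.

## Character completeness (CCM2)

A phylogenetic character list of length `T` is partitioned over skeletal
element/part keys: each key `k` carries `c_k` characters that can be scored
only when that element (or part) is preserved, with `Σ c_k = T`.  Keys are
side-agnostic (a left and right femur are the same key); characters on
elongate limb/girdle bones may be split into proximal-end / distal-end /
shaft sets, and vertebral-column characters into single / anterior /
posterior / series / neural-spine sets per column section.

For a species with specimens whose element inventories union to `U`, the
character completeness is

    CCM2 = 100 × Σ_{k ∈ U} c_k / T .

Properties: CCM2 ∈ [0, 100]; it is non-decreasing under the addition of
specimens or elements; duplicate elements contribute once.  CCM1 (the score
of the single most complete specimen) is available for diagnostics only.

**Rounding conventions.** Canonical scoring uses exact character counts and
rounds only for display (half-up, two decimals).  A *rounded-sum*
compatibility mode instead sums the per-element percentages after rounding
each to two decimals; with a 7-of-655 maxilla (1.07%) and a 17-of-655 femur
(2.60%) this gives 3.67% where count-exact arithmetic gives 24/655 = 3.66%.
The rounded-sum mode exists to reproduce worked examples published under
that convention; count-exact is the default because it is exact and
order-independent.

**Inventory semantics.** Vertebral part keys (`series`, `anterior`, ...) are
explicit inventory entries: no inference is made from bone lists to vertebral
sets, because no principled inference rule exists without specimen-level
anatomy.  The upstream data compiler decides what is present.

## Time binning

Geological stages (shipped: Gradstein et al. 2004 values for the
Tithonian–Maastrichtian, 150.8–65.5 Ma; any contiguous stage table can be
substituted) are each split at their temporal midpoint into an early and a
late substage, giving 26 bins for the default table.  Occurrences dated only
to a stage, or spanning several substages, are ranged through every bin
their possible age intersects.  A point age on a bin boundary belongs to the
younger bin (half-open intervals in Ma before present, oldest bin closed);
this tie-break is arbitrary but deterministic.

Per-bin summaries report the mean CCM2 over the *species* present in the
bin (each species once, using only that bin's specimens), the ddof=1 sample
SD of those species scores, and the number of *specimens* as the sample-size
indicator, following the convention of pairing completeness curves with
specimen counts.  Species present through multiple specimens are not
weighted extra.

## Residual ("sampling-corrected") diversity

Observed taxic diversity per bin is confounded with sampling intensity.  The
residual method models the sampling–diversity relationship by (i)
log10(x+1)-transforming both the taxic counts and a per-bin sampling proxy
(the +1 keeps zero counts usable; base 10 is conventional and irrelevant to
the rank statistics downstream), (ii) sorting each transformed series
ascending *independently*, (iii) fitting OLS of sorted diversity on sorted
proxy, and (iv) applying that line to the proxy in original bin order.
Residual = observed − predicted (log units); positive residuals are
diversity that sampling cannot explain.  Confidence bands sit at
±`k_sd` × `model_sd`, where `model_sd` is the ddof=1 sample SD of the sorted
fit's residuals and `k_sd` defaults to 1.0 (a one-model-SD band;
configurable since published practice varies).

Bins missing either series are removed pairwise before the fit; at least
three complete pairs are required, and a zero-variance proxy is rejected as
degenerate.

## Statistical battery

* **Generalized differencing** removes trend and first-order autocorrelation
  before correlating time series: OLS-detrend the series against bin
  midpoints to get residuals `r_t`; estimate `ρ` as the lag-1 Pearson
  autocorrelation of the *detrended* residuals; output
  `d_t = r_t − ρ·r_{t−1}` for `t ≥ 2`, keeping `d_1 = r_1` so the output
  stays aligned with the input.  A series exactly linear in time degenerates
  to a zero vector (returned with a warning).
* **Spearman's rho** (midranks, two-tailed t-approximation p) and
  **Kendall's tau-b** (tie-corrected, two-tailed normal-approximation p) via
  scipy.  Pipeline correlations difference *both* variables first and use
  pairwise-complete bins only.  p-values are reported uncorrected; tests are
  two-tailed.
* **Mann-Whitney U** on midranks with `U = min(U_a, U_b)`.  For
  `n1 + n2 ≤ 20` the two-tailed p is exact, by full enumeration of all
  `C(n, n1)` group assignments of the combined midranks
  (`p = P(min(U, n1·n2 − U) ≤ observed)`), which remains valid under ties;
  larger samples use the tie-corrected normal approximation with continuity
  correction.

## Geographic summaries

Species are summarised in 5° half-open modern-latitude bins
`[lower, lower+5)`, south negative; boundary latitudes go to the higher bin
and +90° folds into the northernmost bin.  A species with localities in
several bins, landmasses or environments contributes its pooled species
score to each occupied group, so group score lists may overlap; group means
therefore describe "species known from that group", not a partition.
Paleolatitude rotation is deliberately not performed (modern coordinates are
the intended frame).

## Synthetic assemblage generator

The generator emulates the data-generating process the analysis assumes,
with a ledger of the underlying truth:

* **Richness.** True per-bin species counts are Poisson with configurable
  means; the default profile rises from ~3 to ~8 species per bin with two
  radiation peaks, echoing a record of a few species per substage.
* **Completeness.** Each species draws a completeness fraction `f` from a
  per-environment Beta distribution.  Default means are 0.465
  (fluviolacustrine), 0.25 (marine) and 0.31 (other terrestrial) — the
  empirically reported ordering for low-energy versus erosion-prone
  settings — at a common concentration of 6.  A Lagerstätte bin with boost
  `b` maps `f → f + b(1 − f)`, so `b` is the guaranteed completeness floor.
* **Inventories.** The species inventory includes each table key
  independently with probability `f`, which makes the expected *character*
  fraction exactly `f` (completeness is character-weighted, so no extra
  element weighting is needed).  Each specimen retains each species-inventory
  key with probability 0.8 (never coming out empty while the species has
  elements), so the specimen union converges on the species inventory and
  per-bin mean CCM2 converges on the configured Beta means as specimens
  accumulate.
* **Sampling.** Each bin draws a lognormal collecting effort
  (`σ = 0.8` by default); species are detected with probability
  `1 − exp(−rate·effort)`.  The proxy is
  `scale · effort^w · (observed+1)^e` with multiplicative lognormal noise,
  rounded to counts.  With `w = 0, e = 1` and no noise the proxy is
  proportional to observed richness and residual diversity vanishes; with
  `w = 1, e = 0` the proxy is a pure effort gauge, the regime in which
  residual diversity should beat raw counts at tracking true richness.
* **Ages and geography.** Specimens get their bin's substage label; with
  probability 0.2 the age widens to the full stage (range-through then
  spreads them over both substages).  Latitudes come from a two-component
  normal mixture (70% at 45°N ± 8°, 30% at 28°S ± 12°) and landmasses from
  a categorical mix dominated by Asia, mirroring the strong Northern
  Hemisphere skew of the record being emulated.

All randomness flows from a single seed through independent numpy
substreams; repeat calls are byte-identical.

**What the generator does not model:** phylogenetic structure (no trees or
clade-level extinction), taphonomic physics, locality-level spatial
autocorrelation, or taxonomic error (synonymy, splitting).  Passing recovery
tests therefore show that the pipeline recovers signals *of the assumed
form*; they cannot certify behaviour under misidentification or
phylogenetically correlated preservation.

## Validation experiments

Three Monte-Carlo experiments (200 replicate seeds each, seeds recorded in
the tests) exercise the pipeline end to end:

1. **Lagerstätte recovery.** One bin receives a strong boost (`b = 0.9`);
   the test asserts that bin attains the maximum mean CCM2 in ≥95% of
   replicates.  This experiment uses precisely dated specimens
   (age-uncertainty probability 0): with stage-level age uncertainty,
   range-through assignment smears unboosted sibling-substage species into
   the boosted bin and dilutes its mean — a property of the binning
   protocol, not of the completeness signal, so the recovery experiment is
   run controlled.
2. **Environment ordering.** Under generator defaults, the fluviolacustrine
   group mean exceeds both other environments in ≥95% of replicates, the
   secondary (other-terrestrial > marine) ordering in a majority, and
   Mann-Whitney detects the dominant contrast at α = 0.05 in >80%.
3. **Residual diversity.** In the effort-driven sampling regime
   (`effort σ = 1.0`, detection rate 0.7, proxy measuring effort only),
   residuals rank-correlate with true richness more strongly than raw taxic
   counts in most (>50%) replicates.

Problem sizes (26 bins, ~5 species per bin, 200 replicates) were chosen as
the smallest at which these effects are statistically resolvable.

## Known limitations

* The per-bin mean CCM2 is sensitive to tiny samples (a single
  well-preserved species dominates its bin); specimen counts are reported
  alongside precisely so such bins can be discounted.
* Exact reproduction of published correlation p-values is not promised:
  tail conventions and the precise generalized-differencing variant differ
  between implementations; sign and approximate magnitude are the
  meaningful comparison.
* The Mann-Whitney exact enumeration is O(C(n, n1)) and is capped at
  n1 + n2 = 20; beyond that the normal approximation (which agrees within
  0.02 at the cap) takes over.
* When a comparison clade is supplied only as a per-bin mean series, clade
  comparisons necessarily run on the two mean series rather than on
  species-level scores, which weakens them relative to comparisons on full
  score lists.
* The "fluviolacustrine locality counts" series is approximated by per-bin
  fluviolacustrine *specimen* counts, since the occurrence schema carries no
  locality identifiers.
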