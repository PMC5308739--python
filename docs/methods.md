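# Methods

## The analysis chain

The package reproduces, as a tested pipeline, a classic systematic
workflow for drug-response miRNA regulation: microarray screen → validated
target lookup → network statistics → pathway enrichment → single-pathway
interpretation. The stages and their exact rules:

**Replicate averaging.** Probes sharing a miRNA identifier are collapsed
to their per-sample arithmetic mean before anything else. Averaging
precedes normalization so that floor eligibility is defined per miRNA, not
per probe; the pipeline's stages are importable separately, so the
opposite order can be run for sensitivity checks.

**Median normalization.** A probe is *eligible* if its intensity is
≥ 30 fluorescence units in **all** samples. Each sample is divided by the
median intensity of the eligible set in that sample and multiplied by a
common reference scale, taken as the mean of the per-sample medians. The
reference choice is inert downstream: fold changes are within-miRNA ratios
across samples, which any positive common scale leaves untouched.

**Differential screen.** Per cell line, f = treated/control on normalized
intensities (no log transform, no moderated statistic — a pure ratio
filter). Direction is *up* if f ≥ τ and *down* if f ≤ 1/τ, both inclusive,
with τ = 1.5. A miRNA is differential iff both cell lines agree on a
non-null direction. Records with zero control intensity are flagged
`undefined`, excluded and logged rather than pseudo-counted; no
pseudo-count rule is part of the protocol, and exclusion is conservative.

**Interaction unification.** miRNA names are trimmed, internal whitespace
removed, lower-cased, and the mature-miRNA prefix restored to `miR`
(species prefixes like `hsa-` survive); gene symbols are trimmed and
upper-cased. Matching is exact after canonicalization — accession
variants (miR-34a vs miR-34a-5p) are deliberately distinct, since fuzzy
matching would invent interactions. The identity key is the canonical
(miRNA, gene) pair; contributing source labels are kept as a sorted
annotation, so the result is independent of record order and of how
records were split across files.

**Network restriction and degree fit.** Edges are kept only for miRNAs in
the differential set; isolated nodes never appear. The degree frequency
table P(k) (per node side or pooled; pooled is the default, with
`side="mirna"/"gene"` and a complementary-cumulative option exposed) is
fitted by OLS on log₁₀–log₁₀ axes over nonzero-frequency degrees, raw
(unbinned) by default with geometric binning as an option. R² = 1 −
SS_res/SS_tot is the scale-free-ness statistic. A flat response has zero
SS_tot; it is reported as slope 0, R² = 1 with a `degenerate` flag rather
than a division error. Fewer than three distinct degrees is an explicit
"insufficient degree support" error.

**Hypergeometric enrichment.** The default tail is the *exceedance*
probability P(X > x) = 1 − Σ_{t≤x} C(K,t)C(N−K,M−t)/C(N,M) — the formula
the protocol states — although the conventional enrichment tail is
P(X ≥ x); the latter is one switch away (`tail="inclusive"`, identical to
the exclusive tail at x−1), and the suite cross-checks both against exact
enumeration. The universe N defaults to the union of all database genes
and all pathway genes ("whole genome" is not an enumerable input here) and
is user-overridable. Significance is strict raw p < 0.05; Benjamini–
Hochberg is available but never used in the validation suite. Values are
computed through scipy's log-space survival function, with exact boundary
identities short-circuited (P(X > x) = 0 at x = min(K, M); tails at
negative thresholds = 1), and clamped to [0, 1].

**Pathway subnetwork.** The subnetwork of a pathway is the exact
intersection of network edges with (differential miRNAs × pathway genes).
Directions come from the screen — the packaged canonical file's directions
are used only when it itself is loaded as the network (fixture/worked-
example mode). Genes with in-subnetwork degree ≥ 2 are flagged
co-regulated. Comparison against a reference edge list reports edge-level
precision and recall (0/0 → 1 with a `vacuous` flag); a verified-only mode
restricts the reference to its experimentally confirmed subset.

**Quantification.** Two closed forms used downstream of the network
analysis: tumor volume V = (π/6)·d₁·d₂² from the larger/smaller caliper
diameters (mm³; inputs auto-swapped with a warning if reversed), and qPCR
relative expression 2^−ΔΔCt with ΔCt = Ct_target − Ct_reference per sample
and ΔΔCt = ΔCt_treated − ΔCt_control. Single-replicate Ct inputs; no
amplification-efficiency correction.

## The synthetic fixture

The generator emulates the statistical structure the analysis assumes; its
defaults are the study conditions the pipeline is calibrated to and are
not tuning knobs.

- **Design**: 2,000 miRNA probes (a round figure of the right order for a
  mature-miRNA LNA array), 4 samples (two cell lines × treated/control,
  one array per condition; replication is at the probe level: 50 miRNAs
  appear as two probe rows). 100 null probes sit below the eligibility
  floor in at least one sample.
- **Planted truth**: 70 up (true per-line ratio 2.0), 109 down (ratio
  0.4), 40 discordant (up in one line, down in the other), the rest null
  (ratio 1). The five canonical miRNAs are planted with their reference
  directions (miR-155-5p down, the other four up).
- **Intensity model**: baseline log-normal (median ≈ 500 units,
  σ_log ≈ 1), floor-censored at 1 — positively skewed, like real
  fluorescence intensities. Per-sample multiplicative scale factors
  (1.00/1.25/0.85/1.10) emulate array effects that normalization must
  remove. Measurement noise is multiplicative log-normal with σ = 0.05
  **truncated at ±2σ**, so one observed ratio is distorted by at most
  e^0.2 ≈ 1.22×. A planted 2.0 ratio can therefore never be observed
  below 2.0/1.22 ≈ 1.64, and a null ratio never above 1.22 — both clear of
  the 1.5 boundary with room for the small (empirically ~1–3%) residual of
  estimating normalization factors from planted-shifted medians. Planted
  recovery is exact by construction, and the suite asserts it exhaustively
  across 20 seeds.
- **Interaction database**: after canonicalization, de-duplication and
  restriction to differential miRNAs the union contains exactly 5,092
  unique pairs covering exactly 62 differential miRNAs and 4,362 distinct
  genes (gene reuse = 5,092 − 4,362 = 730). Per-miRNA target counts are
  Pareto-shaped (heavy-tailed), capped at a few times the mean — validated
  targetomes run to a few hundred genes, not the whole universe — with the
  final miRNA's count adjusted to hit the exact pair total. The 19
  canonical edges are planted. Each unique pair is emitted into 1–4 of the
  four source tables (≥ 20% into two or more, enforced), names are
  jittered in case/whitespace, and decoy records for non-differential
  miRNAs are added so that restriction has real work to do. 117 of the 179
  differential miRNAs deliberately have no database coverage.
- **Pathways**: 70 gene sets; the first is named "pancreatic cancer" and
  contains the 11 canonical genes plus ~59 fillers; up to three sets are
  planted as exactly one covered miRNA's whole target set (their overlap
  is maximal, so the exceedance p is exactly 0 — the attainable minimum —
  and enrichment must rank them first); the rest are uniform draws of
  20–200 genes.

**What the fixture does *not* emulate** — and hence what passing tests do
not show about real data: probe sequences and cross-hybridization,
background correction, spatial array artifacts, correlated biological
replicates, miRNA families with near-identical names, database curation
errors, or any real miRBase/KEGG content beyond the five canonical miRNAs
and eleven genes. The planted margins make screen recovery *certain*;
real arrays offer no such guarantee, and the recovery tests validate the
implementation, not the biology.

## Numerical choices

- Fold-change thresholds are inclusive on both sides (f = 1.5 is up).
- Hypergeometric values are clamped to [0, 1]; the test oracle is exact
  rational enumeration of all C(N, M) draws for N ≤ 12 at 1e−12 absolute.
- The log-log fit uses `numpy.polyfit` degree 1; tests pin it to the
  closed-form two-variable OLS at 1e−10 relative tolerance.
- Normalized eligible-set medians agree across samples to 1e−9 relative.
- Degree-fit ties: only degrees with nonzero frequency enter; the
  flat-response degenerate rule is described above.
- Determinism: every generator consumes a `numpy.random.default_rng`
  stream derived from the configured seed (sub-streams `[seed, 1]` and
  `[seed, 2]` for the database and gene-set generators), so equal configs
  give byte-identical artifacts.

## Problem sizes used in validation

The validation suite runs the full default-scale fixture (2,000 probes,
5,092 pairs) for the headline counts, a ~300-probe configuration for the
orchestration and CLI round-trips, the exhaustive hypergeometric sweep at
N ≤ 12, and 20 seeds of the default screen for recovery — sizes chosen so
the whole suite completes in well under a minute while still exercising
the exact planted cardinalities.

## Known limitations and open points

- Which node side (miRNA, gene, or pooled) and which distribution form
  (P(k) vs cumulative) best characterizes scale-freeness is genuinely
  underdetermined in this protocol family; all variants are exposed and
  none is privileged by the tests. The R² printed for the synthetic
  network describes the fixture, not any real network.
- The exceedance-vs-inclusive tail choice changes which pairs pass
  p < 0.05 (the exclusive tail can be < 0.05 even at x = 0 for large M);
  both are provided, the printed-formula default is used throughout, and
  no claim is made that either reproduces any particular historical count
  of significant pathways.
- The canonical reference list fixes one textually ambiguous edge
  (miR-34a-5p→IKKα, supported by inhibitor-reversal evidence) and flags 16
  edges as verified; the source material's own summary count of 17
  verified interactions cannot be reconciled edge-by-edge and is left as
  an inconsistency rather than resolved.
- Whether replicate averaging preceded normalization in the original
  protocol is unstated; averaging-first is the default here (it makes
  floor eligibility well-defined per miRNA), and the stages can be
  re-ordered manually.
- `unify_interactions` trusts its canonicalization: no fuzzy accession
  matching, no species inference, no synonym tables.
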