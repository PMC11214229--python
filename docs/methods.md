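# Methods

This note documents the staging model, its parameters and numerical
choices, what the synthetic-registry generator does and does not emulate,
and the design decisions taken where the problem was genuinely open.

## The staging model

### Inputs and the staging window

A case bundle holds everything the registry has for one case: structured
pathology TNM (with tumour-specific fields carried opaquely), coded
hospital-admission records, and optional clinical/MDT records. All dates
are day-granular ISO-8601; registry extracts do not carry time of day.

Stage at diagnosis must reflect disease extent before treatment effect, so
records contribute only inside a window anchored at the diagnosis date.
The default is 120 days (about 4 months), **inclusive at both ends**:
day 0 and day 120 are in, day 121 and any pre-diagnosis date are out. The
inclusive upper boundary is a convention of this implementation (the window
is usually quoted only by its length); it is configurable via
`StagingWindow(window_days)` / `--window-days`.

### TNM tokens and the advancement order

Prefixed TNM strings are parsed with a distributing-prefix grammar: in
`pT1N2 cM1a`, the `p` applies to T and N until `c` overrides it for M. Any
`y` prefix marks a post-therapy value. Unknown prefixes are parse errors,
never silently dropped.

Conflicts are resolved by a per-axis total **advancement order**:

* numerals first (`T: X < 0 < is < 1 < 2 < 3 < 4`; `N: X < 0 < 1 < 2 < 3`;
  `M: X < 0 < 1`);
* within a numeral, the bare category ranks below its lettered
  subcategories (`N2 < N2a < N2b`) — at equal numeral, a lettered value
  carries strictly more adverse specificity;
* two deliberate exceptions: breast `N1mi` (micrometastases) ranks *below*
  bare N1, because unqualified N1 conventionally means macrometastases and
  the breast stage table would otherwise be non-monotone in N; and a binary
  admission-derived value ranks below every stated value of its numeral
  (it is the minimal assumption "category 1", see below);
* `X` (unassessable) ranks below every stated value, so a stated value from
  any source always beats an X from a higher-precedence source.

Cross-source ties at equal advancement break to the more specific value,
then by source precedence clinical > pathology > admission, then to the
earliest record (which affects provenance labelling only). The published
ordering of sibling subcategories across axes has no authoritative source;
the order above is an engineering commitment of this package.

By default a stated-vs-stated conflict across sources is also resolved by
advancement (an admission M=1 overrides an explicit pM0). Whether a
registry would let secondary coded data override an explicit pathology
value is not settled; `EngineConfig(cross_source="precedence")` switches to
strict source precedence for those conflicts.

### Admission supplementation

Coded admissions carry only binary evidence. The default code map treats
C77\* (secondary/unspecified malignant neoplasm of lymph nodes) as nodal
involvement and C78\*/C79\* as distant metastasis; it is a YAML config with
site-specific overrides, matched by normalised prefix, and explicitly a
default rather than a jurisdictional standard — ICD-10-AM deployments
should review it (e.g. whether some regional secondary-site codes should
map to N for a given primary, or be excluded).

Two modelling commitments matter here:

* **A positive code is recorded as category 1.** A nodal code becomes
  N1-without-subcategory, the registry assumption that positive nodal
  coding equals N1. For grouping it expands like bare N1 (its
  subcategories), and because the true burden could be higher, any
  admission-sourced axis always forces the result down to the umbrella
  stage. The alternative reading "any positive N" makes many
  T-known/N-coded cases ungroupable across umbrellas (e.g. breast T1 with
  N1 vs N3) and was rejected.
* **Silence is not a value.** When in-window admissions exist but carry no
  metastasis code, no M0 component is emitted; the M0 arises from the
  absence assumption below, flagged as *corroborated* because the
  admission stream was reviewed. This distinction is what separates Tier 1
  from Tier 3 for otherwise identical pathology.

The admission date (not separation date) is the record date; this is a
configuration point in the reader, since extracts differ.

### Absence assumptions and grouping

After resolution, a missing or X-valued N or M becomes N0/M0, each recorded
in `assumptions_applied`. T is never assumed: with no T and no M1 evidence
the case is unstageable.

Grouping uses site-specific AJCC 8e anatomic tables shipped as text assets.
Leaf-level categories map directly; bare categories expand to their
subcategory leaves, returning the unique sub-stage when all matching rows
agree, the shared umbrella (with `umbrella_only=True`) when only the main
stage is determined, and `not_groupable` otherwise. Melanoma is the shipped
site where clinical and pathological grouping differ (clinical stage III is
undivided; pT1b pN0 is IA pathologically but IB clinically): the grouping
context follows the prefixes of the winning T/N values, and when the
context is genuinely mixed or absent both contexts are evaluated with an
umbrella fallback — a documented behaviour of this package, not a rule
taken from any registry. Breast uses the anatomic table only; prognostic
staging (receptors, grade) is out of scope.

Load-time integrity checks enumerate every valid leaf (T, N, M) triple per
site and context and abort unless exactly one row matches. In-situ disease
is only enumerated with N0, and breast T0 N0 M0 is excluded (it is not a
stage). The test suite repeats the enumeration against an independent
second transcription of the tables written as branch logic.

One caution on orderings: the published melanoma pathological table is not
monotone in N at sub-stage level (pT1a N1b is IIIB while pT1a N2a is IIIA),
so monotonicity guarantees are stated at umbrella level for that context
and at sub-stage level everywhere else.

### Tier assignment

With the stage derived, the tier records how it was reached:

* **Unstageable** — no stage group derivable after supplementation and
  assumptions. Cases whose only TNM is post-therapy (yTNM) are unstageable
  with an explicit reason by default, since post-neoadjuvant pTNM does not
  represent stage at diagnosis; `include_post_therapy=True` opts in to
  using those values.
* **Tier 3** — only pathology contributed: no in-window clinical record, no
  in-window admissions, no clinical-prefixed value. Absence assumptions are
  permitted (a pathology-only pMX is read as M0) but nothing corroborates
  them.
* **Tier 1** — the stage is at sub-stage level (not umbrella-limited), every
  axis is either explicitly stated or a corroborated absence (N/M assumed 0
  with the in-window admission stream reviewed and silent), at least one
  clinical-grade signal exists (clinical record, clinical-prefixed value in
  a pathology report — the pathologist transferring clinical staging — or
  in-window admission data), and any configured tumour-specific required
  fields are present. Required-field lists default to empty and are
  configurable per site (`TierRules.required_fields`), since the minimum
  tumour-specific dataset is registry policy rather than a fixed rule.
* **Tier 2** — everything else stageable: umbrella-only results,
  admission-supplemented values, uncorroborated assumptions.

Tiers are mutually exclusive and exhaustive by construction. Treating a
corroborated absence as Tier-1-complete is the reading under which the
standard worked examples (complete report with clinical M → Tier 1;
NX/MX + nodal code → umbrella Tier 2; subcategoried pathology + silent
admissions → sub-stage Tier 1; same pathology alone → Tier 3) all come out
as published; a stricter reading that demands explicit clinical M for
Tier 1 would push far more of a real cohort into Tier 2.

## The synthetic-registry generator

Each synthetic case draws a site, a true umbrella stage from a per-site
distribution, and a true sub-stage TNM **uniformly among the leaf triples
grouping to that umbrella** (via the stage table's inverse; uniformity is a
transparency choice, not an epidemiological claim). Melanoma truth uses the
clinical-context table, so true stage III is undivided; pathological-context
derivations then produce IIIA–IIID sub-stages whose umbrella always equals
the truth umbrella, keeping the under-staging bound exact.

Sources are then emitted with independent Bernoulli availability:

* a pathology report always exists; each axis is stated with probability
  `pathology_t/n/m` (defaults 0.95/0.90/0.10 — explicit pM is rare) and
  reported as X otherwise; neoadjuvant cases (probability `nat_fraction`)
  emit y-prefixed pathology;
* a clinical record with full truth cTNM exists with probability
  `clinical`;
* node-positive or metastatic cases generate a coded admission with
  probability `admission` (default 0.8), dated a geometric-like offset
  (p = 0.03, truncated at 180 days) after diagnosis so roughly 9% of
  emitted admissions fall outside the 120-day window and exercise the
  filter. N1mi truth never generates a nodal code (micrometastases are a
  microscopy finding);
* with probability `coding_error_rate` (default 0, and 0 throughout the
  test suite) a spurious metastasis-coded admission is added.

Diagnosis dates are uniform over one calendar year (2019). Everything is
driven by one `numpy` generator seeded from the spec, so identical
spec + seed is byte-identical end to end.

Because each case's tier is a deterministic function of its truth triple
and these Bernoulli draws, the expected tier distribution has a closed form
obtained by enumerating the outcome lattice; the test suite computes it
independently and requires empirical agreement within 3 binomial standard
errors at n = 10,000.

**What the generator does not emulate.** Admissions are emitted only for
node-positive/metastatic truth, so node-negative cases can never be
corroborated by an admission stream and complete-pathology early-stage
cases land in Tier 3. Real registries hold coded admissions for most
treated patients regardless of N/M status, which is one reason real tier
mixes (e.g. melanoma dominated by registry-derived stage) differ from
synthetic ones. There is also no record linkage error, no free-text, no
multiple primaries, no death-certificate-only cases, and no correlation
between stage and source availability beyond the admission rule. Passing
tests therefore validate the business rules and their stated invariants,
not the real-world tier mix of any registry.

The named presets (`melanoma-like`, `colorectal-like`, `breast-like`)
encode qualitative mechanisms only — melanoma: near-complete early-stage
pathology, almost no MDT records, minimal neoadjuvant therapy;
colorectal/breast: more clinical availability, later stage, substantial
neoadjuvant fractions — and are illustrative, not calibrated to any
published distribution.

## Reporting

Tier profiles are rendered one column per site, cells as `n (%)` with
integer percentages rounded half-away-from-zero (so 598/999 prints 60, and
a 0.5% share prints 1); percentages always recompute from the printed
counts. The machine-readable report (`report.json`) carries count, total
and percent per cell.

## Problem sizes and determinism

The acceptance checks run the worked examples exactly; table integrity by
exhaustive enumeration (a few hundred triples per site); monotonicity and
under-staging on 400-case mixed cohorts with 10% neoadjuvant fraction;
recovery and calibration at n = 10,000 per spec — sizes chosen so the full
suite completes in well under a minute on one CPU while leaving binomial
tolerances tight. All randomness flows from explicit integer seeds; two
runs with the same inputs, configuration and seed produce byte-identical
tables, staged outputs and reports.

## Known limitations

* Only colorectal, breast and melanoma stage tables ship; the engine is
  site-table-driven, so adding a site means adding (and double-entering)
  its table asset.
* Only AJCC 8th edition; no edition conversion.
* No free-text extraction: TNM must already be tokenised in the input
  tables.
* The default ICD-10 code map is deliberately coarse; jurisdictions using
  ICD-10-AM or wanting site-specific nodal/distant splits must supply
  their own map.
* Melanoma mixed clinical/pathological prefix handling (umbrella fallback)
  and the inclusive day-120 boundary are this package's documented
  conventions where published practice is silent.
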