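# Methods

## The model being verified

The verification substrate is a deterministic, discrete-time, multi-cohort
state-transition model of HIV disease and care engagement. Each calendar
year a new cohort of people living with HIV enters the model and is
distributed over the not-engaged states of the four untreated disease
stages; every cohort then moves among mutually exclusive health states by
annual transition probabilities. Calendar-year outputs sum over all cohorts
alive in that year. The recursion every engine implements is

    count(s, t0)   = entry(t0) · w(s)
    count(s, t+1)  = Σ_from count(from, t) · P(from → s) + entry(t+1) · w(s)

with one simultaneous transition per annual cycle (no half-cycle
correction — standard for this model class, and the natural reading of a
spreadsheet row that advances one column per year) and cohort entries at
the start of each cycle, transitioning within that same cycle.

### State roster

The HIV policy model this design emulates reports 13 main health states
subdivided into 48, without enumerating them. The shipped roster
(`src/nversion/data/hiv_policy_model.yaml`) is therefore a
*faithful-by-count stand-in*, sized to exactly 48 and grouped into exactly
13 main states; the verification method itself is structure-agnostic, so
nothing downstream depends on the particular subdivision:

* untreated: {Asymptomatic-Early, Asymptomatic-Late, Intermediate, AIDS} ×
  {not engaged, pre-ART care, lost to follow-up} — 12 states;
* on ART, by initiation stage {Intermediate, AIDS} × duration
  {years 1–8, 9+} — 18 states;
* lost to follow-up after ART, by initiation stage × duration years 1–8 —
  16 states (drop-outs from the 9+ stratum pool into the year-8 bucket);
* two absorbing death states (AIDS-related, other causes).

The Asymptomatic Early/Late split is a configuration label standing in for
a CD4 distinction the model does not compute; no CD4 arithmetic is
performed anywhere.

### Revisions

Revisions are declared as deltas on the baseline topology, so the roster
and all revision content are data, not code:

* **Re-entry into care** — adds transitions only: untreated LTFU in the
  Intermediate and AIDS stages may return to pre-ART care, and post-ART
  LTFU in the Intermediate- and AIDS-initiated strata may restart ART.
* **Universal ART** — adds transitions only: every not-engaged stage gains
  a direct entry to ART, bypassing pre-ART care. Because the state set is
  fixed under this revision, initiations from the Asymptomatic stages are
  pooled into the Intermediate-initiation stratum; this misstates their
  stratum label but keeps counts and stochasticity exact, and is
  documented here as a pooling approximation.
* **Guideline-based ART** — adds new states: a full Asymptomatic-Late
  initiation stratum (9 on-ART + 8 post-ART-LTFU states) with its pre-ART
  entry edge, i.e. initiation earlier than baseline but later than
  Universal.

## Synthetic parameters

The original transition probabilities were estimated from Haitian clinical
cohort data that are not public, so all experiments run on synthetic
parameter sets. The generator enforces the orderings a clinical reviewer
would check, by construction rather than by rejection:

* annual death probability per (stage, care status) is drawn from disjoint
  stage ranges — Asymptomatic U(0.010, 0.030) (Early ≤ Late by sorting the
  pair), Intermediate U(0.050, 0.100), AIDS U(0.150, 0.300) — so
  AIDS > Intermediate > Asymptomatic holds for every care status;
* on-ART death is the minimum same-stage untreated death times
  U(0.2, 0.6), hence never exceeds the untreated risk; post-ART LTFU
  reverts to the untreated risk of the initiation stage;
* where both death states are reachable, U(0.6, 0.9) of the death mass is
  AIDS-related;
* the remaining mass is split over the surviving exits by a Dirichlet with
  self-continuation (self-loops and the ART duration chain) up-weighted
  (α = 4 vs 1), and each row is renormalized so it sums to 1 within 1e-12.

Defaults: 15 annual cohorts of 10,000 persons, calendar years 2009–2023
(chosen so the 15-cycle horizon ends at the study's reporting year 2023;
configurable). Probabilities are time-invariant by default; whole-row
per-year overrides are supported in all three engines because the model is
multi-cohort over calendar time.

What the generator does *not* emulate: correlations between parameters,
calibration to any epidemic, secular trends in ART scale-up, or parameter
uncertainty. Passing tests therefore demonstrate that the three engines
agree and that injected errors are detected and accounted for on *valid*
inputs of realistic shape — not that any projection is epidemiologically
accurate.

## The compact grid and the engines

The compact grid has one row per health state plus declared aggregate rows
(13 main-group totals, the five care-continuum rows, alive/dead/grand
totals, and the entry row) and one column per year — 70 × 15 = 1,050 cells
for the default baseline, on the order of the ~1,100-cell compact workbook
the design mimics. Exact parity with the published workbook's cell counts
is not claimed: the non-state rows of that workbook are not documented, so
aggregate rows here are declared in the layout and the counts are
layout-dependent.

The named and positional engines compile the recursion into a formula
graph: each state cell's single formula encodes all inflows to that state
as a signed sum of (reference × probability-reference) products, aggregate
rows are sum-over-range formulas, and probabilities/entry weights live in
constant cells (a parameter block below the grid in positional mode).
Evaluation walks a topological order of the dependency graph; the result
is independent of tie-breaking among ready cells, and the two addressing
modes compile to structurally identical graphs. The matrix engine shares
none of that machinery: it builds dense per-year matrices and propagates
per-cohort numpy vectors, its expanded representation (matrices plus one
state vector per cohort-year, ~45,000 cells for the default baseline)
always strictly larger than the compact grid.

### Numerical choices

* **Comparison tolerance.** In a spreadsheet, concordant cells subtract to
  exactly zero. Independent floating-point engines need a tolerance: a
  cell is discrepant when |a − b| > max(1e-6 persons, 1e-9 · max(|a|,|b|)).
  This sits many orders below the 5% materiality scale and several above
  the observed cross-engine accumulation error (~1e-15 relative).
* **Division by zero in the percentage difference.** When the
  gold-standard cell is 0 and the errored cell is not, the percentage is
  undefined; such cells get their own UNDEFINED category, excluded from
  the percentage tallies and counted separately, rather than being mapped
  to 0 or ∞.
* **Materiality boundary.** Exactly 5% is non-material; strictly greater
  is material.
* **Error-size bins.** Default bins for the impact distribution are an
  exact-zero spike plus magnitude bins (0,5], (5,25], (25,100], >100
  percent; signed custom edges are accepted.
* **Addresses.** Internal positional addressing is 0-based (`R7C3`);
  report-facing renderings use spreadsheet-style A1/1-based coordinates.
* **IO fidelity.** CSV grids round-trip bit-exactly (pandas round-trip
  float parsing); XLSX fixtures round-trip to ~15 significant digits, the
  precision of the format's serializer.

## Error injection and accounting

Mutation operators realize the error taxonomy concretely: rebinding one
named reference within its namespace; offsetting one positional reference
by a seeded (row, column) shift constrained to land on an existing cell
(spreadsheets rarely produce hard failures; an option allows broken
references); extending or truncating a sum range; pasting a neighbor's
formula as a relative copy; overwriting a formula with a constant;
swapping SUM for MEAN or MAX; perturbing one digit of one constant;
flipping one +/− sign. Targets are sampled uniformly (seeded) over the
grid cells carrying the feature each operator needs, with
operator-inapplicable cells skipped and redrawn, and every mutation is
logged with enough detail to re-apply or revert it exactly.

This is a *model* of single-programmer revision error, not a measurement
of it: eligibility and uniform sampling stand in for human error
propensity, and nothing here models fatigue, time pressure, or per-hour
error rates. Mode applicability mirrors the real versions (name errors
only exist in the named version; reference offsets and relative-copy
mistakes only in the positional one).

Classification follows the original-sin rule: originals are mutated cells
that are themselves discrepant; propagated errors are discrepant cells in
the forward dependency closure of a mutated cell, counted once however
many originals reach them. The closure is taken over the union of the
clean graph's edges and the edges induced by the mutated formulas; since a
mutation rewires only its own cell's inputs, this union provably has the
same descendants as the clean graph, and the union is kept for
defensiveness. A mutated cell whose output is unchanged (for instance a
formula overwritten with its own current value) is surfaced as an
*undetectable original* and excluded from the originals count — output
comparison can only ever count identified discrepancies, and this is the
method's documented blind spot. A discrepant cell that is neither mutated
nor downstream of a mutation raises an integrity error, since it would
signal an engine bug rather than an injection effect.

The changed-cell denominator for the originals rate is the set of compact
cells that are new under a revision or whose formula set changes (new
inflows, changed entry weights, aggregate membership gains); for baseline
runs with injected errors, where no revision defines a changed set, the
whole grid is used.

## Care continuum mapping

The published model's step definitions are not printed; the shipped
default maps: total infected = all live states; diagnosed/linked = ever
engaged (pre-ART care, on ART, or LTFU after engagement); receiving ART =
all ART-experienced strata; retained pre-ART = currently in pre-ART care;
retained on ART = on ART and engaged. The mapping is configuration, and
step deltas use the same percentage-difference convention as cells.

## Workbook replay

For deposited with-errors/corrected workbook pairs, the analysis is
replayed from cached cell values (foreign formulas are never re-evaluated);
formula texts, where present, supply both the original/propagated split
(a discrepant cell whose own formula text differs is an original) and the
dependency edges used to sanity-check propagation. Without formula texts
the classification degrades to counts-only with a warning. Programmatic
fixture workbooks carry formula texts in a shadow sheet because a freshly
written file has no cached formula results.

## Problem sizes

The test suite and the acceptance script run on the full default model
(48–65 states, 15 years, ~1,050-cell grids): cross-engine agreement over
25 seeded parameter sets per revision in the suite (5 per revision in the
acceptance script), 100 seeded single-mutation experiments per operator in
the suite (25 per operator in the script), and toy chains of ≤ 5 states
for the brute-force oracle. The whole suite runs in about a minute on one
CPU; the acceptance script in about ten seconds.

## Known limitations

* The 48-state roster and the continuum mapping are declared stand-ins;
  reproducing the published workbooks' exact cell counts (1,360 / 1,640 /
  2,140 per revision) would require their exact layout, which is not
  public. Workbook replay exists precisely so those files can be analyzed
  when available.
* Value-preserving errors (and any error whose effects cancel within
  tolerance in every cell) are invisible to output comparison, in any
  number of parallel versions.
* The formula language covers what the model needs (+, −, ×,
  sum/mean/max over ranges); it is not a general spreadsheet interpreter,
  and there is no circular-reference iteration or volatile-function
  semantics.
* Injection samples errors uniformly; observed human error rates are
  version- and revision-dependent in ways uniform sampling does not
  reproduce.
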