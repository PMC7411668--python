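# Methods

## Problem setting

Arable weed floras are compiled from sources with very different scopes: a
comprehensive expert flora of cultivated fields, a short list of specialist
segetal ("messicole") taxa, and plot-based surveys restricted in space and
time. The analyses here quantify (i) how the composition of such lists
differs from a reference pool of open-vegetation species, across habitats
inferred from co-occurrence data, and (ii) whether the plants able to grow
in fields are more habitat-generalist than those that never enter them.

## Pool assembly

Names are matched exactly after string-level normalization (whitespace
collapsed, genus capitalized, epithets lower-cased; rank markers such as
`subsp.` preserved). There is deliberately no fuzzy matching and no
taxonomic-backbone synonymy resolution: assembly is then a pure function of
the input lists and fully reproducible. Infra-specific taxa remain distinct
records. When sources disagree on an attribute, the first-listed source
wins and the conflict is logged; the precedence order is part of the run
configuration. Venn partitions are exhaustive over the 2^k − 1 membership
regions of 2–3 sources and always sum to the union size.

Percentages are reported to one decimal with **round-half-up**. Published
floristic tables are not perfectly consistent in their rounding — for
example 1402/1514 is sometimes printed as 92.5 where half-up gives 92.6,
399/1514 as 26.3 (half-up: 26.4) and 100/258 as 38.7 (half-up: 38.8). The
package standardizes on half-up, which matches the large majority of such
printed values (71.5, 21.9, 44.6, 66.2, 52.9, 39.8, ...), and documents
rather than models the exceptions.

## Co-occurrence null model and habitat classification

For each species pair the number of jointly occupied plots is tested
against an exact hypergeometric null (the probabilistic co-occurrence model
of Veech 2013): conditioning on the two occupancies `occ_i`, `occ_j` and
the plot total `n`, the shared count under random placement is
hypergeometric, and the reported p-value is the upper tail
`P(X ≥ shared)`. The tail is computed from the exact distribution (scipy's
hypergeometric survival function); tests verify it against brute-force
enumeration of all `C(n, occ_j)` draws for n ≤ 12. Species observed in
fewer than `min_occupancy` plots (default 3) are dropped first — pairs of
very rare species can never reach significance and only inflate the
multiple-testing burden.

Pair p-values are corrected by Benjamini–Hochberg FDR and edges retained at
q ≤ α (default α = 0.05). Retained edges are unweighted: the source
analyses state no weighting scheme, and an unweighted graph keeps the
modularity objective simple and comparable. Modules are found by maximizing
Newman–Girvan modularity Q — greedy Clauset–Newman–Moore agglomeration by
default (fully deterministic), Louvain optionally (deterministic given a
seed). On all ≤ 8-node test graphs the greedy optimum coincides with the
brute-force maximum over every partition; on planted-partition benchmarks
(4 blocks × 15 nodes, p_in = 0.6, p_out = 0.02) recovery is essentially
exact (ARI ≥ 0.95 over 20 seeds). Species with no significant edge form
the `unassigned` module.

Habitat labels then propagate in two steps, a convention this package makes
explicit because co-occurrence methods usually leave it implicit:

1. each **plot** is labelled with the module holding the strict majority of
   its module-assigned species (ties → globally larger module, then lowest
   module id);
2. each **species** receives as *main habitat* the plot label under which
   it occurs most often (ties → habitat with more plots, then lowest id).

This is what makes "occurrences outside the main habitat" — the basis of
the generalism index — a computable quantity.

## Generalism

The participation coefficient over a species' habitat occurrence counts,

    c = 1 − Σ_h (n_h / n)²,   n = Σ_h n_h,

is the Guimerà–Amaral participation coefficient applied to occurrence
counts, equivalently the Simpson-diversity complement of the habitat
profile. It is 0 iff exactly one habitat is occupied, bounded by 1 − 1/H,
invariant to habitat relabelling and to rescaling all counts, and strictly
increases when an occurrence moves from the dominant habitat to an empty
one. The related network literature sometimes normalizes by module *degree*
rather than occurrence counts; the count-based form is the declared choice
here, and any alternative index can be supplied via the `formula` argument
of `score_species`.

Group contrasts use the unpaired two-sample Wilcoxon rank-sum test,
reported as the Mann–Whitney U of the first group. The null distribution is
enumerated exactly when n₁ + n₂ ≤ 12 and the pooled sample is tie-free;
otherwise the normal approximation with midrank tie correction and
continuity correction is used (the two agree within 0.02 for tie-free 6+6
samples). Identical constant groups report p = 1 rather than erroring. The
test is calibrated: at n = 30 + 30 under the null its rejection rate at
α = 0.05 is 0.05 ± 0.02 over 1000 simulations.

## Observed vs expected composition

Expected counts allocate a list's total N across habitats by the reference
pool's proportions, `E_h = N · r_h / Σ r`. Displayed tables round half-up
(matching conventions like 379.6 → 380, 166.5 → 167); every chi-square is
computed on the **unrounded** expecteds, so the statistic is exact while
the display matches the printed convention. The 2×2 test uses the Pearson
formula, or with Yates continuity correction
`N(|ad − bc| − N/2)² / ((a+b)(c+d)(a+c)(b+d))` (correction capped at zero
so tiny tables cannot over-correct into a spurious statistic). The
corrected statistic never exceeds the uncorrected one.

The red-list × origin contrast is laid out as red-listed weeds against all
other weeds of the pool: with 65 of 98 red-listed weeds Mediterranean and
602 of 1514 weeds Mediterranean overall, the table is
(65, 33, 537, 879) and the Yates-corrected statistic is 29.7.

## Synthetic survey generator

Each of H habitats contributes P plots and a pool of S species. Species i
has a home habitat and a specialization s_i ∈ [0, 1]; it occurs in a plot
with probability `p_occ` at home and `p_occ · (1 − s_i)` elsewhere,
independently across plots (no co-limitation, no abundance, no spatial
structure). Under this model the participation coefficient a species
converges to is available in closed form from the expected counts,

    c* = 1 − (e_home² + (H−1) e_away²) / (e_home + (H−1) e_away)²,

with `e_home = P·p_occ`, `e_away = P·p_occ·(1−s)`; note c* depends only on
s and H. Defaults are H = 4 (the number of major habitats the analyses
revolve around), P = 100 plots per habitat, S = 50 species per habitat
pool, p_occ = 0.5 and s ~ Uniform(0, 1) — sizes at which module recovery
is reliable and the s ↔ c mapping is well resolved while a full pipeline
run takes well under a second. A weed/non-weed contrast is planted by
drawing s for the two groups from separate distributions (the bundled
scenario uses s = 0.3 for weeds, 0.9 for non-weeds, which reproduces the
qualitative published pattern: weeds more generalist in every habitat).
Attribute tables are independent categorical draws whose default marginals
mirror the French arable flora (60.4% therophytes, 39.8% Mediterranean,
6.5% red-listed, ...).

What the generator does *not* emulate — abundance classes, spatial
autocorrelation, temporal turnover, seed banks, uneven sampling effort —
bounds what passing tests show: they validate the inference machinery under
the model's assumptions, not its robustness to every property of real
survey data.

## Numerical and design choices

- Rounding: half-up everywhere a one-decimal percentage or integer
  expected count is displayed; statistics always computed unrounded.
- Determinism: the greedy module detector is deterministic; Louvain and
  every simulation take explicit integer seeds; CLI runs with equal
  configuration and seed produce byte-identical outputs.
- Degenerate inputs: edgeless graphs raise with advice to relax the
  threshold; plots or species with no assigned module are labelled
  `unassigned` and excluded from habitat counts; empty groups and zero
  margins raise; all-equal rank-sum groups report p = 1.
- Tie-breaks (plot labelling, main habitat) are fixed and documented above
  so repeated runs cannot flip labels.

## Known limitations

- Name matching is string-level only; synonyms or spelling variants across
  sources become distinct taxa unless harmonized upstream.
- The hypergeometric null conditions on occupancies but assumes
  exchangeable plots; survey designs with strong spatial or temporal
  structure violate this.
- Published Wilcoxon W values for the real weed/non-weed contrasts are not
  reproducible here because they depend on the full (non-packaged) survey
  database; the pipeline's behaviour is instead validated on synthetic
  surveys with known truth.
- Observed/expected tables inherit any internal inconsistencies of printed
  sources (e.g. a printed expected of 73 where the marginals give 73.6);
  such cases are documented, not corrected.
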