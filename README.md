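# weedpool

Tools for analysing the species pool of arable weeds: which plants can grow
in cultivated fields, which habitats they come from, and how ecologically
generalist they are compared with plants that never enter fields.

The package is aimed at community ecologists and biodiversity informaticians
working with heterogeneous floristic sources — expert floras, specialist
lists ("messicole"/segetal weeds), and plot-based vegetation surveys — that
disagree in scope, scale and method. It provides four connected analyses:

1. **Pool assembly** — compile a species pool from several source lists with
   exact string-level name matching, per-source membership flags, Venn
   partitions of the sources, and attribute tabulations (Raunkiaer life
   form, biogeographic origin, red-list status).
2. **Habitat classification from co-occurrence** — from a plots × species
   incidence matrix, test every species pair against an exact
   hypergeometric null (shared plots given each species' occupancy),
   retain edges at a Benjamini–Hochberg FDR, and partition the resulting
   network by Newman–Girvan modularity maximisation. Modules correspond to
   habitats; plots inherit the majority module of their species, and each
   species gets a *main habitat* — the label under which it occurs most
   often.
3. **Generalism** — the participation coefficient
   `c = 1 − Σ_h (n_h/n)²` over a species' habitat occurrence counts
   (0 = strict specialist, → 1 − 1/H = perfect generalist over H
   habitats), with unpaired Wilcoxon rank-sum contrasts between groups
   (weeds vs non-weeds, per habitat).
4. **Observed vs expected composition** — scale a reference pool's habitat
   proportions to each weed list's total (`E_h = round_half_up(N·r_h/Σr)`
   for display; tests use unrounded expecteds), chi-square goodness-of-fit,
   and 2×2 contingency tests with optional Yates continuity correction.

A synthetic survey generator with planted habitat modules and a tunable
specialist–generalist gradient makes the whole pipeline testable with no
external data: every species' true home habitat and the participation
coefficient it should converge to are known in closed form.

## Worked example

```python
from weedpool import (habitat_count_table, chisq_2x2, SyntheticConfig,
                      simulate_survey, classify_and_score,
                      compare_groups_by_habitat)

# Observed vs expected habitat composition of a 1161-taxon weed list
# against a 3291-taxon open-vegetation reference pool:
table = habitat_count_table(
    ["dry calcareous", "mesic", "ruderal", "fringes"],
    [1076, 472, 1447, 296],     # reference pool counts per habitat
    [162, 168, 706, 125],       # weed list counts per habitat
)
for h, cell in zip(table.habitats, table.formatted()):
    print(f"{h:16s} {cell}")
print(f"chi2 = {table.test.chi2:.1f}, df = {table.test.df}, p = {table.test.p:.2e}")

# Are red-listed weeds disproportionately Mediterranean? 2x2 with Yates:
res = chisq_2x2(65, 33, 537, 879, yates=True)
print(f"red-list x mediterranean: chi2 = {res.chi2:.1f}, p = {res.p:.2e}")

# Full pipeline on a synthetic survey with a planted generalism contrast
# (weeds specialization 0.3, non-weeds 0.9; 4 habitats, 100 plots each):
cfg = SyntheticConfig(weed_s=0.3, non_weed_s=0.9, seed=42)
inc, truth = simulate_survey(cfg)
result = classify_and_score(inc)
flags = {sp: ("weed" if truth.is_weed[sp] else "non_weed")
         for sp in inc.species}
out = compare_groups_by_habitat(result.scores, flags, result.main_habitat)
```

This prints:

```
dry calcareous   162 (380)
mesic            168 (167)
ruderal          706 (510)
fringes          125 (104)
chi2 = 203.7, df = 3, p = 6.73e-44
red-list x mediterranean: chi2 = 29.7, p = 5.05e-08
```

The weed list is strongly displaced from the reference proportions: taxa of
dry calcareous grasslands are under-represented among weeds (162 observed
where 380 would be expected) while ruderal taxa are over-represented
(706 vs 510). The red-list contrast shows red-listed weeds are far more
often Mediterranean than other weeds (χ² = 29.7 on 1 df). On the synthetic
survey the pipeline recovers the four planted habitats (modularity
Q = 0.740) and finds weeds significantly more generalist in every habitat
(median c ≈ 0.74 vs ≈ 0.38, all p < 10⁻⁸), matching the planted contrast.

## Command line

Each stage is also a CLI subcommand over the same functions:

```sh
weedpool simulate --seed 7 --out sim/
weedpool network --occurrences sim/occurrences.tsv --out-dir net/ \
    --alpha 0.05 --correction bh_fdr --method greedy --seed 1 --min-occupancy 3
weedpool generalism --scores net/generalism_scores.tsv --groups groups.tsv --out contrasts.tsv
weedpool compare --reference reference_counts.tsv --lists lists/*.tsv --out-dir cmp/
weedpool assemble --source flora=flora.tsv --source survey=survey.tsv --out pool.tsv
weedpool report --in-dir cmp/ --out-dir report/
```

All inputs are header-named delimited text (comma or tab, auto-detected);
all stochastic steps take an explicit `--seed`.

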