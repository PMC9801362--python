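# lipedex

DXA regional body-composition analysis for lipedema: the 27-index fat/lean
mass distribution panel, tolerance-based 1:2 case-control matching, a
normality-routed comparison battery with Bonferroni control, ROC/Youden
threshold derivation with DeLong confidence intervals, and the
clinical-plus-DXA rule-out decision procedure — exercised end-to-end on a
synthetic cohort generator calibrated to published group parameters.

The headline quantity is the **leg FM / total FM** share: the fraction of
whole-body fat mass located in the legs. In doubtful clinical presentations
a value below the rule-out cutoff (0.383 by default; 0.384 selectable)
argues against lipedema; the index never overrides fully met clinical
criteria.

## Layout

| module | contents |
|---|---|
| `lipedex.composition` | `ParticipantRecord`, WHO BMI classes, BMI/FMI/LMI/ALMI/BMD, the 27-entry `IndexPanel` |
| `lipedex.simulate` | `GeneratorConfig`, `default_config()`, truncated-Gaussian share sampling, cohort generation |
| `lipedex.matching` | greedy nearest-neighbour matching under age/BMI tolerances, cohort summary table |
| `lipedex.stats` | Shapiro-Wilk routing, t / Mann-Whitney / ANOVA+Tukey / Kruskal-Wallis, Bonferroni, stage correlations, the 27-index battery |
| `lipedex.roc` | empirical ROC (midpoint thresholds), trapezoidal AUC ≡ normalized U, DeLong CI, Youden-optimal cutoff, binormal closed form |
| `lipedex.diagnose` | six clinical criteria, type I–V / stage 1–4 taxonomy, decision rule |
| `lipedex.io` / `lipedex.pipeline` / `lipedex.cli` | CSV tables, manifest-tracked end-to-end run, `lipedex` command |

## Command line

```sh
lipedex simulate --n-cases 74 --seed 42 --out cohort.csv
lipedex indices  --in cohort.csv --out panel.csv
lipedex match    --cases cases.csv --pool pool.csv --ratio 2 \
                 --age-tol 3 --bmi-tol 3 --out matched.csv \
                 --assignment-out assignment.json
lipedex compare  --matched matched.csv --out table2.csv [--stratify bmi_class|type|stage]
lipedex roc      --matched matched.csv --out fig2.csv
lipedex diagnose --leg-share 0.30 --cutoff 0.383 \
                 --disproportionate-symmetric-limb-fat ... # six required flags
lipedex run-all  --n-cases 74 --seed 42 --out-dir out/
```

`run-all` writes `cohort.csv`, `matched.csv`, `assignment.json`,
`table1.csv` (cohort summary), `panel.csv`, `table2.csv` (comparison
battery), `fig2.csv` (ROC summaries) and `report.json` (with the run
manifest: seed, config digest, row counts, warnings). All randomness flows
from the single seed; identical seeds give byte-identical outputs.

Generator configurations round-trip through JSON
(`GeneratorConfig.to_json` / `from_json`, or `--config FILE`).

## Notes

- The synthetic generator calibrates *indices* (shares of total mass), not
  raw masses: shares are drawn from ±4 SD truncated Gaussians and masses
  reconstructed, so the distributions the analysis consumes match the
  configured group parameters by construction.
- Control-pool records are jittered around case age/BMI (within the
  matching tolerances), emulating matched recruitment and guaranteeing
  feasibility of 1:2 matching at the default 4× pool.
- The android/gynoid ratio uses fat/(fat+lean) regional percentages by
  default; a bone-inclusive dialect is available
  (`compute_index_panel(..., pct_fat_denominator="fat_lean_bone")`).
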