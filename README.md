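# synercist

Downstream analytics for studies that combine a drug screen with
differential cistrome and transcriptome profiling — the setting of an
ERβ-agonist plus antiandrogen combination in prostate cancer cells, where
the questions are: which drug pairs inhibit growth beyond additivity,
which gene-set enrichments flip direction between treatments, where in
the chromatin landscape the differential binding sites concentrate, which
motifs and coregulator classes they carry, how binding changes couple to
expression changes, and whether the resulting gene signature stratifies
patient tumors.

`synercist` implements each of those steps as a tested, reusable library
with a thin CLI, plus a synthetic-data module that generates every input
with controllable planted effects, so the whole pipeline can be exercised
and validated without any external dataset.

## The statistics at the core

* **Combination-screen delta.** Raw luminescence is normalized to plate
  controls (viability % = 100·raw/mean(controls); inhibition = 100 −
  viability). The additive expectation at a dose pair is the sum of the
  two single-agent inhibitions, capped at 100%. The delta is
  `observed − expected`: positive = cooperation beyond additivity,
  negative = antagonism. Per dose pair, replicate observed inhibitions
  are compared with replicate-matched expected values by a Welch t-test,
  Benjamini–Hochberg corrected across the dose grid.
* **NES direction switches.** Significant GSEA terms whose normalized
  enrichment score flips sign between two treatments are ranked by
  ΔNES = |NES₁ − NES₂| and classified by keyword category.
* **Hypergeometric interval enrichment.** One exact upper-tail
  hypergeometric primitive, P(X ≥ k) computed as a rational tail sum,
  drives cistrome-vs-cistrome overlap significance, ChromHMM chromatin-
  state enrichment, and coregulator gene-class enrichment; a rank-based
  co-enrichment scan summarizes overlap with a cistrome collection
  (factor enriched when its share of the top-ranked datasets exceeds 1.2×
  its share of the collection).
* **Motif coverage deltas.** PWM log-odds scanning (both strands,
  fraction-of-max threshold) gives per-motif percent-of-regions-covered;
  treatment-minus-reference deltas are aggregated by TF family.
* **score.absFC integration.** Peaks annotated to genes within 100 kb of
  the TSS are joined to differential expression; per pair,
  `score.absFC = peak score × |log2FC|`, labeled Loss/Gain × Down/Up, and
  group differences tested by Welch t.
* **Signature stratification.** Genes selected by three rules (AR
  loss ∧ up; MYC loss ∧ down; H3K27ac loss ∧ down) cluster cohort tumors
  (Ward/Euclidean, k = 2), and cluster–category association is tested by
  chi-squared (Yates-corrected for 2×2 tables).

## Worked example

```python
from synercist.synthetic import SimulationConfig, simulate_screen_plate
from synercist.screen import normalize_viability, combo_test

doses = [0.0, 0.1, 0.3, 1.0, 3.0, 10.0]
config = SimulationConfig(seed=0, embedded_delta_map={(0.3, 1.0): 15.0})
plate = simulate_screen_plate(config, doses, doses)          # 4 replicates
surface = normalize_viability(plate)
result = combo_test(surface)
best = result.loc[result["p_adj"].idxmin()]
print(f"({best.drugA_dose}, {best.drugB_dose}) delta={best.delta:.1f} "
      f"p_adj={best.p_adj:.3f}")
```

prints

```
(0.3, 1.0) delta=17.8 p_adj=0.034
```

— the dose pair carrying the planted 15-point excess inhibition is the
most significant cell of the 6×6 screen, with the delta recovered within
sampling error of the truth (plate noise sd 5%, quadruplicates).

The full chain runs from one command and is byte-deterministic under a
fixed seed:

```bash
synercist pipeline --out demo_out --seed 0
# -> pipeline complete: 8 stages -> demo_out
```

which writes, per stage, the screen delta table, NES switch and word
tables, the Venn membership of the four factor cistromes, the ChromHMM /
overlap / gene-class / co-enrichment tables, motif coverage deltas with
family summaries, score.absFC records with group tests, and the
signature gene list with tumor clusters and chi-squared association.

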