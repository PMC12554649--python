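# ruralcoord

Coupling-coordination analysis of two regional development systems on
provincial panel data.

## The problem

Regional studies of "digital village" construction and rural healthcare
ask whether two subsystems of development move together: a composite
digitalisation index U1 built from an 11-indicator system, and the
technical efficiency U2 of rural healthcare services measured by DEA.
`ruralcoord` implements the full analysis chain such studies use, as a
tested, reusable library with a thin CLI, exercised end to end on a
synthetic 29-province × 8-year panel whose regional structure (East >
Central > West levels, positive trend, positive spatial autocorrelation,
known driver effects) is recorded as ground truth.

## The models

* **CRITIC weighting** — each range-normalized indicator j gets weight
  `W_j ∝ S_j · Σ_i (1 − r_ij)` (contrast intensity × conflict);
  U1 is the weighted sum of normalized indicators.
* **Super-efficiency SBM DEA** — the non-oriented slack-based measure
  `ρ = (1 − (1/m)Σ s_i⁻/x_ik) / (1 + (1/s)Σ s_r⁺/y_rk)` under CRS,
  solved exactly via the Charnes–Cooper transformation; efficient units
  (ρ = 1) are re-ranked with Tone's super-efficiency model (score ≥ 1,
  unit excluded from its own reference set).
* **Coupling coordination degree** —
  `C = 2√(U1·U2)/(U1+U2)`, `N = αU1 + βU2` (α = β = 0.5),
  `D = √(C·N)`, graded into ten tiers from extreme dysregulation to
  high-quality coordination.
* **Dagum Gini decomposition** — total Gini of D per year split exactly
  into within-region, net between-region and transvariation components.
* **Distribution dynamics** — Gaussian KDE curves of D with mode/peak/tail
  descriptors; quartile-state Markov transition matrices at lags 1–3,
  optionally conditioned on the spatial-lag state of adjacent units, plus
  global Moran's I with permutation inference.
* **Driver analysis** — quantile regression (exact LP, pinball loss) of D
  on six drivers (LED, HNL, DIN, GOV, HHC, URB) at τ = 0.1…0.9 with
  xy-pair bootstrap t statistics.

## Worked example

```bash
ruralcoord run-all --seed 1 --out-dir out
```

writes `panel.csv`, `weights.csv`, `u1_scores.csv`, `u2_scores.csv`,
`ccd.csv`, `region_year_levels.csv`, `gini.csv`, `kde.csv`, `markov.csv`,
`moran.csv`, `qreg.csv` and `manifest.json`. On the seed-1 synthetic panel
the region-year mean coordination degrees begin

```
           D
region Central   East   West National
2015     0.782  0.891  0.517    0.732
2016     0.783  0.916  0.549    0.753
2017     0.796  0.907  0.564    0.758
```

i.e. the eastern region leads, the west trails, and the national mean
rises over time — the qualitative pattern the generator encodes.  The
driver table at the median quantile recovers the built-in effect signs
(positive LED/HNL/DIN/GOV, negative HHC/URB), e.g. β_LED = 0.065 and
β_URB = −0.066 with |t| > 4, and every year's Moran's I of D is positive
(mean 0.746) with permutation p < 0.05.

The same stages are available as library calls (`ruralcoord.critic_index`,
`ruralcoord.sbm_dea`, `ruralcoord.coupling`, ...) on any balanced
long-format panel; see `docs/methods.md` for the data contracts.

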