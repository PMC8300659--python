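# vimcys

Quantitative analyses around the single cysteine (Cys328) of vimentin, the
type III intermediate-filament protein: how reactive that thiol is, how
zinc shields it, and which crosslink geometries are possible between
cysteines of neighbouring dimers.

The package is organised as an analysis project: the library under
`src/vimcys/` implements every computation; the numbered scripts under
`analysis/` run the study end to end on synthetic data and write tables
under `results/`.

## What it computes

**Thiol pKa from alkylation kinetics** (`alkylation`, `titration`).
Monobromobimane (MBB) becomes fluorescent when it conjugates a thiol, and
only the thiolate (S⁻) form reacts. Each well's fluorescence time series
F(t) is fitted with a logistic in time to extract the bottom plateau F₀;
the early-phase slope of ln(F(t)/F₀) is the pseudo-first-order rate
constant k_obs. Across pH, k_obs follows a sum of Henderson–Hasselbalch
terms,

    k_obs(pH) = k₀ + Σᵢ k_lim,i / (1 + 10^(pKa_i − pH)),

whose inflexion points are the pKa values. Models with 0, 1 and 2
ionization sites are compared by AICc, and pKa estimates from independent
experiments are pooled as mean ± SD.

**Zinc protection from gel densitometry** (`densitometry`). Band-intensity
tables yield per-lane ratios (biotin/vimentin for probe incorporation,
oligomer/monomer for crosslinking). Protection by a cation is the percent
inhibition 100·(1 − ratio_treated/ratio_control), with Student's t-tests,
and a Spearman trend of inhibition against crosslinker spacer-arm length
(DBB 4.88 Å, TMEA 10.3 Å, BMH 13.0 Å; amine-reactive DST 6.4 Å as a
chemistry control).

**Zinc affinity by chelator competition** (`competition`). The Zincon
assay reads the Zn–Zincon complex at 620 nm (K_D = 214 nM). With protein
present, the mass balance

    Zn_T = z + Zincon_T·z/(K_Z + z) + n·P_T·z/(K_P + z)

is solved for free zinc z by bracketed root finding; K_P (and the site
count n) are estimated by nonlinear least squares on paired ±protein
titrations, with the absorbance scale calibrated on the protein-free
curve.

**Crosslink geometry and ion persistence** (`geometry`). From PDB
structures or multi-MODEL trajectories: inter-chain Cys SG–SG distances;
a feasibility rule per crosslinker (thiol crosslinker bridges iff
distance ≤ spacer arm + slack, with the default slack making the DBB rule
exactly the 6 Å disulfide cutoff); and per-ion contact persistence (the
fraction of frames an ion stays within 3 Å of any protein atom, with
persistent meaning > 90%).

**Synthetic data** (`simulate`). All inputs — kinetics plates, gel tables,
competition curves, toy two-chain structures with placed zinc ions — are
generated with known ground truth, so every estimator is testable by
parameter recovery.

## Worked example

```bash
python analysis/01_simulate_assays.py --seed 1
python analysis/02_cysteine_pka.py    --seed 1
```

prints (seed 1):

```
experiment 1: pKa = 4.55 / 7.44 (R^2 = 0.994)
experiment 2: pKa = 4.34 / 7.29 (R^2 = 0.997)
experiment 3: pKa = 4.68 / 7.41 (R^2 = 0.998)
pooled (n=3): pKa1 = 4.53 +/- 0.17, pKa2 = 7.38 +/- 0.08 (mean +/- SD)
Cys-to-Ser control: model selection keeps 0 ionization site(s); R^2 = -0.005
```

Each experiment is a triplicate plate over pH 3–10.8; the two pooled pKa
values mean the thiol titrates in two steps, leaving a substantial
thiolate fraction at physiological pH, while the cysteine-free control
shows only pH-independent background. The remaining scripts quantify
zinc protection (`03`, printing ~76%/~56%/ns inhibition for
DBB/TMEA/BMH and an inverse spacer trend), the apparent zinc affinity
(`04`, sub-micromolar K_P with ~2 sites), and crosslink geometry
(`05`, the 4 Å arrangement is DBB- and disulfide-feasible, the 22 Å one
is not; pinned zinc ions are >90% persistent).

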