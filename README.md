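# stomatafit

Tools for asking how much **leaf water potential** improves empirical models
of **stomatal conductance**, and for coupling stomatal closure to xylem
hydraulics — aimed at plant ecophysiologists working with leaf gas-exchange
campaigns (gₛ, A, VPD, CO₂) measured concurrently with pressure-chamber
water potentials.

## The models

Four empirical models of water-vapor stomatal conductance gₛ
(mol m⁻² s⁻¹) are fit per species and compared:

| id | model | form |
|----|-------|------|
| `M` | Medlyn | gₛ = 1.6 (A/Cₛ)(1 + g₁/√D) |
| `BBL` | Ball–Berry–Leuning (no g₀) | gₛ = αA / ((Cₛ − Γ\*)(1 + D/d₁)) |
| `T` | Tuzet variant | gₛ = αA e^(−(\|ψ\|/c)ᵇ) / (Cₛ − Γ\*) |
| `BBL.H` | BBL + hydraulics | gₛ = αA e^(−(\|ψ\|/c)ᵇ) / ((Cₛ − Γ\*)(1 + D/d₁)) |

`M` and `BBL` see only atmospheric drought (VPD = D); `T` and `BBL.H` add a
survival-form Weibull response to leaf water potential ψ (MPa ≤ 0). The
same Weibull, S(ψ) = exp(−(|ψ|/c)ᵇ), parameterizes xylem vulnerability:
`weibull_from_p50_p88` builds it in closed form from the potentials at 50%
and 88% loss of stem conductivity, and `plc` evaluates percent loss.

The package provides:

- **`fitting`** — per-species SSE minimization (multistart Nelder–Mead in
  log-parameter space) with AIC = n ln(SSE/n) + 2k, R², RMSE, and decisive
  model selection at ΔAIC > 3.
- **`partial_dependence`** — a 500-tree bagged-regression-tree surrogate
  gₛ ~ {ψ, D, A, Cₐ}; the marginal gₛ(ψ) curve, rescaled to the observed
  degree of stomatal closure, classified by shape, and inverted for
  **ψ_gs50**, the potential at 50% loss of stomatal conductance.
- **`drought_bias`** — residual regressions against T_leaf, VPD and predawn
  ψ, and the percent over/under-prediction under dry soils (records at or
  below the species' 10th-percentile predawn ψ; negative =
  over-prediction), plus VIF collinearity screens.
- **`hydraulics_link`** — ψ_gs50 vs ψ_x50 (= P50) regression, position
  relative to the 1:1 line, PLC at ψ_gs50.
- **`synthetic`** — a coupled leaf (stomatal model × Farquhar
  photosynthesis × soil-to-leaf water transport ψ_leaf = ψ_soil − E/K) that
  forward-simulates campaigns with known ground truth, wet-skewed sampling
  and realistic measurement noise.

## Worked example

```python
from stomatafit import (make_panel, fit_model, select_model, analyze_species,
                        pct_bias_dry)
from stomatafit.fitting import common_row_mask

truths, datasets, truth_table = make_panel(n_species=3, seed=42)
ds, truth = datasets[2], truths[2]   # a species with measured assimilation

mask = common_row_mask(ds, ["M", "BBL", "BBL.H", "T"])
fits = [fit_model(ds, m, row_mask=mask) for m in ("M", "BBL", "BBL.H", "T")]
sel = select_model(fits)
print("best:", sel.best_model_id)
print({m: round(d, 1) for m, d in sel.delta_aics.items()})

curve = analyze_species(ds, seed=1)
print("psi_gs50 =", round(curve.psi_gs50, 2), "MPa",
      "(truth", round(truth.psi_gs50_true, 2), ")")

bias, n_dry, thresh = pct_bias_dry(fits[0], ds)   # the Medlyn fit
print(f"Medlyn dry-soil bias: {bias:.1f}% over n={n_dry} records")
```

Output (seed 42):

```
best: BBL.H
{'M': 243.3, 'BBL': 207.4, 'BBL.H': 0.0, 'T': 377.8}
psi_gs50 = -1.28 MPa (truth -1.47 )
Medlyn dry-soil bias: -119.8% over n=30 records
```

Read: the campaign was generated from the hydraulic model, and AIC
recovers that decisively (every rival is hundreds of AIC units worse); the
marginal-curve estimate of the closure midpoint lands ~0.2 MPa from the
generating truth; and the ψ-blind Medlyn fit badly over-predicts
conductance in the driest tenth of the campaign (this conservative species
nearly closes its stomata there, so the percent bias is large).

The same pipeline runs from the shell on simulated or measured CSVs
(canonical schema `species, gs_mol_m2_s, A_umol_m2_s, Cs_umol_mol, D_kPa,
Tleaf_C, psi_md_MPa, psi_pd_MPa, PAR_umol_m2_s`; a `column_map` adapts
heterogeneous headers):

```sh
stomatafit report --seed 1 --out run1       # fits, selection, PD, bias, hydraulics
stomatafit show-config                      # default settings as JSON
```

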