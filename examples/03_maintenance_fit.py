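"""Estimating non-growth-associated maintenance (NGAM) from rates.

Generates a synthetic exchange-rate dataset from the toy network with
the maintenance flux set to 2.3 mmol ATP/gDW/h (a high-ethanol stress
scenario), then sweeps maintenance over 0-5 and picks the value whose
predicted growth best matches the observation.
"""

from oenoflux import fit_ngam, make_synthetic_rates, make_toy_lab_model

model, _ = make_toy_lab_model()
rates, truth = make_synthetic_rates(model, true_ngam=2.3, noise_sd_rel=0.0, seed=1)

print(f"observed growth rate: {rates.observed_mu:.4f} 1/h")
print("measured rates fixed as equalities:")
for rec in rates.records:
    print(f"  {rec.reaction_id:10s} {rec.rate:8.4f}  ({rec.direction})")

fit = fit_ngam(model, rates)
print(f"\nrecovered NGAM: {fit.best_ngam:.2f} mmol ATP/gDW/h "
      f"(generated at {truth.true_ngam})")
print(f"predicted growth at the fit: {fit.predicted_mu_at_best:.4f} 1/h")

coarse = [(g, e) for g, e in zip(fit.grid, fit.errors)
          if abs(g * 10 - round(g * 10)) < 1e-9][::10]
print("\nerror curve (relative growth-rate error vs maintenance):")
import math

for g, e in coarse:
    if math.isnan(e):
        print(f"  {g:4.1f}  infeasible")
        continue
    bar = "#" * int(min(e, 0.6) * 80)
    print(f"  {g:4.1f}  {e:8.4f} {bar}")
print("The V-shaped minimum identifies the ATP the cell burns on "
      "survival independent of growth.")
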