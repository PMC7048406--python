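"""Calibrate satellite NDVI against ground NDVI and compose the inversion model.

Plot-mean ground NDVI is regressed on the satellite NDVI of the matching
pixel (SOC = c*TM + d); substituting that line into the exponential ground
biomass model yields one closed-form model from satellite NDVI straight to
biomass.
"""

import grassinvert as gi

campaign = gi.simulate_campaign(gi.CampaignConfig(seed=1))
ground = gi.fit_family(
    campaign.quadrats["soc_ndvi"], campaign.quadrats["agb_g_m2"], "exponential"
)
cross = gi.fit_cross_calibration(campaign.plots)
model = gi.compose(ground, cross)

print(f"ground model:       AGB = {ground.coef_a:.3f} e^({ground.coef_b:.3f} NDVI)"
      f"   (R^2 = {ground.r2:.3f}, n = {ground.n})")
print(f"cross-calibration:  SOC_NDVI = {cross.slope:.3f} TM_NDVI + {cross.intercept:.3f}"
      f"   (R^2 = {cross.r2:.3f}, n = {cross.n})")
print(f"composite:          {model.equation()}")
a_red, b_red = model.reduced_form()
print(f"reduced form:       AGB = {a_red:.3f} e^({b_red:.3f} TM_NDVI)")
# The composite keeps all four parent constants for provenance; the reduced
# two-constant form is algebraically identical and evaluates the same.
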