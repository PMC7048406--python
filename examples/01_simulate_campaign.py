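"""Generate a synthetic grassland field campaign.

Builds the default campaign — 39 plots of 30 x 30 m (one satellite pixel
each) holding 173 one-square-metre quadrats — with quadrat reflectance
spectra, clipped dry biomass, plot-level satellite NDVI and a small NDVI
raster, then prints a summary of what a field team would have brought home.
"""

import grassinvert as gi

campaign = gi.simulate_campaign(gi.CampaignConfig(seed=1))

q, p = campaign.quadrats, campaign.plots
print(f"plots: {len(p)}, quadrats: {len(q)}, spectra rows: {len(campaign.spectra)}")
print(f"quadrat ground NDVI:  {q.soc_ndvi.min():.3f} .. {q.soc_ndvi.max():.3f}")
print(f"quadrat biomass:      {q.agb_g_m2.min():.1f} .. {q.agb_g_m2.max():.1f} g/m2")
print(f"plot satellite NDVI:  {p.tm_ndvi.min():.3f} .. {p.tm_ndvi.max():.3f}")
print(f"raster: {campaign.raster.shape}, valid pixels: {int(campaign.raster.valid_mask().sum())}")
# The NDVI ranges mirror a mid-season grassland gradient from sparse to dense
# cover; biomass spans roughly 30-300 g/m2 of dry weight, and each plot's
# satellite NDVI sits at exactly one raster pixel.
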