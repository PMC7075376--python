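"""Monitor-unit hand calculations: GRID-block look-up and beam-on times.

The single-field GRID-block MU formula is dose / [cGy/MU(dmax) x %DD(r, d)]
for an SSD-100 setup; beam-on time is MU / dose rate.
"""

import gridfire as gf
from gridfire.evaluate import gridblock_mu

# 15 Gy prescribed with a look-up-table %DD of 81.5% at the tumor depth
mu = gridblock_mu(1500.0, pdd_percent=81.5)
print(f"GRID-block: 1500 cGy at %DD 81.5 -> {mu:.1f} MU "
      f"({gf.beam_on_time(mu, 400.0):.1f} min at 400 MU/min)")

# the same formula with the 18 MV model's own %DD table
model = gf.BeamModel.default("18MV")
mu2 = gridblock_mu(1500.0, model, field_size_mm=144.0, depth_mm=100.0)
print(f"18 MV table at 10 cm depth, 14.4 cm field: %DD "
      f"{float(model.pdd(100.0, 144.0)[0]):.1f} -> {mu2:.1f} MU")

# crossfire plans carry more MU but spread over six entrances; rescaling a
# 5.6 min 400 MU/min delivery to 600 MU/min:
print(f"5.6 min at 400 MU/min -> {gf.beam_on_time(5.6 * 400.0, 600.0):.2f} min at 600 MU/min")
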