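"""Build one virtual patient: cochlea, electrode insertion and neural response.

Constructs the mean-shape cochlea, inserts the 12-contact array to 27 mm,
computes the point-source potential of a mid-array contact and shows which
fiber bundles spike.
"""

import numpy as np

import ciuq

shape = ciuq.build_cochlea(ciuq.ShapeWeights(0, 0, 0))
print(f"lamina length      {shape.lamina_length:6.2f} mm   (cochlear size measure)")
print(f"duct length        {shape.duct_length:6.2f} mm   (deepest possible insertion)")

fibers = ciuq.place_fibers(shape)
print(f"fiber bundles      {len(fibers)}        ({fibers.fibers_per_bundle} fibers each)")
print(
    f"tonotopy           {fibers.frequency_hz[0]/1000:.1f} kHz at the base -> "
    f"{fibers.frequency_hz[-1]:.0f} Hz at the apex"
)

insertion = ciuq.insert_array(shape, ciuq.ElectrodeArray(), 27.0)
print(f"achieved depth     {insertion.achieved_mm:6.2f} mm   "
      f"(E1 at {insertion.contact_arc_mm[0]:.1f} mm, E12 at {insertion.contact_arc_mm[-1]:.1f} mm)")

cfg = ciuq.default_config()
field = ciuq.potential_at_fibers(fibers, insertion, "E6", 350.0, 65.0)
act = ciuq.activate_threshold(field, cfg.activation.v_threshold)
span = ciuq.activated_arc_span(fibers, act)
print(f"E6 at 350 uA       {act.spikes.sum()} bundles spike over {span:.2f} mm of arc")
print("The activated span sits near the 3 mm acceptable bandwidth: a focused,"
      " place-specific response.")
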