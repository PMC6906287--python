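"""Size-selective transport through a membrane-spanning DNA nanopore.

Computes Stokes-Einstein diffusion coefficients, hindered-transport rate
constants and translocation verdicts for the three canonical cargoes against
the open and PEG-plugged pore, then prints an efflux half-life for the small
dye from a 200 nm vesicle.
"""

import math

from poretrace.transport import (DEFAULT_PLUGGED_PORE, DEFAULT_PORE,
                                 DFITC_40K, DFITC_500K, SRB, Vesicle,
                                 classify_translocation,
                                 stokes_einstein_diffusion,
                                 transport_rate_constant)

vesicle = Vesicle(id=0, diameter=200.0, content={"SRB": 1000.0})

print("cargo        R_h(nm)  D(nm^2/s)    open pore   plugged pore")
for cargo in (SRB, DFITC_40K, DFITC_500K):
    d = stokes_einstein_diffusion(cargo.hydrodynamic_radius, 298.0, 1e-3)
    v_open = classify_translocation(DEFAULT_PORE, cargo)
    v_plug = classify_translocation(DEFAULT_PLUGGED_PORE, cargo)
    print(f"{cargo.name:12s} {cargo.hydrodynamic_radius:7.1f}  {d:9.3g}"
          f"    {v_open:9s}   {v_plug}")

k = transport_rate_constant(DEFAULT_PORE, SRB, vesicle)
print(f"\nSRB efflux rate constant from a 200 nm vesicle: {k:.3g} /s "
      f"(half-life {math.log(2) / k:.3g} s)")
print("The verdicts reproduce the dye-gating experiment: the small dye "
      "always passes, the 40 kDa dextran is slowed by the open pore and "
      "stopped by the plug, and the 500 kDa dextran never fits.")
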