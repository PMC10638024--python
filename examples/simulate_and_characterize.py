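"""Build a small active cell and run the characterization protocol suite.

Constructs a soma + basal-stick morphology with an AIS and myelin sink,
applies an e-model (conductance densities per region), finds the holding
current that keeps the soma at -83 mV and the rheobase by bisection, and
runs 150%/200%-rheobase steps, printing the extracted spike-train features.
"""

import numpy as np

from empop import fixtures, morph, protocols, sim

sec = morph.Section(
    id=0, stype="basal",
    points=np.array([[0, 0, 0, 2.0], [0, 200, 0, 1.5], [0, 400, 0, 1.0]]),
)
m = morph.Morphology(soma_radius=8.0, soma_length=8.0, sections={0: sec})
m = morph.attach_ais_and_myelin(m, ais_diameter=1.2)

params = {**fixtures.BASE_PARAMS, **fixtures.P_TRUE}
cell = sim.build_cell(m, params)
fv = protocols.run_suite(cell, protocols.ProtocolSuite(step_duration=500.0))

print("holding current (nA):", round(fv[("global", "holding_current")], 4))
print("rheobase step (nA):  ", round(fv[("global", "threshold_current")], 4))
for (proto, name), value in sorted(fv.items()):
    if proto.startswith("step"):
        print(f"  {proto:9s} {name:24s} {value:10.3f}")
print(
    "\nThe holding current is the bias needed to sit at -83 mV; the rheobase"
    "\nis the smallest step above it that elicits a spike.  Step features"
    "\n(frequency in Hz, amplitudes/depths in mV, latencies in ms) are the"
    "\nquantities the model cost compares against experimental targets."
)
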