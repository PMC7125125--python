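"""Conduction block in 2-D tissue under an alternating extracellular field.

A plaque-laden bidomain sheet (gap junctions removed along random fiber
segments) carries a plane wave; an AC field applied across the left/right
boundaries polarizes the membrane at the conductivity discontinuities
(virtual electrodes).  The fraction of tissue captured into sustained
depolarization grows with the field strength and falls at higher frequency.
"""

import copy

import numpy as np

from isoflok.bidomain import (BidomainSolver, FieldProtocol, NO_FIELD,
                              TissueGrid, generate_fiber_plaques,
                              run_field_trial)
from isoflok.zoo import build_surrogate_cardiomyocyte

cell = build_surrogate_cardiomyocyte()
base = TissueGrid(nx=50, ny=50, dx=0.0566)
grid = generate_fiber_plaques(base, n_segments=30, seed=11)
print("plaques:", grid.plaque_summary)

solver = BidomainSolver(grid, cell, dt=0.02)
state = solver.initial_state()


def stripe(t):
    if t <= 4.0:
        I = np.zeros((solver.ny, solver.nx))
        I[:, :4] = 15.0
        return I
    return None


state = solver.run(state, NO_FIELD, 30.0, I_stim_fn=stripe)  # launch a wave

for freq, E in [(33.0, 2.0), (33.0, 6.0), (33.0, 18.0), (100.0, 6.0)]:
    res = run_field_trial(copy.deepcopy(state), solver,
                          FieldProtocol(frequency=freq, strength=E,
                                        duration=250.0),
                          post_window=20.0)
    print(f"{freq:5.0f} Hz, {E:4.1f} V/cm: block fraction = "
          f"{res.block_fraction:.3f}")

# Stronger fields recruit more tissue into conduction block near the
# virtual electrodes; at 100 Hz the same strength blocks less than at
# 33 Hz, consistent with the weaker alpha_1 at short stimulation periods.
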