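"""Train a hitchhiker and inspect its decision rule.

Runs a handful of independent training cycles in the standard achiral bath
and aggregates them into a decision diagram.  The GO angle is the width of
the arc of partner orientations the agent accepts; the anticipation angle
is the arc centre relative to the goal direction (zero here, because the
bath has no chirality to anticipate).
"""

import numpy as np

from ihp import BathParams, TrainConfig, train

bath = BathParams()  # rho=0.6, L=25, v0=1.5, D_r=6*pi^2*1e-3
cfg = TrainConfig()  # alpha=0.01, gamma=0.9, 1000 episodes per cycle

result = train(bath, cfg, seed=42, n_cycles=4)
diagram = result.diagram

print(f"bath: N={bath.n_particles}, persistence length l_p={bath.persistence_length:.1f} R_s")
print(f"GO angle       dphi = {diagram.go_angle:.3f} rad "
      f"({np.degrees(diagram.go_angle):.0f} deg of accepted partner headings)")
print(f"anticipation  phi0 = {diagram.anticipation_angle:+.3f} rad "
      "(~0: no chirality to anticipate)")
print(f"last cycle: mean episode duration fell from "
      f"{result.last_cycle.durations[:100].mean():.0f} tau_Q (first 100 episodes) to "
      f"{result.last_cycle.durations[-100:].mean():.0f} tau_Q (last 100)")
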