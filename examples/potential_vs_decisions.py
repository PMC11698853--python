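"""Decision-driven vs. potential-driven hitchhiking at short times.

The same decision diagram drives two transport models: the discrete agent
(one decision per perception time, one partner at a time) and the
potential agent (continuously pulled by every suitable particle in
range).  In a dense bath the potential variant gets moving faster — it
never waits for a decision epoch — while the probability of an instantly
suitable partner is also larger because it is not limited to the nearest
particle.  Paired seeds give both models identical baths.
"""

import numpy as np

from ihp import (
    BathParams,
    DecisionDiagram,
    TheoryParams,
    p0,
    p0_potential,
    simulate_potential_ihp,
    simulate_q_ihp,
)

bath = BathParams(density=2.0)
diagram = DecisionDiagram.from_interval(0.0, np.pi / 2)

d_q, d_pot = [], []
for r in range(200):
    ss = np.random.SeedSequence((77, r))
    tq = simulate_q_ihp(diagram, bath, 1.0, np.random.Generator(np.random.PCG64(ss)))
    tp = simulate_potential_ihp(diagram, bath, 1.0, np.random.Generator(np.random.PCG64(ss)))
    d_q.append(np.hypot(*tq.positions[-1]))
    d_pot.append(np.hypot(*tp.positions[-1]))

theory = TheoryParams(density=2.0, go_angle=diagram.go_angle)
print(f"dense bath rho = 2/R_s^2 (N = {bath.n_particles})")
print(f"instant partner probability: decisions {p0(theory):.3f}  potential {p0_potential(theory):.3f}")
print(f"mean displacement after one perception time:")
print(f"  decision agent  {np.mean(d_q):.3f} R_s")
print(f"  potential agent {np.mean(d_pot):.3f} R_s "
      f"({np.mean(d_pot) / np.mean(d_q):.2f}x faster start)")
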