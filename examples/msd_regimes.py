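"""Transport regimes of a trained hitchhiker.

Simulates an ensemble of greedy hitchhikers driven by an idealised
decision diagram and compares the mean-squared displacement with (i) the
closed form for a free bath particle, which turns diffusive beyond its
persistence time, and (ii) the drift theory built from the partner
probability p(t).  The hitchhiker ends ballistic (log-log slope 2) and
eventually outruns any single bath particle.
"""

import numpy as np

from ihp import (
    BathParams,
    DecisionDiagram,
    TheoryParams,
    abp_msd_closed_form,
    ensemble_msd,
    loglog_slope,
    msd_theory,
    p0,
    simulate_q_ihp,
)

bath = BathParams()
tau = bath.persistence_time
diagram = DecisionDiagram.from_interval(0.0, np.pi / 2)

runs = []
for r in range(60):
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((2024, r))))
    runs.append(simulate_q_ihp(diagram, bath, round(60 * tau), rng))
curve = ensemble_msd(runs)

tp = TheoryParams(go_angle=diagram.go_angle)
_, msd_inf = msd_theory(tp, curve.times)

print(f"partner probability p(0) = {p0(tp):.4f}")
print(f"late-time log-log MSD slope = {loglog_slope(curve, (15 * tau, 60 * tau)):.3f} (ballistic: 2)")
for mult in (1, 5, 20, 50):
    t = mult * tau
    i = int(np.argmin(np.abs(curve.times - t)))
    print(f"t = {mult:3d} tau: MSD = {curve.msd[i]:11.1f}  free ABP = "
          f"{abp_msd_closed_form(t, bath):10.1f}  drift bound = {msd_inf[i]:11.1f}")
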