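"""Herding costs at the deep stag-hunt corner (S=-1, T=0) on a scale-free
population.

The plain pairwise game collapses to defection here at moderate population
sizes, because defectors never earn less than zero while cooperators risk
the sucker's payoff.  Adding the herding mentality as a co-evolving trait
enlarges the basin of the cooperative outcome: nonconforming defector hubs
pay large conformity costs and stop being imitated.  At the small size used
here the outcome is bistable, so individual realizations land on full
cooperation or full defection.
"""

import numpy as np

from herdsim import (
    DynamicsParams,
    GameParams,
    HerdingParams,
    SimConfig,
    run_experiment,
    scale_free_factory,
)

factory = scale_free_factory(500, 2)
sc = SimConfig(max_steps=1500, realizations=5, master_seed=7, record_payoffs=False)

plain = run_experiment(None, GameParams(S=-1, T=0), HerdingParams(tau=0.0),
                       DynamicsParams(variant="pairwise_plain"), sc,
                       network_factory=factory)
four = run_experiment(None, GameParams(S=-1, T=0), HerdingParams(tau=1.0),
                      DynamicsParams(variant="four_strategy"), sc,
                      network_factory=factory)

print(f"plain pairwise game : cooperation = {plain.cooperation_mean:.3f} "
      f"(+/- {plain.cooperation_std:.3f} across realizations)")
print(f"four-strategy, tau=1: cooperation = {four.cooperation_mean:.3f} "
      f"(+/- {four.cooperation_std:.3f}), herders = {four.herder_mean:.3f}")
print("Cooperation near 0 means the realization(s) fixed on defection; a large")
print("std signals bistability (some runs reached the cooperative attractor).")
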