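"""Recover perturbed kinetic parameters from synthetic observations.

Generates a noise-free dataset from the calibrated model, perturbs two
parameters by +/-30%, and fits them back with bounded least squares on log
residuals.
"""

from hsckinetics import (
    ExchangeSchedule,
    ModelKind,
    NoiseModel,
    default_params,
    fit,
    generate_observations,
)

kind = ModelKind.three_state
truth = default_params(kind)
sched = ExchangeSchedule(frequency=2.0)
observed = generate_observations(kind, truth, sched, noise=NoiseModel(kind="none"))

free = ["PR_max_Term", "DR_LSKtoTerm"]
init = truth.with_updates(PR_max_Term=truth.PR_max_Term * 1.3,
                          DR_LSKtoTerm=truth.DR_LSKtoTerm * 0.7)
result = fit(observed, kind, sched, init, free, rtol=1e-6)

print(f"final loss: {result.loss:.3g} (converged: {result.converged})")
for name in free:
    print(f"  {name:14s} truth {truth.get(name):8.4f}  "
          f"recovered {result.params.get(name):8.4f}")

# With noise-free data the optimizer returns to the generating values; the
# loss is the sum of squared log-count residuals over all states and times.
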