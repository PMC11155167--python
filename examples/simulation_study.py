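"""Compare Single, Multi and DLM analyses on correlated exposures.

Runs a reduced replication study (Scenario 1: constant true effect 0.15
at every lag) at exposure correlation gamma = 0.975 and prints bias,
empirical SE and MSE per model at three canonical times, on the x100
reporting scale.  The Single model's bias (~+1.0 raw, i.e. ~100 on the
x100 scale) shows it absorbing the effects of the nine other correlated
waves; the Multi model is unbiased but noisy; the DLM is unbiased with
the smallest MSE.
"""

from fpdlm import compute_metrics, make_scenario, run_replications

scenario = make_scenario(1)
results = run_replications(scenario, gamma=0.975, n=10000, reps=100, master_seed=7)
table = compute_metrics(results, scenario, gamma=0.975)

print(f"Scenario 1, gamma=0.975, {table.n_reps} replications, n=10000 "
      f"(failures: {table.n_failed})\n")
print("time  model   bias(x100)  EmpSE(x100)  MSE(x100)")
for t in (12.0, 24.0, 36.0):
    for model in ("single", "multi", "dlm"):
        print(f" {t:4.0f}  {model:6s}  {table.value('bias', model, t):9.1f}"
              f"  {table.value('empse', model, t):10.1f}"
              f"  {table.value('mse', model, t):8.1f}")
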