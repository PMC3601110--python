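"""Emergence of a shared formal marker system under lateral inhibition."""

import numpy as np

from agreemark import ExperimentConfig, run_series

config = ExperimentConfig(strategy="formal", games=1000, series=10, seed=5)
result = run_series(config)
agg = result.aggregate
g = agg["game"].to_numpy()

print("formal strategy, 10 series x 1,000 games, 10 agents, "
      "turnover 5/1000\n")
print(" game    U      V      I      E   success")
for n in (25, 50, 100, 200, 300, 500, 1000):
    i = int(np.searchsorted(g, n))
    row = agg.iloc[i]
    print(f"{n:>5}  {row['U']:5.1f}  {row['V']:5.2f}  {row['I']:5.1f}"
          f"  {row['E']:5.2f}  {row['success']:7.2f}")

peak = int(g[np.argmax(agg["U"].to_numpy())])
print(f"\nusage peaks near game {peak}, then lateral inhibition damps the")
print("inventory to ~3 markers (one per possible topic object), variation")
print("V falls towards 0 as the population agrees on which forms to use,")
print(f"and efficiency E = U/I ends near {agg['E'].iloc[-1]:.2f}.")
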