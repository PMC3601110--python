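"""Why recruiting existing words beats inventing marker forms de novo."""

import numpy as np

from agreemark import ExperimentConfig, run_series
from agreemark.measures import inventory_size, usage

GAMES, SERIES, SEED = 3000, 4, 11

for strategy in ("meaningful", "reuse"):
    cfg = ExperimentConfig(
        strategy=strategy, games=GAMES, series=SERIES, seed=SEED,
        turnover=0.0, measure_stride=50,
    )
    result = run_series(cfg)
    invented = np.mean([
        inventory_size(s.records, GAMES, s.initial_forms)
        for s in result.series
    ])
    active = np.mean([usage(s.records, GAMES, 500) for s in result.series])
    v = result.aggregate["V"].iloc[-1]
    print(f"{strategy:>10}: {invented:5.1f} marker forms ever introduced, "
          f"{active:4.1f} in active use, final variation V={v:.3f}")

print(
    "\nBoth strategies converge on roughly one marker per attribute-value\n"
    "pair, but de-novo invention lets several agents coin different forms\n"
    "for the same meaning before one wins, while reuse recruits the same\n"
    "shared word everywhere -- far fewer forms ever circulate."
)
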