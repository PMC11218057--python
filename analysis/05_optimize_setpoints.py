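"""Desirability optimization of the fitted campaign models.

Three single-attribute optimizers (fast growth, OCT4 pluripotency, aggregate
stability) plus a combined optimizer over all three criteria, each reporting
the setpoint in actual concentrations, overall desirability, per-criterion
Cpk, probability of failure, and factor contributions.
Writes results/setpoint_<name>.json.
"""

import json
from pathlib import Path

import pandas as pd

from aggdoe.design import DesignTable, default_factors, interaction_model
from aggdoe.modeling import fit_campaign
from aggdoe.optimize import Criterion, optimize_setpoint

SEED = 0
RESULTS = Path(__file__).resolve().parent.parent / "results"

SCENARIOS = {
    # minimize doubling time = maximal growth
    "growth": [Criterion("doubling_time", "minimize", lower=1.0, upper=2.2)],
    # maximal OCT4 expression (fitted on the neglog scale: smaller is better)
    "pluripotency": [Criterion("OCT4_flow", "minimize", lower=0.02, upper=0.30)],
    # aggregate stability: % error near zero, i.e. size change from growth only
    "stability": [
        Criterion("aggregate_pct_error", "target", lower=-0.5, upper=0.5, target=0.0)
    ],
}


def main() -> None:
    factors = default_factors()
    design = DesignTable.read_csv(RESULTS / "design.csv", factors)
    responses = pd.read_csv(RESULTS / "responses.csv").set_index("run_id")
    fits = fit_campaign(design, responses, interaction_model(factors))

    combined = [c for crits in SCENARIOS.values() for c in crits]
    for name, criteria in {**SCENARIOS, "combined": combined}.items():
        sp = optimize_setpoint(fits, criteria, seed=SEED, factors=factors)
        (RESULTS / f"setpoint_{name}.json").write_text(
            json.dumps(sp.to_dict(), indent=1, sort_keys=True)
        )
        settings = ", ".join(f"{k} {v:.3g}" for k, v in sp.actual.items())
        print(f"{name}: D = {sp.desirability:.3f} at {settings}")
        for resp, val in sp.predicted.items():
            extras = []
            if resp in sp.cpk:
                extras.append(f"Cpk {sp.cpk[resp]:.2f}")
            if resp in sp.probability_of_failure:
                extras.append(f"P(fail) {sp.probability_of_failure[resp]:.1f}%")
            top = max(sp.factor_contributions[resp].items(), key=lambda kv: kv[1])
            extras.append(f"top factor {top[0]} ({top[1]:.0f}%)")
            print(f"    {resp}: predicted {val:.3g} ({', '.join(extras)})")


if __name__ == "__main__":
    main()
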