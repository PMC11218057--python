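"""Fit interaction models per response and assess their quality.

Each response is regressed on the 16-term main + two-factor-interaction
model in coded units (neglog transform on the skewed OCT4/TRA-1-60 flow
responses) and scored with R2, Q2, validity and reproducibility.  Also
writes the Pearson correlation matrix between responses.
Writes results/models.json, results/model_metrics.csv, results/corr.csv.
"""

import json
from pathlib import Path

import pandas as pd

from aggdoe.design import DesignTable, default_factors, interaction_model
from aggdoe.modeling import correlation_matrix, fit_campaign

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    factors = default_factors()
    design = DesignTable.read_csv(RESULTS / "design.csv", factors)
    responses = pd.read_csv(RESULTS / "responses.csv").set_index("run_id")
    fits = fit_campaign(design, responses, interaction_model(factors))
    (RESULTS / "models.json").write_text(
        json.dumps({k: f.to_dict() for k, f in fits.items()}, indent=1, sort_keys=True)
    )
    metrics = pd.DataFrame(
        {
            k: {
                "r2": f.r2, "q2": f.q2,
                "validity": f.validity, "reproducibility": f.reproducibility,
            }
            for k, f in fits.items()
        }
    ).T
    metrics.index.name = "response"
    metrics.to_csv(RESULTS / "model_metrics.csv")
    r, p = correlation_matrix(responses.dropna(axis=1, how="any"))
    r.to_csv(RESULTS / "corr.csv")
    p.to_csv(RESULTS / "corr_pvalues.csv")
    print("model quality (coded-space interaction fits):")
    print(metrics.round(3).to_string())
    worst = metrics["r2"].idxmin()
    print(f"\nweakest fit: {worst} (R2 = {metrics.loc[worst, 'r2']:.3f})")


if __name__ == "__main__":
    main()
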