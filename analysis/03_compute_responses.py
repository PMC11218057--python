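"""Turn raw series and endpoint assays into the modeling response table.

Fits per-reactor growth rates, summarizes aggregate diameters, runs the
volume -> cells -> prediction -> % error chain, decodes qPCR Ct pairs to
expression units, then applies the multiplicative center-point batch
normalization (the signed aggregate % error is left unnormalized).
Writes results/responses.csv.
"""

from pathlib import Path

import pandas as pd

from aggdoe.design import DesignTable, default_factors
from aggdoe.kinetics import series_from_frame
from aggdoe.modeling import normalize_to_center_points
from aggdoe.pipeline import assemble_responses, default_normalized_columns

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    design = DesignTable.read_csv(RESULTS / "design.csv", default_factors())
    series = series_from_frame(pd.read_csv(RESULTS / "series.csv"))
    endpoints = pd.read_csv(RESULTS / "endpoints.csv").set_index("run_id")
    responses = assemble_responses(design, series, endpoints)
    responses = normalize_to_center_points(
        responses, design, columns=default_normalized_columns(responses)
    )
    responses.to_csv(RESULTS / "responses.csv")
    print(
        f"{responses.shape[1]} responses x {responses.shape[0]} runs -> "
        f"{RESULTS / 'responses.csv'}"
    )
    summary = responses[["growth_rate", "doubling_time", "aggregate_pct_error"]]
    print(summary.describe().loc[["mean", "min", "max"]].round(3).to_string())


if __name__ == "__main__":
    main()
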