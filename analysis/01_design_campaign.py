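"""Generate the screening campaign design.

Builds the 16-run D-optimal interaction design over the five media additives
(DS, HS, PVA, PA, PEG), appends 3 replicated center points and splits the 19
conditions over 2 batches so each batch carries a normalization anchor.
Writes results/design.csv and prints the design scores.
"""

from pathlib import Path

from aggdoe.design import (
    add_center_points,
    assign_batches,
    d_optimal_search,
    default_factors,
    interaction_model,
    score_design,
)

SEED = 0
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    factors = default_factors()
    model = interaction_model(factors)
    runs = d_optimal_search(factors, model, n_runs=16, seed=SEED)
    score = score_design(runs, model)
    design = assign_batches(add_center_points(runs, 3), n_batches=2, seed=SEED)
    design.write_csv(RESULTS / "design.csv")
    print(
        f"16-run D-optimal design for p={model.p} interaction model: "
        f"log|X'X| = {score.log_det:.3f}, G-efficiency = {score.g_efficiency:.1f}%"
    )
    print(
        f"with center points and batches: {design.n_runs} conditions, "
        f"{int(design.is_center.sum())} center, "
        f"{len(set(design.batch))} batches -> {RESULTS / 'design.csv'}"
    )


if __name__ == "__main__":
    main()
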