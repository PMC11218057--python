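"""Synthetic bioreactor campaigns with known ground truth.

The generator emulates the structure of a 19-condition suspension-culture
screen: a D-optimal design over five media additives run in two batches with
three shared center points, four days of daily sampling per reactor, and a
panel of endpoint assays.  Everything downstream of the wet lab is emulated:

* counts     — triplicate daily cell concentrations N0·exp(K(x)·t) with
               multiplicative lognormal noise; K(x) is linear in the coded
               settings plus interactions,
* aggregates — an explicit population of aggregates (a representative
               subsample of the reactor) whose per-aggregate cell numbers
               grow exponentially and which undergo Poisson pairwise fusion
               (volumes add) and binary fragmentation; daily diameter
               samples of >= 30 aggregates are drawn from it,
* endpoints  — flow-marker percentages generated on the logit scale, qPCR
               Ct pairs that decode to a linear expression truth through the
               1000/2^ΔCt rule, and viability; all subject to a
               multiplicative assay-batch effect.

Because the truth coefficients are known, parameter recovery, coverage and
monotonicity of the whole analysis chain can be tested without any real
culture data.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import (
    DesignTable,
    ModelSpec,
    add_center_points,
    assign_batches,
    d_optimal_search,
    default_factors,
    interaction_model,
    model_matrix,
)
from .kinetics import (
    GeometryConstants,
    ReactorSeries,
    diameter_from_volume,
    sphere_volume,
)

__all__ = [
    "SimTruth",
    "SimCampaign",
    "default_truth",
    "simulate_reactor",
    "simulate_campaign",
    "paper_shape_design",
    "make_fixture",
    "FIXTURE_TAGS",
]

FACTORS = ["DS", "HS", "PVA", "PA", "PEG"]

FLOW_RESPONSES = ["OCT4_flow", "SOX2_flow", "SSEA4_flow", "TRA160_flow"]
QPCR_RESPONSES = ["NANOG_qpcr", "OCT4_qpcr", "SOX2_qpcr"]

# responses whose generative truth is linear on the scale the model is
# fitted on; coefficient-recovery/coverage checks are restricted to these
LINEAR_TRUTH_RESPONSES = ["growth_rate"] + QPCR_RESPONSES + ["viability"]


@dataclass
class SimTruth:
    """Ground-truth parameters of the generator.

    Coefficient dicts map term name ("PEG", "HS:PEG", ...) to its coded-space
    effect.  Fusion/fragmentation rates use an exponential link
    λ(x) = λ0·exp(Σ γ_term·term(x)) so they stay positive and monotone in
    each γ.
    """

    factor_names: list[str] = field(default_factory=lambda: list(FACTORS))
    model: ModelSpec | None = None

    # growth: K(x) = K0 + Σ beta_K[term]·term(x), per day
    K0: float = 0.40
    beta_K: dict[str, float] = field(default_factory=dict)
    N0: float = 1.1e5  # seeding density, cells/ml
    count_cv: float = 0.10  # lognormal CV of replicate counts

    # aggregate population
    n_aggregates: int = 300
    d1_mean: float = 80.0  # µm, day-1 mean diameter
    d1_sigma_log: float = 0.20  # lognormal sd of initial diameters
    diameter_meas_sigma: float = 0.03  # lognormal measurement noise
    n_diameter_samples: int = 40  # per day (>= 30 as in the assay)
    fusion_lam0: float = 0.05  # events/aggregate/day at center
    gamma_fusion: dict[str, float] = field(default_factory=dict)
    frag_lam0: float = 0.0
    gamma_frag: dict[str, float] = field(default_factory=dict)

    # endpoint assays
    marker_logit0: dict[str, float] = field(default_factory=dict)
    beta_marker: dict[str, dict[str, float]] = field(default_factory=dict)
    marker_sigma: float = 0.15  # logit-scale noise
    qpcr_base: dict[str, float] = field(default_factory=dict)  # expression units
    beta_qpcr: dict[str, dict[str, float]] = field(default_factory=dict)
    qpcr_sigma: float = 30.0  # expression-unit noise
    ct_housekeeping: float = 18.0
    viability0: float = 92.0
    beta_viability: dict[str, float] = field(default_factory=dict)
    viability_sigma: float = 1.5
    batch_sigma: float = 0.02  # sd of log multiplicative batch effect
    days: int = 4

    def __post_init__(self) -> None:
        if self.model is None:
            self.model = interaction_model(self.factor_names)

    def term_value(self, coded: np.ndarray, coef: dict[str, float]) -> float:
        """Σ coef[term]·term(x) for one coded point (no intercept column)."""
        X = model_matrix(np.atleast_2d(coded), self.model, self.factor_names)[0]
        names = self.model.term_names
        return float(sum(coef.get(n, 0.0) * X[names.index(n)] for n in coef))

    def growth_rate(self, coded: np.ndarray) -> float:
        return self.K0 + self.term_value(coded, self.beta_K)

    def fusion_rate(self, coded: np.ndarray) -> float:
        return self.fusion_lam0 * math.exp(self.term_value(coded, self.gamma_fusion))

    def frag_rate(self, coded: np.ndarray) -> float:
        return self.frag_lam0 * math.exp(self.term_value(coded, self.gamma_frag))

    def zero_noise(self) -> "SimTruth":
        """Copy with every stochastic component switched off (incl. fusion)."""
        return dataclasses.replace(
            self,
            count_cv=0.0,
            d1_sigma_log=0.0,
            diameter_meas_sigma=0.0,
            fusion_lam0=0.0,
            frag_lam0=0.0,
            marker_sigma=0.0,
            qpcr_sigma=0.0,
            viability_sigma=0.0,
            batch_sigma=0.0,
        )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["model"] = {
            "main_terms": list(self.model.main_terms),
            "interaction_terms": [list(t) for t in self.model.interaction_terms],
            "extra_terms": [list(t) for t in self.model.extra_terms],
            "include_intercept": self.model.include_intercept,
        }
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        m = d.pop("model")
        model = ModelSpec(
            main_terms=tuple(m["main_terms"]),
            interaction_terms=tuple(tuple(t) for t in m["interaction_terms"]),
            extra_terms=tuple(tuple(t) for t in m["extra_terms"]),
            include_intercept=m["include_intercept"],
        )
        return cls(model=model, **d)


def default_truth() -> SimTruth:
    """Default campaign truth.

    Signs and rough magnitudes mirror the qualitative findings of the study
    system: PA/PVA/PEG speed growth with a PA:PEG synergy; PEG raises
    OCT4/SOX2; DS pushes OCT4 down and NANOG up; HS and PEG suppress fusion
    with a negative HS:PEG interaction; DS/PA/PVA promote fusion.
    """
    return SimTruth(
        beta_K={"PA": 0.030, "PVA": 0.020, "PEG": 0.020, "PA:PEG": 0.015},
        gamma_fusion={
            "DS": 0.5, "PA": 0.4, "PVA": 0.4,
            "HS": -0.4, "PEG": -0.3, "HS:PEG": -0.4,
        },
        marker_logit0={
            "OCT4_flow": 2.2, "SOX2_flow": 2.5, "SSEA4_flow": 2.8, "TRA160_flow": 2.0,
        },
        beta_marker={
            "OCT4_flow": {"PEG": 0.35, "DS": -0.25, "HS": 0.15, "HS:PEG": 0.20},
            "SOX2_flow": {"PEG": 0.30, "PA": 0.20, "HS": -0.15, "DS": -0.20},
            "SSEA4_flow": {"PEG": 0.15, "DS": -0.10},
            "TRA160_flow": {"PEG": 0.35, "DS": -0.25, "HS": 0.12, "HS:PEG": 0.18},
        },
        qpcr_base={"NANOG_qpcr": 900.0, "OCT4_qpcr": 1200.0, "SOX2_qpcr": 1000.0},
        beta_qpcr={
            "NANOG_qpcr": {"DS": 120.0, "HS": 60.0, "PA": 40.0, "PEG": 30.0, "DS:HS": 50.0},
            "OCT4_qpcr": {"PEG": 150.0, "DS": -80.0, "HS": 50.0, "HS:PEG": 60.0},
            "SOX2_qpcr": {"PEG": 100.0, "PA": 60.0, "HS": -40.0, "PVA:PEG": 40.0},
        },
        beta_viability={"PA": 1.0, "PEG": 0.5, "DS": -0.8},
    )


def _grow_and_mix(
    cells: np.ndarray, K: float, lam_f: float, lam_b: float, rng: np.random.Generator
) -> np.ndarray:
    """Advance the aggregate population one day.

    Exponential growth of per-aggregate cell numbers, then Poisson pairwise
    fusions (cell numbers, hence volumes, add; count drops by 1 per event)
    and Poisson binary fragmentations (one aggregate splits roughly in half).
    """
    cells = cells * math.exp(K)
    n = len(cells)
    n_fuse = rng.poisson(lam_f * n) if lam_f > 0 else 0
    n_fuse = min(n_fuse, n // 2)
    if n_fuse > 0:
        idx = rng.permutation(n)
        a, b = idx[:n_fuse], idx[n_fuse : 2 * n_fuse]
        cells[a] = cells[a] + cells[b]
        cells = np.delete(cells, b)
    n = len(cells)
    n_frag = rng.poisson(lam_b * n) if lam_b > 0 else 0
    n_frag = min(n_frag, n)
    if n_frag > 0:
        idx = rng.choice(n, size=n_frag, replace=False)
        frac = rng.uniform(0.4, 0.6, size=n_frag)
        new = cells[idx] * (1.0 - frac)
        cells[idx] = cells[idx] * frac
        cells = np.concatenate([cells, new])
    return cells


def simulate_reactor(
    coded: np.ndarray,
    truth: SimTruth,
    days: int | None = None,
    seed: int = 0,
    geom: GeometryConstants = GeometryConstants(),
    run_id: str = "R1",
) -> ReactorSeries:
    """Simulate one bioreactor run: daily counts and aggregate diameters.

    Days are numbered 0..days with counts from day 0 (seeding) and
    diameters from day 1 (aggregates have formed) onward.  Deterministic
    per seed.
    """
    days = truth.days if days is None else days
    if days < 2:
        raise ValueError("need at least 2 days")
    rng = np.random.default_rng(seed)
    K = truth.growth_rate(coded)
    lam_f = truth.fusion_rate(coded)
    lam_b = truth.frag_rate(coded)

    counts: dict[int, np.ndarray] = {}
    sigma_c = (
        math.sqrt(math.log(1.0 + truth.count_cv**2)) if truth.count_cv > 0 else 0.0
    )
    for t in range(days + 1):
        mean = truth.N0 * math.exp(K * t)
        noise = (
            rng.lognormal(-0.5 * sigma_c**2, sigma_c, size=3)
            if sigma_c > 0
            else np.ones(3)
        )
        counts[t] = mean * noise

    # day-1 population: lognormal diameters around d1_mean, converted to cells
    n0 = truth.n_aggregates
    if truth.d1_sigma_log > 0:
        ln_d = rng.normal(
            math.log(truth.d1_mean) - 0.5 * truth.d1_sigma_log**2,
            truth.d1_sigma_log,
            size=n0,
        )
        diam1 = np.exp(ln_d)
    else:
        diam1 = np.full(n0, truth.d1_mean)
    vol1 = sphere_volume(diam1 / 2.0)
    cells = vol1 / geom.cell_volume * geom.packing_density

    diameters: dict[int, np.ndarray] = {}
    viability: dict[int, float] = {}

    def sample_diameters(cells_now: np.ndarray) -> np.ndarray:
        vols = cells_now * geom.cell_volume / geom.packing_density
        diams = diameter_from_volume(vols)
        k = min(truth.n_diameter_samples, len(diams))
        take = rng.choice(len(diams), size=k, replace=False)
        d = diams[take]
        if truth.diameter_meas_sigma > 0:
            d = d * rng.lognormal(
                -0.5 * truth.diameter_meas_sigma**2,
                truth.diameter_meas_sigma,
                size=k,
            )
        return d

    diameters[1] = sample_diameters(cells)
    for t in range(2, days + 1):
        cells = _grow_and_mix(cells, K, lam_f, lam_b, rng)
        diameters[t] = sample_diameters(cells)
    for t in range(1, days + 1):
        viability[t] = float(
            np.clip(truth.viability0 + truth.term_value(coded, truth.beta_viability), 0, 100)
        )
    return ReactorSeries(run_id=run_id, counts=counts, diameters=diameters, viability=viability)


@dataclass
class SimCampaign:
    design: DesignTable
    series: list[ReactorSeries]
    endpoints: pd.DataFrame  # per-run assay endpoints (markers %, Ct, viability)
    truth: SimTruth


def paper_shape_design(
    n_runs: int = 16,
    n_center: int = 3,
    n_batches: int = 2,
    seed: int = 0,
    factors=None,
    model: ModelSpec | None = None,
) -> DesignTable:
    """The study-shaped design: D-optimal runs + center points over batches."""
    factors = default_factors() if factors is None else factors
    model = interaction_model(factors) if model is None else model
    design = d_optimal_search(factors, model, n_runs=n_runs, seed=seed)
    design = add_center_points(design, n_center)
    return assign_batches(design, n_batches, seed=seed)


def simulate_campaign(
    design: DesignTable, truth: SimTruth | None = None, seed: int = 0
) -> SimCampaign:
    """Simulate every reactor of a design plus the endpoint assay tables.

    Endpoint responses get a shared multiplicative batch effect (flow/qPCR
    assay batches); center points share settings but have independent noise.
    """
    truth = default_truth() if truth is None else truth
    rng = np.random.default_rng(seed)
    batches = pd.unique(design.batch)
    log_batch = {
        b: (rng.normal(0.0, truth.batch_sigma) if truth.batch_sigma > 0 else 0.0)
        for b in batches
    }

    series = []
    rows = []
    child = rng.spawn(design.n_runs)
    for i in range(design.n_runs):
        x = design.coded[i]
        run_rng = child[i]
        s = simulate_reactor(
            x, truth, seed=run_rng.integers(2**31), run_id=design.run_ids[i]
        )
        series.append(s)
        bfac = math.exp(log_batch[design.batch[i]])
        row = {"run_id": design.run_ids[i]}
        for name in FLOW_RESPONSES:
            eta = truth.marker_logit0.get(name, 2.0) + truth.term_value(
                x, truth.beta_marker.get(name, {})
            )
            eta += math.log(bfac)  # batch effect on the odds scale
            if truth.marker_sigma > 0:
                eta += run_rng.normal(0.0, truth.marker_sigma)
            row[name] = float(np.clip(100.0 / (1.0 + math.exp(-eta)), 0.0, 100.0))
        for name in QPCR_RESPONSES:
            expr = truth.qpcr_base.get(name, 1000.0) + truth.term_value(
                x, truth.beta_qpcr.get(name, {})
            )
            if truth.qpcr_sigma > 0:
                expr += run_rng.normal(0.0, truth.qpcr_sigma)
            expr = max(expr, 1.0) * bfac
            # encode exactly as a Ct pair; 1000/2^ΔCt decodes back to expr
            dct = math.log2(1000.0 / expr)
            row["ct_housekeeping"] = truth.ct_housekeeping
            row["ct_" + name.replace("_qpcr", "")] = truth.ct_housekeeping + dct
        viab = truth.viability0 + truth.term_value(x, truth.beta_viability)
        if truth.viability_sigma > 0:
            viab += run_rng.normal(0.0, truth.viability_sigma)
        row["viability"] = float(np.clip(viab * bfac, 0.0, 100.0))
        rows.append(row)
    endpoints = pd.DataFrame(rows).set_index("run_id")
    return SimCampaign(design=design, series=series, endpoints=endpoints, truth=truth)


FIXTURE_TAGS = ("clean", "fusion-heavy", "unstable", "paper-shape")


def make_fixture(name: str, seed: int = 0, outdir: str | Path = "fixtures") -> Path:
    """Write a canned scenario (design.csv, series.csv, responses.csv, truth.json).

    Tags: 'clean' (low noise, no fusion), 'fusion-heavy', 'unstable'
    (fragmentation-dominated), 'paper-shape' (default truth on the
    19-run/2-batch/3-center design).
    """
    from .pipeline import assemble_responses  # local import: avoid cycle

    if name not in FIXTURE_TAGS:
        raise ValueError(f"unknown fixture tag {name!r}; choose from {FIXTURE_TAGS}")
    truth = default_truth()
    if name == "clean":
        truth = dataclasses.replace(
            truth,
            count_cv=0.02, d1_sigma_log=0.05, diameter_meas_sigma=0.01,
            fusion_lam0=0.0, marker_sigma=0.03, qpcr_sigma=6.0,
            viability_sigma=0.3, batch_sigma=0.005,
        )
    elif name == "fusion-heavy":
        truth = dataclasses.replace(truth, fusion_lam0=0.5)
    elif name == "unstable":
        truth = dataclasses.replace(truth, fusion_lam0=0.0, frag_lam0=0.3)
    design = paper_shape_design(seed=seed)
    campaign = simulate_campaign(design, truth, seed=seed)
    responses = assemble_responses(campaign.design, campaign.series, campaign.endpoints)

    out = Path(outdir) / name
    out.mkdir(parents=True, exist_ok=True)
    design.write_csv(out / "design.csv")
    from .kinetics import series_to_frame

    series_to_frame(campaign.series).to_csv(out / "series.csv", index=False)
    responses.to_csv(out / "responses.csv")
    (out / "truth.json").write_text(truth.to_json())
    return out
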