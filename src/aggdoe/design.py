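"""D-optimal interaction designs for multi-additive media screens.

Factors are medium additives screened over a concentration range; each run of
the design is one bioreactor condition.  Runs are searched over a discrete
candidate grid in coded units (each factor linearly mapped to [-1, +1]) using
a Meyer–Nachtsheim style coordinate-exchange algorithm that maximizes
det(X'X) of the interaction-model information matrix.  Designs are scored by
the log-determinant and by G-efficiency, the worst-case scaled prediction
variance over the candidate region.  Replicated center points (all factors at
mid-range) supply pure error and anchor batch normalization.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "ModelSpec",
    "DesignTable",
    "DesignScore",
    "default_factors",
    "interaction_model",
    "build_candidate_set",
    "model_matrix",
    "d_optimal_search",
    "g_efficiency",
    "add_center_points",
    "assign_batches",
]


@dataclass(frozen=True)
class FactorSpec:
    """One medium additive with its tested concentration range.

    ``low``/``high`` are in the factor's own units (``units`` is free text,
    e.g. µg/ml for heparin, mg/ml for the polymers).  ``log_scale`` selects a
    log-spaced coded↔actual mapping for factors spanning decades.
    """

    name: str
    low: float
    high: float
    units: str = ""
    log_scale: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("factor name must be non-empty")
        if not self.low < self.high:
            raise ValueError(f"factor {self.name!r}: low must be < high")
        if self.low < 0:
            raise ValueError(f"factor {self.name!r}: concentrations must be >= 0")
        if self.log_scale and self.low <= 0:
            raise ValueError(f"factor {self.name!r}: log scale needs low > 0")

    def to_actual(self, coded: np.ndarray) -> np.ndarray:
        coded = np.asarray(coded, dtype=float)
        if self.log_scale:
            llo, lhi = np.log(self.low), np.log(self.high)
            return np.exp(llo + (coded + 1.0) / 2.0 * (lhi - llo))
        return self.low + (coded + 1.0) / 2.0 * (self.high - self.low)

    def to_coded(self, actual: np.ndarray) -> np.ndarray:
        actual = np.asarray(actual, dtype=float)
        if self.log_scale:
            llo, lhi = np.log(self.low), np.log(self.high)
            return 2.0 * (np.log(actual) - llo) / (lhi - llo) - 1.0
        return 2.0 * (actual - self.low) / (self.high - self.low) - 1.0


def default_factors() -> list[FactorSpec]:
    """Placeholder ranges for the five screened additives.

    The published optimum pins heparin at 0.1 µg/ml and PEG at 10 mg/ml, and
    1 mg/ml is the literature anchor for PVA; full low/high ranges were only
    released in supplementary material, so these bounds are editable
    placeholders bracketing those anchors.
    """
    return [
        FactorSpec("DS", 0.0, 0.2, "mg/ml"),
        FactorSpec("HS", 0.0, 0.2, "ug/ml"),
        FactorSpec("PVA", 0.0, 2.0, "mg/ml"),
        FactorSpec("PA", 0.0, 2.0, "mg/ml"),
        FactorSpec("PEG", 0.0, 20.0, "mg/ml"),
    ]


@dataclass(frozen=True)
class ModelSpec:
    """Terms of the regression model the design must support.

    ``main_terms`` are factor names; ``interaction_terms`` are factor pairs;
    ``extra_terms`` holds higher-order products (e.g. a triple interaction).
    """

    main_terms: tuple[str, ...]
    interaction_terms: tuple[tuple[str, str], ...] = ()
    extra_terms: tuple[tuple[str, ...], ...] = ()
    include_intercept: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "main_terms", tuple(self.main_terms))
        object.__setattr__(
            self, "interaction_terms", tuple(tuple(t) for t in self.interaction_terms)
        )
        object.__setattr__(
            self, "extra_terms", tuple(tuple(t) for t in self.extra_terms)
        )
        declared = set(self.main_terms)
        if len(declared) != len(self.main_terms):
            raise ValueError("duplicate main terms")
        for term in self.interaction_terms + self.extra_terms:
            for name in term:
                if name not in declared:
                    raise ValueError(f"term {term} references undeclared factor {name!r}")
        all_terms = list(self.interaction_terms) + list(self.extra_terms)
        if len({tuple(sorted(t)) for t in all_terms}) != len(all_terms):
            raise ValueError("duplicate interaction/extra terms")

    @property
    def p(self) -> int:
        return (
            int(self.include_intercept)
            + len(self.main_terms)
            + len(self.interaction_terms)
            + len(self.extra_terms)
        )

    @property
    def term_names(self) -> list[str]:
        names = ["Intercept"] if self.include_intercept else []
        names += list(self.main_terms)
        names += [":".join(t) for t in self.interaction_terms]
        names += [":".join(t) for t in self.extra_terms]
        return names


def interaction_model(factors: list[FactorSpec] | list[str]) -> ModelSpec:
    """Full main-effect + two-factor-interaction model over the factors."""
    names = [f.name if isinstance(f, FactorSpec) else f for f in factors]
    pairs = tuple(itertools.combinations(names, 2))
    return ModelSpec(main_terms=tuple(names), interaction_terms=pairs)


@dataclass
class DesignTable:
    """Run settings in coded units plus metadata; actual units are a view."""

    factors: list[FactorSpec]
    coded: np.ndarray  # (n_runs, n_factors)
    run_ids: list[str] = field(default_factory=list)
    is_center: np.ndarray | None = None
    batch: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coded = np.atleast_2d(np.asarray(self.coded, dtype=float))
        n = self.coded.shape[0]
        if self.coded.shape[1] != len(self.factors):
            raise ValueError("coded matrix width does not match factor count")
        if not self.run_ids:
            self.run_ids = [f"N{i + 1}" for i in range(n)]
        if len(set(self.run_ids)) != len(self.run_ids):
            raise ValueError("run_ids must be unique")
        if self.is_center is None:
            self.is_center = np.zeros(n, dtype=bool)
        self.is_center = np.asarray(self.is_center, dtype=bool)
        if self.batch is None:
            self.batch = np.array(["B1"] * n, dtype=object)
        self.batch = np.asarray(self.batch, dtype=object)

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def actual(self) -> np.ndarray:
        cols = [f.to_actual(self.coded[:, j]) for j, f in enumerate(self.factors)]
        return np.column_stack(cols)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"run_id": self.run_ids})
        act = self.actual
        for j, f in enumerate(self.factors):
            df[f.name] = act[:, j]
        for j, f in enumerate(self.factors):
            df[f"coded_{f.name}"] = self.coded[:, j]
        df["is_center"] = self.is_center
        df["batch"] = self.batch
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, factors: list[FactorSpec]) -> "DesignTable":
        coded_cols = [f"coded_{f.name}" for f in factors]
        if all(c in df.columns for c in coded_cols):
            coded = df[coded_cols].to_numpy(float)
        else:
            coded = np.column_stack(
                [f.to_coded(df[f.name].to_numpy(float)) for f in factors]
            )
        return cls(
            factors=factors,
            coded=coded,
            run_ids=[str(r) for r in df["run_id"]],
            is_center=df["is_center"].to_numpy(bool) if "is_center" in df else None,
            batch=df["batch"].to_numpy(object) if "batch" in df else None,
        )

    @classmethod
    def read_csv(cls, path, factors: list[FactorSpec]) -> "DesignTable":
        return cls.from_frame(pd.read_csv(path), factors)


@dataclass(frozen=True)
class DesignScore:
    log_det: float
    g_efficiency: float
    n_runs: int
    p: int


def build_candidate_set(
    factors: list[FactorSpec], levels_per_factor: int = 3
) -> np.ndarray:
    """Full factorial grid of coded levels evenly spaced on [-1, +1]."""
    if not factors:
        raise ValueError("factor list must be non-empty")
    if levels_per_factor < 2:
        raise ValueError("levels_per_factor must be >= 2")
    levels = np.linspace(-1.0, 1.0, levels_per_factor)
    grid = np.array(list(itertools.product(levels, repeat=len(factors))))
    return grid


def model_matrix(
    coded: np.ndarray, model: ModelSpec, factor_names: list[str]
) -> np.ndarray:
    """Expand coded settings into the model's design matrix X."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    idx = {name: j for j, name in enumerate(factor_names)}
    cols = []
    if model.include_intercept:
        cols.append(np.ones(coded.shape[0]))
    for name in model.main_terms:
        cols.append(coded[:, idx[name]])
    for term in model.interaction_terms + model.extra_terms:
        prod = np.ones(coded.shape[0])
        for name in term:
            prod = prod * coded[:, idx[name]]
        cols.append(prod)
    return np.column_stack(cols)


def _log_det(coded_rows: np.ndarray, model: ModelSpec, names: list[str]) -> float:
    X = model_matrix(coded_rows, model, names)
    sign, logdet = np.linalg.slogdet(X.T @ X)
    return logdet if sign > 0 else -np.inf


def d_optimal_search(
    factors: list[FactorSpec],
    model: ModelSpec,
    n_runs: int,
    candidates: np.ndarray | None = None,
    levels_per_factor: int = 3,
    n_starts: int = 20,
    seed: int = 0,
    max_passes: int = 50,
) -> DesignTable:
    """Coordinate-exchange search for a D-optimal exact design.

    Starting from ``n_starts`` random subsets of the candidate grid, each
    coordinate of each run is cycled through the grid levels, keeping any
    exchange that increases det(X'X), until a full pass makes no improvement.
    The best design over all restarts is returned (ties broken first-found);
    the result is deterministic for a given ``seed``.
    """
    names = [f.name for f in factors]
    if candidates is None:
        candidates = build_candidate_set(factors, levels_per_factor)
    candidates = np.atleast_2d(np.asarray(candidates, dtype=float))
    if n_runs < model.p:
        raise ValueError(
            f"n_runs={n_runs} < p={model.p}: information matrix would be singular"
        )
    rng = np.random.default_rng(seed)
    levels = [np.unique(candidates[:, j]) for j in range(candidates.shape[1])]

    best_logdet, best = -np.inf, None
    for _ in range(n_starts):
        take = rng.choice(candidates.shape[0], size=n_runs, replace=True)
        design = candidates[take].copy()
        cur = _log_det(design, model, names)
        for _ in range(max_passes):
            improved = False
            for i in range(n_runs):
                for j in range(design.shape[1]):
                    orig = design[i, j]
                    best_lev, best_val = orig, cur
                    for lev in levels[j]:
                        if lev == orig:
                            continue
                        design[i, j] = lev
                        val = _log_det(design, model, names)
                        if val > best_val + 1e-12:
                            best_lev, best_val = lev, val
                    design[i, j] = best_lev
                    if best_val > cur + 1e-12:
                        cur = best_val
                        improved = True
            if not improved:
                break
        if cur > best_logdet + 1e-12:
            best_logdet, best = cur, design.copy()
    if best is None or not np.isfinite(best_logdet):
        raise ValueError("could not find a nonsingular design; enlarge candidates")
    return DesignTable(factors=factors, coded=best)


def g_efficiency(
    design: DesignTable, model: ModelSpec, candidates: np.ndarray | None = None
) -> float:
    """G-efficiency (%) = 100*p / max_x n*x'(X'X)^-1 x over the candidate set."""
    names = design.factor_names
    if candidates is None:
        candidates = build_candidate_set(design.factors, 3)
    X = model_matrix(design.coded, model, names)
    XtX = X.T @ X
    sign, _ = np.linalg.slogdet(XtX)
    if sign <= 0:
        raise ValueError("singular information matrix; G-efficiency undefined")
    XtX_inv = np.linalg.inv(XtX)
    F = model_matrix(candidates, model, names)
    d = design.n_runs * np.einsum("ij,jk,ik->i", F, XtX_inv, F)
    return 100.0 * model.p / float(np.max(d))


def score_design(
    design: DesignTable, model: ModelSpec, candidates: np.ndarray | None = None
) -> DesignScore:
    return DesignScore(
        log_det=_log_det(design.coded, model, design.factor_names),
        g_efficiency=g_efficiency(design, model, candidates),
        n_runs=design.n_runs,
        p=model.p,
    )


def add_center_points(design: DesignTable, k: int) -> DesignTable:
    """Append k replicated runs with all coded levels at 0 (mid-range)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return design
    n, m = design.coded.shape
    coded = np.vstack([design.coded, np.zeros((k, m))])
    run_ids = design.run_ids + [f"C{i + 1}" for i in range(k)]
    is_center = np.concatenate([design.is_center, np.ones(k, dtype=bool)])
    batch = np.concatenate([design.batch, np.array([design.batch[-1]] * k, object)])
    return DesignTable(design.factors, coded, run_ids, is_center, batch)


def assign_batches(design: DesignTable, n_batches: int, seed: int = 0) -> DesignTable:
    """Split runs into batches, guaranteeing each batch a center point.

    Center points are dealt round-robin to batches first (they anchor the
    between-batch normalization), then the remaining runs are dealt
    round-robin in a seed-shuffled order.
    """
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    labels = [f"B{i + 1}" for i in range(n_batches)]
    batch = np.empty(design.n_runs, dtype=object)
    center_idx = np.flatnonzero(design.is_center)
    other_idx = np.flatnonzero(~design.is_center)
    if n_batches > 1 and len(center_idx) < n_batches:
        raise ValueError(
            f"{len(center_idx)} center points cannot cover {n_batches} batches"
        )
    rng = np.random.default_rng(seed)
    center_idx = rng.permutation(center_idx)
    other_idx = rng.permutation(other_idx)
    for k, i in enumerate(center_idx):
        batch[i] = labels[k % n_batches]
    for k, i in enumerate(other_idx):
        batch[i] = labels[k % n_batches]
    return replace(design, batch=batch)
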