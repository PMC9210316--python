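"""Cross-validation protocol: CV2 folds, MT / MT_P masking, per-environment MSE.

The validation design partitions line x environment *cells* (not lines) into k
near-equal random folds, so a line is typically observed in some environments
while being predicted in others (the CV2 design of incomplete multienvironment
trials).  Two masking scenarios are applied to the test fold:

* MT   — every trait of a test cell is masked;
* MT_P — only the target traits are masked while auxiliary traits stay
  observed, letting residual trait correlation sharpen predictions.

Prediction error is the mean squared error per (fold, environment, trait),
averaged over folds, and then (unweighted) over environments.  Methods are
compared by percent improvement 100 (MSE_ref - MSE_cand) / MSE_cand, and every
method in a grid sees identical folds and masks (paired comparison).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd

from .kernels import InvalidInputError
from .model import FittedModel, ModelSpec, PhenotypeTable, fit_multitrait, predict

logger = logging.getLogger(__name__)

__all__ = [
    "FoldAssignment",
    "ScenarioMask",
    "MSEReport",
    "make_cv2_folds",
    "mask_scenario",
    "mse_by_env_trait",
    "aggregate",
    "percent_improvement",
    "run_cv_experiment",
]


@dataclass
class FoldAssignment:
    """Partition of the n cells into k folds (fold labels 1..k)."""

    fold_of_cell: np.ndarray
    k: int
    seed: int

    def __post_init__(self) -> None:
        self.fold_of_cell = np.asarray(self.fold_of_cell, dtype=int)
        sizes = np.bincount(self.fold_of_cell, minlength=self.k + 1)[1:]
        if sizes.sum() != len(self.fold_of_cell) or (sizes == 0).any():
            raise InvalidInputError("folds must partition all cells with no empty fold")

    def test_cells(self, fold: int) -> np.ndarray:
        return np.where(self.fold_of_cell == fold)[0]


@dataclass
class ScenarioMask:
    """MT or MT_P masking applied to test-fold cells.

    Under MT every trait is masked (``observed_traits`` must be empty); under
    MT_P only ``target_traits`` are masked and ``observed_traits`` stay
    observed in the test cells.
    """

    scenario: str
    target_traits: list = field(default_factory=list)
    observed_traits: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scenario not in ("MT", "MT_P"):
            raise InvalidInputError(f"scenario must be MT or MT_P, got {self.scenario!r}")
        overlap = set(self.target_traits) & set(self.observed_traits)
        if overlap:
            raise InvalidInputError(f"traits cannot be both target and observed: {overlap}")
        if self.scenario == "MT" and self.observed_traits:
            raise InvalidInputError("MT scenario masks all traits; observed_traits must be empty")


@dataclass
class MSEReport:
    """Tidy per-(fold, environment, trait) MSE rows plus aggregates.

    ``per_fold`` columns: fold, env, trait, T, mse.  ``by_env_trait`` averages
    over folds; ``by_trait`` further averages (unweighted) over environments.
    """

    per_fold: pd.DataFrame
    by_env_trait: pd.DataFrame
    by_trait: pd.DataFrame


def make_cv2_folds(data: PhenotypeTable, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Uniformly random partition of cells into k folds with sizes differing by <= 1."""
    n = data.n_cells
    if k > n:
        raise InvalidInputError(f"cannot make {k} folds from {n} cells")
    if k < 2:
        raise InvalidInputError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of_cell = np.zeros(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k), start=1):
        fold_of_cell[chunk] = f
    return FoldAssignment(fold_of_cell=fold_of_cell, k=k, seed=seed)


def mask_scenario(
    data: PhenotypeTable,
    folds: FoldAssignment,
    test_fold: int,
    scenario: ScenarioMask,
) -> PhenotypeTable:
    """Return a copy of ``data`` with the test fold masked per the scenario.

    Training cells are untouched; originally missing entries stay missing
    (masking never unmasks).
    """
    if not 1 <= test_fold <= folds.k:
        raise InvalidInputError(f"test_fold must be in 1..{folds.k}")
    unknown = set(scenario.target_traits + scenario.observed_traits) - set(data.trait_names)
    if unknown:
        raise KeyError(f"traits not present in data: {sorted(unknown)}")
    mask = data.mask.copy()
    test = folds.fold_of_cell == test_fold
    if scenario.scenario == "MT":
        mask[test, :] = False
    else:
        targets = [data.trait_names.index(t) for t in scenario.target_traits]
        for t in targets:
            mask[test, t] = False
    return PhenotypeTable(
        values=data.values.copy(),
        mask=mask,
        line_of_cell=data.line_of_cell.copy(),
        env_of_cell=data.env_of_cell.copy(),
        trait_names=list(data.trait_names),
        line_ids=list(data.line_ids),
        env_ids=list(data.env_ids),
    )


def mse_by_env_trait(
    truth: PhenotypeTable,
    predictions: np.ndarray,
    evaluated_mask: np.ndarray,
) -> pd.DataFrame:
    """MSE = sum (y - yhat)^2 / T per (environment, trait) over evaluated entries.

    ``evaluated_mask`` must select only entries observed in ``truth`` (the
    typical choice: truth-observed entries that were masked for fitting).
    Strata with zero evaluated entries are omitted with a logged notice.
    """
    evaluated_mask = np.asarray(evaluated_mask, dtype=bool)
    if (evaluated_mask & ~truth.mask).any():
        raise InvalidInputError("evaluated entries must be observed in the truth table")
    rows = []
    for e, env_id in enumerate(truth.env_ids):
        in_env = truth.env_of_cell == e
        for t, trait in enumerate(truth.trait_names):
            sel = in_env & evaluated_mask[:, t]
            T = int(sel.sum())
            if T == 0:
                logger.info("no evaluated entries for env %s trait %s; row omitted", env_id, trait)
                continue
            err = truth.values[sel, t] - predictions[sel, t]
            rows.append({"env": env_id, "trait": trait, "T": T, "mse": float(np.mean(err**2))})
    return pd.DataFrame(rows, columns=["env", "trait", "T", "mse"])


def aggregate(per_fold: pd.DataFrame) -> MSEReport:
    """Fold-average per (env, trait), then unweighted environment average per trait."""
    if per_fold.empty:
        raise InvalidInputError("no rows to aggregate")
    by_env_trait = (
        per_fold.groupby(["env", "trait"], as_index=False, sort=True)
        .agg(T=("T", "sum"), mse=("mse", "mean"))
    )
    by_trait = (
        by_env_trait.groupby("trait", as_index=False, sort=True)
        .agg(mse=("mse", "mean"))
    )
    return MSEReport(per_fold=per_fold, by_env_trait=by_env_trait, by_trait=by_trait)


def percent_improvement(mse_ref: float, mse_best: float) -> float:
    """100 (mse_ref - mse_best) / mse_best; positive when the candidate is better."""
    if mse_ref <= 0 or mse_best <= 0:
        raise InvalidInputError("MSE values must be positive")
    return 100.0 * (mse_ref - mse_best) / mse_best


def run_cv_experiment(
    data: PhenotypeTable,
    markers,
    spec_grid: dict[str, ModelSpec] | Sequence[ModelSpec],
    scenario: ScenarioMask,
    k: int = 5,
    seed: int = 0,
    reference: str | None = None,
) -> tuple[dict[str, MSEReport], pd.DataFrame]:
    """Paired k-fold CV2 comparison of a grid of model specifications.

    All methods see identical folds and scenario masks.  Returns a per-method
    :class:`MSEReport` and a comparison table of percent improvements of each
    method over the reference (default: the first method in the grid),
    computed on the across-environment trait aggregates.
    """
    if not isinstance(spec_grid, dict):
        spec_grid = {
            f"{s.kernel_name}{'_gxe' if s.include_gxe else ''}": s for s in spec_grid
        }
    if not spec_grid:
        raise InvalidInputError("spec grid must be non-empty")
    folds = make_cv2_folds(data, k=k, seed=seed)
    target_traits = scenario.target_traits or list(data.trait_names)

    per_method_rows: dict[str, list] = {m: [] for m in spec_grid}
    for fold in range(1, k + 1):
        masked = mask_scenario(data, folds, fold, scenario)
        evaluated = data.mask & ~masked.mask
        for method, spec in spec_grid.items():
            spec_f = dc_replace(spec, seed=int(np.random.SeedSequence([spec.seed, fold]).generate_state(1)[0] % (2**31)))
            t0 = pd.Timestamp.now()
            fit = fit_multitrait(masked, markers, spec_f)
            preds = predict(fit)
            rows = mse_by_env_trait(data, preds, evaluated)
            rows.insert(0, "fold", fold)
            per_method_rows[method].append(rows)
            logger.info(
                "fold %d method %-12s done in %.1fs", fold, method,
                (pd.Timestamp.now() - t0).total_seconds(),
            )

    reports = {
        m: aggregate(pd.concat(rows, ignore_index=True)) for m, rows in per_method_rows.items()
    }
    reference = reference or next(iter(spec_grid))
    comp_rows = []
    ref_by_trait = reports[reference].by_trait.set_index("trait")["mse"]
    for method, rep in reports.items():
        for trait in target_traits:
            if trait not in ref_by_trait.index:
                continue
            cand = rep.by_trait.set_index("trait")["mse"].get(trait)
            comp_rows.append({
                "method": method,
                "trait": trait,
                "mse": cand,
                "reference": reference,
                "pct_improvement_vs_reference": percent_improvement(ref_by_trait[trait], cand),
            })
    comparison = pd.DataFrame(comp_rows)
    return reports, comparison
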