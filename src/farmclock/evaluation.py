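"""Out-of-sample accuracy estimation: LOOCV, LOSO and the clock metrics.

Two validation schemes are provided.  Leave-one-out cross-validation
(LOOCV) refits the entire clock — including the internal cross-validated
penalty selection — on every set of n-1 samples and predicts the held-out
sample, so each prediction comes from a model that never saw that sample.
Leave-one-species-out (LOSO) holds out every sample of one species at a
time and measures how well a pooled multi-species clock transfers to a
species absent from training; it applies only to the relative-age clocks
(2 and 3), and back-transforms each held-out prediction with the held-out
species' own life history.

Accuracy is summarized as the Pearson correlation on the transformed
scale, where the clock's relationship with age is linear, and as the
median absolute error (MAE) between back-transformed DNAm age and
chronological age, in days.  For LOSO the per-fold (within-species)
correlations and their median (med.corr) are reported alongside the
pooled correlation over all held-out predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .clock_model import (
    FittedClock,
    fit_clock,
    predict_transformed,
    transformed_ages,
    _resolve_life_histories,
)
from .life_history import SpeciesLifeHistory
from .preprocess import MethylationDataset

__all__ = [
    "EvaluationResult",
    "Metrics",
    "compute_metrics",
    "loocv",
    "loso",
    "DAYS_PER_MONTH",
]

#: Average month length in days (365.25 / 12), used only for display.
DAYS_PER_MONTH = 30.4375

_PER_SAMPLE_COLUMNS = (
    "sample_id",
    "species",
    "age_days",
    "true_transformed",
    "predicted_transformed",
    "predicted_age_days",
    "fold_id",
)


class Metrics(NamedTuple):
    """Pearson r (requested scale) and median absolute error in days."""

    pearson_r: float
    mae_days: float


@dataclass
class EvaluationResult:
    """Held-out predictions plus summary accuracy metrics.

    ``per_sample`` has one row per sample with its fold label, transformed
    and back-transformed predictions.  ``per_fold`` (LOSO) maps fold id to
    within-fold (r, MAE-days); ``med_corr`` is the median of the per-fold
    correlations.
    """

    per_sample: pd.DataFrame
    pearson_r_transformed: float
    mae_days: float
    per_fold: Optional[dict[str, Metrics]] = None
    med_corr: Optional[float] = None
    scheme: str = ""
    clock_number: int = 0

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.pearson_r_transformed <= 1.0 + 1e-12):
            raise ValueError("pearson r out of [-1, 1]")
        if self.mae_days < 0:
            raise ValueError("MAE must be non-negative")

    @property
    def mae_months(self) -> float:
        return self.mae_days / DAYS_PER_MONTH

    def summary(self) -> dict:
        out = {
            "scheme": self.scheme,
            "clock_number": self.clock_number,
            "n_samples": len(self.per_sample),
            "pearson_r_transformed": self.pearson_r_transformed,
            "mae_days": self.mae_days,
            "mae_months": self.mae_months,
        }
        if self.med_corr is not None:
            out["med_corr"] = self.med_corr
        if self.per_fold is not None:
            out["per_fold"] = {
                str(k): {"pearson_r": m.pearson_r, "mae_days": m.mae_days}
                for k, m in self.per_fold.items()
            }
        return out


def compute_metrics(per_sample: pd.DataFrame, scale: str = "transformed") -> Metrics:
    """Pearson r and median absolute error from per-sample records.

    ``scale`` selects the correlation scale: ``"transformed"`` (default —
    the scale on which the clock is linear) correlates true vs predicted
    transformed age; ``"back_transformed"`` correlates raw ages.  The MAE
    is always the median of |predicted_age_days - age_days|, in days.
    """
    if scale not in ("transformed", "back_transformed"):
        raise ValueError("scale must be 'transformed' or 'back_transformed'")
    if len(per_sample) < 3:
        raise ValueError("need at least 3 records to compute metrics")
    if scale == "transformed":
        x = per_sample["true_transformed"].to_numpy(dtype=float)
        yv = per_sample["predicted_transformed"].to_numpy(dtype=float)
    else:
        x = per_sample["age_days"].to_numpy(dtype=float)
        yv = per_sample["predicted_age_days"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(yv))):
        raise ValueError("non-finite values in metric inputs")
    if np.ptp(x) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero variance: Pearson correlation undefined")
    r = float(pearsonr(x, yv).statistic)
    mae = float(
        np.median(
            np.abs(
                per_sample["predicted_age_days"].to_numpy(dtype=float)
                - per_sample["age_days"].to_numpy(dtype=float)
            )
        )
    )
    return Metrics(pearson_r=r, mae_days=mae)


def _backtransform(
    clock: FittedClock, species: pd.Series, transformed: np.ndarray
) -> np.ndarray:
    out = np.empty(len(transformed))
    sp = species.str.lower().to_numpy()
    for name in np.unique(sp):
        tf = clock.transform_for(name)
        idx = sp == name
        out[idx] = tf.inverse_transform(transformed[idx])
    return out


def loocv(
    dataset: MethylationDataset,
    clock_number: int,
    alpha: float = 0.5,
    n_folds_internal: int = 10,
    seed: int = 0,
    life_histories: Optional[Mapping[str, SpeciesLifeHistory]] = None,
    fast: bool = False,
    clamp_relative_age: bool = True,
) -> EvaluationResult:
    """Leave-one-out cross-validation of a clock.

    For each sample a full clock — internal lambda selection included — is
    fitted on the remaining n-1 samples and applied to the held-out
    sample.  ``fast=True`` deviates from that protocol by selecting lambda
    once on the full data and reusing it in every fold (an order of
    magnitude faster, slightly optimistic); it is intended for exploratory
    runs only.

    Held-out predictions are back-transformed with the held-out sample's
    species constants; the relative-age clamp is enabled by default so a
    prediction beyond a species' maximum lifespan degrades gracefully.
    """
    n = dataset.n_samples
    if n < n_folds_internal + 1:
        raise ValueError("LOOCV needs at least n_folds_internal + 1 samples")
    lhs = _resolve_life_histories(dataset, life_histories)
    true_y = transformed_ages(dataset, clock_number, lhs)

    fixed_grid = None
    if fast:
        full = fit_clock(
            dataset, clock_number, alpha, n_folds_internal, seed, lhs
        )
        fixed_grid = np.array([full.lambda_selected])

    sample_ids = dataset.sample_ids
    pred_t = np.empty(n)
    for i in range(n):
        held = sample_ids[i]
        train = dataset.drop_samples([held])
        # each refit draws its own internal folds, as repeated independent
        # cross-validated fits would; derived deterministically from (seed, i)
        fold_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31)
        try:
            clock = fit_clock(
                train,
                clock_number,
                alpha=alpha,
                n_folds=n_folds_internal,
                seed=fold_seed,
                life_histories=lhs,
                lambda_grid=fixed_grid,
            )
        except Exception as exc:  # identify the failing fold
            raise RuntimeError(f"LOOCV fold for sample {held!r} failed: {exc}") from exc
        clock.clamp_relative_age = clamp_relative_age
        pred_t[i] = predict_transformed(clock, dataset.subset_samples([held])).iloc[0]

    shell = fit_shell(clock_number, lhs, clamp_relative_age)
    pred_age = _backtransform(shell, dataset.species, pred_t)
    per_sample = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "species": dataset.species.to_numpy(),
            "age_days": dataset.age_days.to_numpy(),
            "true_transformed": true_y,
            "predicted_transformed": pred_t,
            "predicted_age_days": pred_age,
            "fold_id": sample_ids,
        }
    )
    metrics = compute_metrics(per_sample, scale="transformed")
    return EvaluationResult(
        per_sample=per_sample,
        pearson_r_transformed=metrics.pearson_r,
        mae_days=metrics.mae_days,
        scheme="loocv" + ("-fast" if fast else ""),
        clock_number=clock_number,
    )


def fit_shell(
    clock_number: int,
    life_histories: Mapping[str, SpeciesLifeHistory],
    clamp_relative_age: bool = True,
) -> FittedClock:
    """A coefficient-free clock carrying transforms only (plumbing helper)."""
    return FittedClock(
        clock_number=clock_number,
        life_histories=dict(life_histories),
        intercept=0.0,
        coefficients={},
        alpha=0.5,
        lambda_selected=1.0,
        clamp_relative_age=clamp_relative_age,
    )


def loso(
    dataset: MethylationDataset,
    clock_number: int,
    alpha: float = 0.5,
    n_folds_internal: int = 10,
    seed: int = 0,
    life_histories: Optional[Mapping[str, SpeciesLifeHistory]] = None,
    clamp_relative_age: bool = True,
) -> EvaluationResult:
    """Leave-one-species-out cross-validation of a pooled farm clock.

    One fold per species: the fold's clock is fitted on all other species
    and applied to every sample of the held-out species, whose own
    life-history constants drive both the true transformed age and the
    back-transformation.  Only the relative-age clocks (2, 3) are
    meaningful across species, so ``clock_number`` must be 2 or 3.

    The pooled Pearson r is computed on the transformed scale over all
    held-out predictions (commensurate across species); per-fold r / MAE
    and their median (med.corr) are reported per species.
    """
    if clock_number not in (2, 3):
        raise ValueError("LOSO applies to the relative-age clocks (2 or 3) only")
    species_names = dataset.species_names()
    if len(species_names) < 2:
        raise ValueError("LOSO needs at least two species")
    lhs = _resolve_life_histories(dataset, life_histories)
    true_y = transformed_ages(dataset, clock_number, lhs)

    rows = []
    per_fold: dict[str, Metrics] = {}
    species_col = dataset.species.astype(str)
    for name in species_names:
        held_ids = species_col.index[species_col == name]
        train = dataset.drop_samples(held_ids)
        clock = fit_clock(
            train,
            clock_number,
            alpha=alpha,
            n_folds=n_folds_internal,
            seed=seed,
            life_histories={k: v for k, v in lhs.items() if k != str(name).lower()},
        )
        # held-out species' constants are a property of its samples
        clock.life_histories[str(name).lower()] = lhs[str(name).lower()]
        clock.clamp_relative_age = clamp_relative_age
        held = dataset.subset_samples(held_ids)
        pred_t = predict_transformed(clock, held).to_numpy()
        pred_age = _backtransform(clock, held.species, pred_t)
        fold_frame = pd.DataFrame(
            {
                "sample_id": held_ids,
                "species": held.species.to_numpy(),
                "age_days": held.age_days.to_numpy(),
                "true_transformed": true_y[dataset.sample_ids.get_indexer(held_ids)],
                "predicted_transformed": pred_t,
                "predicted_age_days": pred_age,
                "fold_id": str(name),
            }
        )
        rows.append(fold_frame)
        per_fold[str(name)] = compute_metrics(fold_frame, scale="transformed")

    per_sample = pd.concat(rows, ignore_index=True)
    pooled = compute_metrics(per_sample, scale="transformed")
    med_corr = float(np.median([m.pearson_r for m in per_fold.values()]))
    return EvaluationResult(
        per_sample=per_sample,
        pearson_r_transformed=pooled.pearson_r,
        mae_days=pooled.mae_days,
        per_fold=per_fold,
        med_corr=med_corr,
        scheme="loso",
        clock_number=clock_number,
    )
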