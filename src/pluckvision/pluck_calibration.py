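"""Per-species d→h calibration and the 85% upper-boundary line.

The plucking height h (top of the flower down to the cut, mm) is
predicted from the flower diameter d (mm) by a per-species ordinary
least squares line h = a·d + b.  Cutting *on* the regression line would
damage roughly half the flowers (their true plucking point lies below
the prediction), so inference uses a parallel line translated upward
until a target fraction of flowers (default 85%) falls at or below it:

    h_boundary(d) = a·d + b + c,

where c is the one-sided coverage-quantile of the training residuals
(default) or z(coverage)·residual-SD under a normal-residual assumption.
Overestimating h moves the cut slightly down the stem — harmless —
while underestimating it would slice through the calyx.

Published coefficients for pansy, snapdragon and marigold ship with the
package and can be overridden by a user config of the same CSV format.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import LinearRegression

from .errors import InsufficientDataError, NoCalibrationError
from .scene_io import Measurement

__all__ = [
    "CalibrationModel",
    "BoundaryLine",
    "fit_species_model",
    "upper_boundary",
    "predict_h",
    "evaluate_underestimation",
    "load_packaged_coefficients",
    "load_calibration_config",
    "write_calibration_config",
    "fit_all_species",
]


@dataclass
class CalibrationModel:
    """OLS line h = slope·d + intercept for one species.

    ``residuals`` are the training residuals (mm); they are ``None`` for
    packaged coefficient sets whose raw measurements are not available.
    """

    species: str
    slope: float
    intercept: float
    residuals: np.ndarray | None = None
    n_train: int = 0
    n_test: int = 0
    train_indices: np.ndarray | None = None
    test_indices: np.ndarray | None = None

    def predict(self, d) -> np.ndarray | float:
        return predict_h(self, d)


@dataclass
class BoundaryLine:
    """The regression line translated up to cover ``coverage`` of flowers."""

    species: str
    slope: float
    intercept_upper: float
    coverage: float

    def predict(self, d) -> np.ndarray | float:
        return predict_h(self, d)


def fit_species_model(
    data: Sequence[Measurement],
    species: str,
    train_frac: float = 0.8,
    seed: int = 0,
) -> CalibrationModel:
    """Fit the per-species OLS line on a seeded random train split.

    ``train_frac`` of the species' measurements (default 80%) train the
    line; the rest are retained as held-out test indices.  Raises
    :class:`InsufficientDataError` below 5 measurements or 3 training
    points.
    """
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must lie in (0, 1)")
    idx = np.array([i for i, m in enumerate(data) if m.species == species])
    if idx.size < 5:
        raise InsufficientDataError(
            f"{species}: {idx.size} measurement(s), need >= 5"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(idx.size)
    n_train = int(round(train_frac * idx.size))
    n_train = min(max(n_train, 1), idx.size - 1)
    if n_train < 3:
        raise InsufficientDataError(
            f"{species}: {n_train} training point(s) after split, need >= 3"
        )
    train_idx = idx[np.sort(perm[:n_train])]
    test_idx = idx[np.sort(perm[n_train:])]
    d = np.array([data[i].d for i in train_idx])
    h = np.array([data[i].h for i in train_idx])
    reg = LinearRegression().fit(d.reshape(-1, 1), h)
    slope = float(reg.coef_[0])
    intercept = float(reg.intercept_)
    residuals = h - (slope * d + intercept)
    return CalibrationModel(
        species=species,
        slope=slope,
        intercept=intercept,
        residuals=residuals,
        n_train=int(n_train),
        n_test=int(idx.size - n_train),
        train_indices=train_idx,
        test_indices=test_idx,
    )


def upper_boundary(
    model: CalibrationModel,
    coverage: float = 0.85,
    method: str = "empirical_quantile",
) -> BoundaryLine:
    """Translate the regression line up to its coverage boundary.

    ``empirical_quantile`` uses the smallest residual order statistic
    r₍ₖ₎ with k = ⌈coverage·n⌉, guaranteeing that at least ``coverage`` of
    the training points fall at or below the boundary; ``normal_theory``
    uses z(coverage) times the residual standard deviation.  The slope is
    untouched — the boundary is a parallel translate.
    """
    if not (0.5 <= coverage < 1.0):
        raise ValueError("coverage must lie in [0.5, 1)")
    if model.residuals is None:
        raise ValueError("model has no residuals; cannot derive a boundary")
    r = np.asarray(model.residuals, dtype=float)
    if method == "empirical_quantile":
        k = int(np.ceil(coverage * r.size))
        c = float(np.sort(r)[k - 1])
    elif method == "normal_theory":
        # residual SD with 2 fitted parameters removed
        sd = float(np.sqrt(np.sum(r ** 2) / max(r.size - 2, 1)))
        c = float(stats.norm.ppf(coverage) * sd)
    else:
        raise ValueError(f"unknown boundary method {method!r}")
    return BoundaryLine(
        species=model.species,
        slope=model.slope,
        intercept_upper=model.intercept + c,
        coverage=coverage,
    )


def predict_h(line: "BoundaryLine | CalibrationModel", d):
    """Evaluate a calibration or boundary line at diameter(s) d (mm)."""
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("diameter must be non-negative")
    intercept = line.intercept_upper if isinstance(line, BoundaryLine) else line.intercept
    out = line.slope * d_arr + intercept
    return float(out) if np.isscalar(d) or d_arr.ndim == 0 else out


def evaluate_underestimation(
    model: CalibrationModel,
    line: BoundaryLine,
    data: Sequence[Measurement],
) -> tuple[int, int]:
    """Count flowers whose true h exceeds the boundary prediction.

    An underestimated flower would be cut through the calyx; on held-out
    data the rate should be ≈ 1 − coverage.
    """
    meas = [m for m in data if m.species == model.species]
    if not meas:
        raise ValueError("no measurements for species " + repr(model.species))
    under = sum(1 for m in meas if m.h > predict_h(line, m.d))
    return under, len(meas)


# ---------------------------------------------------------------------------
# packaged / user coefficient configs
# ---------------------------------------------------------------------------

def _read_config_rows(fh) -> dict[str, tuple[CalibrationModel, BoundaryLine]]:
    out: dict[str, tuple[CalibrationModel, BoundaryLine]] = {}
    for row in csv.DictReader(fh):
        species = row["species"].strip()
        slope = float(row["slope"])
        model = CalibrationModel(
            species=species, slope=slope, intercept=float(row["intercept_regression"])
        )
        line = BoundaryLine(
            species=species,
            slope=slope,
            intercept_upper=float(row["intercept_upper"]),
            coverage=float(row.get("coverage", 0.85) or 0.85),
        )
        out[species] = (model, line)
    return out


def load_calibration_config(path) -> dict[str, tuple[CalibrationModel, BoundaryLine]]:
    """Read a calibration config CSV (species, slope, intercepts, coverage)."""
    with open(path, newline="") as fh:
        return _read_config_rows(fh)


def write_calibration_config(
    calibrations: dict[str, tuple[CalibrationModel, BoundaryLine]], path
) -> None:
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["species", "slope", "intercept_regression", "intercept_upper", "coverage"])
        for species, (model, line) in calibrations.items():
            wr.writerow(
                [species, repr(model.slope), repr(model.intercept),
                 repr(line.intercept_upper), repr(line.coverage)]
            )


def _packaged() -> dict[str, tuple[CalibrationModel, BoundaryLine]]:
    ref = resources.files("pluckvision").joinpath("data/table4_calibration.csv")
    with ref.open(newline="") as fh:
        return _read_config_rows(fh)


def load_packaged_coefficients(species: str) -> tuple[CalibrationModel, BoundaryLine]:
    """Published coefficients for one species (no residuals attached).

    Known species: pansy, snapdragon, marigold.  Raises
    :class:`NoCalibrationError` (listing the known species) otherwise.
    """
    table = _packaged()
    if species not in table:
        raise NoCalibrationError(species, table.keys())
    return table[species]


def fit_all_species(
    data: Sequence[Measurement],
    train_frac: float = 0.8,
    coverage: float = 0.85,
    method: str = "empirical_quantile",
    seed: int = 0,
) -> dict[str, tuple[CalibrationModel, BoundaryLine]]:
    """Fit model + boundary for every species present in ``data``."""
    out: dict[str, tuple[CalibrationModel, BoundaryLine]] = {}
    for species in sorted({m.species for m in data}):
        model = fit_species_model(data, species, train_frac=train_frac, seed=seed)
        out[species] = (model, upper_boundary(model, coverage=coverage, method=method))
    return out
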