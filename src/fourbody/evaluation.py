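"""Agreement statistics between experimental and predicted binding energies.

Given paired observations (x_i experimental, y_i predicted) the package
reports Pearson's correlation coefficient r, the regression standard error

    SE = sqrt( (1 - r^2) * sum (y_i - ybar)^2 / (n - 2) ),

and the ordinary least-squares regression line of y on x.  The standard error
has an algebraically equivalent computational form in terms of raw sums; both
are implemented and cross-checked in the test suite.  Refitting the linear
dQ -> dG calibration on user data is exposed here explicitly and never applied
silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import EvaluationError


@dataclass(frozen=True)
class PairedObservations:
    """Known (x) and predicted (y) values, validated for the statistics below."""

    x: np.ndarray
    y: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
            raise EvaluationError("x and y must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise EvaluationError("observations contain non-finite values")
        if self.labels is not None and len(self.labels) != len(x):
            raise EvaluationError("labels length does not match observations")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class EvalSummary:
    r: float
    se: float
    slope: float
    intercept: float
    n: int

    def as_dict(self) -> dict:
        return {
            "r": self.r,
            "se": self.se,
            "slope": self.slope,
            "intercept": self.intercept,
            "n": self.n,
        }


def pearson_r(obs: PairedObservations) -> float:
    """Pearson's correlation coefficient over the pairs.

    r = sum (x - xbar)(y - ybar) / sqrt( sum (x - xbar)^2 * sum (y - ybar)^2 )
    """
    if obs.n < 3:
        raise EvaluationError(f"need at least 3 pairs for r, got {obs.n}")
    dx = obs.x - obs.x.mean()
    dy = obs.y - obs.y.mean()
    sxx = float(np.sum(dx * dx))
    syy = float(np.sum(dy * dy))
    if sxx == 0 or syy == 0:
        raise EvaluationError("correlation undefined for zero-variance input")
    return float(np.sum(dx * dy)) / math.sqrt(sxx * syy)


def standard_error(obs: PairedObservations, form: str = "moment") -> float:
    """Regression standard error of the predictions (units of y).

    ``form="moment"`` evaluates sqrt((1 - r^2) * sum (y - ybar)^2 / (n - 2));
    ``form="sums"`` evaluates the equivalent expression in raw power sums.
    Both agree to floating-point accuracy and use the n - 2 denominator of a
    two-parameter regression.
    """
    if obs.n < 3:
        raise EvaluationError(f"need at least 3 pairs for SE, got {obs.n}")
    x, y, n = obs.x, obs.y, obs.n
    if form == "moment":
        r = pearson_r(obs)
        syy = float(np.sum((y - y.mean()) ** 2))
        return math.sqrt((1.0 - r * r) * syy / (n - 2))
    if form == "sums":
        sx, sy = float(x.sum()), float(y.sum())
        sxx, syy = float((x * x).sum()), float((y * y).sum())
        sxy = float((x * y).sum())
        denom = n * sxx - sx * sx
        if denom == 0:
            raise EvaluationError("SE undefined for zero-variance x")
        inner = (n * syy - sy * sy) - (n * sxy - sx * sy) ** 2 / denom
        return math.sqrt(max(inner, 0.0) / (n * (n - 2)))
    raise ValueError(f"unknown SE form {form!r}")


def fit_regression(obs: PairedObservations, through_origin: bool = False
                   ) -> tuple[float, float]:
    """Ordinary least squares of y on x; optionally constrained through 0."""
    if obs.n < 2:
        raise EvaluationError(f"need at least 2 pairs to fit a line, got {obs.n}")
    x, y = obs.x, obs.y
    if through_origin:
        sxx = float(np.sum(x * x))
        if sxx == 0:
            raise EvaluationError("regression undefined for all-zero x")
        return float(np.sum(x * y)) / sxx, 0.0
    dx = x - x.mean()
    sxx = float(np.sum(dx * dx))
    if sxx == 0:
        raise EvaluationError("regression undefined for zero-variance x")
    slope = float(np.sum(dx * (y - y.mean()))) / sxx
    return slope, float(y.mean() - slope * x.mean())


def evaluate_predictions(obs: PairedObservations) -> EvalSummary:
    """Bundle r, SE and the fitted regression line for a set of pairs."""
    slope, intercept = fit_regression(obs)
    return EvalSummary(
        r=pearson_r(obs),
        se=standard_error(obs),
        slope=slope,
        intercept=intercept,
        n=obs.n,
    )


def refit_linear_model(dq: np.ndarray, dg_exp: np.ndarray) -> tuple[float, float]:
    """Fit new coefficients dG = dQ/denominator + intercept on user data.

    Returns (denominator, intercept) in the same parameterization as the
    published model.  This produces *new* coefficients; it never alters the
    fixed published ones used by prediction.
    """
    obs = PairedObservations(np.asarray(dq, float), np.asarray(dg_exp, float))
    slope, intercept = fit_regression(obs)
    if slope == 0:
        raise EvaluationError("refit produced a zero slope; denominator undefined")
    return 1.0 / slope, intercept


def load_benchmark_table() -> pd.DataFrame:
    """Ten-complex benchmark: experimental pk_d/dG with two models' predictions.

    Columns: pdb, pk_exp, pk_xscore (a comparison empirical scoring function,
    reported on the pk scale), dg_exp (kcal/mol, from pk_exp), dg_model
    (kcal/mol, this model's predictions).
    """
    with resources.files("fourbody.data").joinpath("xscore_comparison.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def read_pairs_tsv(path, pk_x: bool = False) -> PairedObservations:
    """Read id/x/y pairs from TSV; with ``pk_x`` the x column is converted
    from pk units to kcal/mol before pairing."""
    from .scoring import pk_to_free_energy

    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise EvaluationError("expected TSV columns: id, x, y")
    labels = tuple(str(v) for v in df.iloc[:, 0])
    x = df.iloc[:, 1].to_numpy(dtype=float)
    if pk_x:
        x = np.array([pk_to_free_energy(v) for v in x])
    y = df.iloc[:, 2].to_numpy(dtype=float)
    return PairedObservations(x, y, labels)
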