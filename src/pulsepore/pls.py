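"""Partial least squares regression for electroporation → electrofusion data.

This module implements NIPALS PLS from first principles for tables of
pulsed-electric-field (PEF) experiments: each sample is one pulse condition
(width, strength) with measured YO-PRO-1-positive and PI-positive cell
fractions (proxies for small- and large-pore formation) and a cell fusion
rate.  The bilinear model decomposes the predictor block X and response
block Y into shared latent components,

    X = T P' + E        Y = U C' + G        Y = T C' + F

where T and P are the X scores and loadings, U and C the Y scores and
weights, and E, G, F residual matrices.  Predictors and response are
mean-centered and scaled to unit sample standard deviation before fitting;
predictions are returned in original units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleTable",
    "Scaler",
    "PLSModel",
    "FitStats",
    "PREDICTOR_COLUMNS",
    "RESPONSE_COLUMN",
    "load_reference_table",
    "autoscale",
    "fit_pls",
    "fit_table",
    "predict",
    "fit_stats",
]

#: canonical predictor / response column names for PEF sample tables
PREDICTOR_COLUMNS = ("yp_rate", "pi_rate")
RESPONSE_COLUMN = "fusion_rate"

_CSV_COLUMNS = [
    "sample_id",
    "pulse_width_ns",
    "field_strength_kv_cm",
    "yp_rate",
    "pi_rate",
    "fusion_rate",
    "role",
]

_ROLES = {"train", "test", "unassigned"}


# ---------------------------------------------------------------------------
# Sample table
# ---------------------------------------------------------------------------


@dataclass
class SampleTable:
    """A table of PEF conditions with electroporation and fusion readouts.

    Wraps a :class:`pandas.DataFrame` with the canonical columns
    ``sample_id, pulse_width_ns, field_strength_kv_cm, yp_rate, pi_rate,
    fusion_rate, role`` and validates the domain invariants on
    construction: unique sample ids, dye-positive fractions within
    [0, 100], non-negative fusion rates, and roles drawn from
    {train, test, unassigned}.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        df = df[_CSV_COLUMNS].reset_index(drop=True)
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample_id values: {dups}")
        for col in ("yp_rate", "pi_rate"):
            vals = df[col].to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise ValueError(f"missing values in column {col!r}")
            if (vals < 0).any() or (vals > 100).any():
                raise ValueError(f"column {col!r} must lie in [0, 100]")
        fus = df[RESPONSE_COLUMN].to_numpy(dtype=float)
        if np.isnan(fus).any():
            raise ValueError(f"missing values in column {RESPONSE_COLUMN!r}")
        if (fus < 0).any():
            raise ValueError("fusion_rate must be non-negative")
        bad_roles = set(df["role"].unique()) - _ROLES
        if bad_roles:
            raise ValueError(f"unknown roles: {sorted(bad_roles)}; expected {_ROLES}")
        self.df = df

    # -- accessors -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    def subset(self, role: str) -> "SampleTable":
        """Rows with the given role, as a new table."""
        sub = self.df[self.df["role"] == role].reset_index(drop=True)
        return SampleTable(sub)

    def select_ids(self, ids: Sequence[str]) -> "SampleTable":
        """Rows for the given sample ids, in the given order."""
        idx = self.df.set_index("sample_id")
        try:
            sub = idx.loc[list(ids)].reset_index()
        except KeyError as exc:
            raise ValueError(f"unknown sample id: {exc.args[0]}") from exc
        return SampleTable(sub)

    def with_response(self, values: np.ndarray) -> "SampleTable":
        """Copy of the table with the response column replaced."""
        df = self.df.copy()
        df[RESPONSE_COLUMN] = np.asarray(values, dtype=float)
        return SampleTable(df)

    def predictors(self) -> np.ndarray:
        return self.df[list(PREDICTOR_COLUMNS)].to_numpy(dtype=float)

    def response(self) -> np.ndarray:
        return self.df[RESPONSE_COLUMN].to_numpy(dtype=float)

    # -- I/O -----------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleTable":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError as exc:
            raise ValueError("no samples") from exc
        if len(df) == 0:
            raise ValueError("no samples")
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def load_reference_table() -> SampleTable:
    """The packaged 12-sample PEF/electroporation/fusion table.

    Eight training and four test samples spanning pulse widths
    200 ns – 40 µs and field strengths 0 – 2.4 kV/cm, with the published
    train/test role assignment.
    """
    with resources.files("pulsepore.data").joinpath("pef_samples.csv").open() as fh:
        return SampleTable(pd.read_csv(fh))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


@dataclass
class Scaler:
    """Column-wise centering/scaling constants for X and y.

    Scaling is to zero mean and unit *sample* standard deviation
    (n − 1 denominator).  The stored constants invert the transform
    exactly.
    """

    x_means: np.ndarray
    x_sds: np.ndarray
    y_mean: float
    y_sd: float
    predictor_names: tuple[str, ...]
    response_name: str

    def transform_x(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_means) / self.x_sds

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.y_mean) / self.y_sd

    def inverse_x(self, Xs: np.ndarray) -> np.ndarray:
        return np.asarray(Xs, dtype=float) * self.x_sds + self.x_means

    def inverse_y(self, ys: np.ndarray) -> np.ndarray:
        return np.asarray(ys, dtype=float) * self.y_sd + self.y_mean


def autoscale(
    table: SampleTable,
    predictor_columns: Sequence[str] = PREDICTOR_COLUMNS,
    response_column: str = RESPONSE_COLUMN,
) -> tuple[np.ndarray, np.ndarray, Scaler]:
    """Center and scale predictors and response to mean 0, sample sd 1.

    Returns ``(X_scaled, y_scaled, scaler)``.  Raises on fewer than two
    rows or on any zero-variance column (named in the error).
    """
    df = table.df
    if len(df) < 2:
        raise ValueError("autoscale requires at least 2 rows")
    X = df[list(predictor_columns)].to_numpy(dtype=float)
    y = df[response_column].to_numpy(dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("NaN in input columns")
    x_means = X.mean(axis=0)
    x_sds = X.std(axis=0, ddof=1)
    for name, sd in zip(predictor_columns, x_sds):
        if sd == 0.0:
            raise ValueError(f"zero-variance column: {name!r}")
    y_sd = float(y.std(ddof=1))
    if y_sd == 0.0:
        raise ValueError(f"zero-variance column: {response_column!r}")
    scaler = Scaler(
        x_means=x_means,
        x_sds=x_sds,
        y_mean=float(y.mean()),
        y_sd=y_sd,
        predictor_names=tuple(predictor_columns),
        response_name=response_column,
    )
    return scaler.transform_x(X), scaler.transform_y(y), scaler


# ---------------------------------------------------------------------------
# NIPALS PLS
# ---------------------------------------------------------------------------


@dataclass
class PLSModel:
    """A fitted PLS model: scaling constants plus NIPALS matrices.

    ``W`` holds unit-norm predictor weight vectors (one column per latent
    component), ``T``/``P`` the X scores and loadings, ``U``/``C`` the Y
    scores and weights, and ``E``/``G``/``F`` the residual matrices of the
    X decomposition, the Y decomposition, and the regression, all on the
    scaled data.  ``coef_scaled`` maps scaled predictors directly to the
    scaled response.
    """

    scaler: Scaler
    n_components: int
    W: np.ndarray  # (p, a)
    T: np.ndarray  # (n, a)
    P: np.ndarray  # (p, a)
    U: np.ndarray  # (n, a)
    C: np.ndarray  # (a,)
    E: np.ndarray  # (n, p)
    G: np.ndarray  # (n,)
    F: np.ndarray  # (n,)
    coef_scaled: np.ndarray = field(default=None)  # (p,)

    def __post_init__(self) -> None:
        if self.coef_scaled is None:
            # B = W (P'W)^-1 C' collapses the sequential deflation into a
            # single linear map on scaled X.
            PtW = self.P.T @ self.W
            self.coef_scaled = self.W @ np.linalg.solve(PtW, self.C)

    # -- persistence ---------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "n_components": self.n_components,
            "predictor_names": list(self.scaler.predictor_names),
            "response_name": self.scaler.response_name,
            "x_means": self.scaler.x_means.tolist(),
            "x_sds": self.scaler.x_sds.tolist(),
            "y_mean": self.scaler.y_mean,
            "y_sd": self.scaler.y_sd,
            "W": self.W.tolist(),
            "P": self.P.tolist(),
            "C": self.C.tolist(),
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PLSModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        scaler = Scaler(
            x_means=np.asarray(doc["x_means"], dtype=float),
            x_sds=np.asarray(doc["x_sds"], dtype=float),
            y_mean=float(doc["y_mean"]),
            y_sd=float(doc["y_sd"]),
            predictor_names=tuple(doc["predictor_names"]),
            response_name=doc["response_name"],
        )
        W = np.asarray(doc["W"], dtype=float)
        P = np.asarray(doc["P"], dtype=float)
        C = np.asarray(doc["C"], dtype=float)
        a = int(doc["n_components"])
        empty = np.zeros((0, W.shape[0]))
        return cls(
            scaler=scaler, n_components=a, W=W, T=np.zeros((0, a)), P=P,
            U=np.zeros((0, a)), C=C, E=empty, G=np.zeros(0), F=np.zeros(0),
        )


def fit_pls(
    X_scaled: np.ndarray,
    y_scaled: np.ndarray,
    n_components: int,
    scaler: Scaler | None = None,
) -> PLSModel:
    """Fit a PLS model by NIPALS with per-component deflation of X.

    ``X_scaled`` and ``y_scaled`` are the autoscaled matrices.  For a
    single response the NIPALS inner loop converges in one pass and the
    first weight vector equals the normalized cross-covariance
    X'y / ‖X'y‖.  Weight vectors are sign-oriented so the entry of
    largest magnitude is positive (predictions are unaffected).

    When ``scaler`` is omitted an identity scaler is stored, so the model
    can be used directly on already-scaled data.
    """
    X = np.array(X_scaled, dtype=float)
    y = np.asarray(y_scaled, dtype=float)
    if y.ndim == 2:
        if y.shape[1] != 1:
            raise ValueError("only a single response column is supported")
        y = y[:, 0]
    y = y.copy()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y row counts differ")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("NaN in input")
    if not (1 <= n_components <= p):
        raise ValueError(
            f"n_components must be in [1, {p}] (number of predictors), got {n_components}"
        )

    y0 = y.copy()
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    U = np.zeros((n, n_components))
    C = np.zeros(n_components)

    for a in range(n_components):
        u = y.copy()
        t = np.zeros(n)
        # single-response NIPALS converges on the first pass; the loop is
        # retained for the multi-response extension path
        for _ in range(500):
            w = X.T @ u
            nw = np.linalg.norm(w)
            if nw == 0.0:
                raise ValueError("degenerate component: X'u vanished")
            w /= nw
            t_new = X @ w
            c = float(y @ t_new) / float(t_new @ t_new)
            u = y * c / (c * c) if c != 0.0 else y.copy()
            if np.linalg.norm(t_new - t) <= 1e-12 * max(1.0, np.linalg.norm(t_new)):
                t = t_new
                break
            t = t_new
        # sign convention: largest-|w| entry positive
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w, t, u, c = -w, -t, -u, -c
        pvec = X.T @ t / float(t @ t)
        X -= np.outer(t, pvec)
        y -= c * t
        W[:, a], T[:, a], P[:, a], U[:, a], C[a] = w, t, pvec, u, c

    if scaler is None:
        scaler = Scaler(
            x_means=np.zeros(p), x_sds=np.ones(p), y_mean=0.0, y_sd=1.0,
            predictor_names=tuple(f"x{i}" for i in range(p)),
            response_name="y",
        )
    return PLSModel(
        scaler=scaler, n_components=n_components,
        W=W, T=T, P=P, U=U, C=C,
        E=X, G=y0 - (U * C).sum(axis=1), F=y0 - T @ C,
    )


def fit_table(table: SampleTable, n_components: int = 1) -> PLSModel:
    """Autoscale a sample table's training rows and fit a PLS model.

    Uses the rows with role ``train`` if any are marked, otherwise all
    rows.  At least 3 rows are required for model fitting.
    """
    train = table.subset("train") if (table.df["role"] == "train").any() else table
    if len(train) < 3:
        raise ValueError("model fitting requires at least 3 rows")
    Xs, ys, scaler = autoscale(train)
    return fit_pls(Xs, ys, n_components, scaler=scaler)


def predict(model: PLSModel, X_new: np.ndarray | pd.DataFrame | SampleTable) -> np.ndarray:
    """Predict responses in original units for new predictor rows.

    Accepts a raw (n, p) array in the model's predictor column order, a
    DataFrame, or a SampleTable (columns are checked by name for the
    latter two).
    """
    if isinstance(X_new, SampleTable):
        X_new = X_new.df
    if isinstance(X_new, pd.DataFrame):
        missing = [c for c in model.scaler.predictor_names if c not in X_new.columns]
        if missing:
            raise ValueError(f"missing predictor columns: {missing}")
        X_new = X_new[list(model.scaler.predictor_names)].to_numpy(dtype=float)
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != len(model.scaler.predictor_names):
        raise ValueError(
            f"expected {len(model.scaler.predictor_names)} predictor columns, "
            f"got {X_new.shape[1]}"
        )
    Xs = model.scaler.transform_x(X_new)
    return model.scaler.inverse_y(Xs @ model.coef_scaled)


# ---------------------------------------------------------------------------
# Fit statistics
# ---------------------------------------------------------------------------


@dataclass
class FitStats:
    """Goodness-of-fit summary for a fitted PLS model.

    ``r2_test_ss`` is 1 − SSres/SStot about the held-out mean;
    ``r2_test_corr`` is the squared Pearson correlation of predicted vs
    observed.  Both held-out definitions are reported side by side since
    they generally differ.  ``q2_loo`` is the leave-one-out
    cross-validated R² on the training rows.
    """

    r2_train: float
    r2_test_ss: float | None
    r2_test_corr: float | None
    q2_loo: float | None

    def to_dict(self) -> dict:
        return {
            "r2_train": self.r2_train,
            "r2_test_ss": self.r2_test_ss,
            "r2_test_corr": self.r2_test_corr,
            "q2_loo": self.q2_loo,
        }


def r2_score_ss(observed: np.ndarray, predicted: np.ndarray) -> float:
    """1 − SSres/SStot about the mean of ``observed``."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    sstot = float(((observed - observed.mean()) ** 2).sum())
    if sstot == 0.0:
        raise ValueError("zero response variance")
    return 1.0 - float(((observed - predicted) ** 2).sum()) / sstot


def r2_score_corr(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Squared Pearson correlation of predicted vs observed."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.std() == 0.0:
        raise ValueError("zero response variance")
    if predicted.std() == 0.0:
        return 0.0
    return float(np.corrcoef(observed, predicted)[0, 1] ** 2)


def fit_stats(model: PLSModel, table: SampleTable, compute_q2: bool = True) -> FitStats:
    """Training R², both held-out R² definitions, and leave-one-out Q².

    Training rows are those with role ``train`` (all rows if none are
    marked); held-out statistics are reported when the table has ``test``
    rows, otherwise None.
    """
    has_roles = (table.df["role"] == "train").any()
    train = table.subset("train") if has_roles else table
    test = table.subset("test") if has_roles else None

    pred_train = predict(model, train)
    r2_train = r2_score_ss(train.response(), pred_train)

    r2_test_ss = r2_test_corr = None
    if test is not None and len(test) >= 2:
        pred_test = predict(model, test)
        r2_test_ss = r2_score_ss(test.response(), pred_test)
        r2_test_corr = r2_score_corr(test.response(), pred_test)

    q2 = None
    if compute_q2 and len(train) >= 3:
        from .validation import loo_q2  # deferred: validation builds on this module

        q2 = loo_q2(train, n_components=model.n_components)
    return FitStats(r2_train=r2_train, r2_test_ss=r2_test_ss,
                    r2_test_corr=r2_test_corr, q2_loo=q2)
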