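"""Leave-one-out prediction engine and (h, lambda) hyperparameter selection.

Because only a few hundred cells of the species x event matrix are known,
model assessment uses leave-one-out (LOO): each known observation is
predicted from a model refit on the remaining ones, the prediction is
back-transformed to days, and the prediction error is the mean squared
difference between observed and predicted timings on the original day
scale. For the network, every fold is refit from several random weight
initializations ("restarts") since training can end in local optima; the
per-restart errors are averaged. For the FD model the offset k is
re-estimated inside every training fold so the held-out value never
influences it.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design_matrix import ffnn_design
from .event_data import EventTimingTable
from .fd_model import fit_fd, predict_fd
from .ffnn_model import FFNNArch, predict_ffnn, train


@dataclass(frozen=True)
class FDSpec:
    """FD-model configuration for LOO runs; ``fixed_k=None`` re-estimates
    k within each training fold."""

    fixed_k: float | None = None
    grid_points: int = 200
    scale: str = "original"

    tag = "fd"


@dataclass(frozen=True)
class FFNNSpec:
    hidden_units: int = 1
    skip: bool = False
    decay: float = 0.05
    max_iter: int = 2000

    tag = "ffnn"


@dataclass
class LOOPrediction:
    """Per-observation LOO predictions (days).

    ``frame`` has one row per known observation with columns ``species,
    event, pc_day, is_primate, predicted`` (the restart mean);
    ``realizations`` holds the per-restart predictions, shape
    (n_obs, n_restarts) — a single column for the deterministic FD model.
    """

    frame: pd.DataFrame = field(repr=False)
    realizations: np.ndarray = field(repr=False)
    model_tag: str = "fd"
    spec: object = None

    @property
    def observed(self) -> np.ndarray:
        return self.frame["pc_day"].to_numpy()

    @property
    def predicted(self) -> np.ndarray:
        return self.frame["predicted"].to_numpy()

    def errors_per_restart(self) -> np.ndarray:
        """Day-scale mean squared error of each restart's predictions."""
        obs = self.observed
        return np.array([
            prediction_error(obs, self.realizations[:, r])
            for r in range(self.realizations.shape[1])
        ])


def fold_seed(master_seed: int, species: str, event: str, restart: int) -> int:
    """Deterministic per-(fold, restart) seed, independent of row order."""
    key = f"{master_seed}|{species}|{event}|{restart}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def loo_predict(
    table: EventTimingTable,
    spec: FDSpec | FFNNSpec,
    restarts: int = 10,
    seed: int = 0,
) -> LOOPrediction:
    """Leave each known observation out in turn and predict it.

    The table must already satisfy the coverage filter (every event in
    >= 2 species, every species with >= 2 events) so that dropping one
    observation never removes a species or event from the training fold.
    """
    df = table.data
    n = len(df)
    is_fd = isinstance(spec, FDSpec)
    n_real = 1 if is_fd else restarts
    preds = np.empty((n, n_real))
    for i, rec in enumerate(df.itertuples()):
        fold = table.drop_observation(rec.species, rec.event)
        if rec.species not in fold.species or rec.event not in fold.events:
            raise AssertionError(
                f"held-out ({rec.species}, {rec.event}) left the training fold "
                "unrepresented; run filter_min_coverage first"
            )
        if is_fd:
            fit = fit_fd(fold, k=spec.fixed_k, grid_points=spec.grid_points,
                         scale=spec.scale)
            preds[i, 0] = predict_fd(fit, rec.species, rec.event)
        else:
            design = ffnn_design(fold)
            arch = FFNNArch(n_inputs=design.n_cols,
                            hidden_units=spec.hidden_units,
                            skip=spec.skip, decay=spec.decay)
            y = np.log(fold.data["pc_day"].to_numpy())
            for r in range(restarts):
                s = fold_seed(seed, rec.species, rec.event, r)
                params = train(design.X, y, arch, seed=s, max_iter=spec.max_iter)
                preds[i, r] = predict_ffnn(params, design, rec.species, rec.event)

    frame = df[["species", "event", "pc_day", "is_primate"]].copy()
    frame["predicted"] = preds.mean(axis=1)
    return LOOPrediction(frame=frame, realizations=preds,
                         model_tag=spec.tag, spec=spec)


def prediction_error(observed, predicted) -> float:
    """Mean squared prediction error on the original day scale."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted lengths differ")
    if obs.size == 0:
        raise ValueError("need at least one observation")
    d = obs - pred
    return float(d @ d / d.size)


DEFAULT_LAMBDA_GRID = np.concatenate([[0.0], np.logspace(-3, 0, 21)])


@dataclass
class ErrorGrid:
    h_grid: list[int]
    lambda_grid: np.ndarray
    error: np.ndarray  # (len(h_grid), len(lambda_grid)), restart-averaged
    error_sd: np.ndarray  # across-restart standard deviation
    chosen: tuple[int, float]
    restarts: int
    mode: str = "average_errors"

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {"h": h, "lambda": lam, "error": self.error[i, j],
             "error_sd": self.error_sd[i, j]}
            for i, h in enumerate(self.h_grid)
            for j, lam in enumerate(self.lambda_grid)
        ]
        return pd.DataFrame.from_records(recs)


def grid_search(
    table: EventTimingTable,
    h_grid=(1, 2, 3, 4, 5),
    lambda_grid=None,
    restarts: int = 10,
    seed: int = 0,
    skip: bool = False,
    max_iter: int = 2000,
    mode: str = "average_errors",
) -> ErrorGrid:
    """LOO prediction error over a grid of hidden-unit counts and decay values.

    ``mode="average_errors"`` (default) computes the day-scale MSE of each
    restart's predictions and averages those errors; ``mode="error_of_mean"``
    computes one error from the restart-mean predictions. The chosen
    (h*, lambda*) minimizes the averaged grid, ties broken toward smaller
    h then smaller lambda.
    """
    h_grid = list(h_grid)
    lambda_grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(
        lambda_grid, dtype=float)
    if len(h_grid) == 0 or lambda_grid.size == 0:
        raise ValueError("grids must be nonempty")
    if mode not in ("average_errors", "error_of_mean"):
        raise ValueError("mode must be 'average_errors' or 'error_of_mean'")

    err = np.empty((len(h_grid), lambda_grid.size))
    sd = np.empty_like(err)
    for i, h in enumerate(h_grid):
        for j, lam in enumerate(lambda_grid):
            spec = FFNNSpec(hidden_units=h, skip=skip, decay=float(lam),
                            max_iter=max_iter)
            loo = loo_predict(table, spec, restarts=restarts, seed=seed)
            per_restart = loo.errors_per_restart()
            sd[i, j] = per_restart.std(ddof=1) if per_restart.size > 1 else 0.0
            if mode == "average_errors":
                err[i, j] = per_restart.mean()
            else:
                err[i, j] = prediction_error(loo.observed, loo.predicted)

    # argmin with ties toward smaller h then smaller lambda: C-order argmin
    # scans h-major, lambda-minor, and grids are ascending.
    flat = np.argmin(err)
    i_star, j_star = np.unravel_index(flat, err.shape)
    chosen = (h_grid[i_star], float(lambda_grid[j_star]))
    return ErrorGrid(h_grid=h_grid, lambda_grid=lambda_grid, error=err,
                     error_sd=sd, chosen=chosen, restarts=restarts, mode=mode)
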