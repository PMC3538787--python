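"""Absolute-error threshold profiles split by primate / non-primate group.

For a set of LOO predictions, N(theta) counts the observations whose
absolute prediction error |observed - predicted| exceeds theta days.
Because the empirical data under-represents primates and late (large
magnitude) events, the primate contribution to N(theta) is typically out
of proportion to the primate share of observations — the profile makes
that decomposition, and the overlap in large-error events between two
models, explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .loocv import LOOPrediction


class ExceedanceCounts(NamedTuple):
    n_total: int
    n_primate: int
    n_nonprimate: int


@dataclass
class ErrorProfile:
    theta_grid: np.ndarray
    n_total: np.ndarray
    n_primate: np.ndarray
    n_nonprimate: np.ndarray
    model_tag: str
    event_sets: list = field(repr=False)  # per-theta frozenset of (species, event)
    observations: frozenset = field(default_factory=frozenset, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "theta": self.theta_grid,
                "model": self.model_tag,
                "n_total": self.n_total,
                "n_primate": self.n_primate,
                "n_nonprimate": self.n_nonprimate,
            }
        )

    def exceedance_set(self, theta: float) -> frozenset:
        idx = np.nonzero(np.isclose(self.theta_grid, theta))[0]
        if idx.size == 0:
            raise KeyError(f"theta {theta} not in profile grid")
        return self.event_sets[int(idx[0])]


def absolute_errors(loo: LOOPrediction) -> pd.DataFrame:
    """Per-observation |observed - restart-mean predicted| in days.

    Columns: species, event, abs_error, is_primate.
    """
    df = loo.frame
    out = df[["species", "event", "is_primate"]].copy()
    out["abs_error"] = (df["pc_day"] - df["predicted"]).abs()
    return out[["species", "event", "abs_error", "is_primate"]]


def make_errors_frame(abs_errors, is_primate, species=None, events=None) -> pd.DataFrame:
    """Assemble an errors frame from plain arrays (for errors computed
    outside :func:`absolute_errors`); one synthetic (species, event) label
    per record unless explicit labels are given."""
    abs_errors = np.asarray(abs_errors, dtype=float)
    n = abs_errors.size
    return pd.DataFrame({
        "species": [f"sp{i}" for i in range(n)] if species is None else species,
        "event": [f"ev{i}" for i in range(n)] if events is None else events,
        "abs_error": abs_errors,
        "is_primate": np.asarray(is_primate, dtype=bool),
    })


def count_exceeding(errors: pd.DataFrame, theta: float) -> ExceedanceCounts:
    """Count records with error strictly greater than theta, by group."""
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    exceed = errors["abs_error"].to_numpy() > theta
    primate = errors["is_primate"].to_numpy().astype(bool)
    return ExceedanceCounts(
        n_total=int(exceed.sum()),
        n_primate=int((exceed & primate).sum()),
        n_nonprimate=int((exceed & ~primate).sum()),
    )


DEFAULT_THETA_GRID = np.arange(1.0, 31.0)


def profile(errors: pd.DataFrame, theta_grid=None,
            model_tag: str = "") -> ErrorProfile:
    """Exceedance counts and event sets over an ascending threshold grid."""
    grid = DEFAULT_THETA_GRID if theta_grid is None else np.asarray(
        theta_grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("theta_grid must be sorted ascending")
    n_t, n_p, n_np, sets = [], [], [], []
    err = errors["abs_error"].to_numpy()
    for theta in grid:
        c = count_exceeding(errors, theta)
        n_t.append(c.n_total)
        n_p.append(c.n_primate)
        n_np.append(c.n_nonprimate)
        sub = errors.loc[err > theta, ["species", "event"]]
        sets.append(frozenset(map(tuple, sub.itertuples(index=False))))
    universe = frozenset(
        map(tuple, errors[["species", "event"]].itertuples(index=False)))
    return ErrorProfile(
        theta_grid=grid,
        n_total=np.array(n_t),
        n_primate=np.array(n_p),
        n_nonprimate=np.array(n_np),
        model_tag=model_tag,
        event_sets=sets,
        observations=universe,
    )


def overlap(profile_a: ErrorProfile, profile_b: ErrorProfile,
            theta: float) -> tuple[frozenset, int]:
    """Events exceeding theta under both models (set and its size).

    Both profiles must be computed on the same observation set; events
    flagged by both models regardless of method indicate cells that are
    intrinsically hard to predict.
    """
    if profile_a.observations != profile_b.observations:
        raise ValueError("profiles computed on different observation sets")
    inter = profile_a.exceedance_set(theta) & profile_b.exceedance_set(theta)
    return inter, len(inter)


def overlap_profile(profile_a: ErrorProfile, profile_b: ErrorProfile) -> pd.DataFrame:
    """Overlap counts across the (shared) theta grid of two profiles."""
    if not np.array_equal(profile_a.theta_grid, profile_b.theta_grid):
        raise ValueError("profiles use different theta grids")
    counts = [len(a & b) for a, b in zip(profile_a.event_sets, profile_b.event_sets)]
    return pd.DataFrame({
        "theta": profile_a.theta_grid,
        "n_overlap": counts,
    })
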