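"""Single-trial pattern estimation: the least-squares-all (LSA) GLM.

Every trial in a run receives its own regressor — a boxcar over the word
presentation period convolved with a gamma haemodynamic response function —
and all trial regressors are fitted jointly by ordinary least squares at each
in-mask voxel.  Per-trial coefficient patterns are then averaged over each
item's repetitions across runs, and the condition-mean pattern ("cocktail
blank") is subtracted before any similarity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .lexicon import CONDITIONS

DEFAULT_TR = 1.8
DEFAULT_HRF_LAG = 6.0
DEFAULT_HRF_SIGMA = 3.0
DEFAULT_DURATION = 2.5
DEFAULT_SOA = 6.0

__all__ = [
    "BoldRun",
    "DesignMatrix",
    "TrialPatternSet",
    "ItemPatternSet",
    "gamma_hrf",
    "build_design_matrix",
    "validate_events",
    "TrialGLM",
    "TrialGLMResults",
    "fit_lsa",
    "average_item_patterns",
    "subtract_condition_mean",
]


@dataclass
class BoldRun:
    """One 4D functional run with its acquisition geometry."""

    data: np.ndarray  # (x, y, z, t)
    tr: float
    mask: np.ndarray  # (x, y, z) boolean
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    run_id: str = "run-01"

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D (x, y, z, time)")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match spatial dimensions")
        self.mask = self.mask.astype(bool)

    @property
    def n_vols(self) -> int:
        return self.data.shape[3]

    @property
    def duration(self) -> float:
        return self.n_vols * self.tr


def validate_events(events: pd.DataFrame, run_length: float | None = None) -> pd.DataFrame:
    """Check an events table (columns onset, duration, word, condition)."""
    required = {"onset", "duration", "word", "condition"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events table missing columns {sorted(missing)}")
    onsets = events["onset"].to_numpy(float)
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("onsets must be strictly increasing")
    if events["word"].duplicated().any():
        dup = events.loc[events["word"].duplicated(), "word"].iloc[0]
        raise ValueError(f"word {dup!r} appears more than once in the run")
    bad = set(events["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions {sorted(bad)}")
    if run_length is not None:
        ends = onsets + events["duration"].to_numpy(float)
        if np.any(ends > run_length + 1e-9):
            raise ValueError("trial extends past the end of the run")
    return events


def gamma_hrf(
    lag: float = DEFAULT_HRF_LAG,
    sigma: float = DEFAULT_HRF_SIGMA,
    dt: float = 0.1,
    span: float = 30.0,
) -> np.ndarray:
    """Gamma-density HRF kernel sampled at ``dt``, normalised to unit sum.

    ``lag`` is the response mean and ``sigma`` its standard deviation, giving
    gamma shape (lag/sigma)^2 and scale sigma^2/lag — with the 6 s / 3 s
    defaults, shape 4 and scale 1.5 s (mode at 4.5 s).
    """
    if lag <= 0 or sigma <= 0 or dt <= 0:
        raise ValueError("lag, sigma and dt must be positive")
    shape = (lag / sigma) ** 2
    scale = sigma**2 / lag
    t = np.arange(0.0, span + dt / 2, dt)
    kernel = stats.gamma.pdf(t, a=shape, scale=scale)
    return kernel / kernel.sum()


@dataclass
class DesignMatrix:
    """Time x regressor matrix: trial columns first, then nuisance + intercept."""

    matrix: np.ndarray
    trial_info: pd.DataFrame  # word, condition, onset per trial column
    n_nuisance: int  # nuisance columns including the intercept

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[1] - self.n_nuisance

    @property
    def n_vols(self) -> int:
        return self.matrix.shape[0]


def build_design_matrix(
    events: pd.DataFrame,
    n_vols: int,
    tr: float = DEFAULT_TR,
    hrf: np.ndarray | None = None,
    dt: float = 0.1,
    nuisance: np.ndarray | None = None,
) -> DesignMatrix:
    """One HRF-convolved boxcar regressor per trial, plus nuisance + intercept.

    Boxcars are laid out on a fine grid (step ``dt``), convolved with the
    ``hrf`` kernel (sampled at the same ``dt``), and read off at the volume
    acquisition times t = i * TR.  An intercept column is always appended.
    """
    events = validate_events(events, run_length=n_vols * tr)
    if hrf is None:
        hrf = gamma_hrf(dt=dt)
    grid_len = int(np.ceil(n_vols * tr / dt)) + len(hrf) + 1
    vol_idx = np.round(np.arange(n_vols) * tr / dt).astype(int)
    cols = []
    for row in events.itertuples(index=False):
        boxcar = np.zeros(grid_len)
        i0 = int(np.round(row.onset / dt))
        i1 = int(np.round((row.onset + row.duration) / dt))
        boxcar[i0:i1] = 1.0
        conv = np.convolve(boxcar, hrf)[:grid_len]
        col = conv[vol_idx]
        if not np.any(col):
            raise ValueError(f"trial {row.word!r} yields an all-zero regressor")
        cols.append(col)
    trial_block = (
        np.column_stack(cols) if cols else np.empty((n_vols, 0))
    )
    nuis_cols = [np.ones((n_vols, 1))]
    if nuisance is not None:
        nuisance = np.asarray(nuisance, float)
        if nuisance.shape[0] != n_vols:
            raise ValueError("nuisance matrix must have one row per volume")
        nuis_cols.insert(0, nuisance)
    nuis_block = np.column_stack(nuis_cols)
    info = events[["word", "condition", "onset"]].reset_index(drop=True)
    return DesignMatrix(
        np.column_stack([trial_block, nuis_block]), info, nuis_block.shape[1]
    )


@dataclass
class TrialPatternSet:
    """Per-trial GLM coefficients (trial x in-mask voxel) with trial metadata."""

    patterns: np.ndarray
    trial_info: pd.DataFrame  # word, condition, run
    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        if self.patterns.shape[0] != len(self.trial_info):
            raise ValueError("one metadata row per trial pattern required")
        if self.patterns.shape[1] != int(self.mask.sum()):
            raise ValueError("voxel count must equal mask size")


@dataclass
class ItemPatternSet:
    """Item-level activation patterns (item x in-mask voxel) for one condition."""

    patterns: np.ndarray
    items: tuple[str, ...]
    condition: str
    mask: np.ndarray
    affine: np.ndarray
    centered: bool = False

    def __post_init__(self) -> None:
        if self.patterns.shape[0] != len(self.items):
            raise ValueError("one item label per pattern row required")
        if self.patterns.shape[1] != int(self.mask.sum()):
            raise ValueError("voxel count must equal mask size")


class TrialGLM:
    """Least-squares-all single-trial GLM for one functional run.

    Parameters
    ----------
    run : BoldRun
    events : DataFrame
        BIDS-style events with columns onset, duration, word, condition.
    hrf : ndarray, optional
        HRF kernel sampled at ``dt`` (default: gamma, lag 6 s, sigma 3 s).
    nuisance : ndarray, optional
        Volumes x k matrix of no-interest regressors (e.g. motion parameters);
        an intercept is always added.
    detrend : bool
        Remove a per-voxel linear trend before fitting (off by default; a
        stand-in for high-pass filtering when consuming real data).
    """

    def __init__(
        self,
        run: BoldRun,
        events: pd.DataFrame,
        hrf: np.ndarray | None = None,
        dt: float = 0.1,
        nuisance: np.ndarray | None = None,
        detrend: bool = False,
    ):
        self.run = run
        self.events = validate_events(events, run_length=run.duration)
        self.design = build_design_matrix(
            events, run.n_vols, run.tr, hrf=hrf, dt=dt, nuisance=nuisance
        )
        self.detrend = detrend

    def fit(self) -> "TrialGLMResults":
        pats = fit_lsa(self.run, self.design, detrend=self.detrend)
        return TrialGLMResults(self, pats)


@dataclass
class TrialGLMResults:
    model: TrialGLM
    trial_patterns: TrialPatternSet

    def summary(self) -> str:
        d = self.model.design
        return (
            f"TrialGLM (LSA): {d.n_trials} trial regressors + {d.n_nuisance} nuisance, "
            f"{d.n_vols} volumes, {self.trial_patterns.patterns.shape[1]} voxels"
        )


def fit_lsa(run: BoldRun, design: DesignMatrix, detrend: bool = False) -> TrialPatternSet:
    """OLS fit of the full trial design at every in-mask voxel.

    Returns trial coefficients only; nuisance and intercept coefficients are
    discarded.  Raises on a rank-deficient design.
    """
    X = design.matrix
    if X.shape[0] != run.n_vols:
        raise ValueError(
            f"design has {X.shape[0]} rows but run has {run.n_vols} volumes"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    Y = run.data[run.mask].T.astype(float)  # time x voxel
    if detrend:
        t = np.arange(run.n_vols, dtype=float)
        t = (t - t.mean()) / t.std()
        trend = np.column_stack([np.ones_like(t), t])
        Y = Y - trend @ np.linalg.lstsq(trend, Y, rcond=None)[0]
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    info = design.trial_info.copy()
    info["run"] = run.run_id
    return TrialPatternSet(beta[: design.n_trials], info, run.mask, run.affine)


def average_item_patterns(
    trial_sets: list[TrialPatternSet],
    condition: str,
    item_order: list[str] | None = None,
    n_reps: int = 4,
) -> ItemPatternSet:
    """Average each item's per-trial patterns across runs.

    Every item must appear exactly ``n_reps`` times across the pooled trial
    sets.  ``item_order`` fixes the row order (default: lexicon order as first
    encountered, sorted for stability across run orderings).
    """
    pooled = pd.concat([s.trial_info for s in trial_sets], ignore_index=True)
    pats = np.vstack([s.patterns for s in trial_sets])
    sel = pooled["condition"] == condition
    pooled, pats = pooled[sel], pats[sel.to_numpy()]
    counts = pooled["word"].value_counts()
    wrong = counts[counts != n_reps]
    if len(wrong):
        raise ValueError(
            f"word {wrong.index[0]!r} has {int(wrong.iloc[0])} repetitions, expected {n_reps}"
        )
    items = item_order if item_order is not None else sorted(counts.index)
    missing = set(items) - set(counts.index)
    if missing:
        raise ValueError(f"no trials found for words {sorted(missing)}")
    rows = np.stack(
        [pats[(pooled["word"] == w).to_numpy()].mean(axis=0) for w in items]
    )
    ref = trial_sets[0]
    return ItemPatternSet(rows, tuple(items), condition, ref.mask, ref.affine, False)


def subtract_condition_mean(items: ItemPatternSet) -> ItemPatternSet:
    """Remove the across-item mean pattern at every voxel (idempotent)."""
    if items.patterns.shape[0] < 2:
        raise ValueError("mean-pattern subtraction needs at least 2 items")
    centered = items.patterns - items.patterns.mean(axis=0, keepdims=True)
    return replace(items, patterns=centered, centered=True)
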