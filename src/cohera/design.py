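"""First-level fMRI design construction.

Four event types are modelled: extended speech planning (8-s blocks),
extended speech production (50-s periods decomposed into concatenated
5-s blocks), automatic speech planning and automatic speech production
(the rote-speech baseline, 15-s periods). Block-level covariates such
as coherence and time-in-trial enter as parametric modulators: the 5-s
boxcars are scaled by the (winsorized, mean-centred) covariate before
convolution with the canonical double-gamma haemodynamic response
function. Nuisance columns (motion parameters, externally supplied
noise components), a discrete-cosine drift basis (cutoff 180 s) and
per-run intercepts complete the matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "TrialTiming",
    "ModulatorSeries",
    "DesignMatrix",
    "prepare_modulator",
    "shift_modulator",
    "time_in_trial_covariate",
    "canonical_hrf",
    "hrf_convolve",
    "dct_drift_basis",
    "build_design",
    "CONDITIONS",
]

logger = logging.getLogger(__name__)

CONDITIONS = (
    "extended_planning",
    "extended_production",
    "automatic_planning",
    "automatic_production",
)

DEFAULT_TR = 2.2  # seconds
DEFAULT_HIGHPASS = 180.0  # seconds
DEFAULT_BLOCK_LENGTH = 5.0  # seconds
DEFAULT_WINSOR_SD = 2.0
MICROTIME_RESOLUTION = 16  # bins per TR
MICROTIME_ONSET = 8  # sampled bin (middle of the volume)

DEFAULT_DURATIONS = {
    "extended_planning": 8.0,
    "extended_production": 50.0,
    "automatic_planning": 8.0,
    "automatic_production": 15.0,
}


@dataclass
class TrialTiming:
    condition: str
    onset: float  # seconds from run start
    duration: float
    run_id: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.onset < 0:
            raise ValueError("onset must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class ModulatorSeries:
    """Per-block covariate values for the production blocks of one or
    more runs, plus the trial each block belongs to."""

    values: np.ndarray
    run_ids: np.ndarray
    trial_ids: np.ndarray | None = None  # needed for within-trial shifting
    centered: bool = False
    winsorized: bool = False
    bounds: dict[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.run_ids = np.asarray(self.run_ids)
        if self.values.shape != self.run_ids.shape:
            raise ValueError("values and run_ids must align")
        if self.trial_ids is not None:
            self.trial_ids = np.asarray(self.trial_ids)
            if self.trial_ids.shape != self.values.shape:
                raise ValueError("trial_ids must align with values")


def prepare_modulator(
    values: np.ndarray | ModulatorSeries,
    run_ids: np.ndarray | None = None,
    trial_ids: np.ndarray | None = None,
    winsor_sd: float = DEFAULT_WINSOR_SD,
) -> ModulatorSeries:
    """Winsorize and mean-centre a parametric modulator, per run.

    Within each run, values more than ``winsor_sd`` standard deviations
    from the run mean (both computed on the raw values, SD with n-1
    denominator) are clipped to that bound, then the post-clipping mean
    is subtracted so the prepared series is exactly zero-mean per run.

    Preparation is idempotent by contract: the winsorization bound is
    defined on the raw run statistics, so an already-prepared series is
    returned unchanged.
    """
    if isinstance(values, ModulatorSeries):
        if values.centered and values.winsorized:
            return values
        series = values
        values, run_ids, trial_ids = series.values, series.run_ids, series.trial_ids
    if run_ids is None:
        run_ids = np.zeros(len(values), dtype=int)
    values = np.asarray(values, dtype=float).copy()
    run_ids = np.asarray(run_ids)
    bounds: dict[int, tuple[float, float]] = {}
    for run in np.unique(run_ids):
        sel = run_ids == run
        if np.sum(sel) < 2:
            raise ValueError(f"run {run} has fewer than 2 blocks")
        v = values[sel]
        m, sd = float(np.mean(v)), float(np.std(v, ddof=1))
        if sd == 0:
            logger.warning("run %s modulator has zero variance; centering only", run)
            values[sel] = v - m
            bounds[int(run)] = (-0.0, 0.0)
            continue
        lo, hi = m - winsor_sd * sd, m + winsor_sd * sd
        clipped = np.clip(v, lo, hi)
        post_mean = float(np.mean(clipped))
        values[sel] = clipped - post_mean
        bounds[int(run)] = (lo - post_mean, hi - post_mean)
    return ModulatorSeries(
        values=values,
        run_ids=run_ids,
        trial_ids=trial_ids,
        centered=True,
        winsorized=True,
        bounds=bounds,
    )


def shift_modulator(series: ModulatorSeries, shift: int) -> ModulatorSeries:
    """Shift modulator values in time by whole blocks, within trials.

    ``shift = -1`` is the early model (the value for block 4 appears at
    block 3); ``shift = +1`` the late model (block 4's value appears at
    block 5). The block left vacant at a trial edge receives its
    nearest within-trial neighbour's value (logged); no values leak
    across trials.
    """
    if series.trial_ids is None:
        raise ValueError("shifting requires trial_ids")
    new = series.values.copy()
    for trial in np.unique(series.trial_ids):
        idx = np.flatnonzero(series.trial_ids == trial)
        n = len(idx)
        if abs(shift) >= n:
            raise ValueError(f"|shift|={abs(shift)} >= blocks per trial ({n})")
        v = series.values[idx]
        out = np.empty_like(v)
        for pos in range(n):
            src = pos - shift
            if src < 0 or src >= n:
                src = min(max(src, 0), n - 1)
                logger.info("trial %s block %d filled from edge", trial, pos + 1)
            out[pos] = v[src]
        new[idx] = out
    return replace(series, values=new)


def time_in_trial_covariate(
    trial: TrialTiming, block_length: float = DEFAULT_BLOCK_LENGTH
) -> np.ndarray:
    """Raw block-position covariate 1..n_blocks for one production trial."""
    if trial.condition != "extended_production":
        raise ValueError("time-in-trial is defined for production trials")
    n_blocks = int(round(trial.duration / block_length))
    return np.arange(1, n_blocks + 1, dtype=float)


def canonical_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma HRF.

    Positive gamma (shape 6, scale 1, peaking near 5-6 s) minus an
    undershoot gamma (shape 16) scaled by 1/6; support truncated at
    32 s; peak normalized to 1.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = (t > 0) & (t <= 32.0)
    tp = t[pos]

    def gpdf(x: np.ndarray, shape: float) -> np.ndarray:
        return np.exp((shape - 1) * np.log(x) - x - gammaln(shape))

    h = gpdf(tp, 6.0) - gpdf(tp, 16.0) / 6.0
    out[pos] = h
    peak = out.max()
    return out / peak if peak > 0 else out


def _microtime_grid(n_volumes: int, tr: float) -> np.ndarray:
    dt = tr / MICROTIME_RESOLUTION
    return np.arange(n_volumes * MICROTIME_RESOLUTION) * dt


def hrf_convolve(
    boxcar: np.ndarray, tr: float, n_volumes: int | None = None
) -> np.ndarray:
    """Convolve a microtime-resolution stimulus with the canonical HRF
    and sample at the middle microtime bin of each volume.

    ``boxcar`` is the stimulus evaluated on the microtime grid
    (16 bins per TR); the result has one value per volume.
    """
    boxcar = np.asarray(boxcar, dtype=float)
    if n_volumes is None:
        n_volumes = len(boxcar) // MICROTIME_RESOLUTION
    dt = tr / MICROTIME_RESOLUTION
    hrf_t = np.arange(0, 32.0 + dt, dt)
    kernel = canonical_hrf(hrf_t)
    conv = np.convolve(boxcar, kernel)[: len(boxcar)] * dt
    sample_idx = np.arange(n_volumes) * MICROTIME_RESOLUTION + MICROTIME_ONSET
    sample_idx = np.minimum(sample_idx, len(conv) - 1)
    return conv[sample_idx]


def boxcar_on_grid(
    onset: float, duration: float, n_volumes: int, tr: float, height: float = 1.0
) -> np.ndarray:
    """Indicator (or scaled indicator) of [onset, onset+duration) on the
    microtime grid."""
    if duration < 0:
        raise ValueError("negative duration")
    grid = _microtime_grid(n_volumes, tr)
    return np.where((grid >= onset) & (grid < onset + duration), height, 0.0)


def dct_drift_basis(n_volumes: int, tr: float,
                    cutoff: float = DEFAULT_HIGHPASS) -> np.ndarray:
    """Discrete-cosine drift basis for periods longer than ``cutoff``.

    Number of columns = floor(2 * run_length / cutoff), excluding the
    constant (per-run intercepts are separate columns).
    """
    run_length = n_volumes * tr
    n_basis = int(np.floor(2.0 * run_length / cutoff))
    t = np.arange(n_volumes)
    cols = [
        np.cos(np.pi * k * (t + 0.5) / n_volumes) for k in range(1, n_basis + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_volumes, 0))


@dataclass
class DesignMatrix:
    matrix: pd.DataFrame  # volumes x regressors
    tr: float
    run_ids: np.ndarray  # per-volume run label

    @property
    def names(self) -> list[str]:
        return list(self.matrix.columns)

    def to_tsv(self, path) -> None:
        self.matrix.assign(run=self.run_ids).to_csv(path, sep="\t", index=False)


def _production_block_boxcar(
    timings: list[TrialTiming],
    block_values_by_trial: dict[int, np.ndarray],
    n_volumes: int,
    tr: float,
    block_length: float,
) -> np.ndarray:
    """Sum of 5-s boxcars over all production trials, each block scaled
    by its modulator value, on the microtime grid."""
    grid = np.zeros(n_volumes * MICROTIME_RESOLUTION)
    for ti, trial in enumerate(timings):
        if trial.condition != "extended_production":
            continue
        vals = block_values_by_trial[ti]
        for b, v in enumerate(vals):
            onset = trial.onset + b * block_length
            grid += boxcar_on_grid(onset, block_length, n_volumes, tr, height=v)
    return grid


def build_design(
    timings: list[TrialTiming],
    modulators: dict[str, ModulatorSeries],
    nuisance: pd.DataFrame | None,
    n_volumes: int,
    tr: float = DEFAULT_TR,
    run_ids: np.ndarray | None = None,
    block_length: float = DEFAULT_BLOCK_LENGTH,
    highpass: float = DEFAULT_HIGHPASS,
) -> DesignMatrix:
    """Assemble the first-level design matrix.

    Columns, in order: one HRF-convolved regressor per condition; one
    column per parametric modulator (modulated 5-s production boxcars,
    convolved); nuisance covariates as supplied (motion parameters and
    noise components, unconvolved); a DCT drift basis per run; one
    intercept per run.

    Modulator series must be ordered as production blocks occur in
    time; each series carries ``trial_ids`` indexing production trials
    (position in the timing list). Events extending past the scan end
    are truncated with a warning; modulator length mismatches raise.
    """
    if run_ids is None:
        run_ids = np.zeros(n_volumes, dtype=int)
    run_ids = np.asarray(run_ids)
    if len(run_ids) != n_volumes:
        raise ValueError("run_ids must have one entry per volume")

    scan_end = n_volumes * tr
    timings = list(timings)
    for tr_ev in timings:
        if tr_ev.onset >= scan_end:
            raise ValueError(f"event at {tr_ev.onset}s starts past scan end")
        if tr_ev.onset + tr_ev.duration > scan_end:
            logger.warning("event at %.1fs truncated at scan end", tr_ev.onset)

    cols: dict[str, np.ndarray] = {}
    for cond in CONDITIONS:
        grid = np.zeros(n_volumes * MICROTIME_RESOLUTION)
        any_event = False
        for t in timings:
            if t.condition == cond:
                grid += boxcar_on_grid(t.onset, t.duration, n_volumes, tr)
                any_event = True
        if any_event:
            cols[cond] = hrf_convolve(grid, tr, n_volumes)

    prod_idx = [i for i, t in enumerate(timings)
                if t.condition == "extended_production"]
    n_prod_blocks = sum(
        int(round(timings[i].duration / block_length)) for i in prod_idx
    )
    for name, series in modulators.items():
        if len(series.values) != n_prod_blocks:
            raise ValueError(
                f"modulator {name!r} has {len(series.values)} values; "
                f"{n_prod_blocks} production blocks exist"
            )
        if series.trial_ids is None:
            raise ValueError(f"modulator {name!r} lacks trial_ids")
        by_trial: dict[int, np.ndarray] = {}
        for ti in prod_idx:
            by_trial[ti] = series.values[series.trial_ids == ti]
        grid = _production_block_boxcar(
            timings, by_trial, n_volumes, tr, block_length
        )
        cols[f"mod_{name}"] = hrf_convolve(grid, tr, n_volumes)

    if nuisance is not None:
        if len(nuisance) != n_volumes:
            raise ValueError("nuisance table must have one row per volume")
        for c in nuisance.columns:
            cols[f"nuis_{c}"] = nuisance[c].to_numpy(dtype=float)

    for run in np.unique(run_ids):
        sel = run_ids == run
        basis = dct_drift_basis(int(np.sum(sel)), tr, cutoff=highpass)
        for j in range(basis.shape[1]):
            col = np.zeros(n_volumes)
            col[sel] = basis[:, j]
            cols[f"drift_run{run}_{j + 1}"] = col
    for run in np.unique(run_ids):
        cols[f"intercept_run{run}"] = (run_ids == run).astype(float)

    return DesignMatrix(
        matrix=pd.DataFrame(cols), tr=tr, run_ids=run_ids
    )
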