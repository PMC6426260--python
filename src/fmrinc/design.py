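"""Stimulus designs: event schedules and HRF-convolved design matrices.

The design matrix ``Phi`` (time points x stimuli) encodes when each stimulus
was presented, convolved with a canonical haemodynamic response function
(HRF).  Runs are independent acquisition blocks: the convolution never bleeds
across a run boundary, and the same stimulus column collects events from every
run in which the stimulus appears.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StimulusDesign",
    "canonical_hrf",
    "design_from_events",
    "make_event_design",
]


def canonical_hrf(tr_seconds: float, duration_seconds: float = 32.0) -> np.ndarray:
    """Sample the canonical double-gamma HRF at the repetition time.

    Difference of two unit-dispersion gamma densities with response peak at
    6 s, undershoot peak at 16 s and a peak-to-undershoot amplitude ratio
    of 6.  The kernel is normalised to unit peak.

    Parameters
    ----------
    tr_seconds : repetition time (sampling interval) in seconds.
    duration_seconds : kernel support; 32 s covers the undershoot tail.
    """
    from scipy.stats import gamma

    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    t = np.arange(0.0, duration_seconds + 1e-9, tr_seconds)
    # gamma(shape a, unit scale) peaks at a - 1: shapes 7 and 17 put the
    # response and undershoot modes at exactly 6 s and 16 s
    h = gamma.pdf(t, 7.0) - gamma.pdf(t, 17.0) / 6.0
    peak = np.max(np.abs(h))
    if peak > 0:
        h = h / peak
    return h


@dataclass
class StimulusDesign:
    """HRF-convolved design matrix with run structure.

    Attributes
    ----------
    matrix : (T, n_stimuli) float array, the design matrix Phi.
    run_index : (T,) int array of contiguous, non-decreasing run labels.
    tr_seconds : repetition time in seconds.
    events : long-format table (run, onset_tr, stimulus) of the pre-convolution
        event indicators; used by tests and provenance, not by the solvers.
    """

    matrix: np.ndarray
    run_index: np.ndarray
    tr_seconds: float
    events: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.run_index = np.asarray(self.run_index)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2-D (time x stimuli)")
        if self.run_index.shape[0] != self.matrix.shape[0]:
            raise ValueError("run_index length must match design rows")
        if np.any(np.diff(self.run_index) < 0):
            raise ValueError("run_index must be non-decreasing")

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_runs(self) -> int:
        return int(np.unique(self.run_index).size)

    @property
    def run_ids(self) -> np.ndarray:
        return np.unique(self.run_index)

    def run_slice(self, run) -> slice:
        idx = np.flatnonzero(self.run_index == run)
        if idx.size == 0:
            raise KeyError(f"run {run!r} not present")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def run_matrix(self, run) -> np.ndarray:
        return self.matrix[self.run_slice(run)]


def design_from_events(
    events: pd.DataFrame,
    run_lengths: dict,
    tr_seconds: float,
    n_stimuli: int | None = None,
) -> StimulusDesign:
    """Build an HRF-convolved design matrix from an event table.

    ``events`` needs columns ``run``, ``onset_tr`` (integer volume index
    within the run) and ``stimulus`` (0-based stimulus index).  Stimuli are
    modelled as impulses at their onset volume; each run is convolved
    separately so the HRF never crosses a run boundary.
    """
    required = {"run", "onset_tr", "stimulus"}
    if not required.issubset(events.columns):
        raise ValueError(f"event table must have columns {sorted(required)}")
    if n_stimuli is None:
        n_stimuli = int(events["stimulus"].max()) + 1
    hrf = canonical_hrf(tr_seconds)

    blocks, run_labels = [], []
    for run, t_run in run_lengths.items():
        sub = events[events["run"] == run]
        if len(sub) and int(sub["onset_tr"].max()) >= t_run:
            raise ValueError(
                f"run {run!r} is too short ({t_run} volumes) for its events "
                f"(last onset at volume {int(sub['onset_tr'].max())})"
            )
        ind = np.zeros((t_run, n_stimuli))
        ind[sub["onset_tr"].to_numpy(), sub["stimulus"].to_numpy()] = 1.0
        block = np.apply_along_axis(
            lambda col: np.convolve(col, hrf)[:t_run], 0, ind
        )
        blocks.append(block)
        run_labels.append(np.full(t_run, run))
    return StimulusDesign(
        matrix=np.vstack(blocks),
        run_index=np.concatenate(run_labels),
        tr_seconds=tr_seconds,
        events=events.reset_index(drop=True),
    )


def make_event_design(
    n_stimuli: int,
    n_runs: int,
    tr_seconds: float = 2.6,
    isi_jitter=(2, 3, 4),
    seed=None,
    n_timepoints_per_run: int | None = None,
) -> StimulusDesign:
    """Generate a fast event-related design: every stimulus once per run.

    Within each run the stimulus order is a fresh random permutation and the
    inter-stimulus interval is drawn uniformly from ``isi_jitter`` (in TRs).
    A tail long enough for the HRF to decay is appended to each run.

    Parameters
    ----------
    n_timepoints_per_run : optional fixed run length; raises if shorter than
        the schedule requires.
    """
    if n_stimuli < 1:
        raise ValueError("n_stimuli must be >= 1")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    jitter = np.asarray(list(isi_jitter), dtype=int)
    if jitter.size == 0 or np.any(jitter <= 0):
        raise ValueError("isi_jitter values must be positive integers")
    rng = np.random.default_rng(seed)
    tail = int(np.ceil(32.0 / tr_seconds))

    rows = []
    run_lengths: dict[int, int] = {}
    for run in range(n_runs):
        order = rng.permutation(n_stimuli)
        gaps = rng.choice(jitter, size=n_stimuli)
        onsets = np.concatenate([[0], np.cumsum(gaps[:-1])])
        needed = int(onsets[-1]) + tail + 1
        if n_timepoints_per_run is not None:
            if n_timepoints_per_run < needed:
                raise ValueError(
                    f"run length {n_timepoints_per_run} cannot hold "
                    f"{n_stimuli} events with the requested jitter "
                    f"(needs >= {needed} volumes)"
                )
            needed = n_timepoints_per_run
        run_lengths[run] = needed
        for stim, onset in zip(order, onsets):
            rows.append((run, int(onset), int(stim)))
    events = pd.DataFrame(rows, columns=["run", "onset_tr", "stimulus"])
    return design_from_events(events, run_lengths, tr_seconds, n_stimuli)
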