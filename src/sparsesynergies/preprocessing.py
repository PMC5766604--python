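"""Trial resampling, normalization, vectorization, splitting, noise.

Raw dataglove recordings are variable-length joint-angle time series.  The
pipeline resamples each trial to a common length, maps every sensor
linearly into [-1, 1], and flattens trials time-major into the rows of a
single data matrix X (n trials x p = s*len coordinates).  Evaluation noise
is injected only into validation/test copies, on the normalized scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TrialRecording:
    """One grasp trial: a (time x sensors) joint-angle series with a label."""

    trial_id: int
    class_label: str
    angles: np.ndarray  # (raw_length, s)

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2 or self.angles.shape[0] < 2:
            raise ValueError(
                f"trial {self.trial_id}: angles must be (length >= 2, s), "
                f"got shape {self.angles.shape}"
            )

    @property
    def s(self) -> int:
        return self.angles.shape[1]


@dataclass
class KinematicDataset:
    """Vectorized actions: X is (n, p) with p = s*length, one label per row."""

    X: np.ndarray
    labels: np.ndarray
    s: int
    length: int
    sensor_min: np.ndarray | None = None
    sensor_max: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.shape[1] != self.s * self.length:
            raise ValueError(
                f"p = {self.X.shape[1]} does not equal s*length = {self.s * self.length}"
            )
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("one label per row required")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset(self, class_labels) -> "KinematicDataset":
        """Rows belonging to the given classes (Scenario-2 subproblems)."""
        mask = np.isin(self.labels, list(class_labels))
        return KinematicDataset(
            X=self.X[mask], labels=self.labels[mask], s=self.s, length=self.length,
            sensor_min=self.sensor_min, sensor_max=self.sensor_max,
        )


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint train/validation/test row indices, stratified 0.4/0.3/0.3."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray


def truncate_movement(trial: TrialRecording, threshold: float = 0.05,
                      pad: int = 1) -> TrialRecording:
    """Keep only the interval in which the hand is actually moving.

    Real recordings bracket the reach with rest; this trims leading and
    trailing samples whose maximal per-sensor speed (first difference)
    stays below ``threshold`` times the trial's peak speed, padded by
    ``pad`` samples.  Synthetic trials are generated already-trimmed and
    bypass this.
    """
    speed = np.abs(np.diff(trial.angles, axis=0)).max(axis=1)
    peak = speed.max()
    if peak <= 0:
        return trial  # nothing moves; leave untouched
    active = np.nonzero(speed > threshold * peak)[0]
    lo = max(int(active[0]) - pad, 0)
    hi = min(int(active[-1]) + 1 + pad, trial.angles.shape[0] - 1)
    return TrialRecording(trial_id=trial.trial_id,
                          class_label=trial.class_label,
                          angles=trial.angles[lo:hi + 1])


def resample_trial(trial: TrialRecording, length: int) -> TrialRecording:
    """Linearly interpolate a trial onto ``length`` uniform time points.

    Endpoints are preserved exactly; a trial already on the target grid is
    returned unchanged up to floating point.
    """
    if length < 2:
        raise ValueError(f"target length must be >= 2, got {length}")
    raw = trial.angles
    t_old = np.linspace(0.0, 1.0, raw.shape[0])
    t_new = np.linspace(0.0, 1.0, length)
    out = np.column_stack([np.interp(t_new, t_old, raw[:, j]) for j in range(trial.s)])
    return TrialRecording(trial_id=trial.trial_id, class_label=trial.class_label, angles=out)


def sensor_ranges(trials: list[TrialRecording]) -> tuple[np.ndarray, np.ndarray]:
    """Empirical per-sensor min/max over a list of trials."""
    stacked = np.vstack([t.angles for t in trials])
    return stacked.min(axis=0), stacked.max(axis=0)


def normalize_sensors(
    trials: list[TrialRecording],
    sensor_min: np.ndarray,
    sensor_max: np.ndarray,
) -> list[TrialRecording]:
    """Map each sensor linearly into [-1, 1]: v -> 2(v - min)/(max - min) - 1."""
    sensor_min = np.asarray(sensor_min, dtype=float)
    sensor_max = np.asarray(sensor_max, dtype=float)
    degenerate = np.nonzero(sensor_max <= sensor_min)[0]
    if degenerate.size:
        raise ValueError(
            f"degenerate sensor(s) {degenerate.tolist()}: max must exceed min"
        )
    span = sensor_max - sensor_min
    return [
        TrialRecording(
            trial_id=t.trial_id,
            class_label=t.class_label,
            angles=2.0 * (t.angles - sensor_min) / span - 1.0,
        )
        for t in trials
    ]


def vectorize(trial: TrialRecording) -> np.ndarray:
    """Flatten a (length, s) trial time-major into a length*s row.

    Sensor j at time t lands at 1-based position (t-1)*s + j, so one
    joint's trajectory occupies the stride-s positions j, s+j, 2s+j, ...
    """
    return trial.angles.reshape(-1)


def devectorize(row: np.ndarray, s: int, length: int) -> np.ndarray:
    """Inverse of :func:`vectorize`: back to a (length, s) series."""
    row = np.asarray(row, dtype=float)
    if row.size != s * length:
        raise ValueError(f"row of size {row.size} != s*length = {s * length}")
    return row.reshape(length, s)


def trials_to_dataset(
    trials: list[TrialRecording],
    length: int,
    sensor_min: np.ndarray | None = None,
    sensor_max: np.ndarray | None = None,
) -> KinematicDataset:
    """Resample, normalize and vectorize raw trials into a KinematicDataset.

    Normalization bounds default to the empirical per-sensor extremes of
    the resampled trials (a hardware calibration range may be passed in).
    """
    resampled = [resample_trial(t, length) for t in trials]
    if sensor_min is None or sensor_max is None:
        sensor_min, sensor_max = sensor_ranges(resampled)
    normalized = normalize_sensors(resampled, sensor_min, sensor_max)
    X = np.vstack([vectorize(t) for t in normalized])
    labels = np.array([t.class_label for t in normalized])
    return KinematicDataset(
        X=X, labels=labels, s=trials[0].s, length=length,
        sensor_min=np.asarray(sensor_min, float), sensor_max=np.asarray(sensor_max, float),
    )


def split_dataset(labels: np.ndarray | KinematicDataset, seed: int) -> SplitIndices:
    """Stratified 0.4 / 0.3 / 0.3 train/validation/test split.

    Per class the first two blocks take floor(0.4N) and floor(0.3N) rows of
    a seeded shuffle; the remainder goes to test, so the three sets exhaust
    every row.
    """
    if isinstance(labels, KinematicDataset):
        labels = labels.labels
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if idx.size < 5:
            raise ValueError(f"class {cls!r} has only {idx.size} rows; need >= 5 to split")
        idx = rng.permutation(idx)
        n_tr = int(np.floor(0.4 * idx.size))
        n_val = int(np.floor(0.3 * idx.size))
        train.append(idx[:n_tr])
        val.append(idx[n_tr:n_tr + n_val])
        test.append(idx[n_tr + n_val:])
    return SplitIndices(
        train=np.sort(np.concatenate(train)),
        validation=np.sort(np.concatenate(val)),
        test=np.sort(np.concatenate(test)),
    )


def add_noise(X: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise of SD ``sigma`` elementwise.

    Meant for validation/test copies on the [-1, 1] normalized scale;
    sigma = 0 returns an identical copy.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    X = np.asarray(X, dtype=float)
    if sigma == 0:
        return X.copy()
    rng = np.random.default_rng(seed)
    return X + rng.normal(0.0, sigma, size=X.shape)
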