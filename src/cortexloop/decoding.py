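"""Decoders: directional-tuning regression, shuffle-null feature selection,
the population vector, a generic linear decoder, and 1-D push-pull control.

Directional tuning of each feature is modelled by multiple linear regression
of its (pseudo-Z) activity f_i on the desired movement direction (m_x, m_y):

    f_i = b0_i + bx_i * m_x + by_i * m_y

The preferred direction of feature i is the unit vector
C_i = (bx_i, by_i) / ||(bx_i, by_i)||, and the 2-D population-vector control
signal is the activity-weighted sum over the selected feature subset:

    P = sum_i (d_i - b0_i) * C_i

Feature selection thresholds the regression R^2 against percentiles of a
permutation null: tuning is refit on target-shuffled data (kinematics rows
permuted, breaking the feature-target pairing) many times and the resulting
R^2 values, pooled over features, give the null mean and 80/90/95th
percentiles.  The default selection threshold is the 95th percentile;
the threshold is a live parameter and may be changed mid-run.

The 1-D push-pull scheme maps the band-power difference of two electrodes to
vertical cursor velocity, c_y = a*(s1 - s2) - b, with a and b calibrated so
the baseline control signal has zero mean and unit variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .core import ControlSignal, PacketIndex

__all__ = [
    "TrainingBuffer",
    "TuningModel",
    "fit_tuning",
    "shuffle_null",
    "select_features",
    "population_vector",
    "linear_decoder",
    "PushPullParams",
    "push_pull",
    "calibrate_push_pull",
]

log = logging.getLogger(__name__)


class TrainingBuffer:
    """Paired history of feature frames and desired-movement directions.

    ``kinematics`` rows are the unit vector toward the current target during
    training (norm <= 1; the zero vector is allowed for idle frames).
    """

    def __init__(self) -> None:
        self._features: list[np.ndarray] = []
        self._kinematics: list[np.ndarray] = []

    def append(self, features: np.ndarray, direction: np.ndarray) -> None:
        f = np.asarray(features, dtype=np.float64).reshape(-1)
        k = np.asarray(direction, dtype=np.float64).reshape(-1)
        if k.size != 2:
            raise ValueError("kinematics must be a 2-vector (m_x, m_y)")
        if np.linalg.norm(k) > 1.0 + 1e-9:
            raise ValueError("kinematics rows must have norm <= 1")
        if self._features and f.size != self._features[0].size:
            raise ValueError("feature dimension changed mid-buffer")
        self._features.append(f)
        self._kinematics.append(k)

    def __len__(self) -> int:
        return len(self._features)

    @property
    def features(self) -> np.ndarray:
        return np.asarray(self._features)

    @property
    def kinematics(self) -> np.ndarray:
        return np.asarray(self._kinematics)

    @classmethod
    def from_arrays(cls, features: np.ndarray, kinematics: np.ndarray) -> "TrainingBuffer":
        buf = cls()
        features = np.asarray(features, dtype=np.float64)
        kinematics = np.asarray(kinematics, dtype=np.float64)
        if features.shape[0] != kinematics.shape[0]:
            raise ValueError("features and kinematics must have equal frame counts")
        for f, k in zip(features, kinematics):
            buf.append(f, k)
        return buf


@dataclass(frozen=True)
class TuningModel:
    """Fitted directional tuning of every feature, plus selection state.

    ``pd`` rows are unit preferred-direction vectors (NaN where a feature has
    no direction, i.e. bx = by = 0).  ``null_percentiles``, ``threshold`` and
    ``selected`` are populated by :func:`shuffle_null` / :func:`select_features`.
    """

    b0: np.ndarray
    bx: np.ndarray
    by: np.ndarray
    r2: np.ndarray
    pd: np.ndarray
    null_percentiles: dict | None = None
    threshold: float | None = None
    selected: np.ndarray | None = None
    selection_empty: bool = False

    @property
    def n_features(self) -> int:
        return self.b0.size

    @property
    def preferred_angles(self) -> np.ndarray:
        """Preferred directions as angles in radians (NaN for direction-free features)."""
        return np.arctan2(self.pd[:, 1], self.pd[:, 0])

    def as_linear(self, gain: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """Equivalent generic linear decoder (W, w0) over the full feature vector."""
        if self.selected is None:
            raise ValueError("select features before converting to a linear decoder")
        W = np.zeros((2, self.n_features))
        w0 = np.zeros(2)
        for i in self.selected:
            W[:, i] = gain * self.pd[i]
            w0 -= gain * self.b0[i] * self.pd[i]
        return W, w0

    def summary(self) -> str:
        lines = [
            f"directional tuning: {self.n_features} features",
            f"  R^2: median {np.median(self.r2):.3f}, max {self.r2.max():.3f}",
        ]
        if self.null_percentiles is not None:
            np_ = self.null_percentiles
            lines.append(
                "  shuffle null R^2: mean {mean:.4f}, p80 {p80:.4f}, "
                "p90 {p90:.4f}, p95 {p95:.4f}".format(**np_)
            )
        if self.threshold is not None:
            n_sel = 0 if self.selected is None else self.selected.size
            lines.append(f"  threshold {self.threshold:.4f} -> {n_sel} features selected")
        return "\n".join(lines)


def _design(kinematics: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(kinematics.shape[0]), kinematics])


def fit_tuning(buf: TrainingBuffer) -> TuningModel:
    """Ordinary least squares of every feature on (1, m_x, m_y), all at once."""
    F = buf.features
    K = buf.kinematics
    if F.shape[0] < 10:
        raise ValueError(f"need at least 10 training frames, have {F.shape[0]}")
    X = _design(K)
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("kinematics are collinear (rank-deficient design)")
    beta, *_ = np.linalg.lstsq(X, F, rcond=None)  # (3, n_features)
    resid = F - X @ beta
    sst = np.sum((F - F.mean(axis=0)) ** 2, axis=0)
    ssr = np.sum(resid**2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sst > 0, 1.0 - ssr / sst, 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    b0, bx, by = beta
    norm = np.hypot(bx, by)
    with np.errstate(divide="ignore", invalid="ignore"):
        pd = np.where(norm[:, None] > 0, np.column_stack([bx, by]) / norm[:, None], np.nan)
    return TuningModel(b0=b0, bx=bx, by=by, r2=r2, pd=pd)


def _r2_matrix(X: np.ndarray, F: np.ndarray, sst: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, F, rcond=None)
    ssr = np.sum((F - X @ beta) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.clip(np.where(sst > 0, 1.0 - ssr / sst, 0.0), 0.0, 1.0)


def shuffle_null(
    buf: TrainingBuffer,
    n_iter: int = 1000,
    seed=0,
    max_features: int | None = None,
) -> dict:
    """Percentiles of the target-shuffled R^2 null distribution.

    Each iteration permutes whole kinematics rows (preserving the marginal
    target distribution while breaking the feature-target pairing), refits
    the tuning regression, and records every feature's R^2; the pooled
    distribution yields the mean and 80/90/95th percentiles used for feature
    selection.  ``max_features`` optionally subsamples the feature columns
    (evenly) to bound cost; the pooled percentiles are unchanged in
    expectation.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    F = buf.features
    K = buf.kinematics
    if F.shape[0] < 10:
        raise ValueError(f"need at least 10 training frames, have {F.shape[0]}")
    if max_features is not None and max_features < F.shape[1]:
        cols = np.linspace(0, F.shape[1] - 1, max_features).round().astype(int)
        F = F[:, np.unique(cols)]
    rng = np.random.default_rng(seed)
    sst = np.sum((F - F.mean(axis=0)) ** 2, axis=0)
    pooled = np.empty((n_iter, F.shape[1]))
    for it in range(n_iter):
        perm = rng.permutation(K.shape[0])
        pooled[it] = _r2_matrix(_design(K[perm]), F, sst)
    flat = pooled.ravel()
    return {
        "mean": float(flat.mean()),
        "p80": float(np.percentile(flat, 80)),
        "p90": float(np.percentile(flat, 90)),
        "p95": float(np.percentile(flat, 95)),
    }


def select_features(model: TuningModel, threshold: float) -> TuningModel:
    """Select the features with R^2 at or above the threshold.

    The threshold is a live parameter (adjustable mid-run); an empty selection
    is allowed but flagged, since the population vector needs at least one
    feature to produce output.
    """
    selected = np.flatnonzero(model.r2 >= threshold)
    empty = selected.size == 0
    if empty:
        log.warning("feature selection at threshold %.4f is empty", threshold)
    return replace(model, threshold=float(threshold), selected=selected, selection_empty=empty)


def population_vector(
    model: TuningModel,
    activity: np.ndarray,
    gain: float = 1.0,
    index: PacketIndex = 0,
) -> ControlSignal:
    """The 2-D population-vector control signal from one frame of activity."""
    if model.selected is None or model.selected.size == 0:
        raise ValueError("population vector requires a non-empty selected feature set")
    d = np.asarray(activity, dtype=np.float64).reshape(-1)
    if d.size != model.n_features:
        raise ValueError(
            f"activity length {d.size} does not match model ({model.n_features} features)"
        )
    sel = model.selected
    excess = d[sel] - model.b0[sel]
    P = gain * (excess[:, None] * model.pd[sel]).sum(axis=0)
    return ControlSignal(P, index)


def linear_decoder(
    W: np.ndarray, w0: np.ndarray, activity: np.ndarray, index: PacketIndex = 0
) -> ControlSignal:
    """Generic linear readout v = W @ d + w0."""
    W = np.atleast_2d(np.asarray(W, dtype=np.float64))
    w0 = np.atleast_1d(np.asarray(w0, dtype=np.float64))
    d = np.asarray(activity, dtype=np.float64).reshape(-1)
    if W.shape[1] != d.size or W.shape[0] != w0.size:
        raise ValueError(f"shape mismatch: W {W.shape}, w0 {w0.shape}, activity {d.shape}")
    return ControlSignal(W @ d + w0, index)


@dataclass(frozen=True)
class PushPullParams:
    """Gain/offset and electrode pair for 1-D push-pull control.

    c_y = a*(s1 - s2) - b, where s1, s2 are the high-gamma band powers
    (70-110 Hz by default) of the two electrodes; positive c_y moves the
    cursor up.
    """

    a: float = 1.0
    b: float = 0.0
    ch_pos: int = 0
    ch_neg: int = 1
    band: tuple[float, float] = (70.0, 110.0)

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("push-pull gain a must be positive")


def push_pull(s1: float, s2: float, p: PushPullParams, index: PacketIndex = 0) -> ControlSignal:
    """1-D control signal c_y = a*(s1 - s2) - b (positive = up)."""
    if not (np.isfinite(s1) and np.isfinite(s2)):
        raise ValueError("push-pull inputs must be finite")
    return ControlSignal([p.a * (s1 - s2) - p.b], index)


def calibrate_push_pull(
    diff_samples: np.ndarray, ch_pos: int = 0, ch_neg: int = 1,
    band: tuple[float, float] = (70.0, 110.0),
) -> PushPullParams:
    """Fit a and b so the baseline control signal has zero mean, unit variance.

    ``diff_samples`` are baseline samples of (s1 - s2); a = 1/sd (sample sd),
    b = a * mean, so that a*(s1-s2) - b is standardized over the baseline.
    """
    x = np.asarray(diff_samples, dtype=np.float64).reshape(-1)
    if x.size < 2:
        raise ValueError("need at least 2 baseline samples")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("baseline difference has zero variance; cannot calibrate")
    a = 1.0 / sd
    return PushPullParams(a=a, b=a * float(np.mean(x)), ch_pos=ch_pos, ch_neg=ch_neg, band=band)
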