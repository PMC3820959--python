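"""One-second window feature extraction: 126 features per window.

From the six raw channels we derive per-sample secondary signals (vector
lengths, angular acceleration by finite differencing, the acceleration
tangent ratio a_x/a_z as an attitude proxy, the acceleration/angular-velocity
dot product and its cosine alignment), cut one-second windows that lie fully
inside a single labelled interval, and compute nine window statistics per
scalar signal plus a few extras, for exactly 126 features partitioned into
45 accelerometer-only, 69 gyroscope-only and 12 mixed-sensor entries.

The statistics per scalar signal are: mean, standard deviation, skewness,
kurtosis (excess), minimum, maximum, mean-crossing count, dominant FFT
frequency and dominant FFT magnitude.  Zero-variance windows take skewness
and kurtosis 0 by convention (instead of NaN).  The FFT is the plain
rectangular-window transform of the 100-sample window; only bins 1..n/2 are
candidates for the dominant bin, and magnitudes are amplitude-scaled
(``2 |X_k| / n``) so a pure sinusoid of amplitude A scores ~A.

The manifest is data-driven: a different feature list can be loaded from a
CSV, so an exact published feature table can be dropped in without code
changes.  Features are min-max normalized to [0, 1] with parameters learned
on training data only; out-of-range validation values are clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .sensor_io import (
    BehaviorCategory,
    CATEGORIES,
    InertialRecording,
    LabelTrack,
    ValidationError,
)

__all__ = [
    "ACC_SIGNALS",
    "GYRO_SIGNALS",
    "MIXED_SIGNALS",
    "BASE_STATS",
    "FeatureSpec",
    "default_manifest",
    "DEFAULT_MANIFEST",
    "manifest_frame",
    "load_manifest",
    "save_manifest",
    "DerivedSignals",
    "derive_signals",
    "Window",
    "cut_windows",
    "FeatureDataset",
    "extract_features",
    "featurize_session",
    "NormalizationParams",
    "fit_normalizer",
    "apply_normalizer",
    "write_features",
    "read_features",
]

#: Scalar signals derived from the accelerometer alone.
ACC_SIGNALS = ("a_x", "a_y", "a_z", "a_mag", "r_xz")
#: Scalar signals derived from the gyroscope alone.
GYRO_SIGNALS = ("w_roll", "w_pitch", "w_yaw", "w_mag",
                "alpha_roll", "alpha_pitch", "alpha_yaw")
#: Signals mixing both sensors.
MIXED_SIGNALS = ("d", "c")

#: The nine per-signal window statistics.
BASE_STATS = ("mean", "std", "skew", "kurt", "min", "max",
              "mcross", "fdom", "fmag")

#: Harmonic-magnitude extras of |w|: spectral magnitude at multiples 2..7
#: of the dominant bin (0 beyond Nyquist).
HARMONIC_MULTIPLES = (2, 3, 4, 5, 6, 7)


@dataclass(frozen=True)
class FeatureSpec:
    """One manifest entry: a named (signal, statistic) pair with its group."""

    name: str
    signal: str
    statistic: str
    group: str  # acc_only | gyro_only | mixed


def default_manifest() -> tuple[FeatureSpec, ...]:
    """The default 126-entry manifest (45 acc / 69 gyro / 12 mixed)."""
    specs: list[FeatureSpec] = []
    for sig in ACC_SIGNALS:
        for stat in BASE_STATS:
            specs.append(FeatureSpec(f"{sig}_{stat}", sig, stat, "acc_only"))
    for sig in GYRO_SIGNALS:
        for stat in BASE_STATS:
            specs.append(FeatureSpec(f"{sig}_{stat}", sig, stat, "gyro_only"))
    for h in HARMONIC_MULTIPLES:
        specs.append(FeatureSpec(f"w_mag_h{h}", "w_mag", f"harmonic:{h}", "gyro_only"))
    for stat in BASE_STATS:
        specs.append(FeatureSpec(f"d_{stat}", "d", stat, "mixed"))
    for stat in ("mean", "min", "max"):
        specs.append(FeatureSpec(f"c_{stat}", "c", stat, "mixed"))
    return tuple(specs)


def _check_partition(manifest: Sequence[FeatureSpec]) -> None:
    names = [s.name for s in manifest]
    if len(set(names)) != len(names):
        raise ValidationError("manifest feature names must be unique")
    counts = {g: sum(s.group == g for s in manifest)
              for g in ("acc_only", "gyro_only", "mixed")}
    if (len(manifest), counts["gyro_only"], counts["acc_only"], counts["mixed"]) != (
        126, 69, 45, 12
    ):
        raise ValidationError(
            f"manifest must have 126 features (69 gyro_only / 45 acc_only / "
            f"12 mixed); got {len(manifest)} with {counts}"
        )


DEFAULT_MANIFEST: tuple[FeatureSpec, ...] = default_manifest()
_check_partition(DEFAULT_MANIFEST)  # frozen contract, asserted at import


def manifest_frame(manifest: Sequence[FeatureSpec] = DEFAULT_MANIFEST) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.name, s.signal, s.statistic, s.group) for s in manifest],
        columns=["name", "signal", "statistic", "group"],
    )


def save_manifest(path: str | Path,
                  manifest: Sequence[FeatureSpec] = DEFAULT_MANIFEST) -> None:
    manifest_frame(manifest).to_csv(path, index=False)


def load_manifest(path: str | Path) -> tuple[FeatureSpec, ...]:
    """Load a manifest CSV (name, signal, statistic, group); checks counts."""
    df = pd.read_csv(path)
    manifest = tuple(
        FeatureSpec(r["name"], r["signal"], r["statistic"], r["group"])
        for _, r in df.iterrows()
    )
    _check_partition(manifest)
    return manifest


# --------------------------------------------------------------------------
# Derived per-sample signals
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DerivedSignals:
    """Per-sample scalar signals derived from one recording."""

    signals: dict[str, np.ndarray]
    sample_rate: float
    dog_id: str = ""
    breed: str = ""
    session_index: int = 0

    def __len__(self) -> int:
        return len(self.signals["a_x"])

    def __getitem__(self, name: str) -> np.ndarray:
        return self.signals[name]


def derive_signals(rec: InertialRecording, epsilon_az: float = 0.05) -> DerivedSignals:
    """Compute all derived scalar signals of a recording.

    Angular accelerations (deg/s^2) use central differences with one-sided
    differences at the ends.  The attitude tangent r_xz = a_x / a_z clamps
    |a_z| to *epsilon_az* (keeping its sign, +epsilon at exactly zero) to
    avoid blow-up in dynamic windows.  The cosine alignment c = d/(|a||w|)
    is defined 0 where either vector vanishes.
    """
    if len(rec) < 2:
        raise ValidationError("need at least 2 samples for finite differences")
    acc, gyro = rec.acc, rec.gyro
    a_mag = np.linalg.norm(acc, axis=1)
    w_mag = np.linalg.norm(gyro, axis=1)
    dt = 1.0 / rec.sample_rate
    alpha = np.gradient(gyro, dt, axis=0)
    az = rec.a_z
    az_clamped = np.where(az < 0, np.minimum(az, -epsilon_az),
                          np.maximum(az, epsilon_az))
    d = np.einsum("ij,ij->i", acc, gyro)
    denom = a_mag * w_mag
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, d / np.where(denom > 0, denom, 1.0), 0.0)
    c = np.clip(c, -1.0, 1.0)
    signals = {
        "a_x": rec.a_x, "a_y": rec.a_y, "a_z": rec.a_z,
        "a_mag": a_mag, "r_xz": rec.a_x / az_clamped,
        "w_roll": rec.w_roll, "w_pitch": rec.w_pitch, "w_yaw": rec.w_yaw,
        "w_mag": w_mag,
        "alpha_roll": alpha[:, 0], "alpha_pitch": alpha[:, 1],
        "alpha_yaw": alpha[:, 2],
        "d": d, "c": c,
    }
    return DerivedSignals(signals, rec.sample_rate,
                          dog_id=rec.dog_id, breed=rec.breed,
                          session_index=rec.session_index)


# --------------------------------------------------------------------------
# Windowing
# --------------------------------------------------------------------------


class Window(NamedTuple):
    """A sample-index window [start, stop) carrying its interval's label."""

    start: int
    stop: int
    category: BehaviorCategory


def cut_windows(
    rec: InertialRecording,
    track: LabelTrack,
    window: float = 1.0,
    stride: int = 10,
) -> list[Window]:
    """Enumerate labelled windows of *window* seconds.

    A window is emitted iff its full span lies inside a single labelled
    interval; consecutive windows advance by *stride* samples (default 10,
    i.e. 0.1 s at 100 Hz).  Interval endpoints are aligned to samples by
    flooring.  The caller is expected to have margin-trimmed *track* first.
    """
    if stride <= 0:
        raise ValueError("stride must be a positive sample count")
    n_win_f = window * rec.sample_rate
    n_win = int(round(n_win_f))
    if abs(n_win_f - n_win) > 1e-9 or n_win < 1:
        raise ValueError("window length must be a positive integer number of samples")
    out: list[Window] = []
    for iv in track.intervals:
        i0 = max(int(math.floor(iv.start * rec.sample_rate + 1e-9)), 0)
        i1 = min(int(math.floor(iv.end * rec.sample_rate + 1e-9)), len(rec))
        for stop in range(i0 + n_win, i1 + 1, stride):
            out.append(Window(stop - n_win, stop, iv.category))
    return out


# --------------------------------------------------------------------------
# Feature dataset
# --------------------------------------------------------------------------


@dataclass
class FeatureDataset:
    """Windows x features matrix with labels and per-window provenance."""

    X: np.ndarray
    y: np.ndarray  # object array of BehaviorCategory
    window_time: np.ndarray  # window end time in seconds
    provenance: pd.DataFrame  # columns dog_id, breed, session_index
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        self.window_time = np.asarray(self.window_time, dtype=float)
        n = len(self.X)
        if not (len(self.y) == len(self.window_time) == len(self.provenance) == n):
            raise ValidationError("X, y, window_time and provenance row counts differ")
        if self.X.ndim != 2 or self.X.shape[1] != len(self.feature_names):
            raise ValidationError("X column count must match feature_names")

    def __len__(self) -> int:
        return len(self.X)

    def category_counts(self) -> dict[BehaviorCategory, int]:
        """Window count per category (0 for absent categories)."""
        counts = {c: 0 for c in CATEGORIES}
        for cat in self.y:
            counts[cat] += 1
        return counts

    def subset(self, idx: np.ndarray | Sequence[int]) -> "FeatureDataset":
        idx = np.asarray(idx)
        return FeatureDataset(
            self.X[idx], self.y[idx], self.window_time[idx],
            self.provenance.iloc[idx].reset_index(drop=True),
            self.feature_names,
        )

    @staticmethod
    def concat(datasets: Sequence["FeatureDataset"]) -> "FeatureDataset":
        if not datasets:
            raise ValidationError("cannot concatenate zero datasets")
        names = datasets[0].feature_names
        if any(d.feature_names != names for d in datasets):
            raise ValidationError("datasets have differing feature manifests")
        return FeatureDataset(
            np.vstack([d.X for d in datasets]),
            np.concatenate([d.y for d in datasets]),
            np.concatenate([d.window_time for d in datasets]),
            pd.concat([d.provenance for d in datasets], ignore_index=True),
            names,
        )

    def measurement_keys(self) -> set[tuple[str, int]]:
        """Distinct (dog_id, session_index) pairs contributing windows."""
        return set(
            zip(self.provenance["dog_id"], self.provenance["session_index"].astype(int))
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df.insert(0, "label", [c.value for c in self.y])
        df.insert(1, "window_time", self.window_time)
        for col in ("dog_id", "breed", "session_index"):
            df[col] = self.provenance[col].to_numpy()
        return df


def _window_stats(W: np.ndarray, sample_rate: float) -> dict[str, np.ndarray]:
    """Vectorized window statistics for a (m, n) stack of windows."""
    n = W.shape[1]
    mean = W.mean(axis=1)
    centered = W - mean[:, None]
    m2 = np.mean(centered**2, axis=1)
    m3 = np.mean(centered**3, axis=1)
    m4 = np.mean(centered**4, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(m2 > 0, m3 / np.where(m2 > 0, m2, 1.0) ** 1.5, 0.0)
        kurt = np.where(m2 > 0, m4 / np.where(m2 > 0, m2, 1.0) ** 2 - 3.0, 0.0)
    # mean-crossing count: sign changes of the mean-centred signal
    prod = centered[:, :-1] * centered[:, 1:]
    mcross = (prod < 0).sum(axis=1).astype(float)
    # rectangular-window FFT, amplitude scaling, dominant bin among 1..n//2
    spec = np.abs(np.fft.rfft(W, axis=1)) * (2.0 / n)
    kmax = n // 2
    kdom = np.argmax(spec[:, 1:kmax + 1], axis=1) + 1
    rows = np.arange(len(W))
    return {
        "mean": mean,
        "std": np.sqrt(m2),
        "skew": skew,
        "kurt": kurt,
        "min": W.min(axis=1),
        "max": W.max(axis=1),
        "mcross": mcross,
        "fdom": kdom * sample_rate / n,
        "fmag": spec[rows, kdom],
        "_spec": spec,
        "_kdom": kdom,
    }


def extract_features(
    sig: DerivedSignals,
    windows: Sequence[Window],
    manifest: Sequence[FeatureSpec] = DEFAULT_MANIFEST,
) -> FeatureDataset:
    """Compute the manifest's features for every window.

    Output columns follow manifest order exactly.  Extraction is fully
    deterministic; windows containing non-finite samples raise, naming the
    first offending window.
    """
    _check_partition(manifest)
    names = tuple(s.name for s in manifest)
    prov = pd.DataFrame(
        {
            "dog_id": [sig.dog_id] * len(windows),
            "breed": [sig.breed] * len(windows),
            "session_index": [sig.session_index] * len(windows),
        }
    )
    if not windows:
        return FeatureDataset(
            np.empty((0, len(manifest))), np.empty(0, dtype=object),
            np.empty(0), prov, names,
        )
    n_win = windows[0].stop - windows[0].start
    if any(w.stop - w.start != n_win for w in windows):
        raise ValidationError("all windows must have equal length")
    starts = np.array([w.start for w in windows])
    idx = starts[:, None] + np.arange(n_win)[None, :]
    needed = sorted({s.signal for s in manifest})
    stats: dict[str, dict[str, np.ndarray]] = {}
    for signal in needed:
        W = sig[signal][idx]
        finite = np.isfinite(W).all(axis=1)
        if not finite.all():
            k = int(np.flatnonzero(~finite)[0])
            raise ValidationError(
                f"window {k} (samples {windows[k].start}..{windows[k].stop}) "
                f"contains non-finite values in signal {signal!r}"
            )
        stats[signal] = _window_stats(W, sig.sample_rate)
    m = len(windows)
    X = np.empty((m, len(manifest)))
    rows = np.arange(m)
    for j, spec_entry in enumerate(manifest):
        st = stats[spec_entry.signal]
        if spec_entry.statistic.startswith("harmonic:"):
            h = int(spec_entry.statistic.split(":")[1])
            bins = st["_kdom"] * h
            kmax = n_win // 2
            valid = bins <= kmax
            col = np.zeros(m)
            col[valid] = st["_spec"][rows[valid], bins[valid]]
            X[:, j] = col
        else:
            X[:, j] = st[spec_entry.statistic]
    y = np.array([w.category for w in windows], dtype=object)
    wt = np.array([w.stop / sig.sample_rate for w in windows])
    return FeatureDataset(X, y, wt, prov, names)


def featurize_session(
    rec: InertialRecording,
    track: LabelTrack,
    *,
    margin: float = 1.0,
    window: float = 1.0,
    stride: int = 10,
    manifest: Sequence[FeatureSpec] = DEFAULT_MANIFEST,
    epsilon_az: float = 0.05,
) -> FeatureDataset:
    """Margin-trim, derive, window and featurize one labelled recording."""
    from .sensor_io import apply_margin

    trimmed = apply_margin(track, margin)
    sig = derive_signals(rec, epsilon_az=epsilon_az)
    windows = cut_windows(rec, trimmed, window=window, stride=stride)
    return extract_features(sig, windows, manifest)


# --------------------------------------------------------------------------
# Min-max normalization
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature min/max learned on training data."""

    min_: np.ndarray
    max_: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.max_ < self.min_):
            raise ValidationError("normalization max must be >= min per feature")

    @staticmethod
    def fit(X: np.ndarray) -> "NormalizationParams":
        if len(X) == 0:
            raise ValidationError("cannot fit a normalizer on an empty dataset")
        return NormalizationParams(X.min(axis=0), X.max(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Map to [0, 1]; constant columns map to 0, out-of-range clips."""
        scale = self.max_ - self.min_
        safe = np.where(scale > 0, scale, 1.0)
        Z = (X - self.min_) / safe
        Z[:, scale == 0] = 0.0
        return np.clip(Z, 0.0, 1.0)


def fit_normalizer(train: FeatureDataset) -> NormalizationParams:
    """Learn per-feature min/max from a training dataset."""
    return NormalizationParams.fit(train.X)


def apply_normalizer(params: NormalizationParams, ds: FeatureDataset) -> FeatureDataset:
    """Return a copy of *ds* with features mapped into [0, 1]."""
    return FeatureDataset(
        params.transform(ds.X), ds.y, ds.window_time,
        ds.provenance.copy(), ds.feature_names,
    )


# --------------------------------------------------------------------------
# Feature CSV I/O
# --------------------------------------------------------------------------


def write_features(ds: FeatureDataset, path: str | Path) -> None:
    """Export the dataset as CSV (label + provenance + manifest columns)."""
    ds.to_frame().to_csv(path, index=False)


def read_features(
    path: str | Path,
    manifest: Sequence[FeatureSpec] = DEFAULT_MANIFEST,
) -> FeatureDataset:
    """Read a feature CSV written by :func:`write_features`."""
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    names = tuple(s.name for s in manifest)
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing feature columns {missing[:5]} ...")
    y = np.array([BehaviorCategory.from_text(v) for v in df["label"]], dtype=object)
    prov = df[["dog_id", "breed", "session_index"]].copy().reset_index(drop=True)
    prov["session_index"] = prov["session_index"].astype(int)
    return FeatureDataset(
        df[list(names)].to_numpy(dtype=float), y,
        df["window_time"].to_numpy(dtype=float), prov, names,
    )
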