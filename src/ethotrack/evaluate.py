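"""Training–validation comparison schemes and the error taxonomy.

Validation always means prediction on held-out measurements: a classifier
trained on one set of measurements is fed windows from measurements never
seen during training, never pooled cross-validation folds.  Six schemes
mirror the study design:

* ``within_dog``   — train on one measurement of a dog, validate on the
  other measurement of the same dog;
* ``intra_breed``  — train and validate on different dogs of the same breed;
* ``inter_breed``  — train and validate on dogs of different breeds;
* ``multi_1_1`` / ``multi_3_3`` / ``multi_5_5`` — train on 1+1 / 3+3 / 5+5
  measurements pooled across both breeds, validate on a fixed pool of dogs
  absent from all training sets.

Errors are graded by activity level A (static 0, walk 1, trot 2,
canter/gallop 3): a *perfect* match is the exact category, an *imperfect*
match is a wrong category at the same level (dA = 0), and the remaining
mismatches split by dA = 1, 2, 3.  Per-pair 7x7 recognition matrices are
row-normalized to percentages (rows sum to 100; rows with no true windows
are undefined, reported as NaN) and averaged entrywise over the scheme's
calculations.

Measurements are ranked by *comprehensiveness* — the minimum window count
over the seven categories — because freely moving dogs do not produce the
scripted behaviours in equal amounts; the more comprehensive measurement of
each dog is preferred for training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .featurize import FeatureDataset
from .model import SvmConfig, TrainedModel, predict, train
from .sensor_io import (
    CATEGORIES,
    BehaviorCategory,
    LabelTrack,
    ValidationError,
    activity_level,
)

__all__ = [
    "ValidationBreakdown",
    "RecognitionMatrix",
    "comprehensiveness",
    "DogRanking",
    "rank_measurements",
    "validate_pair",
    "PairResult",
    "ComparisonScheme",
    "SCHEME_NAMES",
    "build_scheme",
    "run_scheme",
    "run_comparison",
    "SchemeResult",
    "IntercoderResult",
    "intercoder_agreement",
    "plot_recognition_matrix",
]

SCHEME_NAMES = (
    "within_dog", "intra_breed", "inter_breed",
    "multi_1_1", "multi_3_3", "multi_5_5",
)

_MULTI_K = {"multi_1_1": 1, "multi_3_3": 3, "multi_5_5": 5}


# --------------------------------------------------------------------------
# Error taxonomy
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationBreakdown:
    """Five-way percentage breakdown of validation outcomes.

    perfect: exact category; imperfect: wrong category, same activity level;
    mismatch{1,2,3}: activity level off by 1, 2 or 3.  Components sum to 100.
    """

    perfect_pct: float
    imperfect_pct: float
    mismatch1_pct: float
    mismatch2_pct: float
    mismatch3_pct: float

    @staticmethod
    def from_predictions(
        y_true: Sequence[BehaviorCategory], y_pred: Sequence[BehaviorCategory]
    ) -> "ValidationBreakdown":
        y_true = np.asarray(y_true, dtype=object)
        y_pred = np.asarray(y_pred, dtype=object)
        if len(y_true) != len(y_pred) or len(y_true) == 0:
            raise ValidationError("need equal, non-empty truth and prediction")
        n = len(y_true)
        perfect = sum(t is p for t, p in zip(y_true, y_pred))
        buckets = [0, 0, 0, 0]  # dA = 0 (imperfect), 1, 2, 3
        for t, p in zip(y_true, y_pred):
            if t is p:
                continue
            buckets[abs(activity_level(t) - activity_level(p))] += 1
        return ValidationBreakdown(
            100.0 * perfect / n,
            100.0 * buckets[0] / n,
            100.0 * buckets[1] / n,
            100.0 * buckets[2] / n,
            100.0 * buckets[3] / n,
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "perfect_pct": self.perfect_pct,
            "imperfect_pct": self.imperfect_pct,
            "mismatch1_pct": self.mismatch1_pct,
            "mismatch2_pct": self.mismatch2_pct,
            "mismatch3_pct": self.mismatch3_pct,
        }

    @property
    def total(self) -> float:
        return sum(self.as_dict().values())

    @staticmethod
    def mean(items: Sequence["ValidationBreakdown"]) -> "ValidationBreakdown":
        if not items:
            raise ValidationError("cannot average zero breakdowns")
        return ValidationBreakdown(
            *(float(np.mean([getattr(b, f) for b in items]))
              for f in ("perfect_pct", "imperfect_pct", "mismatch1_pct",
                        "mismatch2_pct", "mismatch3_pct"))
        )


class RecognitionMatrix:
    """7x7 row-normalized percentage matrix, rows = true, columns = predicted.

    Rows with no true windows are undefined and stored as NaN (blank on
    export), never as zeros.
    """

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (7, 7):
            raise ValidationError("recognition matrix must be 7x7")
        for row in values:
            if np.isnan(row).all():
                continue
            if np.any(row < -1e-9) or abs(row.sum() - 100.0) > 1e-9:
                raise ValidationError("defined rows must be >= 0 and sum to 100")
        self.values = values

    @staticmethod
    def from_counts(counts: np.ndarray) -> "RecognitionMatrix":
        counts = np.asarray(counts, dtype=float)
        totals = counts.sum(axis=1)
        values = np.full((7, 7), np.nan)
        for i, tot in enumerate(totals):
            if tot > 0:
                values[i] = 100.0 * counts[i] / tot
        return RecognitionMatrix(values)

    @staticmethod
    def from_predictions(
        y_true: Sequence[BehaviorCategory], y_pred: Sequence[BehaviorCategory]
    ) -> "RecognitionMatrix":
        index = {c: i for i, c in enumerate(CATEGORIES)}
        counts = np.zeros((7, 7))
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return RecognitionMatrix.from_counts(counts)

    @staticmethod
    def average(matrices: Sequence["RecognitionMatrix"]) -> "RecognitionMatrix":
        """Entrywise mean over calculations; rows undefined everywhere stay
        NaN, otherwise the mean runs over the calculations defining them."""
        if not matrices:
            raise ValidationError("cannot average zero matrices")
        stack = np.stack([m.values for m in matrices])
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(stack, axis=0)
        # renormalize rows averaged over different subsets of calculations
        values = np.full((7, 7), np.nan)
        for i in range(7):
            row = mean[i]
            if not np.isnan(row).all():
                values[i] = 100.0 * row / row.sum()
        return RecognitionMatrix(values)

    def to_frame(self) -> pd.DataFrame:
        names = [c.value for c in CATEGORIES]
        return pd.DataFrame(self.values, index=names, columns=names)

    def largest_offdiagonal(self) -> tuple[BehaviorCategory, BehaviorCategory, float]:
        """The (true, predicted) pair with the largest off-diagonal rate."""
        best = (CATEGORIES[0], CATEGORIES[1], -np.inf)
        for i in range(7):
            for j in range(7):
                if i == j or np.isnan(self.values[i, j]):
                    continue
                if self.values[i, j] > best[2]:
                    best = (CATEGORIES[i], CATEGORIES[j], float(self.values[i, j]))
        return best


# --------------------------------------------------------------------------
# Measurement ranking
# --------------------------------------------------------------------------


def comprehensiveness(ds: FeatureDataset) -> int:
    """Minimum window count over the seven categories (0 if any is absent)."""
    return min(ds.category_counts().values())


@dataclass
class DogRanking:
    """A dog's sessions ordered by comprehensiveness."""

    dog_id: str
    breed: str
    best: FeatureDataset
    other: FeatureDataset | None
    score: int
    total: int


def rank_measurements(datasets: Sequence[FeatureDataset]) -> list[DogRanking]:
    """Pick each dog's more comprehensive session and rank dogs by it.

    Within a dog, ties break by total window count then lower session
    index; across dogs, by score descending, then total windows descending,
    then dog_id ascending — fully deterministic.
    """
    by_dog: dict[str, list[FeatureDataset]] = {}
    for ds in datasets:
        keys = ds.measurement_keys()
        if len(keys) != 1:
            raise ValidationError(
                "rank_measurements expects single-measurement datasets"
            )
        dog = next(iter(keys))[0]
        by_dog.setdefault(dog, []).append(ds)
    rankings: list[DogRanking] = []
    for dog, sessions in by_dog.items():
        ordered = sorted(
            sessions,
            key=lambda d: (
                -comprehensiveness(d), -len(d),
                int(d.provenance["session_index"].iloc[0]) if len(d) else 0,
            ),
        )
        best = ordered[0]
        other = ordered[1] if len(ordered) > 1 else None
        rankings.append(
            DogRanking(
                dog_id=dog,
                breed=str(best.provenance["breed"].iloc[0]) if len(best) else "",
                best=best,
                other=other,
                score=comprehensiveness(best),
                total=len(best),
            )
        )
    rankings.sort(key=lambda r: (-r.score, -r.total, r.dog_id))
    return rankings


# --------------------------------------------------------------------------
# Hold-out validation
# --------------------------------------------------------------------------


@dataclass
class PairResult:
    breakdown: ValidationBreakdown
    matrix: RecognitionMatrix
    y_true: np.ndarray
    y_pred: np.ndarray


def validate_pair(
    train_sets: Sequence[FeatureDataset],
    validation_set: FeatureDataset,
    cfg: SvmConfig = SvmConfig(),
    mask: str = "all",
) -> PairResult:
    """Train on the union of *train_sets*, validate on *validation_set*.

    Raises before any computation if a measurement appears on both sides —
    hold-out discipline is structural, not advisory.
    """
    train_keys: set[tuple[str, int]] = set()
    for ds in train_sets:
        train_keys |= ds.measurement_keys()
    overlap = train_keys & validation_set.measurement_keys()
    if overlap:
        raise ValidationError(
            f"measurements {sorted(overlap)} appear in both training and validation"
        )
    merged = FeatureDataset.concat(list(train_sets))
    model = train(merged, cfg, mask=mask)
    y_pred = predict(model, validation_set)
    return PairResult(
        breakdown=ValidationBreakdown.from_predictions(validation_set.y, y_pred),
        matrix=RecognitionMatrix.from_predictions(validation_set.y, y_pred),
        y_true=validation_set.y,
        y_pred=y_pred,
    )


@dataclass
class ComparisonScheme:
    """A named list of (training measurement set, validation measurement)."""

    name: str
    pairs: list[tuple[list[FeatureDataset], FeatureDataset]]

    def __post_init__(self) -> None:
        for train_sets, val in self.pairs:
            keys: set[tuple[str, int]] = set()
            for ds in train_sets:
                keys |= ds.measurement_keys()
            if keys & val.measurement_keys():
                raise ValidationError(
                    f"scheme {self.name}: training/validation overlap"
                )
            if self.name in _MULTI_K:
                train_dogs = {k[0] for k in keys}
                val_dogs = {k[0] for k in val.measurement_keys()}
                if train_dogs & val_dogs:
                    raise ValidationError(
                        f"scheme {self.name}: validation dog present in training"
                    )


def build_scheme(
    name: str,
    measurements: Sequence[FeatureDataset],
    seed: int = 0,
    n_calculations: int = 10,
) -> ComparisonScheme:
    """Materialize a comparison scheme from per-measurement datasets.

    Dogs are ranked by comprehensiveness; the top (up to 10) per breed form
    the candidate pool.  Pairings within the pool are a seeded permutation
    (derangement for intra-breed), and the multi-training schemes split each
    breed's pool into a fixed validation half (up to 5 dogs) and a training
    pool from which 1, 3 or 5 measurements per breed are drawn per
    calculation.  At most *n_calculations* pairs are produced, balanced
    across breeds.
    """
    if name not in SCHEME_NAMES:
        raise ValueError(f"unknown scheme {name!r}; expected one of {SCHEME_NAMES}")
    rng = np.random.default_rng(seed)
    ranked = rank_measurements(measurements)
    breeds = sorted({r.breed for r in ranked})
    if len(breeds) < (2 if name == "inter_breed" or name in _MULTI_K else 1):
        raise ValidationError(f"scheme {name} needs two breeds")
    top = {b: [r for r in ranked if r.breed == b][:10] for b in breeds}

    pairs: list[tuple[list[FeatureDataset], FeatureDataset]] = []
    if name == "within_dog":
        eligible = {b: [r for r in top[b] if r.other is not None] for b in breeds}
        for group in zip(*(eligible[b] for b in breeds)):
            for r in group:
                pairs.append(([r.best], r.other))
        # leftover dogs if breeds are uneven
        shortest = min(len(eligible[b]) for b in breeds)
        for b in breeds:
            for r in eligible[b][shortest:]:
                pairs.append(([r.best], r.other))
    elif name == "intra_breed":
        for b in breeds:
            dogs = top[b]
            if len(dogs) < 2:
                raise ValidationError(f"intra_breed needs >= 2 dogs of breed {b}")
            order = rng.permutation(len(dogs))
            for i in range(len(dogs)):  # cyclic derangement: X trains, next validates
                tr = dogs[order[i]]
                va = dogs[order[(i + 1) % len(dogs)]]
                pairs.append(([tr.best], va.best))
        pairs = _balanced_truncate(pairs, breeds, n_calculations)
    elif name == "inter_breed":
        b0, b1 = breeds[0], breeds[1]
        o0 = rng.permutation(len(top[b0]))
        o1 = rng.permutation(len(top[b1]))
        k = min(len(top[b0]), len(top[b1]))
        for i in range(k):
            pairs.append(([top[b0][o0[i]].best], top[b1][o1[i]].best))
            pairs.append(([top[b1][o1[i]].best], top[b0][o0[i]].best))
    else:  # multi-training schemes
        k = _MULTI_K[name]
        val_pool: list[DogRanking] = []
        train_pool: dict[str, list[DogRanking]] = {}
        for b in breeds:
            dogs = list(top[b])
            perm = rng.permutation(len(dogs))
            n_val = min(5, len(dogs) // 2)
            val_pool.extend(dogs[i] for i in perm[:n_val])
            train_pool[b] = [dogs[i] for i in perm[n_val:]]
            if len(train_pool[b]) < k:
                raise ValidationError(
                    f"scheme {name}: breed {b} training pool has "
                    f"{len(train_pool[b])} dogs, needs {k}"
                )
        for r_val in val_pool:
            train_sets: list[FeatureDataset] = []
            for b in breeds:
                pick = rng.choice(len(train_pool[b]), size=k, replace=False)
                train_sets.extend(train_pool[b][i].best for i in pick)
            pairs.append((train_sets, r_val.best))

    if n_calculations is not None and len(pairs) > n_calculations:
        pairs = pairs[:n_calculations]
    if not pairs:
        raise ValidationError(f"scheme {name}: no training-validation pairs")
    return ComparisonScheme(name=name, pairs=pairs)


def _balanced_truncate(pairs, breeds, n_calculations):
    """Keep pairs interleaved across the per-breed blocks."""
    if len(pairs) <= n_calculations:
        return pairs
    # pairs were appended breed-block-wise; interleave blocks before cutting
    per_breed: dict[str, list] = {b: [] for b in breeds}
    for train_sets, val in pairs:
        breed = str(val.provenance["breed"].iloc[0])
        per_breed[breed].append((train_sets, val))
    out, i = [], 0
    while len(out) < len(pairs):
        for b in breeds:
            if i < len(per_breed[b]):
                out.append(per_breed[b][i])
        i += 1
    return out[:n_calculations]


@dataclass
class SchemeResult:
    name: str
    breakdowns: list[ValidationBreakdown]
    mean_breakdown: ValidationBreakdown
    matrix: RecognitionMatrix
    pair_matrices: list[RecognitionMatrix]

    def breakdown_frame(self) -> pd.DataFrame:
        rows = [b.as_dict() for b in self.breakdowns]
        df = pd.DataFrame(rows)
        df.insert(0, "calculation", range(1, len(rows) + 1))
        return df


def run_scheme(
    scheme: ComparisonScheme,
    cfg: SvmConfig = SvmConfig(),
    mask: str = "all",
) -> SchemeResult:
    """Run every pair of a materialized scheme and average the results."""
    results = [validate_pair(tr, va, cfg, mask=mask) for tr, va in scheme.pairs]
    return SchemeResult(
        name=scheme.name,
        breakdowns=[r.breakdown for r in results],
        mean_breakdown=ValidationBreakdown.mean([r.breakdown for r in results]),
        matrix=RecognitionMatrix.average([r.matrix for r in results]),
        pair_matrices=[r.matrix for r in results],
    )


def run_comparison(
    name: str,
    measurements: Sequence[FeatureDataset],
    cfg: SvmConfig = SvmConfig(),
    seed: int = 0,
    n_calculations: int = 10,
    mask: str = "all",
) -> SchemeResult:
    """Build and run a named scheme in one call."""
    return run_scheme(build_scheme(name, measurements, seed, n_calculations),
                      cfg, mask=mask)


# --------------------------------------------------------------------------
# Intercoder agreement
# --------------------------------------------------------------------------


@dataclass
class IntercoderResult:
    """Agreement of two coders' tracks on a shared time-node grid.

    ``pct_only_a``/``pct_only_b`` are each relative to that coder's own
    labelled node count; ``pct_common_agree`` is over commonly labelled
    nodes (NaN when there are none, flagged by ``has_common``).
    """

    pct_only_a: float
    pct_only_b: float
    pct_common_agree: float
    matrix: RecognitionMatrix | None
    n_common: int

    @property
    def has_common(self) -> bool:
        return self.n_common > 0


def _labels_on_grid(track: LabelTrack, times: np.ndarray) -> np.ndarray:
    """Category index per node (-1 in gaps), vectorized over the grid."""
    index = {c: i for i, c in enumerate(CATEGORIES)}
    starts = np.array([iv.start for iv in track.intervals])
    ends = np.array([iv.end for iv in track.intervals])
    cats = np.array([index[iv.category] for iv in track.intervals], dtype=int)
    if len(starts) == 0:
        return np.full(len(times), -1, dtype=int)
    k = np.searchsorted(starts, times + 1e-12, side="right") - 1
    out = np.full(len(times), -1, dtype=int)
    valid = (k >= 0) & (times < ends[np.clip(k, 0, None)] - 1e-12)
    out[valid] = cats[k[valid]]
    return out


def intercoder_agreement(
    track_a: LabelTrack,
    track_b: LabelTrack,
    node_stride: float = 0.1,
) -> IntercoderResult:
    """Compare two coders' label tracks on a shared node grid.

    Both tracks should already be margin-trimmed with the same margin.
    Nodes labelled by exactly one coder count toward that coder's
    exclusive percentage; commonly labelled nodes feed the agreement rate
    and a row-normalized 7x7 matrix (rows = coder A).
    """
    t_end = max(track_a.end, track_b.end)
    n_nodes = int(np.floor(t_end / node_stride + 1e-9)) + 1
    times = np.arange(n_nodes) * node_stride
    la = _labels_on_grid(track_a, times)
    lb = _labels_on_grid(track_b, times)
    a_nodes, b_nodes = la >= 0, lb >= 0
    common = a_nodes & b_nodes
    n_a, n_b, n_common = int(a_nodes.sum()), int(b_nodes.sum()), int(common.sum())
    pct_only_a = 100.0 * (a_nodes & ~b_nodes).sum() / n_a if n_a else 0.0
    pct_only_b = 100.0 * (b_nodes & ~a_nodes).sum() / n_b if n_b else 0.0
    if n_common == 0:
        return IntercoderResult(pct_only_a, pct_only_b, float("nan"), None, 0)
    agree = 100.0 * float(np.mean(la[common] == lb[common]))
    counts = np.zeros((7, 7))
    np.add.at(counts, (la[common], lb[common]), 1)
    return IntercoderResult(
        pct_only_a, pct_only_b, agree,
        RecognitionMatrix.from_counts(counts), n_common,
    )


# --------------------------------------------------------------------------
# Plotting
# --------------------------------------------------------------------------


def plot_recognition_matrix(matrix: RecognitionMatrix, path: str | Path,
                            title: str = "") -> None:
    """Save a heatmap of a recognition matrix (green-yellow-red scale)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [c.value for c in CATEGORIES]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.values, cmap="RdYlGn_r", vmin=0, vmax=100)
    ax.set_xticks(range(7), names, rotation=45, ha="right")
    ax.set_yticks(range(7), names)
    ax.set_xlabel("predicted (output)")
    ax.set_ylabel("true (input)")
    for i in range(7):
        for j in range(7):
            v = matrix.values[i, j]
            if not np.isnan(v):
                ax.text(j, i, f"{v:.1f}", ha="center", va="center", fontsize=7)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="recognition rate [%]")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
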