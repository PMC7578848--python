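"""Repeated-split Gaussian-kernel SVM decoding with a permutation null.

Each feature matrix has one row per participant x task x load segment
(216 with the full 18-participant design) and 64 channel columns. Three
target schemes are decoded: the 4-class scheme crossing modality with
binarized load (segments 1-3 = low, 4-6 = high), and the two collapsed
binary schemes (modality alone, load alone).

The classifier emulates the "medium Gaussian" SVM preset: RBF kernel
with kernel scale sqrt(P) for P features (i.e. gamma = 1/P), unit box
constraint, one-vs-one multiclass, features standardized by the
training-set mean and standard deviation. Each of the (default 200)
repetitions redraws a stratified 80-10-10% train / cross-validation /
test split; the held-out cv fold is only used to report a secondary
accuracy, never for tuning. The chance distribution repeats the same
protocol with the train+cv labels permuted, leaving test labels intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

SCHEMES = ("four_class", "modality", "load")

FOUR_CLASS_LABELS = (1, 2, 3, 4)

#: Collapsing maps from 4-class targets to binary groupings.
GROUPINGS = {
    "modality": {1: "visual", 2: "visual", 3: "audiovisual", 4: "audiovisual"},
    "load": {1: "low", 2: "high", 3: "low", 4: "high"},
}


class DecodingError(Exception):
    pass


@dataclass
class FeatureMatrix:
    """Observations x channels feature values with row metadata."""

    values: np.ndarray
    meta: pd.DataFrame  # columns: participant, modality, segment
    family: str
    band: str
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or len(self.meta) != self.values.shape[0]:
            raise DecodingError("values and metadata rows do not align")
        if not np.all(np.isfinite(self.values)):
            raise DecodingError("feature matrix contains non-finite values")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path) -> None:
        cols = self.channel_names or [
            f"ch{i}" for i in range(self.values.shape[1])
        ]
        df = pd.concat(
            [self.meta.reset_index(drop=True), pd.DataFrame(self.values, columns=cols)],
            axis=1,
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, family: str = "", band: str = "") -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        meta = df[["participant", "modality", "segment"]]
        vals = df.drop(columns=["participant", "modality", "segment"])
        return cls(
            values=vals.to_numpy(float),
            meta=meta,
            family=family,
            band=band,
            channel_names=list(vals.columns),
        )


def concat_feature_matrices(parts: list["FeatureMatrix"]) -> "FeatureMatrix":
    """Stack per-participant feature matrices row-wise."""
    if not parts:
        raise DecodingError("nothing to concatenate")
    return FeatureMatrix(
        values=np.vstack([p.values for p in parts]),
        meta=pd.concat([p.meta for p in parts], ignore_index=True),
        family=parts[0].family,
        band=parts[0].band,
        channel_names=parts[0].channel_names,
    )


def make_targets(meta: pd.DataFrame, scheme: str) -> np.ndarray:
    """Labels per row: 4-class numbers 1-4, or binary modality/load."""
    if scheme not in SCHEMES:
        raise DecodingError(f"unknown target scheme {scheme!r}")
    seg = meta["segment"].to_numpy()
    if np.any((seg < 1) | (seg > 6)):
        raise DecodingError("segment index outside 1..6")
    load = np.where(seg <= 3, "low", "high")
    modality = meta["modality"].to_numpy()
    if scheme == "modality":
        return modality.astype(object)
    if scheme == "load":
        return load.astype(object)
    four = np.select(
        [
            (modality == "visual") & (load == "low"),
            (modality == "visual") & (load == "high"),
            (modality == "audiovisual") & (load == "low"),
            (modality == "audiovisual") & (load == "high"),
        ],
        [1, 2, 3, 4],
    )
    return four


def split_80_10_10(
    labels: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified, disjoint, exhaustive 80-10-10% split of row indices.

    The cv and test folds each get round(0.1*n) rows (the convention that
    reproduces 172/22/22 on 216 rows); the training fold keeps the rest.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < 10:
        raise DecodingError("need at least 10 rows for an 80-10-10 split")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < 3:
        raise DecodingError("every class needs at least 3 members")
    n_hold = int(round(0.1 * n))
    rng = np.random.SeedSequence([seed])
    s1, s2 = (int(s.generate_state(1)[0] % 2**31) for s in rng.spawn(2))
    sss = StratifiedShuffleSplit(n_splits=1, test_size=n_hold, random_state=s1)
    rest, test = next(sss.split(np.zeros(n), labels))
    sss2 = StratifiedShuffleSplit(n_splits=1, test_size=n_hold, random_state=s2)
    tr, cv_rel = next(sss2.split(np.zeros(len(rest)), labels[rest]))
    return rest[tr], rest[cv_rel], test


def _medium_gaussian_svm(n_features: int):
    # kernel scale sqrt(P)  <=>  gamma = 1/P; C = 1; ovo multiclass
    return make_pipeline(
        StandardScaler(), SVC(C=1.0, kernel="rbf", gamma=1.0 / n_features)
    )


@dataclass
class SvmResult:
    test_accuracy: float
    cv_accuracy: float
    confusion: np.ndarray  # rows true, cols predicted, in label order
    labels: list


def fit_eval_svm(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_cv: np.ndarray,
    y_cv: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
) -> SvmResult:
    """Fit the medium-Gaussian SVM on train, report test (and cv) accuracy."""
    if len(np.unique(y_train)) < 2:
        raise DecodingError("training set is degenerate: fewer than 2 classes")
    clf = _medium_gaussian_svm(X_train.shape[1])
    clf.fit(X_train, y_train)
    pred_test = clf.predict(X_test)
    pred_cv = clf.predict(X_cv)
    labels = sorted(np.unique(np.concatenate([y_train, y_test])).tolist())
    return SvmResult(
        test_accuracy=float(np.mean(pred_test == y_test)),
        cv_accuracy=float(np.mean(pred_cv == y_cv)),
        confusion=confusion_matrix(y_test, pred_test, labels=labels),
        labels=labels,
    )


@dataclass
class AccuracyDistribution:
    """Test-set accuracies over repeated random splits."""

    accuracies: np.ndarray
    confusions: np.ndarray  # reps x k x k
    labels: list
    condition: str  # "actual" or "chance"
    scheme: str
    seed: int

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if np.any((self.accuracies < 0) | (self.accuracies > 1)):
            raise DecodingError("accuracies must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd(self) -> float:
        return float(self.accuracies.std(ddof=1))


def _rep_seed(seed: int, rep: int, salt: int) -> int:
    ss = np.random.SeedSequence([int(seed), int(salt), int(rep)])
    return int(ss.generate_state(1)[0] % 2**31)


def _repeat(
    features: FeatureMatrix | np.ndarray,
    targets: np.ndarray,
    reps: int,
    seed: int,
    scheme: str,
    permute: bool,
) -> AccuracyDistribution:
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    y = np.asarray(targets)
    if X.shape[0] != len(y):
        raise DecodingError("features and targets do not align")
    accs, confs, labels = [], [], None
    salt = 1 if permute else 0
    for rep in range(reps):
        rs = _rep_seed(seed, rep, 2)  # split seed shared by actual and chance
        train, cv, test = split_80_10_10(y, rs)
        y_fit = y.copy()
        if permute:
            rng = np.random.default_rng(_rep_seed(seed, rep, 3))
            pool = np.concatenate([train, cv])
            y_fit[pool] = rng.permutation(y_fit[pool])
        res = fit_eval_svm(
            X[train], y_fit[train], X[cv], y_fit[cv], X[test], y[test]
        )
        accs.append(res.test_accuracy)
        confs.append(res.confusion)
        labels = res.labels
    return AccuracyDistribution(
        accuracies=np.array(accs),
        confusions=np.array(confs),
        labels=labels,
        condition="chance" if permute else "actual",
        scheme=scheme,
        seed=seed,
    )


def repeated_accuracy(
    features: FeatureMatrix | np.ndarray,
    targets: np.ndarray,
    reps: int = 200,
    seed: int = 0,
    scheme: str = "four_class",
) -> AccuracyDistribution:
    """Accuracy distribution over ``reps`` independent stratified splits."""
    return _repeat(features, targets, reps, seed, scheme, permute=False)


def permutation_chance(
    features: FeatureMatrix | np.ndarray,
    targets: np.ndarray,
    reps: int = 200,
    seed: int = 0,
    scheme: str = "four_class",
) -> AccuracyDistribution:
    """Chance-level distribution: train+cv labels permuted, test labels kept."""
    return _repeat(features, targets, reps, seed, scheme, permute=True)


def confusion_grouping_check(
    confusions: np.ndarray, grouping: dict
) -> np.ndarray:
    """Accuracy after collapsing 4-class confusions by a grouping map.

    ``grouping`` maps each 4-class label to a group name; returns the grouped
    accuracy per repetition.
    """
    confusions = np.asarray(confusions, dtype=float)
    if confusions.ndim == 2:
        confusions = confusions[None]
    k = confusions.shape[-1]
    if set(grouping.keys()) != set(FOUR_CLASS_LABELS) or k != 4:
        raise DecodingError("grouping must cover exactly the four class labels")
    groups = [grouping[l] for l in FOUR_CLASS_LABELS]
    out = []
    for cm in confusions:
        total = cm.sum()
        correct = sum(
            cm[i, j]
            for i in range(k)
            for j in range(k)
            if groups[i] == groups[j]
        )
        out.append(correct / total if total else np.nan)
    arr = np.array(out)
    return arr if arr.size > 1 else arr[0]
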