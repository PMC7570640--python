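"""One-vs-one error-correcting output codes (ECOC) over binary SVMs.

Multiclass classification of LSTM feature vectors is reduced to three
binary maximum-margin problems by the exhaustive one-vs-one coding matrix

                SVM 1   SVM 2   SVM 3
    healthy       1       1       0
    mild         -1       0       1
    moderate      0      -1      -1

where +1 marks the positive class, -1 the negative class and 0 a class the
learner ignores.  Prediction takes each learner's decision sign and picks
the class whose codeword has the smallest Hamming distance to the sign
vector, counting only the nonzero codeword positions.  Ties break by fixed
class order (healthy < mild < moderate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .lstm import FeatureVector
from .recording import CLASSES


@dataclass
class CodingDesign:
    """ECOC coding matrix: entries in {-1, 0, 1}, classes x learners."""

    matrix: np.ndarray
    class_names: tuple[str, ...] = CLASSES
    learner_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        n_cls, n_learners = self.matrix.shape
        if not self.learner_names:
            self.learner_names = tuple(f"SVM {j + 1}" for j in range(n_learners))
        if len(self.class_names) != n_cls or len(self.learner_names) != n_learners:
            raise ValueError("design names do not match matrix shape")
        if not np.isin(self.matrix, (-1, 0, 1)).all():
            raise ValueError("design entries must be in {-1, 0, 1}")
        for j in range(n_learners):
            col = self.matrix[:, j]
            if not ((col == 1).any() and (col == -1).any()):
                raise ValueError(
                    f"column {self.learner_names[j]!r} lacks a +1 or a -1 entry"
                )
        if (self.matrix == 0).all(axis=1).any():
            raise ValueError("design contains an all-zero row")
        if len({tuple(row) for row in self.matrix}) != n_cls:
            raise ValueError("design contains duplicate rows")

    @property
    def n_learners(self) -> int:
        return self.matrix.shape[1]


def default_design() -> CodingDesign:
    """The exhaustive one-vs-one design for healthy / mild / moderate."""
    return CodingDesign(
        matrix=np.array([[1, 1, 0],
                         [-1, 0, 1],
                         [0, -1, -1]]),
        class_names=CLASSES,
    )


@dataclass
class SVMConfig:
    """Binary base-learner settings (linear kernel, C = 1 by default)."""

    C: float = 1.0
    kernel: str = "linear"
    gamma: str | float = "scale"
    seed: int = 0


@dataclass
class EcocModel:
    design: CodingDesign
    learners: list[SVC]
    scaler: StandardScaler
    svm_config: SVMConfig = field(default_factory=SVMConfig)

    def __post_init__(self) -> None:
        if len(self.learners) != self.design.n_learners:
            raise ValueError("learner count does not match design columns")

    def save(self, path) -> None:
        """Serialize design, learners and scaler as one archive."""
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "EcocModel":
        import joblib

        model = joblib.load(path)
        if not isinstance(model, EcocModel):
            raise TypeError(f"{path} does not contain an EcocModel")
        return model


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        return np.atleast_2d(features)
    rows = [f.values if isinstance(f, FeatureVector) else np.asarray(f)
            for f in features]
    return np.vstack(rows)


def train_ecoc(features, labels, design: CodingDesign | None = None,
               svm_config: SVMConfig | None = None) -> EcocModel:
    """Fit one binary margin classifier per design column.

    ``features`` is a list of :class:`FeatureVector` or an (N, H) array;
    ``labels`` are integer class indices (row indices into the design).
    For column j, examples of classes coded +1 form the positive set,
    -1 the negative set, and 0-coded classes are excluded.  Features are
    z-standardized with statistics fitted here.
    """
    design = design or default_design()
    svm_config = svm_config or SVMConfig()
    X = _as_matrix(features)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("feature/label count mismatch")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    learners = []
    for j in range(design.n_learners):
        col = design.matrix[:, j]
        codes = col[y]  # per-example code in this column
        keep = codes != 0
        if not ((codes == 1).any() and (codes == -1).any()):
            raise ValueError(
                f"column {design.learner_names[j]!r} has an empty positive "
                "or negative set"
            )
        clf = SVC(C=svm_config.C, kernel=svm_config.kernel,
                  gamma=svm_config.gamma, random_state=svm_config.seed)
        clf.fit(Xs[keep], codes[keep])
        learners.append(clf)
    return EcocModel(design=design, learners=learners, scaler=scaler,
                     svm_config=svm_config)


def hamming_decode(pred: np.ndarray, design: CodingDesign) -> int:
    """Class of minimal Hamming distance to a +/-1 prediction vector.

    The distance to each codeword counts positions where the codeword entry
    is nonzero and its sign differs from the prediction.  Ties break by row
    order.
    """
    pred = np.asarray(pred, dtype=int).ravel()
    if pred.shape[0] != design.n_learners:
        raise ValueError(
            f"prediction vector has {pred.shape[0]} entries; design has "
            f"{design.n_learners} learners"
        )
    if not np.isin(pred, (-1, 1)).all():
        raise ValueError("prediction entries must be -1 or +1")
    nonzero = design.matrix != 0
    disagree = nonzero & (design.matrix != pred[None, :])
    distances = disagree.sum(axis=1)
    return int(np.argmin(distances))  # argmin keeps the first (row-order) minimum


def predict(model: EcocModel, features) -> np.ndarray:
    """Standardize, take learner decision signs, decode by Hamming distance.

    Accepts a single :class:`FeatureVector`/1-D array or a batch; returns
    integer class indices (scalar array for a single input preserved as
    length-1 array order for batches).
    """
    X = _as_matrix(features)
    if X.shape[1] != model.scaler.mean_.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match the trained "
            f"dimension {model.scaler.mean_.shape[0]}"
        )
    Xs = model.scaler.transform(X)
    signs = np.column_stack([
        np.where(clf.decision_function(Xs) >= 0, 1, -1)
        for clf in model.learners
    ])
    return np.array([hamming_decode(row, model.design) for row in signs])
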