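"""Population decoding of tilt direction from Purkinje-cell responses.

Even cells without individual direction tuning can carry a weak,
consistent directional signal; pooling them supports linear read-out.
Trials-by-cells matrices are classified with a linear support-vector
machine under stratified k-fold cross-validation, against a null obtained
by shuffling trial labels.  Pseudo-populations combine cells that were not
recorded simultaneously by independently permuting trial order within each
direction, which destroys cross-cell noise correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .imaging import CellTrialResponses

__all__ = [
    "PopulationMatrix",
    "DecodingResult",
    "build_population_matrix",
    "pca_summary",
    "decode_accuracy",
    "shuffle_null",
    "pseudo_population_curve",
    "least_tuned_subset",
]


@dataclass
class PopulationMatrix:
    """Trials x cells response matrix with direction labels per trial."""

    X: np.ndarray
    labels: np.ndarray            # "up" / "down" per trial row
    cell_ids: list[str]
    pseudo: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.shape[0] != self.labels.size:
            raise ValueError("one label per trial row required")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("missing entries in population matrix")
        for lab in ("up", "down"):
            if (self.labels == lab).sum() < 2:
                raise ValueError("need >= 2 trials per direction")


@dataclass
class DecodingResult:
    population_size: int
    accuracy: float
    null_accuracies: np.ndarray
    n_folds: int
    seed: int


def build_population_matrix(cells: list[CellTrialResponses],
                            mode: str = "within_fish",
                            seed: int = 0) -> PopulationMatrix:
    """Stack per-cell trial responses into a trials x cells matrix.

    ``within_fish`` keeps the original (simultaneous) trial pairing;
    ``pseudo`` permutes trial order independently per cell within each
    direction.  Unequal trial counts are trimmed to the common minimum.
    """
    if not cells:
        raise ValueError("no cells given")
    protos = {c.protocol for c in cells}
    if len(protos) > 1:
        raise ValueError("cells must share one protocol")
    n_up = min(c.responses_up.size for c in cells)
    n_down = min(c.responses_down.size for c in cells)
    if any(c.responses_up.size != n_up or c.responses_down.size != n_down
           for c in cells):
        warnings.warn("unequal trial counts; trimming to the minimum")
    rng = np.random.default_rng(seed)
    cols = []
    for c in cells:
        up = c.responses_up[:n_up].copy()
        down = c.responses_down[:n_down].copy()
        if mode == "pseudo":
            up = rng.permutation(up)
            down = rng.permutation(down)
        elif mode != "within_fish":
            raise ValueError(f"unknown mode {mode!r}")
        cols.append(np.concatenate([up, down]))
    X = np.column_stack(cols)
    labels = np.array(["up"] * n_up + ["down"] * n_down)
    return PopulationMatrix(X=X, labels=labels,
                            cell_ids=[c.cell_id for c in cells],
                            pseudo=(mode == "pseudo"),
                            provenance={"fish_ids": sorted({c.fish_id for c in cells}),
                                        "protocol": cells[0].protocol})


def pca_summary(matrix: PopulationMatrix):
    """Project trials onto the first two principal components.

    Returns (projections [n_trials x 2], variance fraction per component).
    Zero-variance cells are dropped with a warning.
    """
    X = matrix.X
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need >= 3 trials and >= 2 cells")
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn("dropping zero-variance cells before PCA")
        X = X[:, keep]
    n_comp = min(2, X.shape[1], X.shape[0] - 1)
    pca = PCA(n_components=n_comp)
    proj = pca.fit_transform(X - X.mean(axis=0))
    return proj, pca.explained_variance_ratio_


def _classifier():
    # per-fold z-scoring inside the pipeline avoids train/test leakage
    return make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))


def decode_accuracy(matrix: PopulationMatrix, n_folds: int = 5,
                    seed: int = 0, labels: np.ndarray | None = None) -> float:
    """Stratified k-fold cross-validated accuracy of a linear SVM.

    Accuracy is 1 minus the mean held-out misclassification loss.
    """
    y = matrix.labels if labels is None else labels
    counts = [np.sum(y == lab) for lab in np.unique(y)]
    if min(counts) < n_folds:
        raise ValueError("fewer trials per class than folds")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = cross_val_score(_classifier(), matrix.X, y, cv=cv)
    return float(np.mean(scores))


def shuffle_null(matrix: PopulationMatrix, n_shuffles: int = 100,
                 n_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Null accuracy distribution from permuted trial labels."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_shuffles)
    for i in range(n_shuffles):
        labs = rng.permutation(matrix.labels)
        out[i] = decode_accuracy(matrix, n_folds=n_folds,
                                 seed=int(rng.integers(2**31)), labels=labs)
    return out


def least_tuned_subset(cells: list[CellTrialResponses], n: int) -> list[CellTrialResponses]:
    """The n cells with smallest |DI|; ties broken by cell_id."""
    if n > len(cells):
        raise ValueError("requested more cells than available")
    ranked = sorted(cells, key=lambda c: (abs(c.di), c.cell_id))
    return ranked[:n]


def pseudo_population_curve(cells: list[CellTrialResponses],
                            sizes=(3, 5, 7, 10, 13),
                            n_draws: int = 20,
                            n_folds: int = 5,
                            n_shuffles: int = 100,
                            seed: int = 0,
                            with_null: bool = True) -> list[DecodingResult]:
    """Decoding accuracy of seeded random pseudo-populations per size.

    For each size, ``n_draws`` subsets of cells are drawn without
    replacement.  A pseudo-population is a cell subset plus a trial
    pairing, so even when size equals the number of cells (one possible
    subset) each draw is a distinct pseudo-population through its pairing
    seed.  One shuffle null is computed per size on the first draw.
    """
    rng = np.random.default_rng(seed)
    results = []
    for size in sizes:
        if size > len(cells):
            raise ValueError(f"size {size} exceeds available cells")
        draws = n_draws
        null = np.empty(0)
        for d in range(draws):
            idx = rng.choice(len(cells), size=size, replace=False)
            sub = [cells[i] for i in sorted(idx)]
            sub_seed = int(rng.integers(2**31))
            mat = build_population_matrix(sub, mode="pseudo", seed=sub_seed)
            acc = decode_accuracy(mat, n_folds=n_folds, seed=sub_seed)
            if with_null and d == 0:
                null = shuffle_null(mat, n_shuffles=n_shuffles,
                                    n_folds=n_folds, seed=sub_seed)
            results.append(DecodingResult(population_size=size, accuracy=acc,
                                          null_accuracies=null, n_folds=n_folds,
                                          seed=sub_seed))
    return results
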