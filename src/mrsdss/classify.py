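"""Brain-mass classification: Fisher LDA pipelines and the peak-ratio rule.

The classifier suite mirrors the decision-support workflow: canonical
spectra are restricted to the 4.05-0.01 ppm analysis window (optionally
concatenating the short- and long-TE spectra of a case), features are picked
by greedy sequential forward selection with a correlation-based redundancy
filter, and a Fisher linear discriminant maps the selected intensities to a
2D latent space where a case is labelled by its nearest class mean.  The
class regions of that latent plane ("true boundaries") are exactly the
perpendicular bisectors of the class means.  Classifiers are evaluated with
a stratified out-of-bag bootstrap.

The model-fitting API follows the Model/Results convention: build a
:class:`FisherLDA` model from a labelled dataset, call :meth:`FisherLDA.fit`
and work with the returned :class:`FisherLDAResults` (``predict``,
``project``, ``decision_boundaries``, ``summary``, ``plot``, JSON
persistence).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .spectra_io import CanonicalSpectrum, PpmAxis, TeClass

__all__ = [
    "RESTRICT_BAND",
    "LabeledDataset",
    "FeatureSelection",
    "FisherLDA",
    "FisherLDAResults",
    "DecisionBoundaries",
    "RatioRule",
    "EvaluationResult",
    "restrict_range",
    "restricted_indices",
    "restricted_ppm",
    "concat_te",
    "normalize",
    "sequential_forward_select",
    "fisher_lda_fit",
    "project",
    "predict",
    "decision_boundaries",
    "bootstrap_evaluate",
    "evaluate_on_test",
    "dataset_offset",
    "peak_height",
    "ratio_classify",
    "manual_overview",
    "SelectionError",
]

#: Analysis window for feature selection (ppm, inclusive).
RESTRICT_BAND = (0.01, 4.05)


class SelectionError(RuntimeError):
    """Sequential forward selection could not admit any feature."""


# ---------------------------------------------------------------------------
# Feature extraction from canonical spectra
# ---------------------------------------------------------------------------

def restricted_indices() -> np.ndarray:
    """Canonical-grid column indices whose ppm lies in [0.01, 4.05]."""
    ppm = PpmAxis().values
    return np.flatnonzero((ppm >= RESTRICT_BAND[0]) & (ppm <= RESTRICT_BAND[1]))


def restricted_ppm() -> np.ndarray:
    """The ppm values of the restricted analysis window (descending)."""
    return PpmAxis().values[restricted_indices()]


def restrict_range(spectrum: CanonicalSpectrum) -> np.ndarray:
    """Contiguous slice of a canonical spectrum with ppm in [0.01, 4.05]."""
    return spectrum.intensities[restricted_indices()]


def normalize(vector: np.ndarray, spec: str = "unit") -> np.ndarray:
    """Normalise a feature vector: "unit" (Euclidean) or "none"."""
    vector = np.asarray(vector, dtype=float)
    if spec == "none":
        return vector.copy()
    if spec == "unit":
        norm = np.linalg.norm(vector)
        if norm == 0:
            raise ValueError("cannot unit-normalise a zero vector")
        return vector / norm
    raise ValueError(f"unknown normalisation spec {spec!r}")


def concat_te(
    short: CanonicalSpectrum,
    long: CanonicalSpectrum,
    norm: str = "none",
) -> np.ndarray:
    """Restricted short-TE vector followed by the restricted long-TE vector.

    Column i of the long half maps to the same ppm as column i of the short
    half.  Each half is normalised independently when ``norm != "none"``.
    """
    if short.te_class is TeClass.LONG or long.te_class is TeClass.SHORT:
        raise ValueError(
            f"te_class mismatch: got ({short.te_class.value}, {long.te_class.value}), "
            "expected (short, long)"
        )
    a = restrict_range(short)
    b = restrict_range(long)
    if norm != "none":
        a, b = normalize(a, norm), normalize(b, norm)
    return np.concatenate([a, b])


@dataclass
class LabeledDataset:
    """An n x p matrix of spectral intensities with a superclass per row."""

    vectors: np.ndarray
    labels: list[str]
    te_mode: str = "short"  # short | long | concat
    ppm: np.ndarray | None = None  # ppm per column

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D matrix")
        if len(self.labels) != self.vectors.shape[0]:
            raise ValueError("one label per row required")
        if self.ppm is None and self.vectors.shape[0] > 0:
            base = restricted_ppm()
            if self.vectors.shape[1] == base.size:
                self.ppm = base
            elif self.vectors.shape[1] == 2 * base.size:
                self.ppm = np.concatenate([base, base])
        self.labels = list(self.labels)

    @classmethod
    def from_vectors(
        cls, vectors: np.ndarray, labels: Sequence[str], te_mode: str = "short"
    ) -> "LabeledDataset":
        return cls(np.asarray(vectors, dtype=float), list(labels), te_mode)

    @classmethod
    def from_spectra(
        cls,
        spectra: Sequence[CanonicalSpectrum],
        labels: Sequence[str],
        norm: str = "unit",
    ) -> "LabeledDataset":
        vectors = np.array([normalize(restrict_range(s), norm) for s in spectra])
        te_mode = spectra[0].te_class.value if spectra else "short"
        return cls(vectors, list(labels), te_mode)

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def p(self) -> int:
        return self.vectors.shape[1]

    @property
    def classes(self) -> list[str]:
        """Class names in order of first appearance (deterministic)."""
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    def label_indices(self, classes: Sequence[str] | None = None) -> np.ndarray:
        classes = list(classes) if classes is not None else self.classes
        lookup = {c: i for i, c in enumerate(classes)}
        return np.array([lookup[lab] for lab in self.labels], dtype=int)

    def subset(self, rows: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            self.vectors[rows],
            [self.labels[i] for i in np.atleast_1d(rows)],
            self.te_mode,
            self.ppm,
        )


@dataclass(frozen=True)
class FeatureSelection:
    """Outcome of sequential forward selection."""

    indices: tuple[int, ...]  # in selection order
    criterion_trace: tuple[float, ...]  # training accuracy after each addition
    skipped_correlated: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("selected indices must be unique")


# ---------------------------------------------------------------------------
# Fisher LDA: scatter matrices, generalized eigenproblem, 2D latent space
# ---------------------------------------------------------------------------

def _scatter_matrices(
    X: np.ndarray, y_idx: np.ndarray, n_classes: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Within-class scatter, between-class scatter and class means (p-dim)."""
    p = X.shape[1]
    sw = np.zeros((p, p))
    sb = np.zeros((p, p))
    grand = X.mean(axis=0)
    means = np.zeros((n_classes, p))
    for k in range(n_classes):
        Xk = X[y_idx == k]
        means[k] = Xk.mean(axis=0)
        centred = Xk - means[k]
        sw += centred.T @ centred
        diff = means[k] - grand
        sb += Xk.shape[0] * np.outer(diff, diff)
    return sw, sb, means


def _regularise(sw: np.ndarray, shrinkage: float) -> np.ndarray:
    d = sw.shape[0]
    lam = shrinkage * (np.trace(sw) / d) + 1e-12
    return sw + lam * np.eye(d)


def _fix_signs(w: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector orientation: largest-|.| component positive."""
    w = w.copy()
    for j in range(w.shape[1]):
        i = int(np.argmax(np.abs(w[:, j])))
        if w[i, j] < 0:
            w[:, j] = -w[:, j]
    return w


class FisherLDA:
    """Fisher linear discriminant model over a labelled spectral dataset.

    Parameters
    ----------
    dataset : LabeledDataset
        Training data (row vectors already restricted/normalised).
    features : sequence of int, optional
        Column indices to use; defaults to all columns.
    shrinkage : float
        Trace-scaled ridge added to the within-class scatter so that
        p > n slices stay invertible.
    """

    def __init__(
        self,
        dataset: LabeledDataset,
        features: Sequence[int] | None = None,
        shrinkage: float = 1e-6,
    ) -> None:
        if len(set(dataset.labels)) < 2:
            raise ValueError("training requires at least 2 classes")
        self.dataset = dataset
        self.features = (
            tuple(int(i) for i in features)
            if features is not None
            else tuple(range(dataset.p))
        )
        if len(set(self.features)) != len(self.features):
            raise ValueError("feature indices must be unique")
        if self.features and (min(self.features) < 0 or max(self.features) >= dataset.p):
            raise ValueError("feature index out of range")
        self.shrinkage = float(shrinkage)

    def fit(self) -> "FisherLDAResults":
        """Solve the generalized eigenproblem and keep the top-2 latent axes."""
        import scipy.linalg

        X = self.dataset.vectors[:, list(self.features)]
        classes = self.dataset.classes
        y_idx = self.dataset.label_indices(classes)
        sw, sb, _ = _scatter_matrices(X, y_idx, len(classes))
        sw_reg = _regularise(sw, self.shrinkage)
        try:
            eigvals, eigvecs = scipy.linalg.eigh(sb, sw_reg)
        except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:
            raise RuntimeError(
                f"within-class scatter singular even after shrinkage "
                f"(features {self.features}): {exc}"
            ) from exc
        order = np.argsort(eigvals)[::-1]
        eigvals = eigvals[order]
        eigvecs = eigvecs[:, order]
        d = X.shape[1]
        if d >= 2:
            w = eigvecs[:, :2]
            kept_eigvals = eigvals[:2]
        else:  # a single feature: second (plot-only) axis is identically zero
            w = np.column_stack([eigvecs[:, :1], np.zeros((d, 1))])
            kept_eigvals = np.array([eigvals[0], 0.0])
        w = _fix_signs(w)
        latent = X @ w
        means_2d = np.array([latent[y_idx == k].mean(axis=0) for k in range(len(classes))])
        return FisherLDAResults(
            model=self,
            classes=list(classes),
            projection=w,
            eigenvalues=kept_eigvals,
            class_means_2d=means_2d,
            within_scatter=sw,
            between_scatter=sb,
        )


@dataclass
class FisherLDAResults:
    """Fitted Fisher LDA: selected features, 2D projection, class geometry."""

    model: FisherLDA | None
    classes: list[str]
    projection: np.ndarray  # d x 2
    eigenvalues: np.ndarray
    class_means_2d: np.ndarray  # K x 2
    within_scatter: np.ndarray | None = None
    between_scatter: np.ndarray | None = None
    normalisation: str = "unit"

    @property
    def features(self) -> tuple[int, ...]:
        if self.model is not None:
            return self.model.features
        return self._features

    def _select(self, vectors: np.ndarray) -> np.ndarray:
        vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
        d = self.projection.shape[0]
        if vectors.shape[1] == d:
            return vectors
        feats = list(self.features)
        if vectors.shape[1] > d and max(feats, default=-1) < vectors.shape[1]:
            return vectors[:, feats]
        raise ValueError(
            f"vector length {vectors.shape[1]} matches neither the {d} selected "
            f"features nor the full feature space"
        )

    def project(self, vectors: np.ndarray) -> np.ndarray:
        """2D latent coordinates of one or more feature vectors."""
        single = np.asarray(vectors).ndim == 1
        latent = self._select(vectors) @ self.projection
        return latent[0] if single else latent

    def predict(self, vectors: np.ndarray) -> np.ndarray | str:
        """Label of the nearest class mean in the 2D latent space.

        Ties go to the class declared first in the model.
        """
        single = np.asarray(vectors).ndim == 1
        latent = np.atleast_2d(self.project(vectors))
        dists = ((latent[:, None, :] - self.class_means_2d[None, :, :]) ** 2).sum(-1)
        idx = np.argmin(dists, axis=1)  # argmin takes the first class on ties
        labels = np.array([self.classes[i] for i in idx])
        return str(labels[0]) if single else labels

    def training_accuracy(self) -> float:
        if self.model is None:
            raise ValueError("training data not attached to deserialised results")
        pred = self.predict(self.model.dataset.vectors)
        return float(np.mean(pred == np.array(self.model.dataset.labels)))

    def decision_boundaries(
        self, region: tuple[float, float, float, float] | None = None
    ) -> "DecisionBoundaries":
        return decision_boundaries(self, region)

    def summary(self) -> str:
        lines = [
            "Fisher LDA results",
            "==================",
            f"classes:        {', '.join(self.classes)}",
            f"n features:     {len(self.features)}",
            f"feature idx:    {list(self.features)}",
            f"eigenvalues:    {np.array2string(self.eigenvalues, precision=4)}",
        ]
        if self.model is not None:
            lines.append(f"n training:     {self.model.dataset.n}")
            lines.append(f"train accuracy: {self.training_accuracy():.4f}")
        lines.append("class means (2D latent):")
        for name, (x, y) in zip(self.classes, self.class_means_2d):
            lines.append(f"  {name:<20s} x={x:+.5f}  y={y:+.5f}")
        return "\n".join(lines)

    def plot(self, ax=None, show_boundaries: bool = True):
        """Latent-space scatter of the training set with class regions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        bounds = self.decision_boundaries()
        if show_boundaries:
            for name, polys in bounds.regions.items():
                for poly in polys:
                    ax.fill(poly[:, 0], poly[:, 1], alpha=0.15, label=None)
        if self.model is not None:
            latent = self.project(self.model.dataset.vectors)
            labels = np.array(self.model.dataset.labels)
            for name in self.classes:
                pts = latent[labels == name]
                ax.scatter(pts[:, 0], pts[:, 1], s=12, label=name)
        ax.scatter(
            self.class_means_2d[:, 0], self.class_means_2d[:, 1],
            marker="x", c="k", s=60, label="class means",
        )
        ax.set_xlabel("latent axis 1")
        ax.set_ylabel("latent axis 2")
        ax.legend(fontsize=8)
        return ax

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "features": list(self.features),
            "projection": self.projection.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "class_means_2d": self.class_means_2d.tolist(),
            "normalisation": self.normalisation,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, data: dict) -> "FisherLDAResults":
        results = cls(
            model=None,
            classes=list(data["classes"]),
            projection=np.asarray(data["projection"], dtype=float),
            eigenvalues=np.asarray(data["eigenvalues"], dtype=float),
            class_means_2d=np.asarray(data["class_means_2d"], dtype=float),
            normalisation=data.get("normalisation", "unit"),
        )
        results._features = tuple(int(i) for i in data["features"])
        return results

    @classmethod
    def from_json(cls, path: str | Path) -> "FisherLDAResults":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fisher_lda_fit(
    dataset: LabeledDataset,
    features: Sequence[int] | None = None,
    shrinkage: float = 1e-6,
) -> FisherLDAResults:
    """Convenience wrapper: ``FisherLDA(dataset, features).fit()``."""
    return FisherLDA(dataset, features, shrinkage).fit()


def project(results: FisherLDAResults, vector: np.ndarray) -> np.ndarray:
    return results.project(vector)


def predict(results: FisherLDAResults, vector: np.ndarray):
    return results.predict(vector)


# ---------------------------------------------------------------------------
# Sequential forward selection with correlation-based redundancy filter
# ---------------------------------------------------------------------------

def _batched_lda_accuracy(
    X: np.ndarray,
    y_idx: np.ndarray,
    sw_full: np.ndarray,
    sb_full: np.ndarray,
    class_masks: list[np.ndarray],
    candidate_sets: np.ndarray,
    shrinkage: float,
) -> np.ndarray:
    """Training accuracy of a Fisher LDA refit for every candidate feature set.

    ``candidate_sets`` is a (C, d) integer array; all C generalized
    eigenproblems are solved in one batched pass (Cholesky reduction to a
    standard symmetric eigenproblem), and accuracy is nearest-class-mean in
    the top-2 latent axes — identical geometry to :class:`FisherLDAResults`.
    """
    C, d = candidate_sets.shape
    rows = candidate_sets
    sw = sw_full[rows[:, :, None], rows[:, None, :]]
    sb = sb_full[rows[:, :, None], rows[:, None, :]]
    lam = shrinkage * (np.trace(sw, axis1=1, axis2=2) / d) + 1e-12
    sw = sw + lam[:, None, None] * np.eye(d)[None]
    L = np.linalg.cholesky(sw)
    # A = L^-1 Sb L^-T, symmetric
    tmp = np.linalg.solve(L, sb)
    A = np.linalg.solve(L, tmp.transpose(0, 2, 1))
    A = 0.5 * (A + A.transpose(0, 2, 1))
    _, vecs = np.linalg.eigh(A)  # ascending eigenvalues
    k = min(2, d)
    v_top = vecs[:, :, -1: -1 - k: -1]  # top-k standard eigenvectors
    W = np.linalg.solve(L.transpose(0, 2, 1), v_top)  # (C, d, k)
    Xc = X[:, rows].transpose(1, 0, 2)  # (C, n, d)
    latent = Xc @ W  # (C, n, k)
    K = len(class_masks)
    dists = np.empty((C, X.shape[0], K))
    for j, mask in enumerate(class_masks):
        mean_j = latent[:, mask].mean(axis=1)  # (C, k)
        dists[:, :, j] = ((latent - mean_j[:, None, :]) ** 2).sum(-1)
    pred = np.argmin(dists, axis=2)  # (C, n)
    return (pred == y_idx[None, :]).mean(axis=1)


def sequential_forward_select(
    dataset: LabeledDataset,
    max_features: int = 13,
    correlation_threshold: float = 0.8,
    shrinkage: float = 1e-6,
) -> FeatureSelection:
    """Greedy forward feature selection validated by a correlation criterion.

    At each step the admissible candidate column maximising the training
    accuracy of a Fisher LDA refit on the augmented set is added (ties break
    toward the lower column index).  A candidate whose |Pearson r| with any
    already-selected column exceeds ``correlation_threshold`` is skipped as
    redundant.  Selection stops at ``max_features`` or as soon as no
    admissible candidate improves the criterion.
    """
    if max_features < 1:
        raise ValueError("max_features must be >= 1")
    if len(set(dataset.labels)) < 2:
        raise ValueError("selection requires at least 2 classes")
    X = dataset.vectors
    classes = dataset.classes
    y_idx = dataset.label_indices(classes)
    class_masks = [y_idx == k for k in range(len(classes))]
    sw_full, sb_full, _ = _scatter_matrices(X, y_idx, len(classes))

    # column-standardised copy for Pearson correlations
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (X - X.mean(axis=0)) / sd_safe
    constant = sd == 0

    selected: list[int] = []
    trace: list[float] = []
    skipped: set[int] = set()
    best = -np.inf
    p = dataset.p
    while len(selected) < max_features:
        admissible = []
        for c in range(p):
            if c in selected:
                continue
            if selected:
                r = np.abs(Z[:, selected].T @ Z[:, c]) / X.shape[0]
                if constant[c]:
                    r = np.zeros_like(r)
                if np.any(r > correlation_threshold):
                    skipped.add(c)
                    continue
            admissible.append(c)
        if not admissible:
            if not selected:
                raise SelectionError("no admissible candidate at the first step")
            break
        sets = np.array([selected + [c] for c in admissible], dtype=int)
        accs = _batched_lda_accuracy(
            X, y_idx, sw_full, sb_full, class_masks, sets, shrinkage
        )
        j = int(np.argmax(accs))  # first maximum -> lowest column index wins ties
        if selected and accs[j] <= best + 1e-12:
            break
        selected.append(admissible[j])
        best = float(accs[j])
        trace.append(best)
    return FeatureSelection(tuple(selected), tuple(trace), tuple(sorted(skipped)))


# ---------------------------------------------------------------------------
# Decision boundaries of the nearest-mean latent classifier
# ---------------------------------------------------------------------------

@dataclass
class DecisionBoundaries:
    """Planar partition of the 2D latent space by class.

    For nearest-class-mean classification the boundaries are exactly the
    perpendicular bisectors of the latent class means; each class region is
    the intersection of its "closer-to-me" half-planes, clipped to ``box``.
    ``lines`` holds one entry per class pair: coefficients (a, b, c) of
    a*x + b*y = c, the locus equidistant from the two means.
    """

    classes: list[str]
    lines: list[dict]
    regions: dict[str, list[np.ndarray]]
    box: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax

    def _polygons(self):
        from shapely.geometry import Polygon

        if not hasattr(self, "_poly_cache"):
            self._poly_cache = [
                (name, [Polygon(p) for p in polys])
                for name, polys in self.regions.items()
            ]
        return self._poly_cache

    def regions_of(self, points: np.ndarray) -> np.ndarray:
        """Class label per latent point (object array; None outside the box).

        A point on a shared boundary edge is covered by several regions;
        the first class in declaration order wins, matching the tie rule of
        nearest-mean prediction.
        """
        import shapely

        points = np.atleast_2d(np.asarray(points, dtype=float))
        geoms = shapely.points(points)
        out = np.full(points.shape[0], None, dtype=object)
        for name, polys in self._polygons():
            covered = np.zeros(points.shape[0], dtype=bool)
            for poly in polys:
                covered |= shapely.covers(poly, geoms)
            out[covered & (out == None)] = name  # noqa: E711
        return out

    def region_of(self, point: Sequence[float]) -> str | None:
        """Class whose polygon covers a latent point (None outside the box)."""
        return self.regions_of(np.asarray(point, dtype=float)[None, :])[0]


def decision_boundaries(
    results: FisherLDAResults,
    region: tuple[float, float, float, float] | None = None,
) -> DecisionBoundaries:
    """Perpendicular-bisector partition of the latent plane by class."""
    from shapely.geometry import Polygon

    means = results.class_means_2d
    names = results.classes
    if region is None:
        lo = means.min(axis=0)
        hi = means.max(axis=0)
        span = float(np.max(hi - lo))
        span = span if span > 0 else 1.0
        pad = 2.0 * span
        region = (lo[0] - pad, lo[1] - pad, hi[0] + pad, hi[1] + pad)
    xmin, ymin, xmax, ymax = region
    box = Polygon([(xmin, ymin), (xmax, ymin), (xmax, ymax), (xmin, ymax)])
    diameter = float(np.hypot(xmax - xmin, ymax - ymin))
    R = 10.0 * diameter

    lines: list[dict] = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = means[j] - means[i]
            c = float((means[j] @ means[j] - means[i] @ means[i]) / 2.0)
            lines.append(
                {"classes": (names[i], names[j]), "a": float(a), "b": float(b), "c": c}
            )

    regions: dict[str, list[np.ndarray]] = {}
    for i, name in enumerate(names):
        poly = box
        for j in range(len(names)):
            if j == i or poly.is_empty:
                continue
            mi, mj = means[i], means[j]
            u = mj - mi
            nu = np.linalg.norm(u)
            if nu == 0:  # coincident means: tie always goes to the earlier class
                if j < i:
                    poly = Polygon()
                continue
            u = u / nu
            v = np.array([-u[1], u[0]])
            p0 = (mi + mj) / 2.0
            half = Polygon(
                [
                    p0 + R * v,
                    p0 - R * v,
                    p0 - R * v - 2 * R * u,
                    p0 + R * v - 2 * R * u,
                ]
            )
            poly = poly.intersection(half)
        polys: list[np.ndarray] = []
        if not poly.is_empty:
            geoms = getattr(poly, "geoms", [poly])
            for g in geoms:
                if g.area > 0:
                    polys.append(np.asarray(g.exterior.coords))
        regions[name] = polys
    return DecisionBoundaries(list(names), lines, regions, region)


# ---------------------------------------------------------------------------
# Bootstrap evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    """Classifier evaluation: point accuracy, confusion, OOB distribution."""

    accuracy: float
    n_bootstrap: int
    classes: list[str]
    confusion: np.ndarray  # rows: true class, cols: predicted
    oob_accuracies: np.ndarray | None = None
    oob_interval: tuple[float, float] | None = None
    redraws: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")

    def summary(self) -> str:
        lines = [
            f"accuracy: {self.accuracy:.4f}  (B={self.n_bootstrap})",
        ]
        if self.oob_interval is not None:
            lines.append(
                f"OOB 2.5-97.5 percentile: "
                f"[{self.oob_interval[0]:.4f}, {self.oob_interval[1]:.4f}]"
            )
        lines.append("confusion (rows true, cols predicted):")
        header = "  ".join(f"{c[:12]:>12s}" for c in self.classes)
        lines.append(" " * 14 + header)
        for name, row in zip(self.classes, self.confusion):
            cells = "  ".join(f"{int(v):>12d}" for v in row)
            lines.append(f"{name[:12]:>12s}  {cells}")
        return "\n".join(lines)


def default_trainer(
    max_features: int = 13,
    correlation_threshold: float = 0.8,
    shrinkage: float = 1e-6,
) -> Callable[[LabeledDataset], FisherLDAResults]:
    """The standard pipeline trainer: SFS followed by a Fisher LDA fit."""

    def train(dataset: LabeledDataset) -> FisherLDAResults:
        sel = sequential_forward_select(
            dataset, max_features, correlation_threshold, shrinkage
        )
        return fisher_lda_fit(dataset, sel.indices, shrinkage)

    return train


def bootstrap_evaluate(
    dataset: LabeledDataset,
    trainer: Callable[[LabeledDataset], FisherLDAResults] | None = None,
    B: int = 200,
    seed: int = 0,
) -> EvaluationResult:
    """Stratified out-of-bag bootstrap evaluation of the full pipeline.

    Each replicate resamples every class with replacement to its original
    size (so no class can vanish), refits the trainer (including feature
    selection) and scores the rows never drawn.  Reported accuracy is the
    mean OOB accuracy over replicates; the confusion matrix aggregates all
    OOB predictions.  Fully reproducible given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    trainer = trainer or default_trainer()
    rng = np.random.default_rng(seed)
    classes = dataset.classes
    y = np.array(dataset.labels)
    class_rows = {c: np.flatnonzero(y == c) for c in classes}
    lookup = {c: i for i, c in enumerate(classes)}

    oob_accs: list[float] = []
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    redraws = 0
    for _ in range(B):
        while True:
            draw = np.concatenate(
                [rng.choice(rows, size=rows.size, replace=True)
                 for rows in class_rows.values()]
            )
            oob = np.setdiff1d(np.arange(dataset.n), draw)
            if oob.size > 0 and len(set(y[draw])) == len(classes):
                break
            redraws += 1
        fitted = trainer(dataset.subset(draw))
        pred = np.atleast_1d(fitted.predict(dataset.vectors[oob]))
        truth = y[oob]
        oob_accs.append(float(np.mean(pred == truth)))
        for t, q in zip(truth, pred):
            if q in lookup:  # a resample may use a class order subset
                confusion[lookup[t], lookup[q]] += 1
    oob_accs_arr = np.array(oob_accs)
    return EvaluationResult(
        accuracy=float(oob_accs_arr.mean()),
        n_bootstrap=B,
        classes=list(classes),
        confusion=confusion,
        oob_accuracies=oob_accs_arr,
        oob_interval=(
            float(np.percentile(oob_accs_arr, 2.5)),
            float(np.percentile(oob_accs_arr, 97.5)),
        ),
        redraws=redraws,
    )


def evaluate_on_test(
    results: FisherLDAResults, test: LabeledDataset
) -> EvaluationResult:
    """Accuracy and confusion on held-out data; no refit."""
    if test.n == 0:
        raise ValueError("empty test set")
    pred = np.atleast_1d(results.predict(test.vectors))
    truth = np.array(test.labels)
    classes = list(results.classes)
    for label in truth:
        if label not in classes:
            classes.append(label)
    lookup = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for t, q in zip(truth, pred):
        confusion[lookup[t], lookup[q]] += 1
    return EvaluationResult(
        accuracy=float(np.mean(pred == truth)),
        n_bootstrap=0,
        classes=classes,
        confusion=confusion,
    )


# ---------------------------------------------------------------------------
# Peak heights, the min-offset rule, ratio classification, manual overviews
# ---------------------------------------------------------------------------

def dataset_offset(spectra: Sequence[CanonicalSpectrum]) -> float:
    """Positivity offset for ratio displays: -(dataset minimum), floored at 0.

    The minimum intensity over *all* spectra in the active set defines a
    common additive offset that turns every point positive, so peak-height
    ratios cannot divide by zero.  It must be recomputed whenever the set
    changes (e.g. a new case arrives).
    """
    if not spectra:
        return 0.0
    minimum = min(float(np.min(s.intensities)) for s in spectra)
    return max(0.0, -minimum)


def peak_height(
    spectrum: CanonicalSpectrum,
    ppm: float,
    halfwidth_pts: int = 5,
    dataset_offset_value: float = 0.0,
) -> float:
    """Maximum intensity within +/-halfwidth points of a ppm, plus the offset."""
    axis = PpmAxis()
    if not (axis.ppm_min <= ppm <= axis.ppm_max):
        raise ValueError(f"{ppm} ppm is outside the canonical axis")
    centre = axis.index_of(ppm)
    lo = max(centre - halfwidth_pts, 0)
    hi = min(centre + halfwidth_pts, axis.n_points - 1)
    return float(spectrum.intensities[lo: hi + 1].max()) + dataset_offset_value


@dataclass(frozen=True)
class RatioRule:
    """Peak-ratio classifier: Cho/NAA at short TE vs mI/NAA at long TE.

    The x coordinate is the choline-to-NAA peak-height ratio on the short-TE
    spectrum, the y coordinate the myo-inositol-to-NAA ratio on the long-TE
    spectrum, both after the dataset positivity offset.  ``boundary`` is an
    optional piecewise-linear polyline ((x, y) vertices, ascending x);
    points above it are labelled ``class_above``, others ``class_below``.
    The boundary ships unset, in which case only coordinates are produced.
    """

    cho_ppm: float = 3.21
    naa_ppm: float = 2.01
    mi_ppm: float = 3.55
    halfwidth_pts: int = 5
    boundary: tuple[tuple[float, float], ...] | None = None
    class_above: str = "tumoural"
    class_below: str = "pseudotumoural"

    def __post_init__(self) -> None:
        if self.cho_ppm == self.naa_ppm or self.mi_ppm == self.naa_ppm:
            raise ValueError("numerator and denominator peaks must differ")
        if self.boundary is not None:
            xs = [p[0] for p in self.boundary]
            if len(xs) < 2 or any(b <= a for a, b in zip(xs, xs[1:])):
                raise ValueError("boundary vertices must have ascending x")

    def classify_point(self, x: float, y: float) -> str | None:
        if self.boundary is None:
            return None
        xs = np.array([p[0] for p in self.boundary])
        ys = np.array([p[1] for p in self.boundary])
        y_line = float(np.interp(x, xs, ys))
        return self.class_above if y > y_line else self.class_below


def ratio_classify(
    short: CanonicalSpectrum,
    long: CanonicalSpectrum,
    rule: RatioRule | None = None,
    dataset: Sequence[CanonicalSpectrum] = (),
) -> tuple[float, float, str | None]:
    """Coordinates (and optional class) under the peak-ratio rule.

    The positivity offset is computed over the two case spectra together
    with any further ``dataset`` spectra in the active set, so denominators
    are strictly positive even with inverted long-TE lactate.
    """
    rule = rule or RatioRule()
    offset = dataset_offset([short, long, *dataset])
    h = rule.halfwidth_pts
    cho = peak_height(short, rule.cho_ppm, h, offset)
    naa_s = peak_height(short, rule.naa_ppm, h, offset)
    mi = peak_height(long, rule.mi_ppm, h, offset)
    naa_l = peak_height(long, rule.naa_ppm, h, offset)
    assert naa_s > 0 and naa_l > 0, "offset rule guarantees positive denominators"
    x = cho / naa_s
    y = mi / naa_l
    return x, y, rule.classify_point(x, y)


def manual_overview(
    spectra: Sequence[CanonicalSpectrum],
    ppm_a: float,
    ppm_b: float,
    mode: str = "height",
    halfwidth_pts: int = 5,
) -> np.ndarray:
    """Personalised 2D overview of a spectrum set.

    ``height`` mode plots the raw peak height at ``ppm_a`` against the one
    at ``ppm_b``.  ``ratio`` mode applies the dataset positivity offset and
    plots the a/b height ratio against its reciprocal b/a (so two spectra
    differing only in scale coincide, and ``ppm_a == ppm_b`` collapses onto
    the point (1, 1)).  Returns an (n, 2) array, empty for an empty set.
    """
    if mode not in ("height", "ratio"):
        raise ValueError(f"unknown overview mode {mode!r}")
    if not spectra:
        return np.empty((0, 2))
    if mode == "height":
        return np.array(
            [
                (
                    peak_height(s, ppm_a, halfwidth_pts),
                    peak_height(s, ppm_b, halfwidth_pts),
                )
                for s in spectra
            ]
        )
    offset = dataset_offset(spectra)
    out = []
    for s in spectra:
        ha = peak_height(s, ppm_a, halfwidth_pts, offset)
        hb = peak_height(s, ppm_b, halfwidth_pts, offset)
        out.append((ha / hb, hb / ha))
    return np.array(out)
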