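"""Kohonen self-organizing-map ethogram.

A small SOM (3x3 grid by default, hence nine nodes) is trained without
supervision on the pooled, z-scored six-descriptor frames of all fish. Each
node, once labelled N1..N9, is read as a discrete swimming mode; assigning
every frame to its best-matching unit turns a trajectory into a sequence of
behavioural classes. Classes are then characterized by per-descriptor
one-way ANOVA across classes with a Tukey-Kramer (unequal n) post-hoc test
summarised as a compact letter display: two classes share a letter iff their
means do not differ significantly for that descriptor.

Frames are treated as independent units in the ANOVA. With tens of
thousands of frames from a handful of fish this is pseudoreplication; it is
retained deliberately because the characterization is descriptive (which
descriptors distinguish which classes), not inferential about fish.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .core import DESCRIPTOR_COLUMNS

__all__ = [
    "SOMConfig",
    "EthogramModel",
    "ClassCharacterization",
    "standardize",
    "train_som",
    "assign_classes",
    "characterize_classes",
    "relabel_by_convention",
    "compact_letter_display",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class SOMConfig:
    """Topology and training schedule of the map.

    Learning rate and neighbourhood radius decay linearly over all training
    steps from their initial to their final value; presentation order is
    reshuffled every epoch from the seed.
    """

    grid_rows: int = 3
    grid_cols: int = 3
    epochs: int = 50
    lr_initial: float = 0.5
    lr_final: float = 0.01
    radius_initial: float = 1.5
    radius_final: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.lr_initial > self.lr_final > 0:
            raise ValueError("require lr_initial > lr_final > 0")
        if not self.radius_initial >= self.radius_final >= 0:
            raise ValueError("require radius_initial >= radius_final >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @property
    def n_nodes(self) -> int:
        return self.grid_rows * self.grid_cols


@dataclass
class EthogramModel:
    """Trained SOM: node weights in z-scored descriptor space + scaling + labels."""

    weights: np.ndarray              # (n_nodes, n_features)
    feature_names: tuple[str, ...]
    scaling_mean: np.ndarray         # per-feature mean used for z-scoring
    scaling_std: np.ndarray          # per-feature population s.d.
    labels: tuple[str, ...]          # node index -> class label, a bijection
    config: SOMConfig
    quantization_history: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("EthogramModel.weights must be finite")
        if np.any(self.scaling_std <= 0):
            raise ValueError("EthogramModel scaling s.d. must be > 0")
        if len(set(self.labels)) != len(self.labels) or len(self.labels) != len(self.weights):
            raise ValueError("labels must be a bijection onto nodes")

    def transform(self, frames: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Z-score natural-unit frames with the stored scaling."""
        X = _as_matrix(frames, self.feature_names)
        return (X - self.scaling_mean) / self.scaling_std


def _as_matrix(frames, feature_names) -> np.ndarray:
    if isinstance(frames, pd.DataFrame):
        missing = [c for c in feature_names if c not in frames.columns]
        if missing:
            raise ValueError(f"frames missing descriptor columns {missing}")
        X = frames[list(feature_names)].to_numpy(dtype=float)
    else:
        X = np.asarray(frames, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(feature_names):
            raise ValueError(
                f"feature dimension mismatch: expected {len(feature_names)} columns, "
                f"got shape {X.shape}"
            )
    return X


def standardize(
    frames: pd.DataFrame | np.ndarray,
    feature_names: tuple[str, ...] = DESCRIPTOR_COLUMNS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score pooled frames column-wise (population s.d.).

    Returns ``(Z, mean, std)``. A constant column cannot be scaled and is
    rejected naming the descriptor.
    """
    X = _as_matrix(frames, feature_names)
    mean = X.mean(axis=0)
    std = X.std(axis=0)  # population s.d., ddof=0
    for j, s in enumerate(std):
        if s == 0 or not np.isfinite(s):
            raise ValueError(f"descriptor '{feature_names[j]}' is constant; cannot standardize")
    return (X - mean) / std, mean, std


def _grid_coords(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.divmod(np.arange(rows * cols), cols)
    return np.column_stack([rr, cc]).astype(float)


def train_som(
    frames: pd.DataFrame | np.ndarray,
    config: SOMConfig = SOMConfig(),
    feature_names: tuple[str, ...] = DESCRIPTOR_COLUMNS,
) -> EthogramModel:
    """Train the map by online Kohonen learning on pooled frames.

    Weights are initialized by sampling input rows (seeded). Per step the
    best-matching unit (BMU) is the node of minimal Euclidean distance (ties
    break to the lowest node index), and every node moves toward the input by
    ``lr(t) * exp(-d_grid^2 / (2 sigma(t)^2))`` with ``lr`` and ``sigma``
    decaying linearly over all steps. The quantization-error history records
    the mean pre-update BMU distance per epoch.
    """
    Z, mean, std = standardize(frames, feature_names)
    n, p = Z.shape
    m = config.n_nodes
    if n < m:
        raise ValueError(f"need at least {m} frames to train a {m}-node map, got {n}")
    rng = np.random.default_rng(config.seed)
    W = Z[rng.choice(n, size=m, replace=False)].copy()

    coords = _grid_coords(config.grid_rows, config.grid_cols)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)  # (m, m)

    total = config.epochs * n
    denom = max(total - 1, 1)
    lr0, lr1 = config.lr_initial, config.lr_final
    r0, r1 = config.radius_initial, config.radius_final
    history = np.empty(config.epochs)
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        qe_sum = 0.0
        for idx in order:
            x = Z[idx]
            frac = step / denom
            alpha = lr0 + (lr1 - lr0) * frac
            sigma = r0 + (r1 - r0) * frac
            diff = x - W
            d2 = np.einsum("ij,ij->i", diff, diff)
            bmu = int(np.argmin(d2))
            qe_sum += np.sqrt(d2[bmu])
            if sigma > 0:
                h = np.exp(-grid_d2[bmu] / (2.0 * sigma * sigma))
            else:
                h = (grid_d2[bmu] == 0).astype(float)
            W += (alpha * h)[:, None] * diff
            step += 1
        history[epoch] = qe_sum / n

    labels = tuple(f"N{i + 1}" for i in range(m))  # row-major grid order
    return EthogramModel(
        weights=W,
        feature_names=tuple(feature_names),
        scaling_mean=mean,
        scaling_std=std,
        labels=labels,
        config=config,
        quantization_history=history,
    )


def assign_classes(model: EthogramModel, frames: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Assign each natural-unit frame to its best-matching node's class label.

    Deterministic: ties in distance break to the lowest node index.
    """
    Z = model.transform(frames)
    d2 = ((Z[:, None, :] - model.weights[None, :, :]) ** 2).sum(axis=2)
    bmu = np.argmin(d2, axis=1)
    return np.asarray(model.labels, dtype=object)[bmu]


def relabel_by_convention(
    model: EthogramModel,
    labels_assigned: np.ndarray | None = None,
    by: str = "grid",
) -> tuple[EthogramModel, dict[str, str]]:
    """Relabel nodes N1..N9 by a stated convention.

    ``by='grid'`` (default) numbers nodes in row-major grid order;
    ``by='frequency'`` numbers them by descending assignment frequency
    (requires ``labels_assigned``, the current labels of a frame set).
    Returns the relabelled model and the old->new mapping.
    """
    m = len(model.weights)
    if by == "grid":
        new = tuple(f"N{i + 1}" for i in range(m))
    elif by == "frequency":
        if labels_assigned is None:
            raise ValueError("frequency relabelling requires assigned labels")
        counts = pd.Series(labels_assigned).value_counts()
        order = sorted(
            range(m),
            key=lambda i: (-counts.get(model.labels[i], 0), i),
        )
        new = [""] * m
        for rank, node in enumerate(order):
            new[node] = f"N{rank + 1}"
        new = tuple(new)
    else:
        raise ValueError(f"unknown relabelling convention {by!r}")
    mapping = {old: nw for old, nw in zip(model.labels, new)}
    return replace(model, labels=new), mapping


# ---------------------------------------------------------------------------
# class characterization: ANOVA + Tukey-Kramer + compact letter display


@dataclass
class ClassCharacterization:
    """Per-class descriptor means, homogeneous-group letters and ANOVA table."""

    means: pd.DataFrame        # class x descriptor, natural units
    counts: pd.Series          # frames per class
    letters: pd.DataFrame      # class x descriptor, homogeneous-group letters
    anova: pd.DataFrame        # descriptor -> F, df1, df2, p
    pairwise_p: dict[str, pd.DataFrame]  # descriptor -> class x class Tukey p
    alpha: float


def compact_letter_display(
    names: list[str], means: np.ndarray, significant: np.ndarray
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``significant[i, j]`` marks pairs whose means differ. Two names share a
    letter iff they are not significantly different; letters are ordered by
    ascending group mean.
    """
    k = len(names)
    order = np.argsort(means, kind="stable")
    cols: list[set[int]] = [set(range(k))]
    for a in range(k):
        for b in range(a + 1, k):
            if not significant[a, b]:
                continue
            new_cols: list[set[int]] = []
            for col in cols:
                if a in col and b in col:
                    new_cols.append(col - {a})
                    new_cols.append(col - {b})
                else:
                    new_cols.append(col)
            # absorb: drop columns that are subsets of another
            cols = []
            for col in new_cols:
                if any(col < other for other in new_cols) or col in cols:
                    continue
                cols.append(col)
    rank = {int(g): r for r, g in enumerate(order)}
    cols.sort(key=lambda col: min(rank[g] for g in col) if col else k)
    letters = {name: "" for name in names}
    for li, col in enumerate(cols):
        letter = chr(ord("a") + li) if li < 26 else f"z{li}"
        for g in col:
            letters[names[g]] += letter
    return {name: "".join(sorted(s)) for name, s in letters.items()}


def characterize_classes(
    frames: pd.DataFrame,
    labels: np.ndarray,
    alpha: float = 0.05,
    feature_names: tuple[str, ...] = DESCRIPTOR_COLUMNS,
) -> ClassCharacterization:
    """Characterize behavioural classes by descriptor means and post-hoc groups.

    For every descriptor: one-way ANOVA across classes on frame-level values,
    then all pairwise Tukey-Kramer comparisons (studentized-range reference
    distribution with unequal-n standard errors), summarised as a compact
    letter display. Classes with fewer than 2 frames are excluded with a
    warning.
    """
    lab = pd.Series(np.asarray(labels, dtype=object), name="class")
    if len(lab) != len(frames):
        raise ValueError("labels and frames must align")
    counts = lab.value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        warnings.warn(f"classes with < 2 frames excluded from ANOVA: {small}")
    keep = sorted(counts[counts >= 2].index)
    if len(keep) < 2:
        raise ValueError("need at least two classes with >= 2 frames")

    X = frames[list(feature_names)].to_numpy(dtype=float)
    groups_idx = [np.flatnonzero((lab == g).to_numpy()) for g in keep]
    n_g = np.array([len(ix) for ix in groups_idx])
    N = int(n_g.sum())
    k = len(keep)
    df1, df2 = k - 1, N - k

    means_rows, letters_rows = [], []
    anova_rows = []
    pairwise_p: dict[str, pd.DataFrame] = {}
    for j, name in enumerate(feature_names):
        samples = [X[ix, j] for ix in groups_idx]
        gmeans = np.array([s.mean() for s in samples])
        F, p = stats.f_oneway(*samples)
        ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
        msw = ssw / df2
        # Tukey-Kramer: q = |mi - mj| / sqrt(msw/2 * (1/ni + 1/nj))
        pmat = np.ones((k, k))
        sig = np.zeros((k, k), dtype=bool)
        for a in range(k):
            for b in range(a + 1, k):
                se = np.sqrt(msw / 2.0 * (1.0 / n_g[a] + 1.0 / n_g[b]))
                if se == 0:
                    pv = 1.0 if gmeans[a] == gmeans[b] else 0.0
                else:
                    q = abs(gmeans[a] - gmeans[b]) / se
                    pv = float(stats.studentized_range.sf(q, k, df2))
                pmat[a, b] = pmat[b, a] = pv
                sig[a, b] = sig[b, a] = pv < alpha
        letters = compact_letter_display(list(keep), gmeans, sig)
        means_rows.append(gmeans)
        letters_rows.append([letters[g] for g in keep])
        anova_rows.append({"descriptor": name, "F": float(F), "df1": df1, "df2": df2, "p": float(p)})
        pairwise_p[name] = pd.DataFrame(pmat, index=keep, columns=keep)

    means = pd.DataFrame(np.column_stack(means_rows), index=keep, columns=list(feature_names))
    letters_df = pd.DataFrame(
        np.column_stack([np.array(r, dtype=object) for r in letters_rows]),
        index=keep,
        columns=list(feature_names),
    )
    anova = pd.DataFrame(anova_rows).set_index("descriptor")
    return ClassCharacterization(
        means=means,
        counts=counts.loc[keep],
        letters=letters_df,
        anova=anova,
        pairwise_p=pairwise_p,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# serialization


def save_model(model: EthogramModel, path) -> None:
    """Serialize the trained map to a structured text (YAML) file."""
    doc = {
        "feature_names": list(model.feature_names),
        "weights": model.weights.tolist(),
        "scaling_mean": model.scaling_mean.tolist(),
        "scaling_std": model.scaling_std.tolist(),
        "labels": list(model.labels),
        "config": {
            "grid_rows": model.config.grid_rows,
            "grid_cols": model.config.grid_cols,
            "epochs": model.config.epochs,
            "lr_initial": model.config.lr_initial,
            "lr_final": model.config.lr_final,
            "radius_initial": model.config.radius_initial,
            "radius_final": model.config.radius_final,
            "seed": model.config.seed,
        },
        "quantization_history": model.quantization_history.tolist(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def load_model(path) -> EthogramModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return EthogramModel(
        weights=np.asarray(doc["weights"], dtype=float),
        feature_names=tuple(doc["feature_names"]),
        scaling_mean=np.asarray(doc["scaling_mean"], dtype=float),
        scaling_std=np.asarray(doc["scaling_std"], dtype=float),
        labels=tuple(doc["labels"]),
        config=SOMConfig(**doc["config"]),
        quantization_history=np.asarray(doc["quantization_history"], dtype=float),
    )
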