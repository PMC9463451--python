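"""TiME phenotyping from ordinal feature tables.

Lesions are graded 0-3 on a small set of tumor-immune-microenvironment
features (vessel number, dilated vessels, trafficking, intratumor /
peritumor / perivascular inflammation). Phenotypes are derived by
hierarchical clustering on principal components (HCPC): grades are z-score
standardized, projected onto the leading principal components explaining at
least 95% of total variance, and Ward-clustered in that space; the cluster
count is either fixed or chosen automatically from the inertia profile of
the dendrogram. Each cluster is named Inflam^{HIGH|LOW} Vasc^{HIGH|LOW} by
where its centroid falls on the two components dominated by the
inflammation and vasculature feature sets.

The module follows the Model/Results convention: ``PhenotypeModel(table)``
holds the data, ``.fit()`` returns a :class:`PhenotypeResults` carrying
loadings, eigenvalues, scores, cluster assignments, centroids and labels,
with ``summary()``, projection of new samples, and plotting.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

VASCULAR_FEATURES = ("number_of_vessels", "dilated_vessels", "trafficking")
INFLAMMATION_FEATURES = ("intratumor_inflammation", "peritumor_inflammation",
                         "perivascular_inflammation")


def validate_feature_table(table: pd.DataFrame,
                           features: Sequence[str] | None = None
                           ) -> tuple[pd.DataFrame, pd.Series | None]:
    """Split a table into integer 0-3 grade columns and an optional response.

    ``features`` defaults to every column except ``response``. Grades must
    be integers in {0, 1, 2, 3} with no missing values.
    """
    if features is None:
        features = [c for c in table.columns if c != "response"]
    if len(set(features)) != len(features):
        raise ValueError("feature names must be unique")
    grades = table[list(features)]
    if grades.isna().any().any():
        raise ValueError("feature table contains missing values")
    values = grades.to_numpy()
    if not np.array_equal(values, np.rint(values)) or values.min() < 0 \
            or values.max() > 3:
        raise ValueError("grades must be integers in {0, 1, 2, 3}")
    response = None
    if "response" in table.columns:
        response = table["response"]
        if not set(response.dropna().unique()) <= {0, 1}:
            raise ValueError("response must be binary in {0, 1}")
    return grades.astype(float), response


def _within_inertia(scores: np.ndarray, assignment: np.ndarray) -> float:
    total = 0.0
    for k in np.unique(assignment):
        pts = scores[assignment == k]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


class PhenotypeModel:
    """HCPC phenotyping model over an ordinal TiME feature table."""

    def __init__(self, table: pd.DataFrame,
                 features: Sequence[str] | None = None) -> None:
        self.grades, self.response = validate_feature_table(table, features)
        if len(self.grades) < 4:
            raise ValueError("phenotyping needs at least 4 samples")
        if self.grades.shape[1] < 2:
            raise ValueError("phenotyping needs at least 2 features")
        self.feature_names = list(self.grades.columns)
        self.sample_ids = list(self.grades.index)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "PhenotypeModel":
        return cls(pd.read_csv(path, index_col=0), **kwargs)

    def fit(self, n_clusters: int | str = "auto",
            variance_retained: float = 0.95,
            consolidate: bool = False) -> "PhenotypeResults":
        """Standardize, run PCA, and Ward-cluster the retained scores.

        ``n_clusters='auto'`` picks the cut k in 2..6 maximizing the
        relative loss of within-cluster inertia between successive
        partitions; an integer forces that many clusters. ``consolidate``
        runs a k-means pass initialized at the Ward centroids (off by
        default for reproducibility).
        """
        x = self.grades.to_numpy()
        means = x.mean(axis=0)
        sds = x.std(axis=0)  # population SD: correlation-matrix PCA
        for name, sd in zip(self.feature_names, sds):
            if sd == 0:
                raise ValueError(f"feature '{name}' has zero variance; "
                                 "drop it before fitting")
        z = (x - means) / sds

        n = len(z)
        # PCA via SVD of the standardized matrix
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        eigenvalues = s ** 2 / n
        loadings = vt.T
        # deterministic sign: largest-magnitude loading positive
        for c in range(loadings.shape[1]):
            j = np.argmax(np.abs(loadings[:, c]))
            if loadings[j, c] < 0:
                loadings[:, c] *= -1
        scores_full = z @ loadings

        explained = eigenvalues / eigenvalues.sum()
        cum = np.cumsum(explained)
        n_retained = int(np.searchsorted(cum, variance_retained - 1e-12) + 1)
        scores = scores_full[:, :n_retained]

        link = linkage(scores, method="ward")
        if n_clusters == "auto":
            k_max = min(6, n - 1)
            inertia = {1: _within_inertia(scores, np.zeros(n, dtype=int))}
            for k in range(2, min(k_max + 2, n) + 1):
                inertia[k] = _within_inertia(
                    scores, fcluster(link, k, criterion="maxclust"))
            best_k, best_q = 2, -np.inf
            # drops below 0.1% of total inertia are noise (integer grades
            # collapse duplicate rows, driving W to exactly 0 at large k);
            # flooring both drops keeps negligible ones from dominating
            floor = 1e-3 * max(inertia[1], 1e-12)
            for k in range(2, k_max + 1):
                drop = inertia[k - 1] - inertia[k]
                nxt = inertia.get(k + 1, inertia[k])
                q = max(drop, floor) / max(inertia[k] - nxt, floor)
                if q > best_q:
                    best_k, best_q = k, q
            k = best_k
        else:
            k = int(n_clusters)
            if not 1 < k <= n:
                raise ValueError("n_clusters must be in 2..n_samples")
        raw = fcluster(link, k, criterion="maxclust")
        # renumber clusters 0..k-1 by order of first appearance (stable
        # under sample and feature permutations up to relabeling)
        remap: dict[int, int] = {}
        assignment = np.array([remap.setdefault(c, len(remap)) for c in raw])
        centroids = np.vstack([scores[assignment == i].mean(axis=0)
                               for i in range(k)])
        if consolidate:
            from sklearn.cluster import KMeans
            km = KMeans(n_clusters=k, init=centroids, n_init=1,
                        max_iter=100).fit(scores)
            assignment = km.labels_
            centroids = km.cluster_centers_

        return PhenotypeResults(
            model=self, feature_means=means, feature_sds=sds,
            loadings=loadings, eigenvalues=eigenvalues,
            n_retained=n_retained, scores=scores,
            cluster_of_sample=assignment, centroids=centroids)


@dataclasses.dataclass
class PhenotypeResults:
    """Fitted HCPC phenotyping results."""

    model: PhenotypeModel
    feature_means: np.ndarray
    feature_sds: np.ndarray
    loadings: np.ndarray  # features x components, orthonormal columns
    eigenvalues: np.ndarray  # non-increasing
    n_retained: int
    scores: np.ndarray  # samples x retained components
    cluster_of_sample: np.ndarray
    centroids: np.ndarray  # clusters x retained components
    vascular_axis: int | None = None  # 1-based retained component index
    inflammation_axis: int | None = None
    axis_signs: tuple[float, float] | None = None
    cluster_labels: list[str] | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def variable_contributions(self, component: int) -> pd.Series:
        """Per-feature contribution (%) to a component, summing to 100.

        ``component`` is 1-based (PC1 = 1) and must not exceed the number of
        retained components. The contribution of feature j is
        100 * loading(j, c)^2 / sum_j loading(j, c)^2.
        """
        if not 1 <= component <= self.n_retained:
            raise ValueError(f"component must be in 1..{self.n_retained}")
        col = self.loadings[:, component - 1] ** 2
        return pd.Series(100.0 * col / col.sum(),
                         index=self.model.feature_names,
                         name=f"PC{component}")

    def assign_phenotype_labels(
            self,
            vascular_features: Sequence[str] = VASCULAR_FEATURES,
            inflammation_features: Sequence[str] = INFLAMMATION_FEATURES,
    ) -> "PhenotypeResults":
        """Name the vascular and inflammation axes and label each cluster.

        The vascular axis is the retained component where the summed
        contribution of the vascular features is largest (inflammation axis
        likewise); the two must differ. Each axis is sign-oriented so its
        defining features' loadings sum positive, and a cluster is HIGH on
        an axis when its centroid sits above 0 (the grand mean) on the
        oriented axis. Labels read ``Inflam^{HIGH|LOW} Vasc^{HIGH|LOW}``.
        """
        vas = set(vascular_features)
        inf = set(inflammation_features)
        if vas & inf:
            raise ValueError("vascular and inflammation feature sets overlap")
        missing = (vas | inf) - set(self.model.feature_names)
        if missing:
            raise ValueError(f"features not in the table: {sorted(missing)}")

        def axis_for(feature_set: set[str]) -> int:
            sums = [self.variable_contributions(c)[sorted(feature_set)].sum()
                    for c in range(1, self.n_retained + 1)]
            return int(np.argmax(sums)) + 1

        v_axis = axis_for(vas)
        i_axis = axis_for(inf)
        if v_axis == i_axis:
            raise ValueError(
                "vascular and inflammation features both dominate component "
                f"{v_axis}; pass explicit axes or revise the feature sets")

        names = self.model.feature_names

        def sign_for(axis: int, feature_set: set[str]) -> float:
            idx = [names.index(f) for f in sorted(feature_set)]
            total = self.loadings[idx, axis - 1].sum()
            return 1.0 if total >= 0 else -1.0

        v_sign = sign_for(v_axis, vas)
        i_sign = sign_for(i_axis, inf)
        labels = []
        for centroid in self.centroids:
            v = "HIGH" if v_sign * centroid[v_axis - 1] > 0 else "LOW"
            i = "HIGH" if i_sign * centroid[i_axis - 1] > 0 else "LOW"
            labels.append(f"Inflam^{i} Vasc^{v}")
        self.vascular_axis = v_axis
        self.inflammation_axis = i_axis
        self.axis_signs = (i_sign, v_sign)
        self.cluster_labels = labels
        return self

    def project(self, new_table: pd.DataFrame) -> pd.DataFrame:
        """Project new samples onto the fitted model.

        Standardizes with the training means/SDs, computes retained-PC
        scores, and assigns each sample the nearest centroid (Euclidean;
        ties broken by lowest cluster index), inheriting its label.
        """
        grades, _ = validate_feature_table(new_table,
                                           self.model.feature_names)
        z = (grades.to_numpy() - self.feature_means) / self.feature_sds
        scores = z @ self.loadings[:, :self.n_retained]
        dists = np.linalg.norm(scores[:, None, :] - self.centroids[None],
                               axis=2)
        clusters = dists.argmin(axis=1)  # argmin takes the lowest index on ties
        out = pd.DataFrame(scores, index=grades.index,
                           columns=[f"PC{i+1}" for i in range(self.n_retained)])
        out["cluster"] = clusters
        if self.cluster_labels is not None:
            out["label"] = [self.cluster_labels[c] for c in clusters]
        return out

    def summary(self) -> str:
        lines = ["TiME phenotyping (HCPC on standardized 0-3 grades)",
                 f"samples: {len(self.scores)}   features: "
                 f"{len(self.model.feature_names)}",
                 f"retained components: {self.n_retained} "
                 f"({100 * self.explained_variance_ratio[:self.n_retained].sum():.1f}"
                 "% of variance)", ""]
        lines.append("component  eigenvalue  % variance  % cumulative")
        cum = 0.0
        for i, (ev, r) in enumerate(zip(self.eigenvalues,
                                        self.explained_variance_ratio), 1):
            cum += 100 * r
            lines.append(f"PC{i:<8} {ev:10.3f} {100 * r:11.1f} {cum:13.1f}")
        lines.append("")
        sizes = np.bincount(self.cluster_of_sample,
                            minlength=self.n_clusters)
        for c in range(self.n_clusters):
            label = (self.cluster_labels[c] if self.cluster_labels
                     else f"cluster {c}")
            lines.append(f"cluster {c}: n={sizes[c]:<4} {label}")
        if self.vascular_axis is not None:
            lines.append(f"vascular axis: PC{self.vascular_axis}   "
                         f"inflammation axis: PC{self.inflammation_axis}")
        return "\n".join(lines)

    def plot_scores(self, ax=None):
        """Scatter of samples on the inflammation/vascular axes (or PC1/PC2)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        cx = (self.vascular_axis or 1) - 1
        cy = (self.inflammation_axis or 2) - 1
        cy = min(cy, self.n_retained - 1)
        for c in range(self.n_clusters):
            pts = self.scores[self.cluster_of_sample == c]
            label = (self.cluster_labels[c] if self.cluster_labels
                     else f"cluster {c}")
            ax.scatter(pts[:, cx], pts[:, cy], label=label, s=25)
        ax.axhline(0, color="0.8", lw=0.8)
        ax.axvline(0, color="0.8", lw=0.8)
        ax.set_xlabel(f"PC{cx + 1} (vascular)")
        ax.set_ylabel(f"PC{cy + 1} (inflammation)")
        ax.legend(fontsize=8)
        return ax

    def to_dict(self) -> dict:
        """JSON-serializable model state (for `phenotype fit --out`)."""
        return {
            "feature_names": self.model.feature_names,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "n_retained": self.n_retained,
            "centroids": self.centroids.tolist(),
            "cluster_labels": self.cluster_labels,
            "vascular_axis": self.vascular_axis,
            "inflammation_axis": self.inflammation_axis,
        }


def fit_phenotype_model(table: pd.DataFrame, n_clusters: int | str = "auto",
                        variance_retained: float = 0.95) -> PhenotypeResults:
    """Convenience wrapper: ``PhenotypeModel(table).fit(...)``."""
    return PhenotypeModel(table).fit(n_clusters=n_clusters,
                                     variance_retained=variance_retained)


def variable_contributions(results: PhenotypeResults,
                           component: int) -> pd.Series:
    return results.variable_contributions(component)


def assign_phenotype_labels(results: PhenotypeResults,
                            vascular_features: Sequence[str] = VASCULAR_FEATURES,
                            inflammation_features: Sequence[str] = INFLAMMATION_FEATURES
                            ) -> PhenotypeResults:
    return results.assign_phenotype_labels(vascular_features,
                                           inflammation_features)


def project_samples(results: PhenotypeResults,
                    new_table: pd.DataFrame) -> pd.DataFrame:
    return results.project(new_table)
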