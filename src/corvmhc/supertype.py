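"""Physicochemical supertyping of MHC alleles.

Alleles are reduced to their residues at positively selected sites,
encoded with five physicochemical descriptors per residue (the z1-z5
scales: hydrophobicity, steric bulk, polarity and two electronic
terms), collapsed to unique amino-acid strings, and clustered by
K-means in principal-component space with the number of clusters chosen
by BIC. Discriminant analysis of principal components (DAPC) describes
the clusters, and a sharing summary reports which species possess each
supertype — supertypes private to a species pair are the signature of
convergent selection on a shared pathogen.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

STANDARD_AAS = "ACDEFGHIKLMNPQRSTVWY"


def load_z_table(path: str | Path | None = None) -> dict[str, np.ndarray]:
    """Load an amino-acid descriptor table (default: packaged five-z scale)."""
    if path is None:
        ref = resources.files("corvmhc.data") / "z_descriptors.tsv"
        with resources.as_file(ref) as p:
            return load_z_table(p)
    table: dict[str, np.ndarray] = {}
    with open(path) as fh:
        rows = [r for r in fh if not r.startswith("#") and r.strip()]
    reader = csv.DictReader(rows, delimiter="\t")
    for row in reader:
        aa = row.pop("aa")
        table[aa] = np.asarray([float(v) for v in row.values()])
    if len(table) != 20:
        raise ValueError(f"descriptor table has {len(table)} rows; expected 20")
    return table


def encode_z(
    aa_strings: list[str],
    table: dict[str, np.ndarray] | None = None,
    collapse: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Encode selected-site residue strings as a (alleles x 5L) matrix.

    Rows are the per-site descriptor vectors concatenated in site order.
    With ``collapse=True`` duplicate amino-acid strings are reduced to
    unique rows (first occurrence order) before clustering. Returns
    ``(matrix, unique_strings)``.
    """
    if table is None:
        table = load_z_table()
    if len({len(s) for s in aa_strings}) != 1:
        raise ValueError("selected-site strings of unequal length")
    strings = list(dict.fromkeys(aa_strings)) if collapse else list(aa_strings)
    width = len(next(iter(table.values())))
    rows = np.empty((len(strings), width * len(strings[0])))
    for i, s in enumerate(strings):
        for j, aa in enumerate(s):
            if aa not in table:
                raise ValueError(f"nonstandard residue {aa!r} in allele {i} site {j + 1}")
            rows[i, width * j: width * (j + 1)] = table[aa]
    return rows, strings


@dataclass
class SupertypeModel:
    k: int
    assignments: np.ndarray            # 1-based cluster labels per row
    bic_trace: dict[int, float] = field(default_factory=dict)
    pca_components: np.ndarray | None = None
    coordinates: np.ndarray | None = None   # rows x discriminant functions
    eigenvalues: np.ndarray | None = None
    n_pc: int | None = None
    n_df: int | None = None


def _kmeans_bic(X: np.ndarray, labels: np.ndarray, k: int) -> float:
    """BIC of a hard-assignment spherical Gaussian mixture for a K-means fit.

    Log-likelihood includes the cluster mixing proportions; parameters
    are k centroids, k-1 free proportions and one shared variance.
    """
    n, d = X.shape
    wcss = 0.0
    mixing = 0.0
    for c in range(k):
        pts = X[labels == c]
        if len(pts):
            wcss += ((pts - pts.mean(axis=0)) ** 2).sum()
            mixing += len(pts) * np.log(len(pts) / n)
    var = max(wcss / (n * d), 1e-12)
    loglik = mixing - 0.5 * n * d * (np.log(2 * np.pi * var) + 1.0)
    n_params = k * d + (k - 1) + 1
    return -2.0 * loglik + n_params * np.log(n)


def select_k(
    X: np.ndarray,
    k_max: int = 20,
    seed: int | None = None,
    standardize: bool = True,
    n_restarts: int = 10,
    bic_window: float = 2.0,
) -> SupertypeModel:
    """K-means over a PCA transform with BIC-based choice of K.

    K ranges over 1..k_max; the chosen K minimises BIC, with ties inside
    ``bic_window`` BIC units resolved toward the smallest K (parsimony).
    Deterministic under a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < max(2, k_max):
        k_max = max(2, min(k_max, X.shape[0]))
    std = X.std(axis=0)
    if standardize:
        keep = std > 0
        if not keep.any():
            raise ValueError("degenerate matrix: zero variance in every column")
        X = (X[:, keep] - X[:, keep].mean(axis=0)) / std[keep]
    elif np.allclose(std, 0):
        raise ValueError("degenerate matrix: zero variance in every column")
    pca = PCA(random_state=0)
    Z = pca.fit_transform(X)

    trace: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(1, k_max + 1):
        if k == 1:
            labels = np.zeros(Z.shape[0], dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
            labels = km.fit_predict(Z)
        trace[k] = _kmeans_bic(Z, labels, k)
        labels_by_k[k] = labels
    best = min(trace.values())
    chosen = min(k for k, b in trace.items() if b <= best + bic_window)
    return SupertypeModel(
        k=chosen,
        assignments=labels_by_k[chosen] + 1,
        bic_trace=trace,
        pca_components=pca.components_,
    )


def dapc(
    X: np.ndarray,
    assignments: np.ndarray,
    n_pc: int = 10,
    n_df: int = 3,
    standardize: bool = True,
) -> SupertypeModel:
    """Discriminant analysis of principal components for cluster description.

    Retains ``n_pc`` principal components (clipped to rank) and fits a
    linear discriminant analysis against the cluster labels, keeping at
    most ``n_df`` (and K-1) discriminant functions.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(assignments)
    k = len(np.unique(labels))
    if k < 2:
        raise ValueError("need at least 2 clusters for discrimination")
    if standardize:
        std = X.std(axis=0)
        keep = std > 0
        X = (X[:, keep] - X[:, keep].mean(axis=0)) / std[keep]
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    n_pc_eff = max(1, min(n_pc, rank, X.shape[0] - 1))
    pca = PCA(n_components=n_pc_eff, random_state=0)
    Z = pca.fit_transform(X)
    n_df_eff = min(n_df, k - 1, n_pc_eff)
    lda = LinearDiscriminantAnalysis(n_components=n_df_eff)
    coords = lda.fit_transform(Z, labels)
    eig = lda.explained_variance_ratio_
    return SupertypeModel(
        k=k,
        assignments=labels,
        pca_components=pca.components_,
        coordinates=coords,
        eigenvalues=np.asarray(eig),
        n_pc=n_pc_eff,
        n_df=n_df_eff,
    )


@dataclass
class SupertypeSummary:
    species_by_supertype: dict[int, set[str]]
    exclusive: dict[int, tuple[str, ...]]  # supertypes not shared by all species

    @property
    def n_shared_by_all(self) -> int:
        all_species = set().union(*self.species_by_supertype.values())
        return sum(
            1 for sp in self.species_by_supertype.values() if sp == all_species
        )


def supertype_sharing(
    assignments: np.ndarray,
    species_sets: list[set[str]],
) -> SupertypeSummary:
    """Species membership per supertype.

    ``species_sets[i]`` is the set of species carrying allele row i
    (collapsed amino-acid strings may occur in several species).
    """
    if len(assignments) != len(species_sets):
        raise ValueError("assignments and species sets differ in length")
    by_st: dict[int, set[str]] = {}
    for st, sps in zip(assignments, species_sets):
        by_st.setdefault(int(st), set()).update(sps)
    all_species = set().union(*species_sets) if species_sets else set()
    # a supertype is "exclusive" when it is confined to fewer species than
    # could share it (with a single input species everything is exclusive)
    exclusive = {
        st: tuple(sorted(sp))
        for st, sp in by_st.items()
        if len(sp) < max(len(all_species), 2)
    }
    return SupertypeSummary(by_st, exclusive)
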