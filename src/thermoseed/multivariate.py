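"""Accession trait matrices, correlation-matrix PCA and HCPC.

The per-accession thermal responses are condensed into a small trait
matrix: for germination, the replicate means of Gmax, alpha and tc at each
of the 8 temperatures (24 columns); for seedling growth, the mean radicle
and hypocotyl RER_max at each of the 7 sub-lethal temperatures
(14 columns).  PCA is run on the correlation matrix (columns standardized
to zero mean, unit variance), so the eigenvalues sum to the number of
variables and each variable's contribution to a component is
100 * squared standardized loading / eigenvalue.

HCPC — hierarchical clustering on principal components — is Ward linkage
on Euclidean distances between accession scores restricted to the leading
components (by default the smallest number reaching 90% cumulative
variance), with the tree cut into k groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage, to_tree

__all__ = [
    "TraitMatrix",
    "PCAResult",
    "HCPCResult",
    "GERMINATION_PARAMS",
    "GROWTH_PARAMS",
    "build_trait_matrix",
    "run_pca",
    "run_hcpc",
    "linkage_to_newick",
]

GERMINATION_PARAMS = ("gmax", "alpha", "tc")
GROWTH_PARAMS = ("rer_radicle", "rer_hypocotyl")


@dataclass(frozen=True)
class TraitMatrix:
    """Accessions x named response variables, ready for PCA."""

    data: pd.DataFrame  # index: accessions; columns: named variables
    scheme: str  # "germination24" | "growth14"
    imputed: tuple = ()  # audit log of (accession, column, value)

    @property
    def shape(self):
        return self.data.shape


def _expected_columns(scheme: str, temperatures) -> list[str]:
    params = GERMINATION_PARAMS if scheme == "germination24" else GROWTH_PARAMS
    # parameter-major, temperature-minor ordering
    return [f"{p}_{t:g}" for p in params for t in temperatures]


def build_trait_matrix(summaries: pd.DataFrame, scheme: str,
                       fill_values: dict | None = None) -> TraitMatrix:
    """Pivot accession x temperature summaries into the PCA trait matrix.

    ``summaries`` is long-format.  For scheme "germination24" it needs
    columns accession, temperature, gmax, alpha, tc; for "growth14" it
    needs accession, temperature, axis, rer_max (axes radicle/hypocotyl).
    Missing cells are resolved by ``fill_values`` (a mapping from
    parameter name to fill value); an unresolvable hole raises an error
    naming the cell.  Column order is parameter-major, temperature-minor.
    """
    if scheme not in ("germination24", "growth14"):
        raise ValueError(f"unknown scheme {scheme!r}")
    df = summaries.copy()
    if scheme == "growth14":
        need = {"accession", "temperature", "axis", "rer_max"}
        if not need <= set(df.columns):
            raise ValueError(f"summaries need columns {sorted(need)}")
        df = df.pivot_table(index=["accession", "temperature"],
                            columns="axis", values="rer_max",
                            aggfunc="mean").reset_index()
        df = df.rename(columns={"radicle": "rer_radicle",
                                "hypocotyl": "rer_hypocotyl"})
        params = GROWTH_PARAMS
    else:
        need = {"accession", "temperature", "gmax", "alpha", "tc"}
        if not need <= set(df.columns):
            raise ValueError(f"summaries need columns {sorted(need)}")
        params = GERMINATION_PARAMS

    temperatures = sorted(df["temperature"].unique())
    accessions = sorted(df["accession"].unique())
    if len(accessions) < 2:
        raise ValueError("PCA needs at least 2 accessions")
    fill_values = fill_values or {}
    wide = pd.DataFrame(index=pd.Index(accessions, name="accession"),
                        columns=_expected_columns(scheme, temperatures),
                        dtype=float)
    cell = df.set_index(["accession", "temperature"])
    imputed = []
    for acc in accessions:
        for T in temperatures:
            try:
                row = cell.loc[(acc, T)]
            except KeyError:
                row = None
            for p in params:
                col = f"{p}_{T:g}"
                val = np.nan if row is None else float(row[p])
                if not np.isfinite(val):
                    if p in fill_values:
                        val = float(fill_values[p])
                        imputed.append((acc, col, val))
                    else:
                        raise ValueError(
                            f"missing value for accession {acc!r}, "
                            f"variable {col!r} and no fill rule"
                        )
                wide.loc[acc, col] = val
    n_expect = 24 if scheme == "germination24" else 14
    if wide.shape[1] != n_expect:
        raise ValueError(
            f"{scheme} matrix has {wide.shape[1]} columns, expected "
            f"{n_expect} (got temperatures {temperatures})"
        )
    return TraitMatrix(wide, scheme, tuple(imputed))


@dataclass(frozen=True)
class PCAResult:
    """Correlation-matrix PCA of a trait matrix."""

    eigenvalues: np.ndarray  # non-increasing, sums to n columns
    pct_variance: np.ndarray  # %
    cum_pct_variance: np.ndarray  # %
    loadings: pd.DataFrame  # variables x components, scaled by sqrt(eig)
    eigenvectors: pd.DataFrame  # variables x components, unit norm
    scores: pd.DataFrame  # accessions x components
    contributions: pd.DataFrame  # variables x components, % (sums to 100)
    standardized: pd.DataFrame  # the z-scored input

    @property
    def n_components_for(self) -> np.ndarray:
        return self.cum_pct_variance

    def n_components_at(self, cum_pct: float = 90.0) -> int:
        """Smallest component count reaching ``cum_pct`` cumulative %."""
        return int(np.searchsorted(self.cum_pct_variance, cum_pct) + 1)

    def eigenvalue_table(self) -> pd.DataFrame:
        k = self.eigenvalues.size
        return pd.DataFrame({
            "component": np.arange(1, k + 1),
            "eigenvalue": self.eigenvalues,
            "pct_variance": self.pct_variance,
            "cum_pct_variance": self.cum_pct_variance,
        })


def run_pca(matrix: TraitMatrix | pd.DataFrame) -> PCAResult:
    """PCA on the correlation matrix of a trait matrix.

    Columns are standardized (ddof = 1); eigenvectors of the correlation
    matrix give the components.  A zero-variance column is an error naming
    the column.  Components are ordered by decreasing eigenvalue; tiny
    negative eigenvalues from roundoff are clipped to zero.
    """
    data = matrix.data if isinstance(matrix, TraitMatrix) else matrix
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("PCA needs at least 2 rows and 2 columns")
    if data.isna().any().any():
        raise ValueError("trait matrix contains missing values")
    X = data.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    dead = np.nonzero(sd == 0)[0]
    if dead.size:
        raise ValueError(
            f"zero-variance column(s): {list(data.columns[dead])}"
        )
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign convention: largest-|v| entry of each vector > 0
    for j in range(eigvec.shape[1]):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    p = X.shape[1]
    pct = 100.0 * eigval / p
    comp_names = [f"PC{i + 1}" for i in range(p)]
    loadings = pd.DataFrame(eigvec * np.sqrt(eigval), index=data.columns,
                            columns=comp_names)
    eigenvectors = pd.DataFrame(eigvec, index=data.columns,
                                columns=comp_names)
    scores = pd.DataFrame(Z @ eigvec, index=data.index, columns=comp_names)
    contributions = pd.DataFrame(100.0 * eigvec ** 2, index=data.columns,
                                 columns=comp_names)
    zdf = pd.DataFrame(Z, index=data.index, columns=data.columns)
    return PCAResult(eigenvalues=eigval, pct_variance=pct,
                     cum_pct_variance=np.cumsum(pct), loadings=loadings,
                     eigenvectors=eigenvectors, scores=scores,
                     contributions=contributions, standardized=zdf)


@dataclass(frozen=True)
class HCPCResult:
    """Ward tree on truncated PCA scores, cut into k clusters."""

    linkage_matrix: np.ndarray
    labels: pd.Series  # cluster id (1..k) per accession
    k: int
    n_components: int

    def partition(self) -> dict[int, tuple]:
        groups: dict[int, list] = {}
        for acc, lab in self.labels.items():
            groups.setdefault(int(lab), []).append(acc)
        return {lab: tuple(sorted(v)) for lab, v in groups.items()}


def run_hcpc(pca: PCAResult, k: int = 3,
             n_components: int | None = None) -> HCPCResult:
    """Hierarchical clustering on principal components.

    Ward linkage on Euclidean distances between accession scores in the
    leading ``n_components`` (default: smallest count reaching 90%
    cumulative variance).  The tree is cut into ``k`` clusters; labels are
    renumbered 1..k in order of first appearance for stability.
    """
    n_rows = pca.scores.shape[0]
    if k > n_rows:
        raise ValueError(f"k={k} exceeds the number of accessions {n_rows}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_components is None:
        n_components = pca.n_components_at(90.0)
    n_avail = int(np.count_nonzero(pca.eigenvalues > 1e-12))
    n_components = min(n_components, max(n_avail, 1))
    pts = pca.scores.to_numpy(dtype=float)[:, :n_components]
    Z = linkage(pts, method="ward")
    raw = cut_tree(Z, n_clusters=k).ravel()
    # renumber clusters by order of first appearance
    remap: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap) + 1
        labels[i] = remap[r]
    return HCPCResult(Z, pd.Series(labels, index=pca.scores.index,
                                   name="cluster"),
                      k, n_components)


def linkage_to_newick(Z: np.ndarray, leaf_names) -> str:
    """Render a SciPy linkage matrix as a Newick tree string."""
    tree = to_tree(Z)
    names = list(leaf_names)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = walk(node.get_left(), node.dist)
        right = walk(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({walk(tree.get_left(), tree.dist)}," \
           f"{walk(tree.get_right(), tree.dist)});"
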