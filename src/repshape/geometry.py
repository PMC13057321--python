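"""Repertoire overlap geometry and multivariate feature analysis.

Pairwise repertoire similarity uses the F2 overlap: clonotypes are
aggregated by ``(V gene, CDR3 amino-acid sequence)`` within the functional
sub-repertoire, and F2(A, B) is the sum over shared keys of the geometric
mean of the two frequencies.  Distances are ``-log10(F2)`` with a
configurable floor for non-overlapping pairs, embedded in 2D by classical
(Torgerson) multidimensional scaling.

Feature tables (convergence, diversity, insert size, CDR3 length, mean
Kidera factors, ...) are z-scored per column and summarized by PCA and
average-linkage hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _scipy_linkage

from .errors import (
    DegenerateGeometryError,
    EmptyPartitionError,
    InsufficientFeaturesError,
    ValidationError,
)
from .io import Repertoire


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape must match sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValidationError("distance matrix must have a zero diagonal")


def _aa_frequencies(rep: Repertoire) -> dict[tuple[str, str], float]:
    """Functional-subset frequencies aggregated by (V gene, CDR3aa)."""
    func = rep.functional().clonotypes
    if not func:
        raise EmptyPartitionError(f"no functional clonotypes in {rep.sample_id}")
    total = sum(c.umi_count for c in func)
    out: dict[tuple[str, str], float] = {}
    for c in func:
        key = (c.v_gene, c.cdr3_aa)
        out[key] = out.get(key, 0.0) + c.umi_count / total
    return out


def f2_overlap(a: Repertoire, b: Repertoire) -> float:
    """Sum over shared (V, CDR3aa) keys of sqrt(fA * fB); in [0, 1]."""
    fa, fb = _aa_frequencies(a), _aa_frequencies(b)
    if len(fb) < len(fa):
        fa, fb = fb, fa
    return float(sum(np.sqrt(p * fb[k]) for k, p in fa.items() if k in fb))


def f2_distance_matrix(reps: list[Repertoire], floor: float = 1e-12) -> DistanceMatrix:
    """d(i, j) = -log10(max(F2(i, j), floor)); zero diagonal by construction."""
    if len(reps) < 2:
        raise ValidationError("need at least 2 repertoires")
    n = len(reps)
    freqs = [_aa_frequencies(r) for r in reps]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            fa, fb = freqs[i], freqs[j]
            if len(fb) < len(fa):
                fa, fb = fb, fa
            f2 = sum(np.sqrt(p * fb[k]) for k, p in fa.items() if k in fb)
            d[i, j] = d[j, i] = -np.log10(max(f2, floor))
    return DistanceMatrix([r.sample_id for r in reps], d)


def classical_mds(dm: DistanceMatrix, k: int = 2) -> tuple[np.ndarray, np.ndarray, bool]:
    """Torgerson classical MDS.

    Double-centers the squared distances, eigendecomposes, and returns
    (n x k coordinates, the k retained eigenvalues, negative-eigenvalue
    flag).  Axis signs are fixed so the largest-|value| coordinate on each
    axis is positive.
    """
    n = len(dm.sample_ids)
    if n < k + 1:
        raise ValidationError(f"need at least {k + 1} samples for {k} dimensions")
    d2 = dm.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if eigvals[0] <= 0:
        raise DegenerateGeometryError("no positive eigenvalue: degenerate geometry")
    top = eigvals[:k]
    truncated = bool((top < 0).any())
    top = np.clip(top, 0.0, None)
    coords = eigvecs[:, :k] * np.sqrt(top)
    for axis in range(k):
        col = coords[:, axis]
        if np.any(col != 0) and col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    return coords, top, truncated


@dataclass
class MultivariateResult:
    zscored: pd.DataFrame
    coords: np.ndarray  # samples x k PCA coordinates
    explained_variance: np.ndarray
    explained_ratio: np.ndarray
    linkage: np.ndarray  # scipy linkage matrix
    merges: list[tuple[int, int]]  # nested merge list (node indices)
    dropped_columns: list[str]


def feature_multivariate(table: pd.DataFrame, k: int = 2,
                         linkage: str = "average") -> MultivariateResult:
    """Z-score features, run PCA (SVD) and hierarchical clustering.

    Zero-variance columns are dropped and reported; z-scores use the n-1
    denominator; PCA axis signs follow the same convention as MDS.
    """
    if len(table) < 3:
        raise ValidationError("need at least 3 samples")
    numeric = table.select_dtypes(include=[np.number])
    sd = numeric.std(ddof=1)
    dropped = list(numeric.columns[(sd == 0) | sd.isna()])
    kept = numeric.drop(columns=dropped)
    if kept.isna().any().any():
        raise ValidationError("feature table contains missing values")
    if kept.shape[1] < 2:
        raise InsufficientFeaturesError("fewer than 2 non-constant feature columns")
    z = (kept - kept.mean()) / kept.std(ddof=1)
    x = z.to_numpy()
    u, s, _vt = np.linalg.svd(x, full_matrices=False)
    k_eff = min(k, len(s))
    coords = u[:, :k_eff] * s[:k_eff]
    for axis in range(k_eff):
        col = coords[:, axis]
        if np.any(col != 0) and col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    var = s**2 / (len(table) - 1)
    zmat = _scipy_linkage(x, method=linkage, metric="euclidean")
    merges = [(int(a), int(b)) for a, b in zmat[:, :2]]
    return MultivariateResult(
        zscored=z,
        coords=coords,
        explained_variance=var[:k_eff],
        explained_ratio=var[:k_eff] / var.sum(),
        linkage=zmat,
        merges=merges,
        dropped_columns=dropped,
    )


def build_feature_table(reps: list[Repertoire], weighting: str = "clonotype",
                        top_n: int = 3000, diversity_depth: int | None = None,
                        kidera_window: int = 5, seed: int = 0,
                        insert_features: bool = True,
                        include_kidera: bool = True) -> pd.DataFrame:
    """One row per sample: summary features plus mean Kidera factors.

    The assembled table feeds :func:`feature_multivariate` and the group
    statistics module; rows are indexed by sample id and carry subset /
    age-group metadata columns.
    """
    from .features import repertoire_summary
    from .physchem import kidera_profile, load_kidera_table

    kidera = load_kidera_table() if include_kidera else None
    rows = []
    for rep in reps:
        summ = repertoire_summary(rep, weighting=weighting, top_n=top_n,
                                  diversity_depth=diversity_depth, seed=seed,
                                  insert_features=insert_features)
        row = {
            "sample_id": rep.sample_id,
            "subset": rep.subset,
            "age_group": rep.age_group,
            "pct_nonfunctional_clonotypes": summ.pct_nonfunctional_clonotypes,
            "pct_nonfunctional_umis": summ.pct_nonfunctional_umis,
            "mean_cdr3_nt_length": summ.mean_cdr3_nt_length,
            "mean_insert_size": summ.mean_insert_size,
            "zero_insert_freq": summ.zero_insert_freq,
            "convergence": summ.convergence,
            "observed_diversity": summ.observed_diversity,
            "normalized_shannon": summ.normalized_shannon,
        }
        if include_kidera:
            row.update(kidera_profile(rep, kidera, w=kidera_window).to_dict())
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
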