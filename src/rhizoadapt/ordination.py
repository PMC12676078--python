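"""Distance-based multivariate inference.

Implements the McArdle-Anderson machinery on Gower-centered distance
matrices: principal coordinates, PERMANOVA with sequential (Type-I)
sum-of-squares partitioning, Moran's eigenvector maps (dbMEM) from truncated
spatial or genetic distance matrices, conditioned distance-based redundancy
analysis (dbRDA), and forward model selection with permutation tests.

All tests use the P-value convention (1 + b) / (1 + m) where b counts
permutation statistics at least as extreme as the observed one. The
whole-model PERMANOVA permutes sample labels freely; forward-selection
marginal tests permute residuals under the current reduced model.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orth, qr
from scipy.sparse.csgraph import minimum_spanning_tree

from .datatypes import DistanceMatrix, GenotypePanel, SSRMatrix, ValidationError

__all__ = [
    "GowerMatrix",
    "gower_center",
    "PCoAResult",
    "pcoa",
    "permanova",
    "MEMBasis",
    "dbmem",
    "select_broad_mems",
    "DbrdaModel",
    "dbrda",
    "forward_select",
    "hamming_distance_matrix",
    "haversine_distance_matrix",
    "expand_to_samples",
]

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# Gower centering and principal coordinates
# ---------------------------------------------------------------------------

@dataclass
class GowerMatrix:
    ids: list
    G: np.ndarray


def gower_center(dm: DistanceMatrix) -> GowerMatrix:
    """G = -1/2 J D^2 J with J = I - 11'/n (double-centered squared distances)."""
    D2 = dm.values ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J
    G = (G + G.T) / 2.0
    return GowerMatrix(ids=list(dm.ids), G=G)


@dataclass
class PCoAResult:
    ids: list
    eigenvalues: np.ndarray       # all eigenvalues, descending (negatives last)
    coordinates: np.ndarray       # axes for positive eigenvalues, scaled sqrt(l)
    neg_coordinates: np.ndarray   # axes for negative eigenvalues, scaled sqrt(-l)


def pcoa(dm: DistanceMatrix, eig_tol: float = 1e-10) -> PCoAResult:
    """Eigendecomposition of the Gower matrix.

    Negative eigenvalues (semi-metric dissimilarities) are retained and
    reported; their axes are returned separately for Anderson-style corrected
    geometry (used by beta-dispersion).
    """
    gm = gower_center(dm)
    evals, evecs = np.linalg.eigh(gm.G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = max(abs(evals[0]), abs(evals[-1]), 1.0)
    pos = evals > eig_tol * scale
    neg = evals < -eig_tol * scale
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    neg_coords = evecs[:, neg] * np.sqrt(-evals[neg])
    return PCoAResult(
        ids=list(dm.ids),
        eigenvalues=evals,
        coordinates=coords,
        neg_coordinates=neg_coords,
    )


# ---------------------------------------------------------------------------
# Design-matrix helpers
# ---------------------------------------------------------------------------

def _expand_column(design: pd.DataFrame, name: str) -> np.ndarray:
    col = design[name]
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(float).reshape(-1, 1)
    dummies = pd.get_dummies(col.astype(str))
    return dummies.to_numpy(float)


def term_matrix(design: pd.DataFrame, term: str) -> np.ndarray:
    """Expand a term ('genotype', 'soil_nitrogen', 'a:b') into columns.

    Factors expand to full indicator sets (rank handled downstream by
    orthogonal projection); interactions are all pairwise column products.
    """
    parts = [p.strip() for p in term.split(":")]
    for p in parts:
        if p not in design.columns:
            raise KeyError(f"term component {p!r} not a design column")
    mat = _expand_column(design, parts[0])
    for p in parts[1:]:
        nxt = _expand_column(design, p)
        mat = np.einsum("ij,ik->ijk", mat, nxt).reshape(len(design), -1)
    return mat


def _orth_basis(X: np.ndarray, tol: float | None = None) -> np.ndarray:
    if X.size == 0:
        return np.empty((X.shape[0], 0))
    return orth(X, rcond=tol)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _random_permutations(n: int, n_perm: int, rng: np.random.Generator):
    for _ in range(n_perm):
        yield rng.permutation(n)


def permanova(
    dm: DistanceMatrix,
    design: pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int = 0,
    permutations: str | None = None,
) -> pd.DataFrame:
    """Sequential (Type-I) PERMANOVA of a distance matrix on ordered terms.

    SS(term) = trace(H_term G) with H_term the increment of the cumulative
    hat matrix; pseudo-F uses the residual mean square. P-values come from
    free permutation of sample labels; ``permutations='exact'`` enumerates
    all n! relabelings (small n only).

    ``design`` rows must align with ``dm.ids``.
    """
    if len(design) != len(dm.ids):
        raise ValidationError("design rows must match distance-matrix samples")
    n = len(dm.ids)
    G = gower_center(dm).G
    ss_total = float(np.trace(G))

    bases = [np.ones((n, 1)) / math.sqrt(n)]
    deltas, dfs = [], []
    cum = bases[0]
    for term in terms:
        X = np.hstack([cum, term_matrix(design, term)])
        new = _orth_basis(X)
        df = new.shape[1] - cum.shape[1]
        if df == 0:
            raise ValidationError(
                f"term {term!r} is aliased with earlier terms (adds no rank)"
            )
        deltas.append(new @ new.T - cum @ cum.T)
        dfs.append(df)
        cum = new
    H_full = cum @ cum.T - np.ones((n, n)) / n
    df_res = n - cum.shape[1]
    if df_res <= 0:
        raise ValidationError("saturated design: no residual degrees of freedom")

    def _stats(Gp: np.ndarray):
        ss = np.array([float(np.sum(d * Gp)) for d in deltas])
        ss_res = float(np.trace(Gp)) - float(np.sum(H_full * Gp))
        f = (ss / np.array(dfs)) / (ss_res / df_res)
        return ss, ss_res, f

    ss_terms, ss_res, f_obs = _stats(G)

    if permutations == "exact":
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8")
        count = np.zeros(len(terms))
        total = 0
        for perm in itertools.permutations(range(n)):
            idx = np.array(perm)
            _, _, f_star = _stats(G[np.ix_(idx, idx)])
            count += f_star >= f_obs - 1e-12
            total += 1
        pvals = count / total
    else:
        if n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        rng = np.random.default_rng(seed)
        count = np.zeros(len(terms))
        for idx in _random_permutations(n, n_perm, rng):
            _, _, f_star = _stats(G[np.ix_(idx, idx)])
            count += f_star >= f_obs - 1e-12
        pvals = (1.0 + count) / (1.0 + n_perm)

    rows = []
    for term, df, ss, f, p in zip(terms, dfs, ss_terms, f_obs, pvals):
        rows.append(
            dict(term=term, df=df, SS=ss, R2=ss / ss_total, F=f, p=p)
        )
    rows.append(
        dict(term="Residual", df=df_res, SS=ss_res, R2=ss_res / ss_total,
             F=np.nan, p=np.nan)
    )
    rows.append(
        dict(term="Total", df=n - 1, SS=ss_total, R2=1.0, F=np.nan, p=np.nan)
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Moran's eigenvector maps
# ---------------------------------------------------------------------------

@dataclass
class MEMBasis:
    source: str
    ids: list
    eigenvectors: np.ndarray  # n x k, orthonormal
    eigenvalues: np.ndarray   # positive, descending
    threshold: float


def dbmem(
    dm_source: DistanceMatrix,
    truncation: str | float = "mst-longest-edge",
    source: str = "geographic",
) -> MEMBasis:
    """Moran's eigenvector map of a truncated distance matrix.

    Distances above the truncation threshold (default: the longest edge of
    the minimum spanning tree, which keeps the graph connected) are replaced
    by 4x the threshold; the truncated matrix is double-centered and
    eigen-decomposed; only positive-eigenvalue eigenvectors are retained.
    """
    n = len(dm_source.ids)
    if n < 4:
        raise ValidationError("dbMEM needs at least 4 points")
    D = dm_source.values
    if np.allclose(D, 0):
        raise ValidationError("all points coincident; dbMEM undefined")
    if truncation == "mst-longest-edge":
        mst = minimum_spanning_tree(D).toarray()
        thr = float(mst.max())
    else:
        thr = float(truncation)
        if thr <= 0:
            raise ValueError("truncation threshold must be positive")
    Dt = np.where(D <= thr, D, 4.0 * thr)
    np.fill_diagonal(Dt, 0.0)
    gm = gower_center(DistanceMatrix(dm_source.ids, Dt, "truncated"))
    evals, evecs = np.linalg.eigh(gm.G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > 1e-8 * max(abs(evals[0]), 1.0)
    return MEMBasis(
        source=source,
        ids=list(dm_source.ids),
        eigenvectors=evecs[:, keep],
        eigenvalues=evals[keep],
        threshold=thr,
    )


def select_broad_mems(basis: MEMBasis) -> MEMBasis:
    """Broad-scale subset: eigenvectors whose eigenvalue exceeds the mean of
    the positive eigenvalues.

    Conditioning on every positive-eigenvalue eigenvector from two sources
    can span the whole between-unit space (annihilating any unit-level
    predictor); the large-eigenvalue eigenvectors carry the broad-scale
    autocorrelation the conditioning is meant to remove.
    """
    thr = basis.eigenvalues.mean()
    keep = basis.eigenvalues > thr
    return MEMBasis(
        source=basis.source,
        ids=list(basis.ids),
        eigenvectors=basis.eigenvectors[:, keep],
        eigenvalues=basis.eigenvalues[keep],
        threshold=basis.threshold,
    )


# ---------------------------------------------------------------------------
# dbRDA and forward selection
# ---------------------------------------------------------------------------

@dataclass
class DbrdaModel:
    ids: list
    total_inertia: float
    conditioned_inertia: float
    constrained_inertia: float
    unconstrained_inertia: float
    eigenvalues: np.ndarray
    predictors: list
    marginal: pd.DataFrame | None = None
    selected: list = field(default_factory=list)
    selection_table: pd.DataFrame | None = None

    @property
    def constrained_proportion(self) -> float:
        return self.constrained_inertia / self.total_inertia

    def to_dict(self) -> dict:
        out = dict(
            total_inertia=self.total_inertia,
            conditioned_inertia=self.conditioned_inertia,
            constrained_inertia=self.constrained_inertia,
            unconstrained_inertia=self.unconstrained_inertia,
            constrained_proportion=self.constrained_proportion,
            eigenvalues=list(map(float, self.eigenvalues)),
            predictors=list(self.predictors),
            selected=list(self.selected),
        )
        if self.selection_table is not None:
            out["selection_table"] = self.selection_table.to_dict("records")
        if self.marginal is not None:
            out["marginal"] = self.marginal.to_dict("records")
        return out


def _standardize(X: pd.DataFrame) -> pd.DataFrame:
    sd = X.std(ddof=0)
    const = sd[sd == 0].index.tolist()
    if const:
        raise ValidationError(f"constant predictor column(s): {const}")
    return (X - X.mean()) / sd


def _condition_block(n: int, condition) -> np.ndarray:
    cols = [np.ones((n, 1))]
    if condition is not None:
        if isinstance(condition, MEMBasis):
            condition = [condition]
        if isinstance(condition, (list, tuple)):
            for c in condition:
                arr = c.eigenvectors if isinstance(c, MEMBasis) else np.asarray(c, float)
                if arr.ndim == 1:
                    arr = arr[:, None]
                cols.append(arr)
        else:
            arr = np.asarray(condition, float)
            if arr.ndim == 1:
                arr = arr[:, None]
            cols.append(arr)
    Z = np.hstack(cols)
    if Z.shape[0] != n:
        raise ValidationError("condition rows must match samples")
    return Z


def _drop_collinear(Xr: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Pivoted QR to discard columns collinear with the condition/other columns."""
    if Xr.shape[1] == 0:
        return Xr, names
    _, R, piv = qr(Xr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xr.shape) * np.finfo(float).eps if diag.size else 0.0
    keep = sorted(piv[i] for i in range(len(diag)) if diag[i] > tol)
    dropped = [names[i] for i in range(len(names)) if i not in keep]
    if dropped:
        warnings.warn(
            f"predictor(s) collinear with condition/others dropped: {dropped}",
            stacklevel=3,
        )
    return Xr[:, keep], [names[i] for i in keep]


def dbrda(
    dm: DistanceMatrix,
    predictors: pd.DataFrame,
    condition=None,
    standardize: bool = True,
    marginal_tests: bool = True,
) -> DbrdaModel:
    """Conditioned distance-based redundancy analysis.

    The Gower matrix and the predictors are residualized on the condition
    block (plus intercept); constrained inertia is the trace of the
    residualized Gower matrix projected onto the residualized predictor
    space. Inertia decomposes exactly as conditioned + constrained +
    unconstrained = total.
    """
    n = len(dm.ids)
    if len(predictors) != n:
        raise ValidationError("predictor rows must match samples")
    X = _standardize(predictors) if standardize else predictors.copy()
    names = list(X.columns)
    G = gower_center(dm).G
    total = float(np.trace(G))

    Z = _condition_block(n, condition)
    Uz = _orth_basis(Z)
    R = np.eye(n) - Uz @ Uz.T       # residual-maker of the condition block
    Gr = R @ G @ R
    conditioned = total - float(np.trace(Gr))

    Xr = R @ X.to_numpy(float)
    Xr, names = _drop_collinear(Xr, names)
    Ux = _orth_basis(Xr)
    Hx = Ux @ Ux.T
    constrained = float(np.sum(Hx * Gr))
    unconstrained = total - conditioned - constrained

    C = Hx @ Gr @ Hx
    evals = np.linalg.eigvalsh((C + C.T) / 2.0)[::-1]
    evals = evals[evals > 1e-10 * max(abs(evals[0]), 1.0)] if evals.size else evals

    marginal = None
    if marginal_tests and names:
        df_res = n - Uz.shape[1] - Xr.shape[1]
        rows = []
        for j, name in enumerate(names):
            others = np.delete(Xr, j, axis=1)
            Uo = _orth_basis(np.hstack([Uz, others])) if others.size else Uz
            # marginal SS: extra inertia of column j beyond condition + others
            Ho = Uo @ Uo.T
            xj = Xr[:, [j]] - Ho @ Xr[:, [j]]
            nrm = np.linalg.norm(xj)
            if nrm < 1e-12:
                rows.append(dict(term=name, df=1, SS=0.0, F=np.nan))
                continue
            u = (xj / nrm).ravel()
            ss_j = float(u @ G @ u)
            ss_res = unconstrained
            f = ss_j / (ss_res / max(df_res, 1))
            rows.append(dict(term=name, df=1, SS=ss_j, F=f))
        marginal = pd.DataFrame(rows)

    return DbrdaModel(
        ids=list(dm.ids),
        total_inertia=total,
        conditioned_inertia=conditioned,
        constrained_inertia=constrained,
        unconstrained_inertia=unconstrained,
        eigenvalues=evals,
        predictors=names,
        marginal=marginal,
    )


def _group_permutations(groups, n: int, n_perm: int, rng) -> np.ndarray:
    """Sample-index permutations that shuffle whole groups as units.

    Replicated designs (several samples per genotype) are not exchangeable at
    the sample level when testing genotype-level covariates; permuting
    balanced groups keeps the within-group correlation intact. Unbalanced
    groups fall back to free sample permutation with a warning.
    """
    labels = pd.Series(groups).astype(str).to_numpy()
    if len(labels) != n:
        raise ValidationError("groups must align with samples")
    uniq, inv = np.unique(labels, return_inverse=True)
    idx_by_group = [np.where(inv == k)[0] for k in range(len(uniq))]
    sizes = {len(ix) for ix in idx_by_group}
    if len(sizes) != 1:
        warnings.warn(
            "unbalanced groups: falling back to free sample permutation",
            stacklevel=3,
        )
        return np.array([rng.permutation(n) for _ in range(n_perm)])
    perms = np.empty((n_perm, n), dtype=int)
    for b in range(n_perm):
        gp = rng.permutation(len(uniq))
        order = np.empty(n, dtype=int)
        for k, tgt in enumerate(gp):
            order[idx_by_group[k]] = idx_by_group[tgt]
        perms[b] = order
    return perms


def forward_select(
    dm: DistanceMatrix,
    candidates: pd.DataFrame,
    condition=None,
    alpha: float = 0.05,
    n_perm: int = 199,
    seed: int = 0,
    standardize: bool = True,
    groups=None,
) -> DbrdaModel:
    """Forward model selection for conditioned dbRDA.

    At each step the candidate with the smallest permutation P for its
    marginal addition is entered (ties broken by larger pseudo-F); residuals
    are permuted under the current reduced model (condition + already
    selected terms). Selection stops when the best P exceeds ``alpha`` or no
    candidates remain. The returned model carries a sequential variance
    partition over the selected terms.

    ``groups`` (e.g. genotype labels) makes the residual permutation shuffle
    whole groups as exchangeable units — required when candidates are
    group-level covariates measured on replicated samples.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    n = len(dm.ids)
    X = _standardize(candidates) if standardize else candidates.copy()
    G = gower_center(dm).G
    rng = np.random.default_rng(seed)

    Z0 = _condition_block(n, condition)
    remaining = list(X.columns)
    selected: list[str] = []
    steps = []

    while remaining:
        Z = np.hstack([Z0] + [X[[s]].to_numpy(float) for s in selected]) if selected else Z0
        Uz = _orth_basis(Z)
        Rm = np.eye(n) - Uz @ Uz.T
        Gr = Rm @ G @ Rm
        tr_gr = float(np.trace(Gr))
        df_res = n - Uz.shape[1] - 1
        if df_res < 1:
            break

        if groups is not None:
            perms = _group_permutations(groups, n, n_perm, rng)
        else:
            perms = np.array([rng.permutation(n) for _ in range(n_perm)])

        best = None
        for name in remaining:
            x = X[name].to_numpy(float)
            xr = Rm @ x
            nrm = np.linalg.norm(xr)
            if nrm < 1e-10:
                continue
            u = xr / nrm
            ss = float(u @ Gr @ u)
            f = ss / ((tr_gr - ss) / df_res)
            # permute the candidate over exchangeable units, re-residualize
            # on the reduced model, refit (the residual matrix stays fixed)
            Xp = x[perms].T                      # (n, n_perm)
            Xpr = Rm @ Xp
            norms = np.linalg.norm(Xpr, axis=0)
            ok = norms > 1e-10
            U = Xpr[:, ok] / norms[ok]
            ss_star = np.einsum("ip,ij,jp->p", U, Gr, U)
            f_star = ss_star / ((tr_gr - ss_star) / df_res)
            p = (1.0 + np.sum(f_star >= f - 1e-12)) / (1.0 + n_perm)
            if best is None or (p, -f) < (best[1], -best[2]):
                best = (name, p, f)
        if best is None:
            break
        name, p, f = best
        if p > alpha:
            break
        selected.append(name)
        remaining.remove(name)
        steps.append(dict(term=name, F=f, p=p))

    if selected:
        model = dbrda(
            dm,
            X[selected],
            condition=condition,
            standardize=False,
            marginal_tests=False,
        )
    else:
        Uz0 = _orth_basis(Z0)
        Rm0 = np.eye(n) - Uz0 @ Uz0.T
        total = float(np.trace(G))
        conditioned = total - float(np.trace(Rm0 @ G @ Rm0))
        model = DbrdaModel(
            ids=list(dm.ids),
            total_inertia=total,
            conditioned_inertia=conditioned,
            constrained_inertia=0.0,
            unconstrained_inertia=total - conditioned,
            eigenvalues=np.array([]),
            predictors=[],
        )

    # sequential (adonis2-style) partition of the selected terms
    rows = []
    if selected:
        Uz0 = _orth_basis(Z0)
        cum = Uz0
        total = model.total_inertia
        for step in steps:
            Xc = np.hstack([cum, X[[step["term"]]].to_numpy(float)])
            new = _orth_basis(Xc)
            delta = new @ new.T - cum @ cum.T
            ss = float(np.sum(delta * G))
            rows.append(dict(term=step["term"], SS=ss, R2=ss / total,
                             F=step["F"], p=step["p"]))
            cum = new
    model.selected = selected
    model.selection_table = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["term", "SS", "R2", "F", "p"]
    )
    return model


# ---------------------------------------------------------------------------
# Source distance matrices for conditioning
# ---------------------------------------------------------------------------

def hamming_distance_matrix(ssr: SSRMatrix) -> DistanceMatrix:
    """Pairwise proportion of mismatching alleles over non-missing loci."""
    arr = ssr.data.to_numpy(dtype=float, na_value=np.nan)
    n = arr.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(arr[i]) & ~np.isnan(arr[j])
            if not ok.any():
                raise ValidationError(
                    f"no shared non-missing loci between "
                    f"{ssr.genotypes[i]} and {ssr.genotypes[j]}"
                )
            d[i, j] = d[j, i] = np.mean(arr[i, ok] != arr[j, ok])
    return DistanceMatrix(ssr.genotypes, d, "hamming")


def haversine_distance_matrix(panel: GenotypePanel) -> DistanceMatrix:
    """Great-circle distances (km) between genotype source locations."""
    coords = panel.coordinates().to_numpy()
    lon, lat = np.radians(coords[:, 0]), np.radians(coords[:, 1])
    dlon = lon[:, None] - lon[None, :]
    dlat = lat[:, None] - lat[None, :]
    a = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat[:, None]) * np.cos(lat[None, :]) * np.sin(dlon / 2) ** 2
    )
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(panel.genotypes, d, "haversine_km")


def expand_to_samples(
    genotype_values: pd.DataFrame | pd.Series, sample_genotypes: pd.Series
) -> pd.DataFrame:
    """Broadcast genotype-level columns to sample level by genotype membership."""
    if isinstance(genotype_values, pd.Series):
        genotype_values = genotype_values.to_frame()
    missing = set(sample_genotypes.astype(str)) - set(genotype_values.index.astype(str))
    if missing:
        raise ValidationError(f"genotypes without panel values: {sorted(missing)[:5]}")
    out = genotype_values.loc[sample_genotypes.astype(str)]
    out.index = sample_genotypes.index
    return out
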