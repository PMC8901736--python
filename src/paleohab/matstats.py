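"""Distance matrices and permutation-based matrix statistics.

The common currency linking assemblage composition to environment is the
labelled pairwise distance matrix: Jaccard/Hamming dissimilarity of binary
tool-type or raw-material flags, absolute differences of numeric site
attributes (mid-age, buffer-mean temperature and precipitation, altitude,
roughness), 0/1 mismatch of binary attributes (site type, excavation
method), and geographic separation (great-circle, or a user-supplied
cost-path matrix).

Inference is permutational throughout: the simple Mantel test correlates
the lower triangles of two matrices and builds its null by jointly
permuting the rows and columns of one of them; multiple matrix regression
with randomization (MMRR) regresses one unfolded distance matrix on several
others and assesses coefficients and the model F the same way. Permutation
p-values use the "+1" estimator p = (1 + #{null >= observed}) / (1 + n_perm)
so they are never zero; for small n an exhaustive enumeration over all n!
label permutations is available. The Benjamini-Hochberg step-up adjustment
controls the false discovery rate across a family of tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateScalingError,
    InvalidConfigError,
    InvalidMatrixError,
)

EARTH_RADIUS_KM = 6371.0088


@dataclass
class DistanceMatrix:
    """Labelled symmetric nonnegative matrix with a zero diagonal."""

    labels: list[str]
    values: np.ndarray
    kind: str = "numeric"

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise InvalidMatrixError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise InvalidMatrixError("labels must be unique")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise InvalidMatrixError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise InvalidMatrixError("diagonal must be zero")
        if np.any(self.values < -1e-10):
            raise InvalidMatrixError("entries must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def triangle(self) -> np.ndarray:
        """Lower-triangle entries, row-major, as a flat vector."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def align(self, labels: list[str]) -> "DistanceMatrix":
        """Reorder to a canonical label order (error on mismatch)."""
        if set(labels) != set(self.labels):
            raise InvalidMatrixError("label sets differ; matrices not comparable")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, kind: str = "numeric") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(float), kind)


def composition_distance(
    flags: pd.DataFrame, metric: str = "jaccard"
) -> DistanceMatrix:
    """Pairwise dissimilarity of presence/absence profiles.

    Jaccard distance between two all-zero rows is defined as 0 (two empty
    assemblages are identical, not maximally distinct).
    """
    if metric not in ("jaccard", "hamming"):
        raise InvalidConfigError(f"unknown composition metric {metric!r}")
    X = flags.to_numpy()
    if X.shape[0] < 2:
        raise InvalidConfigError("need >= 2 occupations")
    if not np.isin(X, (0, 1)).all():
        raise InvalidConfigError("composition flags must be binary 0/1")
    X = X.astype(bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d = pdist(X, metric=metric)
    d = np.nan_to_num(d, nan=0.0)  # empty-vs-empty jaccard -> 0
    return DistanceMatrix(
        [str(x) for x in flags.index], squareform(d), kind="binary-composition"
    )


def numeric_distance(values: pd.Series) -> DistanceMatrix:
    """Absolute pairwise differences of a numeric per-occupation attribute."""
    v = values.to_numpy(float)
    if not np.all(np.isfinite(v)):
        raise InvalidConfigError("numeric attribute contains non-finite values")
    return DistanceMatrix(
        [str(x) for x in values.index], np.abs(v[:, None] - v[None, :]), kind="numeric"
    )


def binary_attribute_distance(values: pd.Series) -> DistanceMatrix:
    """0/1 mismatch matrix for a binary attribute (site type, method)."""
    v = values.to_numpy()
    if not np.isin(v, (0, 1)).all():
        raise InvalidConfigError("attribute must be binary 0/1")
    v = v.astype(float)
    return DistanceMatrix(
        [str(x) for x in values.index],
        np.abs(v[:, None] - v[None, :]),
        kind="binary-attribute",
    )


def geographic_distance(
    coords: pd.DataFrame | None = None,
    mode: str = "greatcircle",
    supplied: DistanceMatrix | None = None,
    labels: list[str] | None = None,
) -> DistanceMatrix:
    """Great-circle km between sites, or a supplied cost-path matrix.

    ``supplied`` mode passes a precomputed matrix through after validating
    its symmetry, zero diagonal and (if given) label agreement.
    """
    if mode == "supplied":
        if supplied is None:
            raise InvalidConfigError("supplied mode needs a matrix")
        if labels is not None:
            supplied = supplied.align(list(labels))
        return DistanceMatrix(supplied.labels, supplied.values, kind="geographic")
    if mode != "greatcircle":
        raise InvalidConfigError(f"unknown geographic mode {mode!r}")
    if coords is None:
        raise InvalidConfigError("greatcircle mode needs coordinates")
    lon = np.radians(coords["lon"].to_numpy(float))
    lat = np.radians(coords["lat"].to_numpy(float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    )
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix([str(x) for x in coords.index], d, kind="geographic")


# ---------------------------------------------------------------------------
# Mantel test


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    tail: str
    p_adj: float | None = None
    seed: int | None = None


def _check_pair(D1: DistanceMatrix, D2: DistanceMatrix) -> None:
    if D1.labels != D2.labels:
        raise InvalidMatrixError("matrices must share an identical label order")
    if D1.n < 3:
        raise InvalidConfigError("Mantel test needs n >= 3")


def _triangle_corr(t1: np.ndarray, t2: np.ndarray) -> float:
    s1, s2 = t1.std(), t2.std()
    if s1 == 0 or s2 == 0:
        raise DegenerateScalingError("zero variance in a distance triangle")
    return float(np.corrcoef(t1, t2)[0, 1])


def mantel(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    n_perm: int = 999,
    tail: str = "upper",
    seed: int | None = 0,
    exact: bool = False,
) -> MantelResult:
    """Simple Mantel test: Pearson r of lower triangles, permutation null.

    The null permutes rows and columns of ``D2`` jointly. ``exact=True``
    enumerates all n! label permutations (identity included) and reports
    p = #{r_perm >= r_obs}/n!; otherwise p uses the "+1" estimator over
    ``n_perm`` random permutations. ``tail`` is ``upper`` (one-sided,
    positive association) or ``two`` (on \\|r\\|).
    """
    _check_pair(D1, D2)
    if tail not in ("upper", "two"):
        raise InvalidConfigError(f"unknown tail {tail!r}")
    n = D1.n
    t1 = D1.triangle()
    V2 = D2.values
    i, j = np.tril_indices(n, k=-1)
    r_obs = _triangle_corr(t1, V2[i, j])

    def stat(perm: np.ndarray) -> float:
        t2 = V2[np.ix_(perm, perm)][i, j]
        r = np.corrcoef(t1, t2)[0, 1]
        return abs(r) if tail == "two" else r

    observed = abs(r_obs) if tail == "two" else r_obs
    if exact:
        if n > 8:
            raise InvalidConfigError("exact enumeration limited to n <= 8")
        stats = np.array([stat(np.array(p)) for p in itertools.permutations(range(n))])
        p_val = float(np.mean(stats >= observed - 1e-12))
        n_used = stats.size
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if stat(perm) >= observed - 1e-12:
                count += 1
        p_val = (1 + count) / (1 + n_perm)
        n_used = n_perm
    return MantelResult(r=r_obs, p=p_val, n_perm=n_used, tail=tail, seed=seed)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise InvalidConfigError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Multiple matrix regression with randomization (MMRR)


@dataclass
class MMRRResult:
    coefficients: dict[str, float]
    coef_p: dict[str, float]
    coef_t: dict[str, float]
    F: float
    r_squared: float
    p_model: float
    n_perm: int
    seed: int | None
    standardized: bool
    collinear: bool = False


def mmrr(
    Dy: DistanceMatrix,
    predictors: dict[str, DistanceMatrix],
    n_perm: int = 999,
    seed: int | None = 0,
    standardize: bool = False,
    condition_threshold: float = 1e8,
) -> MMRRResult:
    """Multiple matrix regression with randomization.

    OLS of the unfolded lower triangle of ``Dy`` on the unfolded predictor
    triangles (plus intercept). Significance of each coefficient (via its
    t statistic) and of the model F comes from jointly permuting the rows
    and columns of ``Dy`` and refitting; p-values use the "+1" estimator.
    With ``standardize=True`` predictor triangles are z-scored first.
    """
    if not predictors:
        raise InvalidConfigError("MMRR needs at least one predictor")
    names = list(predictors)
    n = Dy.n
    if n < len(names) + 2:
        raise InvalidConfigError("need n >= number of predictors + 2")
    for name, Dx in predictors.items():
        _check_pair(Dy, Dx)

    i, j = np.tril_indices(n, k=-1)
    m = i.size
    cols = []
    for name in names:
        t = predictors[name].values[i, j].astype(float)
        if standardize:
            s = t.std(ddof=1)
            if s == 0:
                raise DegenerateScalingError(f"predictor {name!r} has zero variance")
            t = (t - t.mean()) / s
        cols.append(t)
    X = np.column_stack([np.ones(m)] + cols)
    k = len(names)

    collinear = False
    cond = np.linalg.cond(X)
    if cond > condition_threshold:
        collinear = True
        warnings.warn(
            f"predictor set nearly collinear (condition number {cond:.3g}); "
            "using pseudo-inverse fit",
            RuntimeWarning,
            stacklevel=2,
        )
    XtX_inv = np.linalg.pinv(X.T @ X)
    H = XtX_inv @ X.T  # hat projector; reused across permutations
    Vy = Dy.values

    def fit(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
        beta = H @ y
        resid = y - X @ beta
        df_resid = m - (k + 1)
        sse = float(resid @ resid)
        sst = float(((y - y.mean()) ** 2).sum())
        mse = sse / df_resid
        se = np.sqrt(np.maximum(np.diag(XtX_inv) * mse, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        r2 = 1.0 - sse / sst if sst > 0 else np.nan
        F = (r2 / k) / ((1.0 - r2) / df_resid) if 0 <= r2 < 1 else np.inf
        return beta, tstat, F, r2

    y_obs = Vy[i, j].astype(float)
    if y_obs.std() == 0:
        raise DegenerateScalingError("response triangle has zero variance")
    beta, tstat, F_obs, r2 = fit(y_obs)

    rng = np.random.default_rng(seed)
    count_t = np.zeros(k + 1)
    count_F = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_p = Vy[np.ix_(perm, perm)][i, j].astype(float)
        _, t_p, F_p, _ = fit(y_p)
        count_t += np.abs(t_p) >= np.abs(tstat) - 1e-12
        if F_p >= F_obs - 1e-12:
            count_F += 1
    p_t = (1 + count_t) / (1 + n_perm)
    p_model = (1 + count_F) / (1 + n_perm)

    return MMRRResult(
        coefficients={name: float(b) for name, b in zip(names, beta[1:])},
        coef_p={name: float(p) for name, p in zip(names, p_t[1:])},
        coef_t={name: float(t) for name, t in zip(names, tstat[1:])},
        F=float(F_obs),
        r_squared=float(r2),
        p_model=float(p_model),
        n_perm=n_perm,
        seed=seed,
        standardized=standardize,
        collinear=collinear,
    )


def mantel_table(
    Dy: DistanceMatrix,
    others: dict[str, DistanceMatrix],
    n_perm: int = 999,
    tail: str = "upper",
    seed: int | None = 0,
) -> pd.DataFrame:
    """Run a family of simple Mantel tests against one response matrix and
    BH-adjust the p-values within that family."""
    rows = []
    for idx, (name, Dx) in enumerate(others.items()):
        res = mantel(Dy, Dx, n_perm=n_perm, tail=tail, seed=None if seed is None else seed + idx)
        rows.append({"variable": name, "r": res.r, "p": res.p, "n_perm": res.n_perm})
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    return df
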