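"""Monotone-constrained GLM fits and BIC sequence comparison.

For one outcome vector y (an ROI volume or a voxel's GM values) and a
candidate progression sequence over 4 ATN groups, the model is

    y = X beta + C gamma + e

where X is difference-coded over sequence positions — beta_1 is the mean of
the first group and beta_g (g = 2, 3, 4) the difference between successive
group means — C holds mean-centered covariates (unconstrained), and the fit
minimizes the residual sum of squares subject to beta_g <= 0 for g = 2..4,
i.e. a monotone non-increasing volume profile along the hypothesized order.

Because the constraint region is a coordinate cone in the difference coding,
the exact solution is found by enumerating the 2^3 active-constraint
patterns (clamping each subset of the three differences to zero, solving
OLS, and keeping the feasible fit with minimal SSE).  Model evidence uses
the Gaussian BIC, n ln(SSE/n) + k ln n, with k counting all four
mean-structure coefficients, the covariates, and the residual variance; at
fixed k and n the BIC ranking over sequences therefore reduces to the SSE
ranking.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, InsufficientGroupError, ValidationError
from .sequences import GroupSequence, SequenceSet

__all__ = [
    "DesignSpec",
    "ConstrainedFit",
    "OLSFit",
    "ModelComparison",
    "TrendResult",
    "build_design",
    "fit_monotone",
    "fit_monotone_many",
    "fit_unconstrained",
    "bic",
    "compare_sequences",
    "trend_test",
    "trend_test_many",
]

_TIE_TOL = 1e-9
_CONSTRAINT_TOL = 1e-10

#: the 8 candidate active sets over the three difference coefficients
_PATTERNS: tuple[tuple[int, ...], ...] = tuple(
    subset
    for r in range(4)
    for subset in itertools.combinations((1, 2, 3), r)
)


@dataclass
class DesignSpec:
    """Design for one sequence on one cohort subset.

    ``mean_block`` is the n × 4 difference-coded group design (column g is
    the indicator of position >= g+1, column 0 all-ones); ``cov_block`` is
    the n × p matrix of mean-centered covariates.
    """

    sequence: GroupSequence
    positions: np.ndarray            # 1..4 per included subject
    mean_block: np.ndarray
    cov_block: np.ndarray
    covariate_names: list[str]
    included: np.ndarray             # indices into the original subject axis
    n_excluded: int
    counts: np.ndarray               # subjects per position (length 4)

    @property
    def n(self) -> int:
        return self.mean_block.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.cov_block.shape[1]

    @property
    def k(self) -> int:
        """BIC parameter count: 4 mean coefficients + covariates + sigma^2."""
        return 4 + self.n_covariates + 1

    @property
    def X(self) -> np.ndarray:
        return np.column_stack([self.mean_block, self.cov_block])


def build_design(
    groups,
    sequence: GroupSequence,
    covariates: pd.DataFrame | np.ndarray | None = None,
    min_per_group: int = 3,
) -> DesignSpec:
    """Build the difference-coded design for one sequence.

    Subjects whose group is not one of the sequence's 4 states are excluded
    (and counted); covariates are mean-centered over the included subjects.
    """
    labels = pd.Series(groups).astype("object").to_numpy()
    pos = np.array(
        [sequence.position_of(g) if isinstance(g, str) else None for g in labels],
        dtype=object,
    )
    keep = np.array([p is not None for p in pos])
    positions = pos[keep].astype(int)
    counts = np.bincount(positions, minlength=5)[1:5]
    for p, state in enumerate(sequence.states, start=1):
        if counts[p - 1] < min_per_group:
            raise InsufficientGroupError(
                f"{sequence.name}: state {state} has {counts[p - 1]} subjects "
                f"(< {min_per_group})"
            )
    n = int(keep.sum())
    mean_block = np.ones((n, 4))
    for g in (2, 3, 4):
        mean_block[:, g - 1] = (positions >= g).astype(float)

    if covariates is None:
        cov = np.empty((n, 0))
        names: list[str] = []
    else:
        if isinstance(covariates, pd.DataFrame):
            names = list(covariates.columns)
            cov = covariates.to_numpy(dtype=float)[keep]
        else:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
            cov = cov[keep]
            names = [f"cov{j}" for j in range(cov.shape[1])]
        if not np.all(np.isfinite(cov)):
            raise ValidationError("covariates contain non-finite values")
        cov = cov - cov.mean(axis=0, keepdims=True)
        full = np.column_stack([mean_block, cov])
        if np.linalg.matrix_rank(full) < full.shape[1]:
            raise FitError("design matrix is rank deficient (collinear covariates)")
    return DesignSpec(
        sequence=sequence,
        positions=positions,
        mean_block=mean_block,
        cov_block=cov,
        covariate_names=names,
        included=np.flatnonzero(keep),
        n_excluded=int((~keep).sum()),
        counts=counts,
    )


@dataclass
class ConstrainedFit:
    """Result of a monotone-constrained fit for one outcome vector."""

    sequence_name: str
    beta1: float
    beta_diffs: np.ndarray           # the three successive differences, <= 0
    covariate_coefs: np.ndarray
    fitted_position_means: np.ndarray
    sse: float
    n: int
    k: int
    active_constraints: np.ndarray   # True where a difference was clamped to 0

    @property
    def bic(self) -> float:
        return bic(self.sse, self.n, self.k)


@dataclass
class OLSFit:
    coefs: np.ndarray
    se: np.ndarray
    sse: float
    n: int
    df_resid: int


def _pattern_solvers(design: DesignSpec):
    """Pseudo-inverses of the reduced design for each active-set pattern."""
    X = design.X
    solvers = []
    for pattern in _PATTERNS:
        # pattern entries index the difference coefficients 1..3 -> columns 1..3
        free_cols = [0] + [c for c in (1, 2, 3) if c not in pattern] + list(
            range(4, X.shape[1])
        )
        Xr = X[:, free_cols]
        solvers.append((pattern, free_cols, np.linalg.pinv(Xr), Xr))
    return solvers


def fit_monotone_many(
    Y: np.ndarray, design: DesignSpec, tol: float = _CONSTRAINT_TOL
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized monotone fit for many outcome columns at once.

    ``Y`` is n × V (V outcome vectors sharing one design).  Returns the
    per-column constrained SSE and the full coefficient matrix
    (V × (4 + p), clamped differences exactly zero).  Exact via enumeration
    of all 8 active-constraint patterns.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != design.n:
        raise ValidationError(f"outcome length {Y.shape[0]} != design n {design.n}")
    if not np.all(np.isfinite(Y)):
        raise ValidationError("outcome contains non-finite values")
    V = Y.shape[1]
    ncoef = 4 + design.n_covariates
    best_sse = np.full(V, np.inf)
    best_beta = np.zeros((V, ncoef))
    for pattern, free_cols, pinv, Xr in _pattern_solvers(design):
        B = pinv @ Y                       # (k_r, V)
        resid = Y - Xr @ B
        sse = (resid**2).sum(axis=0)
        beta = np.zeros((V, ncoef))
        beta[:, free_cols] = B.T
        feasible = np.all(beta[:, 1:4] <= tol, axis=1)
        better = feasible & (sse < best_sse)
        best_sse[better] = sse[better]
        best_beta[better] = beta[better]
    if np.any(~np.isfinite(best_sse)):
        raise FitError("no feasible active-set pattern (should not happen)")
    return best_sse, best_beta


def fit_monotone(y: np.ndarray, design: DesignSpec) -> ConstrainedFit:
    """Monotone-constrained least squares for one outcome vector."""
    sse, beta = fit_monotone_many(np.asarray(y, dtype=float), design)
    b = beta[0]
    diffs = np.minimum(b[1:4], 0.0)      # clamp numerical dust
    means = b[0] + np.concatenate([[0.0], np.cumsum(diffs)])
    return ConstrainedFit(
        sequence_name=design.sequence.name,
        beta1=float(b[0]),
        beta_diffs=diffs,
        covariate_coefs=b[4:],
        fitted_position_means=means,
        sse=float(sse[0]),
        n=design.n,
        k=design.k,
        active_constraints=np.abs(b[1:4]) <= _CONSTRAINT_TOL,
    )


def fit_unconstrained(y: np.ndarray, design: DesignSpec) -> OLSFit:
    """Ordinary least squares on the same design (oracle / trend baseline)."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValidationError("outcome contains non-finite values")
    X = design.X
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("design matrix is rank deficient")
    coefs, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coefs
    sse = float((resid**2).sum())
    df = design.n - X.shape[1]
    sigma2 = sse / df if df > 0 else np.nan
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    return OLSFit(coefs=coefs, se=se, sse=sse, n=design.n, df_resid=df)


def bic(sse: float, n: int, k: int) -> float:
    """Gaussian BIC, n ln(SSE/n) + k ln n; −inf sentinel for a perfect fit."""
    if n <= k:
        raise FitError(f"BIC requires n > k (n={n}, k={k})")
    if sse <= 0:
        warnings.warn("SSE is zero; BIC is -inf", RuntimeWarning, stacklevel=2)
        return -np.inf
    return float(n * np.log(sse / n) + k * np.log(n))


@dataclass
class ModelComparison:
    """Per-sequence BIC table with winner, runner-up gap and reference rank."""

    table: pd.DataFrame              # index: sequence name; columns sse, bic, n, k
    winner: str
    delta_bic: float                 # winner BIC minus runner-up BIC (<= 0)
    reference: str
    reference_rank: int
    tie: bool
    dropped: list[str] = field(default_factory=list)

    @property
    def fits(self) -> pd.DataFrame:
        return self.table


def _rank_with_ties(bics: np.ndarray) -> np.ndarray:
    """1-based competition order by BIC, canonical (input) order on ties."""
    order = np.lexsort((np.arange(len(bics)), bics))
    ranks = np.empty(len(bics), dtype=int)
    ranks[order] = np.arange(1, len(bics) + 1)
    return ranks


def compare_sequences(
    y: np.ndarray,
    groups,
    covariates: pd.DataFrame | np.ndarray | None,
    sequences: SequenceSet,
    min_per_group: int = 3,
) -> ModelComparison:
    """Fit each candidate sequence's monotone model and rank them by BIC.

    Each sequence is fit on the subjects belonging to its own 4 states.
    Minimal BIC wins; ties (ΔBIC < 1e-9) are resolved by canonical set order
    with the tie flag raised.  Sequences whose groups are too small are
    dropped with a warning; an empty comparison is an error.
    """
    y = np.asarray(y, dtype=float)
    rows = []
    dropped = []
    for seq in sequences:
        try:
            design = build_design(groups, seq, covariates, min_per_group)
        except InsufficientGroupError as exc:
            warnings.warn(str(exc), RuntimeWarning, stacklevel=2)
            dropped.append(seq.name)
            continue
        fit = fit_monotone(y[design.included], design)
        rows.append(
            {"sequence": seq.name, "sse": fit.sse, "bic": fit.bic,
             "n": fit.n, "k": fit.k}
        )
    if not rows:
        raise FitError("every candidate sequence failed its design preconditions")
    table = pd.DataFrame(rows).set_index("sequence")
    bics = table["bic"].to_numpy()
    ranks = _rank_with_ties(bics)
    table["rank"] = ranks
    winner_idx = int(np.flatnonzero(ranks == 1)[0])
    winner = table.index[winner_idx]
    tie = False
    delta = np.nan
    if len(bics) > 1:
        order = np.argsort(ranks)
        b0, b1 = bics[order[0]], bics[order[1]]
        delta = float(b0 - b1) if np.isfinite(b0) and np.isfinite(b1) else (
            0.0 if b0 == b1 else -np.inf
        )
        tie = bool(abs(b0 - b1) < _TIE_TOL) if np.isfinite(b0) and np.isfinite(b1) \
            else bool(b0 == b1)
    reference = sequences.reference
    ref_rank = int(table.loc[reference, "rank"]) if reference in table.index else -1
    return ModelComparison(
        table=table,
        winner=str(winner),
        delta_bic=delta,
        reference=reference,
        reference_rank=ref_rank,
        tie=tie,
        dropped=dropped,
    )


@dataclass
class TrendResult:
    t: float
    p: float                        # one-sided, for decline (negative slope)
    slope: float
    df: int
    sequence_name: str


def _trend_design(design: DesignSpec) -> np.ndarray:
    pos = design.positions.astype(float)
    pos = pos - pos.mean()
    return np.column_stack([np.ones(design.n), pos, design.cov_block])


def trend_test(
    y: np.ndarray,
    groups,
    covariates: pd.DataFrame | np.ndarray | None,
    sequence: GroupSequence,
    min_per_group: int = 3,
) -> TrendResult:
    """Covariate-adjusted linear trend across sequence positions.

    Sequence position (1..4, centered) enters as a single regressor; the
    statistic is the position slope's t ratio and the p value is one-sided
    for decline (negative slope).
    """
    design = build_design(groups, sequence, covariates, min_per_group)
    t, p, slope, df = _trend_many(np.asarray(y, dtype=float)[design.included, None], design)
    return TrendResult(float(t[0]), float(p[0]), float(slope[0]), int(df),
                       sequence.name)


def _trend_many(Y: np.ndarray, design: DesignSpec):
    X = _trend_design(design)
    n, k = X.shape
    if n <= k:
        raise FitError(f"trend test requires n > {k} subjects, have {n}")
    xtx_inv = np.linalg.inv(X.T @ X)
    B = xtx_inv @ (X.T @ Y)                    # (k, V)
    resid = Y - X @ B
    df = n - k
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, B[1] / se, np.sign(B[1]) * np.inf)
    p = stats.t.cdf(t, df)                     # one-sided: decline means t << 0
    return t, p, B[1], df


def trend_test_many(
    Y: np.ndarray,
    groups,
    covariates: pd.DataFrame | np.ndarray | None,
    sequence: GroupSequence,
    min_per_group: int = 3,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized trend test over many outcome columns (n × V).

    Returns (t statistics, one-sided p values, residual df); used by the
    voxel-wise log-p maps.
    """
    design = build_design(groups, sequence, covariates, min_per_group)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    t, p, _, df = _trend_many(Y[design.included], design)
    return t, p, int(df)
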