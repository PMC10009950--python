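"""ATN classification: cutoff estimation, volume adjustment, group labels.

Each participant is rated normal (−) or abnormal (+) in three binary
categories: amyloid (A, CSF Aβ42/Aβ40 ratio, abnormal *below* cutoff), tau
(T, CSF p-tau181, abnormal *above* cutoff) and neurodegeneration (N, either
adjusted hippocampal volume — abnormal below — or CSF total tau — abnormal
above).  Hippocampal volume is first residualized on age, sex, education,
total intracranial volume and WMH load by ordinary least squares, then
shifted back to the raw-volume mean so the adjusted scale stays in μl.

Cutoffs may be fixed numbers, estimated from a labelled reference by ROC /
Youden's J, or estimated without labels by a two-component Gaussian mixture
(the equal-posterior point between the component means).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from . import reference
from .cohort import AnalysisConfig, CohortTable
from .errors import (
    ClassificationError,
    DegenerateMixtureError,
    FitError,
    NoCandidateError,
    ValidationError,
)
from .sequences import ALL_GROUPS, group_label

__all__ = [
    "CutoffSet",
    "ATNStatus",
    "AdjustmentModel",
    "GroupAssignment",
    "MARKER_DIRECTIONS",
    "adjust_volume",
    "estimate_gmm_cutoff",
    "estimate_youden_cutoff",
    "classify_subject",
    "assign_groups",
]

#: Abnormality direction per marker, fixed by biology.
MARKER_DIRECTIONS: dict[str, str] = {
    "abeta_ratio": "abnormal_below",
    "ptau": "abnormal_above",
    "ahv": "abnormal_below",
    "ttau": "abnormal_above",
}


@dataclass(frozen=True)
class CutoffSet:
    """Per-marker thresholds with provenance (fixed / youden / gmm)."""

    abeta_cutoff: float
    ptau_cutoff: float
    n_cutoff: float
    n_marker: str  # "ahv" or "ttau"
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("abeta_cutoff", "ptau_cutoff", "n_cutoff"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be finite and positive, got {v}")
        if self.n_marker not in ("ahv", "ttau"):
            raise ValidationError(f"unknown n_marker {self.n_marker!r}")


@dataclass(frozen=True)
class ATNStatus:
    a_positive: bool
    t_positive: bool
    n_positive: bool

    @property
    def group_label(self) -> str:
        return group_label(self.a_positive, self.t_positive, self.n_positive)


@dataclass
class AdjustmentModel:
    """OLS model of hippocampal volume on centered covariates.

    ``apply`` residualizes new data with the training coefficients and adds
    back the training grand mean, so adjusted values remain interpretable
    on the raw μl scale.
    """

    covariates: list[str]
    coef: np.ndarray            # per-covariate slope, training centering
    intercept: float            # fitted mean at covariate means
    covariate_means: np.ndarray
    grand_mean: float           # training mean of raw volumes
    r_squared: float
    residual_sd: float

    def apply(self, volumes: np.ndarray, covariate_values: pd.DataFrame) -> np.ndarray:
        X = covariate_values[self.covariates].to_numpy(dtype=float) - self.covariate_means
        fitted = self.intercept + X @ self.coef
        return np.asarray(volumes, dtype=float) - fitted + self.grand_mean


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    rank = np.linalg.matrix_rank(X)
    culprits = []
    for j, name in enumerate(names):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            culprits.append(name)
    return culprits


def adjust_volume(
    cohort: CohortTable,
    covariates: list[str] | None = None,
    volume_column: str = "hippocampal_volume",
    fit_on: pd.Series | np.ndarray | None = None,
) -> tuple[pd.Series, AdjustmentModel]:
    """Residualize a volume column on covariates; return adjusted μl values.

    The model is fit on subjects with complete data (optionally restricted by
    the boolean ``fit_on``) and applied to every subject with complete
    covariates.  Adjusted = residual + grand mean of the training volumes.
    Subjects with missing inputs get NaN.
    """
    covariates = list(covariates) if covariates is not None else [
        "age", "sex", "education", "ticv", "wmh"
    ]
    df = cohort.df
    y_all = df[volume_column].to_numpy(dtype=float)
    X_all = df[covariates].to_numpy(dtype=float)
    complete = np.isfinite(y_all) & np.all(np.isfinite(X_all), axis=1)
    train = complete.copy()
    if fit_on is not None:
        train &= np.asarray(fit_on, dtype=bool)
    n_train = int(train.sum())
    if n_train < len(covariates) + 2:
        raise FitError(
            f"need at least {len(covariates) + 2} complete subjects, have {n_train}"
        )

    means = X_all[train].mean(axis=0)
    Xc = X_all[train] - means
    design = np.column_stack([np.ones(n_train), Xc])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        culprits = _collinear_columns(design[:, 1:], covariates)
        raise FitError(f"collinear covariate column(s): {culprits or covariates}")
    beta, _, _, _ = np.linalg.lstsq(design, y_all[train], rcond=None)
    fitted = design @ beta
    resid = y_all[train] - fitted
    ss_tot = float(((y_all[train] - y_all[train].mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    dof = max(n_train - design.shape[1], 1)
    model = AdjustmentModel(
        covariates=covariates,
        coef=beta[1:],
        intercept=float(beta[0]),
        covariate_means=means,
        grand_mean=float(y_all[train].mean()),
        r_squared=r2,
        residual_sd=float(np.sqrt((resid ** 2).sum() / dof)),
    )
    adjusted = np.full(len(df), np.nan)
    cov_ok = np.all(np.isfinite(X_all), axis=1) & np.isfinite(y_all)
    adjusted[cov_ok] = model.apply(y_all[cov_ok], df.loc[cov_ok, covariates])
    return pd.Series(adjusted, index=df.index, name=f"adjusted_{volume_column}"), model


def _gmm_boundary(
    w: np.ndarray, mu: np.ndarray, sd: np.ndarray
) -> float:
    """Equal-posterior point strictly between the two component means.

    Solves w1 N(x; mu1, sd1) = w2 N(x; mu2, sd2), a quadratic in x; falls
    back to bisection on the log-density difference if the closed form finds
    no root in the open interval.
    """
    (w1, w2), (m1, m2), (s1, s2) = w, mu, sd
    lo, hi = (m1, m2) if m1 < m2 else (m2, m1)
    a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = (
        m2**2 / (2 * s2**2)
        - m1**2 / (2 * s1**2)
        + np.log((w1 * s2) / (w2 * s1))
    )
    if abs(a) < 1e-300:
        roots = np.array([-c / b]) if b != 0 else np.array([])
    else:
        disc = b**2 - 4 * a * c
        roots = np.roots([a, b, c]) if disc >= 0 else np.array([])
    roots = np.real(roots[np.isreal(roots)]) if len(roots) else roots
    inside = [r for r in np.atleast_1d(roots) if lo < r < hi]
    if inside:
        return float(inside[0] if len(inside) == 1 else min(inside, key=lambda r: abs(r - (lo + hi) / 2)))
    # numeric fallback: log w1 φ1 − log w2 φ2 changes sign on (lo, hi)
    from scipy.optimize import brentq

    def f(x: float) -> float:
        return (
            np.log(w1) - np.log(s1) - (x - m1) ** 2 / (2 * s1**2)
            - (np.log(w2) - np.log(s2) - (x - m2) ** 2 / (2 * s2**2))
        )

    left, right = lo + 1e-9 * (hi - lo), hi - 1e-9 * (hi - lo)
    if f(left) * f(right) > 0:
        # one component dominates the whole interval: no equal-posterior
        # point exists between the means
        raise DegenerateMixtureError(
            "no equal-posterior point between the component means"
        )
    return float(brentq(f, left, right))


def estimate_gmm_cutoff(
    values: np.ndarray,
    seed: int = 0,
    min_separation_sd: float = 0.5,
    n_init: int = 5,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> float:
    """Two-component Gaussian-mixture cutoff at the equal-posterior point.

    The mixture is fit by EM with ``n_init`` seeded restarts; the cutoff is
    the point strictly between the component means where posterior
    membership is 50/50.  Components closer than ``min_separation_sd``
    pooled SDs raise :class:`DegenerateMixtureError` (callers may fall back
    to a fixed cutoff).  Deterministic given seed.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 20:
        raise ValidationError(f"need >= 20 finite values, have {x.size}")
    gmm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=n_init,
        max_iter=max_iter,
        tol=tol,
        random_state=int(seed),
    ).fit(x.reshape(-1, 1))
    mu = gmm.means_.ravel()
    sd = np.sqrt(gmm.covariances_.ravel())
    w = gmm.weights_.ravel()
    pooled_sd = float(np.sqrt(np.mean(sd**2)))
    if abs(mu[0] - mu[1]) < min_separation_sd * pooled_sd:
        raise DegenerateMixtureError(
            f"component means {mu} closer than {min_separation_sd} pooled SD "
            f"({pooled_sd:.4g}); distribution looks unimodal"
        )
    return _gmm_boundary(w, mu, sd)


@dataclass(frozen=True)
class YoudenResult:
    cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float


def estimate_youden_cutoff(
    values: np.ndarray,
    labels: np.ndarray,
    direction: str,
) -> YoudenResult:
    """Threshold maximizing Youden's J = sensitivity + specificity − 1.

    Candidates are midpoints between adjacent distinct sorted values;
    ``direction`` states which side of the threshold is abnormal.  Ties in J
    are broken toward the candidate with higher specificity.
    """
    if direction not in ("abnormal_below", "abnormal_above"):
        raise ValidationError(f"unknown direction {direction!r}")
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    ok = np.isfinite(x)
    x, y = x[ok], y[ok]
    if set(np.unique(y)) != {0, 1}:
        raise ValidationError("both label classes must be present")
    distinct = np.unique(x)
    if distinct.size < 2:
        raise NoCandidateError("a single distinct value admits no threshold")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    pos, neg = y == 1, y == 0
    best: YoudenResult | None = None
    for c in candidates:
        abnormal = x < c if direction == "abnormal_below" else x > c
        sens = float(abnormal[pos].mean())
        spec = float((~abnormal[neg]).mean())
        j = sens + spec - 1.0
        if best is None or j > best.youden_j + 1e-12 or (
            abs(j - best.youden_j) <= 1e-12 and spec > best.specificity
        ):
            best = YoudenResult(float(c), j, sens, spec)
    if best.youden_j <= 0:
        raise NoCandidateError(
            f"no threshold separates the classes (max J = {best.youden_j:.3g})"
        )
    return best


def classify_subject(
    record: pd.Series,
    cutoffs: CutoffSet,
    adjusted_volume: float | None = None,
) -> ATNStatus:
    """Binary A/T/N status of one subject under strict-inequality cutoffs.

    A+ iff abeta_ratio < cutoff; T+ iff ptau > cutoff; N+ iff adjusted
    hippocampal volume < cutoff (aHV mode) or total tau > cutoff (ttau
    mode).  A value exactly at its cutoff classifies normal (−).
    """
    def _require(name: str, value) -> float:
        if value is None or not np.isfinite(value):
            raise ClassificationError(f"missing marker {name!r}")
        return float(value)

    abeta = _require("abeta_ratio", record.get("abeta_ratio"))
    ptau = _require("ptau", record.get("ptau"))
    a_pos = abeta < cutoffs.abeta_cutoff
    t_pos = ptau > cutoffs.ptau_cutoff
    if cutoffs.n_marker == "ahv":
        vol = _require("adjusted_volume", adjusted_volume)
        n_pos = vol < cutoffs.n_cutoff
    else:
        ttau = _require("ttau", record.get("ttau"))
        n_pos = ttau > cutoffs.n_cutoff
    return ATNStatus(bool(a_pos), bool(t_pos), bool(n_pos))


@dataclass
class GroupAssignment:
    """Per-subject group labels plus the 8-group size table and exclusions."""

    labels: pd.Series             # group label per classified subject (NaN if excluded)
    sizes: pd.Series              # counts over all 8 groups, zeros allowed
    excluded: pd.DataFrame        # subject_id + reason
    cutoffs: CutoffSet
    adjusted_volume: pd.Series | None
    adjustment_model: AdjustmentModel | None

    @property
    def n_classified(self) -> int:
        return int(self.labels.notna().sum())


def _resolve_cutoffs(
    config: AnalysisConfig,
    adjusted: pd.Series | None,
    cohort: CohortTable,
) -> CutoffSet:
    prov: dict[str, str] = {}

    def fixed_or(name: str, value, fallback_key: str, series: np.ndarray | None):
        if isinstance(value, str):  # "gmm" directive
            try:
                cut = estimate_gmm_cutoff(series, seed=config.seed)
                prov[name] = "gmm"
                return cut
            except DegenerateMixtureError:
                prov[name] = f"fixed (gmm degenerate, fallback {fallback_key})"
                return reference.FIXED_CUTOFFS[fallback_key]
        prov[name] = "fixed"
        return float(value)

    abeta = fixed_or(
        "abeta_ratio", config.abeta_cutoff, "abeta_ratio",
        cohort.df["abeta_ratio"].to_numpy(dtype=float),
    )
    ptau = fixed_or(
        "ptau", config.ptau_cutoff, "ptau", cohort.df["ptau"].to_numpy(dtype=float)
    )
    if config.n_marker == "ahv":
        series = adjusted.to_numpy(dtype=float) if adjusted is not None else None
        n_cut = fixed_or("ahv", config.n_cutoff, "ahv", series)
    else:
        n_cut = fixed_or(
            "ttau", config.n_cutoff, "ttau", cohort.df["ttau"].to_numpy(dtype=float)
        )
    return CutoffSet(abeta, ptau, n_cut, config.n_marker, prov)


def assign_groups(
    cohort: CohortTable, config: AnalysisConfig | None = None
) -> GroupAssignment:
    """Classify every subject with complete markers into the 8 ATN groups.

    In aHV mode, hippocampal volume is first covariate-adjusted (on all
    complete subjects, or only biomarker-negative ones when
    ``config.adjust_on == "atn_negative"``); mixture-based cutoffs are then
    estimated on the adjusted values.  Subjects missing a required marker
    are excluded and listed, never imputed.
    """
    config = config or AnalysisConfig()
    df = cohort.df
    if config.hippocampal_volume_unit == "ml":
        df = df.assign(hippocampal_volume=df["hippocampal_volume"] * 1000.0)
        cohort = CohortTable(df=df, source=cohort.source, units=cohort.units)
        df = cohort.df

    adjusted: pd.Series | None = None
    model: AdjustmentModel | None = None
    if config.n_marker == "ahv":
        fit_on = None
        if config.adjust_on == "atn_negative":
            # provisional screen on the two CSF markers with fixed cutoffs
            fit_on = (
                (df["abeta_ratio"] >= reference.FIXED_CUTOFFS["abeta_ratio"])
                & (df["ptau"] <= reference.FIXED_CUTOFFS["ptau"])
            ).to_numpy()
        adjusted, model = adjust_volume(cohort, config.covariates, fit_on=fit_on)

    cutoffs = _resolve_cutoffs(config, adjusted, cohort)

    labels = pd.Series(pd.NA, index=df.index, dtype="object")
    excluded_rows = []
    for i, row in df.iterrows():
        try:
            vol = float(adjusted.iloc[i]) if adjusted is not None else None
            labels.iloc[i] = classify_subject(row, cutoffs, adjusted_volume=vol).group_label
        except ClassificationError as exc:
            excluded_rows.append({"subject_id": row["subject_id"], "reason": str(exc)})
    sizes = pd.Series(
        {g: int((labels == g).sum()) for g in ALL_GROUPS}, name="group_size"
    )
    return GroupAssignment(
        labels=labels,
        sizes=sizes,
        excluded=pd.DataFrame(excluded_rows, columns=["subject_id", "reason"]),
        cutoffs=cutoffs,
        adjusted_volume=adjusted,
        adjustment_model=model,
    )
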