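"""Voxel-wise evidence maps, FDR-corrected log-p maps, and ROI summaries.

The sequence comparison of :mod:`atnseq.monotone` is applied independently
at every gray-matter voxel, yielding a winner map (which candidate sequence
has minimal BIC at each voxel), winner percentages over the GM mask, ROI
summaries (best sequence on the summed in-ROI volume plus the share of ROI
voxels won by the reference sequence), −log10 p maps of the linear trend
test with Benjamini–Hochberg FDR control, and Braak-stage composite
volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import FitError, ValidationError
from .images import ROIMask, VoxelDataset
from .monotone import (
    _TIE_TOL,
    bic,
    build_design,
    compare_sequences,
    fit_monotone_many,
    trend_test,
    trend_test_many,
)
from .sequences import GroupSequence, SequenceSet

__all__ = [
    "EvidenceResult",
    "StatMap",
    "ROISummary",
    "BraakComposite",
    "DEFAULT_BRAAK_STAGES",
    "gm_mask",
    "voxelwise_compare",
    "winner_percentages",
    "roi_summary",
    "logp_map",
    "fdr_bh",
    "braak_composites",
]


def gm_mask(dataset: VoxelDataset, threshold: float = 0.05) -> ROIMask:
    """Gray-matter inclusion mask: mean value across subjects >= threshold."""
    mean_img = dataset.values.mean(axis=0)
    data = mean_img >= threshold
    if not data.any():
        raise ValidationError(
            f"GM mask is empty at absolute threshold {threshold}"
        )
    return ROIMask(name=f"gm>={threshold}", data=data)


@dataclass
class EvidenceResult:
    """Per-voxel winning sequence inside the analysis mask.

    ``winner`` holds the index into ``sequence_names`` (−1 outside the
    mask); ``delta_bic`` the winner-minus-runner-up BIC gap (<= 0).
    """

    winner: np.ndarray               # int grid, -1 outside mask
    delta_bic: np.ndarray            # float grid, NaN outside mask
    tie: np.ndarray                  # bool grid
    sequence_names: list[str]
    mask: ROIMask
    affine: np.ndarray

    def winner_name_at(self, idx: tuple[int, int, int]) -> str | None:
        w = int(self.winner[idx])
        return self.sequence_names[w] if w >= 0 else None


def voxelwise_compare(
    dataset: VoxelDataset,
    groups,
    covariates: pd.DataFrame | np.ndarray | None,
    sequences: SequenceSet,
    gm_threshold: float = 0.05,
    mask: ROIMask | None = None,
    min_per_group: int = 3,
) -> EvidenceResult:
    """Run the BIC sequence comparison independently at every GM voxel.

    Each sequence's constrained model is fit (vectorized over voxels) on the
    subjects belonging to its own 4 states; per voxel the sequence with
    minimal BIC wins, ties (ΔBIC < 1e-9) resolved by canonical set order
    with a tie flag.  Deterministic and invariant to subject order.
    """
    groups = pd.Series(groups).astype("object")
    dataset.check_alignment(len(groups))
    if mask is None:
        mask = gm_mask(dataset, gm_threshold)
    elif mask.data.shape != dataset.grid_shape:
        raise ValidationError("mask grid disagrees with dataset grid")
    flat = dataset.values.reshape(dataset.n_subjects, -1)
    in_mask = mask.data.reshape(-1)
    Y = flat[:, in_mask]                    # n_subjects × V
    V = Y.shape[1]

    if isinstance(covariates, pd.DataFrame):
        cov_arr: pd.DataFrame | np.ndarray | None = covariates
    else:
        cov_arr = covariates

    bics = np.full((len(sequences), V), np.inf)
    names = sequences.names
    kept = np.zeros(len(sequences), dtype=bool)
    for i, seq in enumerate(sequences):
        try:
            design = build_design(groups, seq, cov_arr, min_per_group)
        except FitError as exc:
            import warnings

            warnings.warn(f"dropping {seq.name}: {exc}", RuntimeWarning, stacklevel=2)
            continue
        sse, _ = fit_monotone_many(Y[design.included], design)
        n, k = design.n, design.k
        with np.errstate(divide="ignore"):
            b = np.where(sse > 0, n * np.log(np.maximum(sse, 1e-300) / n)
                         + k * np.log(n), -np.inf)
        bics[i] = b
        kept[i] = True
    if not kept.any():
        raise FitError("no candidate sequence satisfied its design preconditions")

    winner_flat = np.argmin(bics, axis=0)   # first minimum = canonical order
    sorted_b = np.sort(bics, axis=0)
    if len(sequences) > 1:
        both_inf = np.isneginf(sorted_b[0]) & np.isneginf(sorted_b[1])
        with np.errstate(invalid="ignore"):
            gap = np.where(both_inf, 0.0, sorted_b[0] - sorted_b[1])
        tie_flat = both_inf | (np.abs(gap) < _TIE_TOL)
    else:
        gap = np.zeros(V)
        tie_flat = np.zeros(V, dtype=bool)

    shape = dataset.grid_shape
    winner = np.full(np.prod(shape), -1, dtype=int)
    winner[in_mask] = winner_flat
    delta = np.full(np.prod(shape), np.nan)
    delta[in_mask] = np.where(np.isfinite(gap), gap, -np.inf)
    tie = np.zeros(np.prod(shape), dtype=bool)
    tie[in_mask] = tie_flat
    return EvidenceResult(
        winner=winner.reshape(shape),
        delta_bic=delta.reshape(shape),
        tie=tie.reshape(shape),
        sequence_names=names,
        mask=mask,
        affine=dataset.affine,
    )


def winner_percentages(
    result: EvidenceResult, mask: ROIMask | None = None
) -> pd.Series:
    """Percentage of in-mask voxels won per sequence (sums to 100)."""
    mask = mask or result.mask
    if mask.data.shape != result.winner.shape:
        raise ValidationError("mask grid disagrees with evidence grid")
    sel = mask.data & (result.winner >= 0)
    total = int(sel.sum())
    if total == 0:
        raise ValidationError("mask contains no analyzed voxels")
    counts = np.bincount(result.winner[sel], minlength=len(result.sequence_names))
    return pd.Series(
        100.0 * counts / total, index=result.sequence_names, name="winner_pct"
    )


@dataclass
class ROISummary:
    """ROI-level sequence evidence (Table-style row)."""

    roi: str
    best_sequence: str
    t: float
    p: float
    reference: str
    reference_rank: int
    reference_vx_pct: float          # % of ROI voxels won by the reference
    n_sequences: int
    comparison: pd.DataFrame = field(repr=False, default=None)


def roi_summary(
    dataset: VoxelDataset | None,
    groups,
    covariates,
    roi: ROIMask | None,
    sequences: SequenceSet,
    evidence: EvidenceResult | None = None,
    roi_volumes: np.ndarray | None = None,
    min_per_group: int = 3,
) -> ROISummary:
    """Sequence evidence for one ROI.

    The comparison runs on the per-subject summed in-ROI volume (or on
    ``roi_volumes`` directly when a scalar per subject is supplied, e.g. an
    atlas volume).  The trend t/p are for the best sequence.  If a
    voxel-wise :class:`EvidenceResult` is given, the reference sequence's
    share of ROI voxels (VX%) is included.
    """
    if roi_volumes is None:
        if dataset is None or roi is None:
            raise ValidationError("need either roi_volumes or (dataset, roi)")
        if roi.data.shape != dataset.grid_shape:
            raise ValidationError("ROI grid disagrees with dataset grid")
        roi_volumes = dataset.values[:, roi.data].sum(axis=1)
    roi_volumes = np.asarray(roi_volumes, dtype=float)

    comp = compare_sequences(roi_volumes, groups, covariates, sequences,
                             min_per_group)
    best = comp.winner
    trend = trend_test(roi_volumes, groups, covariates, sequences.get(best),
                       min_per_group)
    vx_pct = np.nan
    if evidence is not None and roi is not None:
        pct = winner_percentages(evidence, roi)
        vx_pct = float(pct.get(sequences.reference, np.nan))
    return ROISummary(
        roi=roi.name if roi is not None else "roi_volumes",
        best_sequence=best,
        t=trend.t,
        p=trend.p,
        reference=sequences.reference,
        reference_rank=comp.reference_rank,
        reference_vx_pct=vx_pct,
        n_sequences=len(comp.table),
        comparison=comp.table,
    )


@dataclass
class StatMap:
    """Per-voxel trend statistics for one sequence with FDR control.

    Out-of-mask voxels hold 0 in ``neglog10p`` and NaN in ``t``/``p``/``q``;
    statistics are computed within the mask only.
    """

    sequence_name: str
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    neglog10p: np.ndarray
    significant: np.ndarray          # bool grid, q <= alpha
    alpha: float
    mask: ROIMask
    affine: np.ndarray


def logp_map(
    dataset: VoxelDataset,
    groups,
    covariates,
    sequence: GroupSequence,
    gm_threshold: float = 0.05,
    q: float = 0.05,
    mask: ROIMask | None = None,
    min_per_group: int = 3,
) -> StatMap:
    """Voxel-wise one-sided trend test along one sequence, BH-FDR corrected.

    FDR is applied across in-mask voxels for this sequence alone; −log10 p
    is stored for display, with out-of-mask voxels at 0.
    """
    groups = pd.Series(groups).astype("object")
    dataset.check_alignment(len(groups))
    if mask is None:
        mask = gm_mask(dataset, gm_threshold)
    flat = dataset.values.reshape(dataset.n_subjects, -1)
    in_mask = mask.data.reshape(-1)
    t_flat, p_flat, _ = trend_test_many(
        flat[:, in_mask], groups, covariates, sequence, min_per_group
    )
    reject, qvals = fdr_bh(p_flat, q)

    shape = dataset.grid_shape
    def _grid(vals, fill):
        out = np.full(np.prod(shape), fill, dtype=float)
        out[in_mask] = vals
        return out.reshape(shape)

    sig = np.zeros(np.prod(shape), dtype=bool)
    sig[in_mask] = reject
    with np.errstate(divide="ignore"):
        nlp = -np.log10(np.maximum(p_flat, np.finfo(float).tiny))
    return StatMap(
        sequence_name=sequence.name,
        t=_grid(t_flat, np.nan),
        p=_grid(p_flat, np.nan),
        q=_grid(qvals, np.nan),
        neglog10p=_grid(nlp, 0.0),
        significant=sig.reshape(shape),
        alpha=q,
        mask=mask,
        affine=dataset.affine,
    )


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up over a p-value vector.

    Returns (rejected flags, monotone q-values).
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValidationError("fdr_bh expects a 1-D p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValidationError("q must lie in (0, 1)")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, qvals


#: Default assignment of ROI names to tau-pathology stage composites:
#: transentorhinal/hippocampal first, limbic-insular-temporal next, the
#: remaining cortex (incl. primary sensory/motor and precuneus) last.
DEFAULT_BRAAK_STAGES: dict[str, tuple[str, ...]] = {
    "I/II": ("entorhinal", "hippocampus"),
    "III/IV": ("amygdala", "parahippocampal", "fusiform", "insula",
               "temporal", "cingulate"),
    "V/VI": ("frontal", "parietal", "occipital", "precuneus",
             "precentral", "postcentral"),
}


@dataclass
class BraakComposite:
    stage: str
    rois: tuple[str, ...]
    volumes: pd.Series               # aggregated volume per subject


def braak_composites(
    roi_volume_table: pd.DataFrame,
    stage_map: dict[str, tuple[str, ...]] | None = None,
) -> list[BraakComposite]:
    """Aggregate per-subject ROI volumes into stage composites.

    ``roi_volume_table`` is subjects × ROI names; ``stage_map`` assigns each
    ROI to exactly one stage (unknown ROIs in the table are ignored, ROIs
    claimed by two stages or empty stages are errors).
    """
    stage_map = stage_map or {
        k: tuple(r for r in v if r in roi_volume_table.columns)
        for k, v in DEFAULT_BRAAK_STAGES.items()
    }
    seen: dict[str, str] = {}
    for stage, rois in stage_map.items():
        if len(rois) == 0:
            raise ValidationError(f"stage {stage!r} has no constituent ROIs")
        for r in rois:
            if r in seen:
                raise ValidationError(
                    f"ROI {r!r} assigned to both {seen[r]!r} and {stage!r}"
                )
            seen[r] = stage
            if r not in roi_volume_table.columns:
                raise ValidationError(f"ROI {r!r} not present in the volume table")
    return [
        BraakComposite(
            stage=stage,
            rois=tuple(rois),
            volumes=roi_volume_table[list(rois)].sum(axis=1).rename(stage),
        )
        for stage, rois in stage_map.items()
    ]
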