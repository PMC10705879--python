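"""Colormap calibration from registered OCT/SEM pairs.

Paired pixels (OCT intensity in dB, SEM zone label) sampled over a
registered region feed one-vs-rest ROC curves per demineralization zone;
the operating threshold is the curve point nearest the ideal classifier
(sensitivity 1 at zero false-positive rate).  Candidate colormaps are then
scored by per-zone pixelwise agreement against the segmented SEM reference
and the best-agreeing map is selected.

Registration is assumed given (the frames cover the same region of
interest); the OCT frame is resampled to the SEM grid by nearest-neighbour
replication so the two maps share one pixel raster.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BScan, ColorMap, LABEL_AIR, LABEL_IA, LABEL_IE
from .segmentation import ContractError, detect_surface, label_zones, remove_background
from .sem import SEMLabelMap, interfaces_from_labels

log = logging.getLogger(__name__)


class ROCUndefinedError(ValueError):
    """Raised when one of the two classes is empty."""


@dataclass
class ROCResult:
    """ROC sweep of an intensity threshold classifier (positive = bright)."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    nearest_point: tuple[float, float]
    nearest_distance: float
    selected_threshold: float


@dataclass
class CorrelationReport:
    """Per-zone and interface agreement (%) of an OCT labeling vs SEM."""

    pct_ia: float
    pct_ie: float
    pct_interface: float
    cmap: ColorMap | None = None


def resample_to_grid(frame: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resampling of a 2-D array onto a target shape."""
    frame = np.asarray(frame)
    rows = (np.arange(shape[0]) * frame.shape[0] // shape[0])
    cols = (np.arange(shape[1]) * frame.shape[1] // shape[1])
    return frame[np.ix_(rows, cols)]


def sample_paired_pixels(
    oct_frame: BScan,
    sem: SEMLabelMap,
    n: int,
    seed: int,
    stratify: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` registered (OCT dB, SEM label) pixel pairs reproducibly.

    The OCT frame is resampled to the SEM grid; pairs are drawn from SEM
    tissue pixels, stratified proportionally over the tissue labels when
    ``stratify`` is set.
    """
    oct_on_sem = resample_to_grid(oct_frame.intensity_db, sem.shape)
    tissue = sem.labels != LABEL_AIR
    total = int(tissue.sum())
    if total == 0:
        raise ContractError("SEM map contains no tissue")
    if n > total:
        raise ValueError(f"requested {n} pairs but only {total} tissue pixels")
    rng = np.random.default_rng(seed)
    flat_labels = sem.labels.ravel()
    flat_db = oct_on_sem.ravel()
    candidates = np.flatnonzero(tissue.ravel())
    if stratify:
        chosen = []
        labels_present = np.unique(flat_labels[candidates])
        remaining = n
        for k, lab in enumerate(labels_present):
            pool = candidates[flat_labels[candidates] == lab]
            if k == len(labels_present) - 1:
                take = remaining
            else:
                take = min(remaining, round(n * pool.size / total))
            take = min(take, pool.size)
            chosen.append(rng.choice(pool, size=take, replace=False))
            remaining -= take
        idx = np.concatenate(chosen)
        if idx.size < n:  # top up from the leftover pool
            leftover = np.setdiff1d(candidates, idx, assume_unique=False)
            idx = np.concatenate(
                [idx, rng.choice(leftover, size=n - idx.size, replace=False)]
            )
    else:
        idx = rng.choice(candidates, size=n, replace=False)
    return flat_db[idx], flat_labels[idx]


def roc_from_samples(
    intensities: np.ndarray,
    positives: np.ndarray,
    grid_step_db: float = 0.1,
) -> ROCResult:
    """ROC of the rule "positive if intensity >= threshold".

    Thresholds sweep the union of a regular dB grid (``grid_step_db``) over
    the observed range and the observed values themselves, so the
    trapezoidal AUC equals the pairwise-concordance (Mann-Whitney)
    statistic while the selected threshold lies on the grid whenever it
    falls in a gap between classes.  The operating point minimizes the
    Euclidean distance to the ideal point (FPR 0, TPR 1); distance ties are
    broken by the middle tied threshold.
    """
    x = np.asarray(intensities, dtype=float)
    y = np.asarray(positives, dtype=bool)
    if x.size != y.size or x.size == 0:
        raise ValueError("intensities and labels must be equal-length, non-empty")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ROCUndefinedError("ROC needs both classes present")
    lo, hi = x.min(), x.max()
    grid = np.arange(np.floor(lo / grid_step_db) * grid_step_db,
                     hi + 2 * grid_step_db, grid_step_db)
    thresholds = np.unique(np.concatenate([grid, x]))[::-1]  # descending
    pos_sorted = np.sort(x[y])
    neg_sorted = np.sort(x[~y])
    # count of values >= t via searchsorted on the sorted class values
    tpr = (n_pos - np.searchsorted(pos_sorted, thresholds, side="left")) / n_pos
    fpr = (n_neg - np.searchsorted(neg_sorted, thresholds, side="left")) / n_neg
    # prepend the all-negative classifier so the curve starts at (0, 0)
    thresholds = np.concatenate([[np.inf], thresholds])
    tpr = np.concatenate([[0.0], tpr])
    fpr = np.concatenate([[0.0], fpr])
    auc = float(np.trapezoid(tpr, fpr))
    dist = np.hypot(fpr, 1.0 - tpr)
    finite = np.isfinite(thresholds)
    best = dist[finite].min()
    tied = np.flatnonzero(finite & (dist <= best))
    pick = int(tied[len(tied) // 2])
    return ROCResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        nearest_point=(float(fpr[pick]), float(tpr[pick])),
        nearest_distance=float(dist[pick]),
        selected_threshold=float(thresholds[pick]),
    )


def zone_rocs(
    intensities: np.ndarray, labels: np.ndarray, grid_step_db: float = 0.1
) -> dict[str, ROCResult]:
    """One-vs-rest ROCs for both demineralization zones.

    The Ia curve uses Ia pixels as positives against all other tissue; the
    Ie curve uses Ie pixels as positives against sound tissue only (Ia
    pixels are excluded, as they sit above the Ie band).
    """
    labels = np.asarray(labels)
    out = {}
    out["ia"] = roc_from_samples(intensities, labels == LABEL_IA, grid_step_db)
    keep = labels != LABEL_IA
    out["ie"] = roc_from_samples(
        np.asarray(intensities)[keep], labels[keep] == LABEL_IE, grid_step_db
    )
    return out


def frame_agreement(
    oct_labels: np.ndarray,
    sem: SEMLabelMap,
    interface_tol_px: int = 1,
    cmap: ColorMap | None = None,
) -> CorrelationReport:
    """Pixelwise agreement of an OCT zone labeling against the SEM reference.

    Per zone: 100 x |pixels both maps call that zone| / |SEM pixels of that
    zone|.  Interface agreement compares the per-column last-Ia and last-Ie
    rows of the two maps within a +/- ``interface_tol_px`` band, pooled
    over both interfaces and the columns where the SEM defines them.
    """
    oct_labels = np.asarray(oct_labels)
    if oct_labels.shape != sem.shape:
        raise ContractError(
            f"grid mismatch: OCT {oct_labels.shape} vs SEM {sem.shape}"
        )
    pct = {}
    for name, lab in (("ia", LABEL_IA), ("ie", LABEL_IE)):
        ref = sem.labels == lab
        denom = int(ref.sum())
        pct[name] = (
            100.0 * int((ref & (oct_labels == lab)).sum()) / denom
            if denom else float("nan")
        )
    _, oct_ia, oct_ie = interfaces_from_labels(oct_labels)
    matches = 0
    defined = 0
    for sem_rows, oct_rows in ((sem.ia_ie_interface, oct_ia),
                               (sem.ie_sound_interface, oct_ie)):
        cols = sem_rows >= 0
        defined += int(cols.sum())
        matches += int(
            (cols & (np.abs(oct_rows - sem_rows) <= interface_tol_px)).sum()
        )
    pct_interface = 100.0 * matches / defined if defined else float("nan")
    return CorrelationReport(pct_ia=pct["ia"], pct_ie=pct["ie"],
                             pct_interface=pct_interface, cmap=cmap)


def oct_labels_on_sem_grid(
    oct_frame: BScan, sem_shape: tuple[int, int], cmap: ColorMap
) -> np.ndarray:
    """Segment an OCT frame with a candidate colormap on the SEM grid."""
    resampled = BScan(
        resample_to_grid(oct_frame.intensity_db, sem_shape),
        ps_axial=oct_frame.ps_axial,
        ps_lateral=oct_frame.ps_lateral,
        frame_id=oct_frame.frame_id,
    )
    clean = remove_background(resampled, cmap.background_db)
    surface = detect_surface(clean)
    return label_zones(clean, surface, cmap)


def select_colormap(
    candidates: list[ColorMap],
    pairs: list[tuple[BScan, SEMLabelMap]],
    interface_tol_px: int = 1,
) -> tuple[ColorMap, pd.DataFrame]:
    """Pick the candidate colormap agreeing best with the SEM references.

    Each candidate is scored by the mean over pairs of
    ``(pct_ia + pct_ie) / 2``; ties are broken by higher interface
    agreement, then by candidate order.  Returns the winner and the full
    score table.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    if not pairs:
        raise ValueError("need at least one registered OCT/SEM pair")
    rows = []
    for k, cand in enumerate(candidates):
        reports = [
            frame_agreement(
                oct_labels_on_sem_grid(oct_frame, sem.shape, cand),
                sem, interface_tol_px=interface_tol_px, cmap=cand,
            )
            for oct_frame, sem in pairs
        ]
        rows.append({
            "candidate": k,
            "pct_ia": float(np.mean([r.pct_ia for r in reports])),
            "pct_ie": float(np.mean([r.pct_ie for r in reports])),
            "pct_interface": float(np.mean([r.pct_interface for r in reports])),
        })
    table = pd.DataFrame(rows)
    table["score"] = (table["pct_ia"] + table["pct_ie"]) / 2.0
    order = table.sort_values(
        by=["score", "pct_interface", "candidate"],
        ascending=[False, False, True],
        kind="stable",
    )
    winner = int(order.iloc[0]["candidate"])
    return candidates[winner], table
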