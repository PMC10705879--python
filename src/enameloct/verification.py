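"""Batch verification of the depth pipeline against oracles and ground truth.

For every simulated frame the mean zone depths are computed four ways: by
the algorithm on the curved surface, by the algorithm after surface
alignment, by the independent spreadsheet-style manual oracle, and from the
generator's ground truth.  Trendline R^2 values (ordinary least squares)
and absolute-difference summaries quantify their agreement.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ColorMap, default_colormap
from .quantification import manual_oracle_depths, quantify_frame
from .simulation import SimulatedBScan

log = logging.getLogger(__name__)


class UndefinedR2Error(ValueError):
    """Raised when the trendline R^2 is undefined (too few points or zero
    variance in x)."""


def trendline_r2(x, y) -> float:
    """Coefficient of determination of the OLS line of ``y`` on ``x``.

    In this simple-regression setting it equals the squared Pearson
    correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise UndefinedR2Error("need at least 3 paired points")
    if np.var(x) == 0:
        raise UndefinedR2Error("x has zero variance")
    fit = stats.linregress(x, y)
    return float(fit.rvalue ** 2)


@dataclass
class VerificationTable:
    """Per-frame depth estimates plus R^2 / difference summaries.

    ``table`` has one row per successfully processed frame; ``summary``
    maps metric names to values:

    - ``r2_curved_vs_aligned_{ia,ie}`` — algorithm curved vs aligned depths
    - ``r2_alg_vs_oracle_{ia,ie}`` — curved algorithm vs manual oracle
    - ``r2_alg_vs_truth_{ia,ie}`` — curved algorithm vs generator truth
    - ``diff_alg_oracle_mean_um`` / ``_sd_um`` — |algorithm - oracle| pooled
      over both zones
    ``failures`` lists (frame_id, reason) for skipped frames.
    """

    table: pd.DataFrame
    summary: dict[str, float]
    failures: list[tuple[str, str]]


def run_verification(
    frames: list[SimulatedBScan],
    cmap: ColorMap | None = None,
    background_db: float | None = None,
) -> VerificationTable:
    """Run the full depth pipeline and the manual oracle over a batch.

    Frames that fail to process are skipped and flagged rather than
    aborting the batch.
    """
    cmap = cmap if cmap is not None else default_colormap()
    rows = []
    failures: list[tuple[str, str]] = []
    for sim in frames:
        frame_id = sim.bscan.frame_id
        try:
            result, geom = quantify_frame(sim.bscan, cmap, background_db)
            from .segmentation import detect_surface, remove_background
            from .quantification import align_to_surface

            clean = remove_background(sim.bscan, background_db)
            aligned, _ = align_to_surface(clean, detect_surface(clean))
            oracle = manual_oracle_depths(aligned, cmap)
            t_ia, t_ie = sim.true_depths()
        except Exception as exc:  # skip-and-flag batch policy
            log.warning("frame %s skipped: %s", frame_id, exc)
            failures.append((frame_id, str(exc)))
            continue
        rows.append({
            "frame_id": frame_id,
            "surface_kind": sim.surface_kind,
            "d_ia_alg": result.d_ia,
            "d_ie_alg": result.d_ie,
            "dl_ia_alg": result.dl_ia,
            "dl_ie_alg": result.dl_ie,
            "d_ia_oracle": oracle.dl_ia,
            "d_ie_oracle": oracle.dl_ie,
            "d_ia_truth": t_ia,
            "d_ie_truth": t_ie,
            "curvature_index": geom.curvature_index,
            "alpha_median_rad": geom.alpha_median,
        })
    table = pd.DataFrame(rows)
    summary: dict[str, float] = {}
    if len(table) >= 3:
        def safe_r2(x, y):
            try:
                return trendline_r2(x, y)
            except UndefinedR2Error:
                return float("nan")

        for zone in ("ia", "ie"):
            summary[f"r2_curved_vs_aligned_{zone}"] = safe_r2(
                table[f"dl_{zone}_alg"], table[f"d_{zone}_alg"]
            )
            summary[f"r2_alg_vs_oracle_{zone}"] = safe_r2(
                table[f"d_{zone}_oracle"], table[f"d_{zone}_alg"]
            )
            summary[f"r2_alg_vs_truth_{zone}"] = safe_r2(
                table[f"d_{zone}_truth"], table[f"d_{zone}_alg"]
            )
        diffs = np.concatenate([
            np.abs(table["d_ia_alg"] - table["d_ia_oracle"]),
            np.abs(table["d_ie_alg"] - table["d_ie_oracle"]),
        ])
        summary["diff_alg_oracle_mean_um"] = float(diffs.mean())
        summary["diff_alg_oracle_sd_um"] = float(diffs.std(ddof=1))
    return VerificationTable(table=table, summary=summary, failures=failures)
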