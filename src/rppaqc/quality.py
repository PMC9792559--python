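"""Continuous per-antibody quality factors from a paired AP/untreated dataset.

Four factors feed the composite antibody score:

1. **Spot-quality fraction** — the share of the antibody's total RFI carried
   by spots not flagged ``poor`` by image analysis (both treatment arms pooled).
2. **Signal-to-noise ratio** — the mean, over ok spots, of raw RFI divided by
   the local background.  Using raw spot RFI over background keeps this factor
   independent of the series-aggregation rule; downstream tertile classing is
   rank-based, so the additive offset versus a background-corrected reading
   does not change any class.
3. **Dilution linearity** — per untreated sample, the Pearson correlation of
   background-subtracted ok-spot RFI against the printed dilution fraction
   (the series is 4 concentrations x 2 replicate spots), averaged over
   samples.  Only the untreated arm is used, because the AP arm's signal is
   deliberately altered; the signed r (not r^2) penalises inverted series.
4. **AP log fold change** — per sample, log2 of the ratio of aggregated AP to
   untreated signal; the factor is the arithmetic mean over samples in which
   both arms are positive.  A negative value means alkaline phosphatase
   removed the epitope the antibody binds — the expected behaviour for a
   phospho-specific antibody.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSignalError,
    DivisionGuardError,
    InsufficientSeriesError,
    RppaError,
    UnpairedOrDegenerateError,
)
from .io import RPPADataset, _aggregate_frame

logger = logging.getLogger(__name__)


@dataclass
class QualityMetrics:
    """The four continuous quality factors for one antibody."""

    antibody_id: str
    spot_quality_fraction: float  # factor 1, in [0, 1]
    snr: float  # factor 2, >= 0
    dilution_linearity: float  # factor 3, in [-1, 1]
    ap_logfc: float  # factor 4, mean per-sample log2(AP / untreated)
    per_sample_logfc: dict[str, float] = field(default_factory=dict)
    n_samples_used: int = 0


@dataclass(frozen=True)
class MetricFailure:
    """Explicit record for an antibody whose metrics could not be computed."""

    antibody_id: str
    reason: str


def spot_quality_fraction(dataset: RPPADataset, antibody_id: str) -> float:
    """Fraction of the antibody's total RFI on ok spots (both arms pooled)."""
    spots = dataset.spots_for(antibody_id)
    total = float(spots["rfi"].sum())
    if spots.empty or total <= 0:
        raise DegenerateSignalError(f"{antibody_id}: total RFI is zero")
    ok_sum = float(spots.loc[spots["flag"] == "ok", "rfi"].sum())
    return ok_sum / total


def signal_to_noise(
    dataset: RPPADataset, antibody_id: str, *, background_floor: float | None = None
) -> float:
    """Mean over ok spots of RFI / local background."""
    spots = dataset.spots_for(antibody_id)
    ok = spots[spots["flag"] == "ok"]
    if ok.empty:
        raise DegenerateSignalError(f"{antibody_id}: no ok spots")
    bg = ok["background"].to_numpy(float)
    if background_floor is not None:
        bg = np.maximum(bg, background_floor)
    if np.any(bg == 0):
        raise DivisionGuardError(
            f"{antibody_id}: ok spot with zero background; set background_floor in config"
        )
    return float(np.mean(ok["rfi"].to_numpy(float) / bg))


def dilution_linearity(dataset: RPPADataset, antibody_id: str) -> float:
    """Mean per-sample Pearson r between net spot signal and dilution fraction.

    Uses ok spots of the untreated arm only, pooling replicates.  Samples with
    fewer than three distinct dilution points, or zero signal variance, are
    excluded (with a logged warning for the latter); if no sample qualifies an
    :class:`InsufficientSeriesError` is raised.
    """
    spots = dataset.spots_for(antibody_id)
    ok = spots[(spots["flag"] == "ok") & (spots["treatment"] == "untreated")]
    rs: list[float] = []
    any_enough_points = False
    for sample_id, grp in ok.groupby("sample_id"):
        d = grp["dilution_fraction"].to_numpy(float)
        if len(np.unique(d)) < 3:
            continue
        any_enough_points = True
        net = grp["rfi"].to_numpy(float) - grp["background"].to_numpy(float)
        if np.ptp(net) == 0:
            logger.warning(
                "%s / %s: zero signal variance, excluded from linearity",
                antibody_id,
                sample_id,
            )
            continue
        # Pearson r; dilution variance is nonzero because >=3 distinct points
        r = np.corrcoef(net, d)[0, 1]
        rs.append(float(r))
    if not any_enough_points:
        raise InsufficientSeriesError(
            f"{antibody_id}: fewer than 3 distinct dilution points in every sample"
        )
    if not rs:
        raise DegenerateSignalError(
            f"{antibody_id}: all samples excluded (zero variance) from linearity"
        )
    return float(np.mean(rs))


def ap_log_fold_change(
    dataset: RPPADataset, antibody_id: str, *, pseudo_intensity: float | None = None
) -> tuple[float, dict[str, float]]:
    """Per-sample log2(RNFI_AP / RNFI_untreated) and its mean over samples.

    Samples with a zero (or missing) arm are excluded and logged rather than
    floored; ``pseudo_intensity`` optionally adds a small constant to both
    arms instead.  Raises :class:`UnpairedOrDegenerateError` if no sample
    qualifies.
    """
    spots = dataset.spots_for(antibody_id)
    agg = _aggregate_frame(spots)
    wide = agg.pivot(index="sample_id", columns="treatment", values="rnfi")
    per_sample: dict[str, float] = {}
    for sample_id in dataset.sample_ids:
        if sample_id not in wide.index:
            continue
        row = wide.loc[sample_id]
        ap = row.get("AP", math.nan)
        unt = row.get("untreated", math.nan)
        if pseudo_intensity is not None:
            ap = ap + pseudo_intensity
            unt = unt + pseudo_intensity
        if not (np.isfinite(ap) and np.isfinite(unt)) or ap <= 0 or unt <= 0:
            logger.info("%s / %s: zero or missing arm, excluded from logFC", antibody_id, sample_id)
            continue
        per_sample[sample_id] = float(np.log2(ap / unt))
    if not per_sample:
        raise UnpairedOrDegenerateError(
            f"{antibody_id}: no sample with both arms aggregatable and positive"
        )
    return float(np.mean(list(per_sample.values()))), per_sample


def panel_ap_logfc(dataset: RPPADataset) -> pd.DataFrame:
    """Vectorised AP logFC for every antibody at once.

    Applies the same rule as :func:`ap_log_fold_change` (per-sample
    log2(RNFI_AP / RNFI_untreated) over samples with both arms positive,
    then the mean) across the whole panel in one grouped pass.  Antibodies
    with no qualifying sample get NaN.  Returns columns ``antibody_id``,
    ``ap_logfc``, ``n_samples_used``.
    """
    agg = _aggregate_frame(dataset.spots)
    wide = agg.pivot(index=["antibody_id", "sample_id"], columns="treatment", values="rnfi")
    for arm in ("AP", "untreated"):
        if arm not in wide.columns:
            wide[arm] = math.nan
    valid = (wide["AP"] > 0) & (wide["untreated"] > 0)
    logfc = np.log2(wide.loc[valid, "AP"] / wide.loc[valid, "untreated"])
    per_ab = logfc.groupby(level="antibody_id").agg(["mean", "size"])
    out = (
        per_ab.rename(columns={"mean": "ap_logfc", "size": "n_samples_used"})
        .reindex(dataset.antibody_ids)
        .reset_index()
        .rename(columns={"index": "antibody_id"})
    )
    out["n_samples_used"] = out["n_samples_used"].fillna(0).astype(int)
    return out


def compute_all_metrics(
    dataset: RPPADataset,
    *,
    background_floor: float | None = None,
    pseudo_intensity: float | None = None,
) -> tuple[list[QualityMetrics], list[MetricFailure]]:
    """Compute all four factors for every annotated antibody.

    Antibodies failing any metric's preconditions produce an explicit
    :class:`MetricFailure` naming the antibody and the reason, never a silent
    omission.
    """
    metrics: list[QualityMetrics] = []
    failures: list[MetricFailure] = []
    present = set(dataset.spots["antibody_id"])
    for antibody_id in dataset.antibody_ids:
        if antibody_id not in present:
            failures.append(MetricFailure(antibody_id, "no spots in dataset"))
            continue
        try:
            sqf = spot_quality_fraction(dataset, antibody_id)
            snr = signal_to_noise(dataset, antibody_id, background_floor=background_floor)
            lin = dilution_linearity(dataset, antibody_id)
            logfc, per_sample = ap_log_fold_change(
                dataset, antibody_id, pseudo_intensity=pseudo_intensity
            )
        except RppaError as exc:
            failures.append(MetricFailure(antibody_id, str(exc)))
            continue
        metrics.append(
            QualityMetrics(
                antibody_id=antibody_id,
                spot_quality_fraction=sqf,
                snr=snr,
                dilution_linearity=lin,
                ap_logfc=logfc,
                per_sample_logfc=per_sample,
                n_samples_used=len(per_sample),
            )
        )
    return metrics, failures


def metrics_frame(
    metrics: list[QualityMetrics], failures: list[MetricFailure] | None = None
) -> pd.DataFrame:
    """Tabular metrics report (one row per antibody, failures appended)."""
    rows = [
        {
            "antibody_id": m.antibody_id,
            "spot_quality_fraction": m.spot_quality_fraction,
            "snr": m.snr,
            "dilution_linearity": m.dilution_linearity,
            "ap_logfc": m.ap_logfc,
            "n_samples_used": m.n_samples_used,
            "failure_reason": "",
        }
        for m in metrics
    ]
    for f in failures or []:
        rows.append(
            {
                "antibody_id": f.antibody_id,
                "spot_quality_fraction": math.nan,
                "snr": math.nan,
                "dilution_linearity": math.nan,
                "ap_logfc": math.nan,
                "n_samples_used": 0,
                "failure_reason": f.reason,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "antibody_id",
            "spot_quality_fraction",
            "snr",
            "dilution_linearity",
            "ap_logfc",
            "n_samples_used",
            "failure_reason",
        ],
    )
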