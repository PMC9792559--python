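"""Tertile classing, Boolean gates, and the composite 0-12 antibody score.

Each of the four continuous quality factors is converted to a class in
{1, 2, 3} by an equal-frequency (tertile) partition of the panel's values —
higher class means better performance.  Factors 1-3 (spot quality, S/N,
linearity) are better when higher; factor 4 (AP fold reduction) is better
when the log fold change is *lower* (a larger reduction indicates
phospho-specific binding).  The two visual-QC gates — positive-reference
quality (b5) and spot morphology (b6) — are Booleans.  The composite score is

    score = (c1 + c2 + c3 + c4) * b5 * b6

so its range is {0} union {4, ..., 12}, and either failed gate annihilates
the score.  Antibodies are labelled Good when score >= cutoff (default 8).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PanelTooSmallError, ValidationError
from .quality import MetricFailure, QualityMetrics


@dataclass(frozen=True)
class FactorClasses:
    antibody_id: str
    c1: int  # spot-quality fraction class
    c2: int  # signal-to-noise class
    c3: int  # dilution-linearity class
    c4: int  # AP fold-reduction class
    b5: int  # positive-reference gate
    b6: int  # morphology gate


@dataclass(frozen=True)
class AntibodyScore:
    antibody_id: str
    score: int | None  # None when metrics failed
    label: str  # "Good" | "Bad"
    failure_reason: str = ""


@dataclass
class ScoringConfig:
    """Scoring and evaluation settings.

    ``score_cutoff``: composite score at or above which an antibody is Good.
    ``logfc_cutoff``: AP logFC at or below which an antibody passes the
    fold-change selection filter (inclusive).
    """

    score_cutoff: int = 8
    logfc_cutoff: float = -0.792
    tertile_rule: str = "panel_quantile"
    background_floor: float | None = None
    pseudo_intensity: float | None = None
    sweep_cutoffs: tuple[int, ...] = (5, 6, 7, 8)

    def __post_init__(self) -> None:
        if not 0 <= self.score_cutoff <= 12:
            raise ValidationError(f"score_cutoff must be in [0, 12], got {self.score_cutoff}")
        if self.tertile_rule != "panel_quantile":
            raise ValidationError(f"unknown tertile_rule {self.tertile_rule!r}")


def tertile_classes(
    values, better: str = "higher", ids: list[str] | None = None
) -> np.ndarray:
    """Partition a panel's factor values into classes 3 (best) / 2 / 1 (worst).

    The panel is ranked in the direction given by ``better`` and cut at the
    empirical 1/3 and 2/3 quantiles, so class sizes differ by at most one for
    distinct values.  Ties at a boundary are broken by stable input order
    (``ids`` order when given) and resolve toward the lower class.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise PanelTooSmallError(f"need >= 3 values to form tertiles, got {values.size}")
    if not np.all(np.isfinite(values)):
        raise ValidationError("factor values must be finite")
    if better not in ("higher", "lower"):
        raise ValidationError(f"better must be 'higher' or 'lower', got {better!r}")
    goodness = values if better == "higher" else -values
    order = np.argsort(goodness, kind="stable")  # worst first, ties by input order
    n = values.size
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    classes = 1 + (3 * ranks) // n  # rank r -> class 1 + floor(3r/n), in {1,2,3}
    return classes


def composite_score(classes: FactorClasses) -> int:
    """(c1 + c2 + c3 + c4) * b5 * b6, validated."""
    for name in ("c1", "c2", "c3", "c4"):
        c = getattr(classes, name)
        if c not in (1, 2, 3):
            raise ValidationError(f"{name} must be in {{1,2,3}}, got {c}")
    for name in ("b5", "b6"):
        b = getattr(classes, name)
        if b not in (0, 1):
            raise ValidationError(f"{name} must be 0 or 1, got {b}")
    return (classes.c1 + classes.c2 + classes.c3 + classes.c4) * classes.b5 * classes.b6


def classify(score: int, config: ScoringConfig) -> str:
    """Good when score >= cutoff, else Bad (inclusive at the cutoff)."""
    return "Good" if score >= config.score_cutoff else "Bad"


@dataclass
class PanelScores:
    """Classes and scores for a whole panel, plus per-antibody failures."""

    classes: list[FactorClasses] = field(default_factory=list)
    scores: list[AntibodyScore] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        cls_by_id = {c.antibody_id: c for c in self.classes}
        rows = []
        for s in self.scores:
            c = cls_by_id.get(s.antibody_id)
            rows.append(
                {
                    "antibody_id": s.antibody_id,
                    "c1": c.c1 if c else np.nan,
                    "c2": c.c2 if c else np.nan,
                    "c3": c.c3 if c else np.nan,
                    "c4": c.c4 if c else np.nan,
                    "b5": c.b5 if c else np.nan,
                    "b6": c.b6 if c else np.nan,
                    "score": s.score if s.score is not None else np.nan,
                    "label": s.label,
                    "failure_reason": s.failure_reason,
                }
            )
        return pd.DataFrame(rows)


def score_panel(
    metrics: list[QualityMetrics],
    annotations: pd.DataFrame,
    config: ScoringConfig | None = None,
    failures: list[MetricFailure] | None = None,
) -> PanelScores:
    """Score a panel: tertile-class the four factors, apply gates, label.

    Deterministic given inputs and config; antibodies with metric failures are
    labelled Bad with an absent score and the failure reason carried through.
    """
    config = config or ScoringConfig()
    metrics = sorted(metrics, key=lambda m: m.antibody_id)  # stable panel order
    ids = [m.antibody_id for m in metrics]
    ann = annotations.set_index("antibody_id")

    out = PanelScores()
    if metrics:
        c1 = tertile_classes([m.spot_quality_fraction for m in metrics], "higher", ids)
        c2 = tertile_classes([m.snr for m in metrics], "higher", ids)
        c3 = tertile_classes([m.dilution_linearity for m in metrics], "higher", ids)
        # larger AP-induced reduction (more negative logFC) is better
        c4 = tertile_classes([m.ap_logfc for m in metrics], "lower", ids)
        for i, m in enumerate(metrics):
            row = ann.loc[m.antibody_id]
            fc = FactorClasses(
                antibody_id=m.antibody_id,
                c1=int(c1[i]),
                c2=int(c2[i]),
                c3=int(c3[i]),
                c4=int(c4[i]),
                b5=int(bool(row["positive_reference_ok"])),
                b6=int(bool(row["morphology_ok"])),
            )
            score = composite_score(fc)
            out.classes.append(fc)
            out.scores.append(AntibodyScore(m.antibody_id, score, classify(score, config)))
    for f in failures or []:
        out.scores.append(AntibodyScore(f.antibody_id, None, "Bad", f.reason))
    out.scores.sort(key=lambda s: s.antibody_id)
    return out
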