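"""Model/Results facade over the antibody-characterization pipeline.

:class:`AntibodyPanelModel` is built from a paired AP/untreated spot-level
dataset; ``fit()`` runs the whole chain — quality factors, tertile classes,
composite 0-12 scores, Good/Bad labels, the ROC of the AP logFC against those
labels, the Youden operating point, the chi-square association, and the AUC
sweep over candidate score cutoffs — and returns a :class:`PanelResults`
carrying the estimates, diagnostics and a ``summary()`` table.

    >>> from rppaqc import AntibodyPanelModel, make_benchmark_panel
    >>> dataset, truth = make_benchmark_panel("overlap", seed=1)
    >>> results = AntibodyPanelModel(dataset).fit()
    >>> print(results.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedRocError
from .evaluation import (
    ContingencyResult,
    RocResult,
    auc_sweep,
    chi_square_association,
    roc_auc,
    select_antibodies,
)
from .io import RPPADataset, read_spot_table
from .quality import MetricFailure, QualityMetrics, compute_all_metrics, metrics_frame
from .scoring import PanelScores, ScoringConfig, score_panel


class AntibodyPanelModel:
    """The antibody-quality model for one paired AP/untreated RPPA panel.

    Parameters
    ----------
    dataset : RPPADataset
        Validated spot-level data with annotations.
    config : ScoringConfig, optional
        Score cutoff (default 8), logFC cutoff (default -0.792) and numeric
        guards.
    """

    def __init__(self, dataset: RPPADataset, config: ScoringConfig | None = None):
        self.dataset = dataset
        self.config = config or ScoringConfig()

    @classmethod
    def from_csv(
        cls,
        spot_path,
        annotation_path=None,
        config: ScoringConfig | None = None,
        sep: str = ",",
    ) -> "AntibodyPanelModel":
        """Build the model straight from the delimited spot/annotation tables."""
        dataset = read_spot_table(spot_path, annotation_path, sep=sep)
        return cls(dataset, config=config)

    def fit(self) -> "PanelResults":
        """Run the full pipeline and return the results object."""
        cfg = self.config
        metrics, failures = compute_all_metrics(
            self.dataset,
            background_floor=cfg.background_floor,
            pseudo_intensity=cfg.pseudo_intensity,
        )
        panel = score_panel(metrics, self.dataset.annotations, cfg, failures)

        mframe = metrics_frame(metrics, failures)
        sframe = panel.frame()
        merged = mframe.merge(
            sframe[["antibody_id", "score", "label"]], on="antibody_id", how="left"
        )
        scored = merged[merged["failure_reason"] == ""]

        roc: RocResult | None = None
        contingency: ContingencyResult | None = None
        sweep = pd.DataFrame()
        if not scored.empty:
            logfc = scored["ap_logfc"].to_numpy(float)
            labels = scored["label"].to_numpy()
            try:
                roc = roc_auc(logfc, labels)
                contingency = chi_square_association(logfc, labels, cfg.logfc_cutoff)
            except UndefinedRocError:
                roc = None
            sweep = auc_sweep(logfc, scored["score"].to_numpy(float), cfg.sweep_cutoffs)

        return PanelResults(
            model=self,
            metrics=metrics,
            failures=failures,
            panel_scores=panel,
            table=merged,
            roc=roc,
            contingency=contingency,
            sweep=sweep,
        )


@dataclass
class PanelResults:
    """Estimates and diagnostics from :meth:`AntibodyPanelModel.fit`.

    ``table`` holds one row per antibody: the four continuous factors, the
    tertile classes implied score and Good/Bad label (failures carry the
    reason instead).  ``roc``/``contingency``/``sweep`` evaluate the AP logFC
    as a standalone predictor of the label.
    """

    model: AntibodyPanelModel
    metrics: list[QualityMetrics]
    failures: list[MetricFailure]
    panel_scores: PanelScores
    table: pd.DataFrame
    roc: RocResult | None
    contingency: ContingencyResult | None
    sweep: pd.DataFrame = field(default_factory=pd.DataFrame)

    # -- headline numbers --------------------------------------------------

    @property
    def n_antibodies(self) -> int:
        return len(self.table)

    @property
    def n_good(self) -> int:
        return int((self.table["label"] == "Good").sum())

    @property
    def n_bad(self) -> int:
        return int((self.table["label"] == "Bad").sum())

    @property
    def auc(self) -> float:
        return self.roc.auc if self.roc is not None else float("nan")

    @property
    def youden_cutoff(self) -> float:
        return self.roc.youden_cutoff if self.roc is not None else float("nan")

    def selected_antibodies(self, logfc_cutoff: float | None = None) -> list[str]:
        """Antibodies passing the inclusive logFC <= cutoff selection filter."""
        cutoff = self.model.config.logfc_cutoff if logfc_cutoff is None else logfc_cutoff
        ok = self.table[self.table["failure_reason"] == ""]
        return select_antibodies(ok, cutoff)

    # -- presentation --------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table in the spirit of statsmodels results."""
        cfg = self.model.config
        lines = [
            "Antibody panel quality summary",
            "=" * 46,
            f"{'antibodies scored':<32}{len(self.metrics):>14d}",
            f"{'metric failures':<32}{len(self.failures):>14d}",
            f"{'score cutoff (Good >=)':<32}{cfg.score_cutoff:>14d}",
            f"{'Good / Bad':<32}{f'{self.n_good} / {self.n_bad}':>14}",
            f"{'logFC selection cutoff (<=)':<32}{cfg.logfc_cutoff:>14.3f}",
            f"{'antibodies selected':<32}{len(self.selected_antibodies()):>14d}",
        ]
        if self.roc is not None:
            lines += [
                f"{'ROC AUC (logFC vs label)':<32}{self.roc.auc:>14.3f}",
                f"{'Youden logFC cutoff':<32}{self.roc.youden_cutoff:>14.3f}",
            ]
        if self.contingency is not None:
            c = self.contingency
            lines += [
                f"{'chi-square (1 df)':<32}{c.chi2:>14.2f}",
                f"{'chi-square p-value':<32}{c.p_value:>14.3g}",
                f"{'2x2 table [<=cut x Good/Bad]':<32}{str(c.table.tolist()):>14}",
            ]
        if not self.sweep.empty:
            lines.append("-" * 46)
            lines.append("AUC sweep over score cutoffs")
            for _, row in self.sweep.iterrows():
                auc_txt = "undefined" if np.isnan(row["auc"]) else f"{row['auc']:.3f}"
                lines.append(
                    f"  cutoff {int(row['score_cutoff']):>2d}: AUC {auc_txt}"
                    f"  (Good {int(row['n_good'])}, Bad {int(row['n_bad'])})"
                )
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """ROC curve with the Youden operating point marked."""
        if self.roc is None:
            raise UndefinedRocError("no ROC available (single-class labels)")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.roc.fpr, self.roc.tpr, label=f"AUC = {self.roc.auc:.3f}")
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
        j = self.roc.tpr - self.roc.fpr
        k = int(np.argmax(j))
        ax.scatter([self.roc.fpr[k]], [self.roc.tpr[k]], zorder=3,
                   label=f"Youden cutoff = {self.roc.youden_cutoff:.3f}")
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend(loc="lower right")
        return ax
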