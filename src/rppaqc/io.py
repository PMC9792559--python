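"""Spot-level RPPA data model and delimited-text I/O.

A reverse-phase protein array experiment is represented at spot resolution:
each printed spot carries the identity of the array (one antibody per array),
the lysate sample, the treatment arm (alkaline-phosphatase treated or
untreated), the printed dilution fraction of the series, a replicate index,
the relative fluorescence intensity (RFI), the locally estimated background,
and the image-analysis quality flag (``ok``/``poor``).

The on-disk format is a plain delimited table (CSV by default, tab via
``sep``) with one row per spot; antibody annotations (phospho status plus the
two Boolean visual-QC gates) live in a companion table.  Lines starting with
``#`` are treated as comments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGroupError,
    FormatError,
    PairingError,
    ValidationError,
)

TREATMENTS = ("untreated", "AP")
FLAGS = ("ok", "poor")

SPOT_COLUMNS = [
    "array_id",
    "antibody_id",
    "sample_id",
    "treatment",
    "dilution_fraction",
    "replicate",
    "rfi",
    "background",
    "flag",
]

ANNOTATION_COLUMNS = [
    "antibody_id",
    "target_name",
    "is_phospho",
    "positive_reference_ok",
    "morphology_ok",
]


@dataclass(frozen=True)
class SpotMeasurement:
    """One array spot."""

    array_id: str
    antibody_id: str
    sample_id: str
    treatment: str  # "untreated" | "AP"
    dilution_fraction: float  # in (0, 1]; printed series 1.00/0.75/0.50/0.25
    replicate: int
    rfi: float  # relative fluorescence intensity, arbitrary units, >= 0
    background: float  # local background, same units, >= 0
    flag: str = "ok"  # "ok" | "poor"


@dataclass(frozen=True)
class AntibodyAnnotation:
    """Per-antibody metadata: target, phospho status, visual-QC gates."""

    antibody_id: str
    target_name: str
    is_phospho: bool
    positive_reference_ok: bool  # gate b5
    morphology_ok: bool  # gate b6 (graininess / donut effect)


@dataclass(frozen=True)
class AggregatedSignal:
    """Representative background-corrected signal for one (antibody, sample,
    treatment) dilution series, rescaled to the 100%-dilution equivalent."""

    antibody_id: str
    sample_id: str
    treatment: str
    rnfi: float
    n_spots: int


@dataclass
class RPPADataset:
    """Spot table plus annotations for a paired AP/untreated experiment.

    ``spots`` and ``annotations`` are pandas DataFrames with the column sets
    ``SPOT_COLUMNS`` and ``ANNOTATION_COLUMNS``.  Construction validates value
    ranges, annotation coverage, and the paired design (every AP group has an
    untreated partner).
    """

    spots: pd.DataFrame
    annotations: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spots = self.spots.reset_index(drop=True)
        self.annotations = self.annotations.reset_index(drop=True)
        if not self.sample_ids:
            self.sample_ids = list(pd.unique(self.spots["sample_id"].astype(str)))
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        spots, ann = self.spots, self.annotations
        for col in SPOT_COLUMNS:
            if col not in spots.columns:
                raise FormatError(f"spot table is missing required column {col!r}")
        for col in ANNOTATION_COLUMNS:
            if col not in ann.columns:
                raise FormatError(f"annotation table is missing required column {col!r}")

        if ann["antibody_id"].duplicated().any():
            dups = ann.loc[ann["antibody_id"].duplicated(), "antibody_id"].tolist()
            raise ValidationError(f"duplicate antibody_id in annotations: {dups}")

        bad = spots.index[~spots["treatment"].isin(TREATMENTS)]
        if len(bad):
            raise ValidationError(
                f"unknown treatment at row {bad[0]}: {spots.loc[bad[0], 'treatment']!r}"
            )
        bad = spots.index[~spots["flag"].isin(FLAGS)]
        if len(bad):
            raise ValidationError(f"unknown flag at row {bad[0]}: {spots.loc[bad[0], 'flag']!r}")

        for col in ("rfi", "background"):
            vals = spots[col].to_numpy(dtype=float)
            nonfinite = np.flatnonzero(~np.isfinite(vals))
            if nonfinite.size:
                raise ValidationError(f"non-finite {col} at row {nonfinite[0]}")
            negative = np.flatnonzero(vals < 0)
            if negative.size:
                raise ValidationError(f"negative {col} at row {negative[0]}")
        d = spots["dilution_fraction"].to_numpy(dtype=float)
        bad_d = np.flatnonzero((d <= 0) | (d > 1) | ~np.isfinite(d))
        if bad_d.size:
            raise ValidationError(f"dilution_fraction outside (0, 1] at row {bad_d[0]}")

        unknown = set(spots["antibody_id"]) - set(ann["antibody_id"])
        if unknown:
            raise ValidationError(
                f"spots reference antibodies absent from annotations: {sorted(unknown)}"
            )

        # paired design: every AP (antibody, sample) needs an untreated partner
        groups = spots.groupby(["antibody_id", "sample_id"])["treatment"].agg(set)
        orphans = [key for key, arms in groups.items() if arms == {"AP"}]
        if orphans:
            raise PairingError(
                "AP-treated groups without an untreated partner: "
                + ", ".join(f"({a}, {s})" for a, s in sorted(orphans))
            )

    # -- convenience -----------------------------------------------------

    @property
    def antibody_ids(self) -> list[str]:
        return list(self.annotations["antibody_id"])

    def spots_for(self, antibody_id: str) -> pd.DataFrame:
        return self.spots[self.spots["antibody_id"] == antibody_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RPPADataset):
            return NotImplemented
        return (
            self.spots[SPOT_COLUMNS].reset_index(drop=True).equals(
                other.spots[SPOT_COLUMNS].reset_index(drop=True)
            )
            and self.annotations[ANNOTATION_COLUMNS]
            .reset_index(drop=True)
            .equals(other.annotations[ANNOTATION_COLUMNS].reset_index(drop=True))
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_table(path, sep: str, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_spot_table(path, annotation_path=None, *, sep: str = ",") -> RPPADataset:
    """Read a spot table (and annotation table) into a validated dataset.

    Row order is irrelevant; unknown columns are preserved but ignored.
    Raises :class:`FormatError` for missing columns, :class:`ValidationError`
    for out-of-range values (naming the row), and :class:`PairingError` for
    AP groups lacking an untreated partner.
    """
    spots = _read_table(path, sep, SPOT_COLUMNS)
    spots["antibody_id"] = spots["antibody_id"].astype(str)
    spots["sample_id"] = spots["sample_id"].astype(str)
    if annotation_path is not None:
        ann = read_annotation_table(annotation_path, sep=sep)
    else:
        # annotations embedded: derive a permissive default (gates pass)
        ids = pd.unique(spots["antibody_id"])
        ann = pd.DataFrame(
            {
                "antibody_id": ids,
                "target_name": ids,
                "is_phospho": True,
                "positive_reference_ok": True,
                "morphology_ok": True,
            }
        )
    return RPPADataset(spots=spots, annotations=ann)


def read_annotation_table(path, *, sep: str = ",") -> pd.DataFrame:
    ann = _read_table(path, sep, ANNOTATION_COLUMNS)
    ann["antibody_id"] = ann["antibody_id"].astype(str)
    for col in ("is_phospho", "positive_reference_ok", "morphology_ok"):
        ann[col] = ann[col].astype(bool)
    return ann


def _write_csv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def write_spot_table(dataset: RPPADataset, path, annotation_path=None,
                     header_comment: str | None = None) -> None:
    """Write the dataset back to delimited text (missing values as empty fields)."""
    _write_csv(dataset.spots[SPOT_COLUMNS], path, header_comment)
    if annotation_path is not None:
        _write_csv(dataset.annotations[ANNOTATION_COLUMNS], annotation_path, header_comment)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def aggregate_signal(
    dataset: RPPADataset,
    antibody_id: str,
    sample_id: str,
    treatment: str,
    *,
    loading: dict[str, float] | None = None,
) -> AggregatedSignal:
    """Reduce one (antibody, sample, treatment) dilution series to a single RNFI.

    Each ok spot is background-subtracted, clamped at zero, and rescaled to its
    100%-dilution equivalent by dividing by the dilution fraction; the RNFI is
    the mean over ok spots.  Poor spots are excluded, not imputed.  ``loading``
    optionally supplies a per-sample divisor (e.g. SyproRuby total-protein
    loading) applied after aggregation.
    """
    spots = dataset.spots
    mask = (
        (spots["antibody_id"] == antibody_id)
        & (spots["sample_id"] == sample_id)
        & (spots["treatment"] == treatment)
    )
    group = spots[mask]
    ok = group[group["flag"] == "ok"]
    if ok.empty:
        raise DegenerateGroupError(
            f"no ok spots for ({antibody_id}, {sample_id}, {treatment})"
        )
    net = np.maximum(ok["rfi"].to_numpy(float) - ok["background"].to_numpy(float), 0.0)
    rnfi = float(np.mean(net / ok["dilution_fraction"].to_numpy(float)))
    if loading is not None:
        rnfi /= float(loading[sample_id])
    return AggregatedSignal(antibody_id, sample_id, treatment, rnfi, len(ok))


def _aggregate_frame(spots: pd.DataFrame) -> pd.DataFrame:
    """Vectorised ok-spot aggregation over all groups; all-poor groups are NaN."""
    df = spots.copy()
    net = np.maximum(df["rfi"].to_numpy(float) - df["background"].to_numpy(float), 0.0)
    df["_scaled"] = np.where(
        df["flag"].to_numpy() == "ok", net / df["dilution_fraction"].to_numpy(float), np.nan
    )
    out = (
        df.groupby(["antibody_id", "sample_id", "treatment"], sort=False)["_scaled"]
        .mean()
        .rename("rnfi")
        .reset_index()
    )
    return out


def to_paired_matrix(
    dataset: RPPADataset, *, loading: dict[str, float] | None = None
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Side-by-side antibodies x (sample, arm) matrix for both treatment arms.

    Columns are named ``<sample>_<treatment>``; the returned mapping gives
    each column's treatment arm (the grouping used for AP-vs-untreated
    clustering).
    """
    parts = []
    col_groups: dict[str, str] = {}
    for treatment in TREATMENTS:
        mat = to_expression_matrix(dataset, treatment, loading=loading)
        mat = mat.rename(columns={s: f"{s}_{treatment}" for s in mat.columns})
        for c in mat.columns:
            col_groups[c] = treatment
        parts.append(mat)
    return pd.concat(parts, axis=1), col_groups


def to_expression_matrix(
    dataset: RPPADataset,
    treatment: str,
    *,
    loading: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Aggregate to an antibodies x samples RNFI matrix for one treatment arm.

    Groups whose spots are all flagged poor (or absent) appear as NaN, never
    silently as zero.  The result is invariant to the spot-table row order.
    """
    if treatment not in TREATMENTS:
        raise ValidationError(f"unknown treatment {treatment!r}")
    agg = _aggregate_frame(dataset.spots[dataset.spots["treatment"] == treatment])
    mat = agg.pivot(index="antibody_id", columns="sample_id", values="rnfi")
    # canonical sorted axes so the matrix is invariant to spot-table row order
    mat = mat.reindex(index=sorted(dataset.antibody_ids), columns=sorted(dataset.sample_ids))
    mat.index.name = "antibody_id"
    mat.columns.name = "sample_id"
    if loading is not None:
        mat = mat.div(pd.Series(loading).reindex(mat.columns), axis=1)
    return mat
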