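"""Shared fixtures: hand-built spot tables and small synthetic panels."""

from __future__ import annotations

import pandas as pd
import pytest

from rppaqc.io import RPPADataset


def spot(
    antibody="Ab1",
    sample="S1",
    treatment="untreated",
    dilution=1.0,
    replicate=1,
    rfi=10.0,
    background=2.0,
    flag="ok",
    array="A1",
):
    return {
        "array_id": array,
        "antibody_id": antibody,
        "sample_id": sample,
        "treatment": treatment,
        "dilution_fraction": dilution,
        "replicate": replicate,
        "rfi": rfi,
        "background": background,
        "flag": flag,
    }


def build_dataset(rows, annotations=None) -> RPPADataset:
    """Dataset from spot dicts; annotations default to all-pass phospho gates."""
    spots = pd.DataFrame(rows)
    if annotations is None:
        ids = list(pd.unique(spots["antibody_id"])) if len(spots) else []
        annotations = pd.DataFrame(
            {
                "antibody_id": ids,
                "target_name": ids,
                "is_phospho": True,
                "positive_reference_ok": True,
                "morphology_ok": True,
            }
        )
    else:
        annotations = pd.DataFrame(annotations)
    if spots.empty:
        spots = pd.DataFrame(columns=list(spot().keys()))
    return RPPADataset(spots=spots, annotations=annotations)


def paired_series(
    antibody="Ab1",
    samples=("S1",),
    ap_ratio=0.5,
    base=100.0,
    background=0.0,
    dilutions=(1.0, 0.75, 0.5, 0.25),
    replicates=1,
):
    """Noise-free paired AP/untreated dilution series: untreated signal is
    ``base * d``, the AP arm is ``ap_ratio`` times that."""
    rows = []
    for s in samples:
        for d in dilutions:
            for r in range(1, replicates + 1):
                for treatment, scale in (("untreated", 1.0), ("AP", ap_ratio)):
                    rows.append(
                        spot(
                            antibody=antibody,
                            sample=s,
                            treatment=treatment,
                            dilution=d,
                            replicate=r,
                            rfi=base * d * scale + background,
                            background=background,
                        )
                    )
    return rows


@pytest.fixture
def toy_paired_dataset() -> RPPADataset:
    """One antibody, two samples, clean half-signal under AP."""
    return build_dataset(paired_series(samples=("S1", "S2")))


@pytest.fixture(scope="session")
def small_clean_panel():
    """A small, fully separable synthetic panel (fast to generate)."""
    from rppaqc.simulate import make_benchmark_panel

    return make_benchmark_panel("clean", seed=7, n_phospho=20, n_total=3)


@pytest.fixture(scope="session")
def overlap_panel():
    """Default benchmark composition: 106 phospho + 7 total antibodies."""
    from rppaqc.simulate import make_benchmark_panel

    return make_benchmark_panel("overlap", seed=11)
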