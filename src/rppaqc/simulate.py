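"""Generative model of paired AP/untreated RPPA experiments.

Each antibody sees a per-sample analyte amount; alkaline phosphatase removes
the phospho-epitope from a fraction ``phi * rho`` of it (``phi`` the phospho
signal fraction the antibody depends on, ``rho`` the AP removal efficiency),
acting as a deterministic bulk reaction because the lysate is treated before
printing.  A spot's relative fluorescence is

    rfi = L_s * A * d * m * eps + B * eta

with ``L_s`` the per-sample loading, ``A`` the antibody's amplitude, ``d`` the
printed dilution fraction, ``m = 1`` untreated and ``m = 1 - phi * rho`` under
AP, ``eps`` multiplicative lognormal noise (mean 1, CV ``noise_cv``; array
intensities are positive and right-skewed), and an additive background of
level ``B`` with its own lognormal noise.  The recorded local background is an
independent draw of the same background process.  Poor-spot flags are
Bernoulli per spot; the two visual-QC gates are Bernoulli once per antibody,
independent of the continuous quality, so gate annihilation is exercised.

The closed-form expectation ``log2(1 - phi * rho)`` for the AP log fold
change is the recovery oracle for the whole pipeline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import RPPADataset


@dataclass
class AntibodyParams:
    """Generative parameters for one antibody."""

    antibody_id: str
    target_name: str = ""
    is_phospho: bool = True
    phospho_fraction: float = 0.9  # phi, fraction of signal from the phospho-epitope
    ap_efficiency: float = 0.9  # rho, fraction of phosphates AP removes
    amplitude: float = 1000.0  # A, arbitrary fluorescence units at 100% dilution
    noise_cv: float = 0.1  # multiplicative spot noise CV
    p_poor: float = 0.0  # per-spot poor-flag probability
    gate_defect_prob: float = 0.0  # per-gate Bernoulli defect probability
    b5: int | None = None  # explicit gates; None -> drawn from gate_defect_prob
    b6: int | None = None
    true_label: str | None = None  # None -> derived (see GroundTruth)
    latent_quality: float = math.nan

    def validate(self) -> None:
        for name in ("phospho_fraction", "ap_efficiency", "p_poor", "gate_defect_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1 or (name == "p_poor" and v >= 1):
                raise ValidationError(f"{self.antibody_id}: {name}={v} out of range")
        if self.amplitude <= 0:
            raise ValidationError(f"{self.antibody_id}: amplitude must be positive")
        if self.noise_cv < 0:
            raise ValidationError(f"{self.antibody_id}: noise_cv must be >= 0")

    @property
    def effect(self) -> float:
        """phi * rho, the AP-removable signal fraction (0 for total antibodies)."""
        return 0.0 if not self.is_phospho else self.phospho_fraction * self.ap_efficiency


@dataclass
class SimulationConfig:
    """Experiment-level generative settings (defaults mirror the study design:
    8 samples, a 100/75/50/25% dilution series, duplicate spots)."""

    antibodies: list[AntibodyParams] = field(default_factory=list)
    n_samples: int = 8
    dilution_series: tuple[float, ...] = (1.0, 0.75, 0.50, 0.25)
    replicates: int = 2
    loading_cv: float = 0.2  # per-sample loading L_s lognormal CV
    background_level: float = 20.0  # B, arbitrary units
    background_cv: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if not self.antibodies:
            raise ValidationError("config needs at least one antibody")
        if self.n_samples < 1 or self.replicates < 1:
            raise ValidationError("n_samples and replicates must be positive")
        if any(not 0 < d <= 1 for d in self.dilution_series):
            raise ValidationError("dilution fractions must lie in (0, 1]")
        if self.background_level < 0 or self.background_cv < 0 or self.loading_cv < 0:
            raise ValidationError("background and loading parameters must be >= 0")
        for ab in self.antibodies:
            ab.validate()


def expected_logfc(phospho_fraction: float, ap_efficiency: float) -> float:
    """Closed-form AP log fold change: log2(1 - phi * rho).

    A product of exactly 1 yields a -inf sentinel with an explicit warning.
    """
    if not (0 <= phospho_fraction <= 1 and 0 <= ap_efficiency <= 1):
        raise ValidationError("phospho_fraction and ap_efficiency must be in [0, 1]")
    effect = phospho_fraction * ap_efficiency
    if effect == 1:
        warnings.warn("phi * rho == 1: AP arm is fully extinguished (logFC = -inf)", stacklevel=2)
        return float("-inf")
    return float(np.log2(1.0 - effect))


def _lognormal(rng: np.random.Generator, cv, shape) -> np.ndarray:
    """Mean-1 lognormal noise with the given coefficient of variation."""
    cv = np.asarray(cv, dtype=float)
    sigma = np.sqrt(np.log1p(cv**2))
    z = rng.standard_normal(shape)
    return np.exp(z * sigma - sigma**2 / 2.0)


def generate_dataset(config: SimulationConfig) -> tuple[RPPADataset, pd.DataFrame]:
    """Draw one experiment; fully reproducible from ``config.seed``.

    Returns the validated spot-level dataset plus a ground-truth table with
    one row per antibody: phi, rho, true_logfc = log2(1 - phi*rho), the gates
    as drawn, and the true Good/Bad label.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    abs_ = config.antibodies
    n_ab = len(abs_)
    n_s = config.n_samples
    dil = np.asarray(config.dilution_series, dtype=float)
    n_d = dil.size
    n_r = config.replicates

    effects = np.array([ab.effect for ab in abs_])
    if np.any(effects >= 1.0) and config.background_level == 0:
        warnings.warn("phi*rho = 1 with zero background: degenerate AP arm", stacklevel=2)

    sample_ids = [f"S{i + 1}" for i in range(n_s)]
    loading = _lognormal(rng, config.loading_cv, n_s) if config.loading_cv > 0 else np.ones(n_s)

    # gates: explicit when provided, else one Bernoulli draw per antibody/gate
    gate_p = np.array([ab.gate_defect_prob for ab in abs_])
    b5 = np.array(
        [ab.b5 if ab.b5 is not None else -1 for ab in abs_], dtype=int
    )
    b6 = np.array([ab.b6 if ab.b6 is not None else -1 for ab in abs_], dtype=int)
    draw5 = (rng.random(n_ab) >= gate_p).astype(int)
    draw6 = (rng.random(n_ab) >= gate_p).astype(int)
    b5 = np.where(b5 < 0, draw5, b5)
    b6 = np.where(b6 < 0, draw6, b6)

    shape = (n_ab, n_s, 2, n_d, n_r)  # antibody, sample, arm (0=untreated,1=AP), dilution, rep
    amp = np.array([ab.amplitude for ab in abs_])[:, None, None, None, None]
    cv = np.array([ab.noise_cv for ab in abs_])[:, None, None, None, None]
    p_poor = np.array([ab.p_poor for ab in abs_])[:, None, None, None, None]
    m = np.stack([np.ones(n_ab), 1.0 - effects], axis=1)[:, None, :, None, None]
    L = loading[None, :, None, None, None]
    d = dil[None, None, None, :, None]

    eps = _lognormal(rng, np.broadcast_to(cv, shape), shape)
    B = config.background_level
    eta1 = _lognormal(rng, config.background_cv, shape) if B > 0 else np.zeros(shape)
    eta2 = _lognormal(rng, config.background_cv, shape) if B > 0 else np.zeros(shape)
    rfi = L * amp * d * m * eps + B * eta1
    background = B * eta2
    poor = rng.random(shape) < p_poor

    idx = np.indices(shape)
    ab_i, s_i, arm_i, d_i, r_i = (a.ravel() for a in idx)
    ab_ids = np.array([ab.antibody_id for ab in abs_])
    spots = pd.DataFrame(
        {
            "array_id": np.array([f"A{i + 1:03d}" for i in range(n_ab)])[ab_i],
            "antibody_id": ab_ids[ab_i],
            "sample_id": np.array(sample_ids)[s_i],
            "treatment": np.array(["untreated", "AP"])[arm_i],
            "dilution_fraction": dil[d_i],
            "replicate": r_i + 1,
            "rfi": rfi.ravel(),
            "background": background.ravel(),
            "flag": np.where(poor.ravel(), "poor", "ok"),
        }
    )

    annotations = pd.DataFrame(
        {
            "antibody_id": [ab.antibody_id for ab in abs_],
            "target_name": [ab.target_name or ab.antibody_id for ab in abs_],
            "is_phospho": [ab.is_phospho for ab in abs_],
            "positive_reference_ok": b5.astype(bool),
            "morphology_ok": b6.astype(bool),
        }
    )

    true_logfc = np.where(effects < 1, np.log2(np.maximum(1.0 - effects, 1e-300)), -np.inf)
    labels = []
    for ab, g5, g6 in zip(abs_, b5, b6):
        if ab.true_label is not None:
            labels.append(ab.true_label if g5 and g6 else "Bad")
        else:
            ok_effect = ab.effect >= 0.5 if ab.is_phospho else True
            labels.append("Good" if (g5 and g6 and ok_effect) else "Bad")

    truth = pd.DataFrame(
        {
            "antibody_id": [ab.antibody_id for ab in abs_],
            "is_phospho": [ab.is_phospho for ab in abs_],
            "phi": [ab.phospho_fraction if ab.is_phospho else 0.0 for ab in abs_],
            "rho": [ab.ap_efficiency if ab.is_phospho else 0.0 for ab in abs_],
            "true_logfc": true_logfc,
            "true_label": labels,
            "b5": b5,
            "b6": b6,
            "latent_quality": [ab.latent_quality for ab in abs_],
        }
    )
    dataset = RPPADataset(spots=spots, annotations=annotations, sample_ids=sample_ids)
    return dataset, truth


# ---------------------------------------------------------------------------
# benchmark presets
# ---------------------------------------------------------------------------

PRESETS = ("overlap", "clean", "separation")


def benchmark_config(
    preset: str = "overlap",
    seed: int = 0,
    n_phospho: int = 106,
    n_total: int = 7,
    n_samples: int = 8,
    noise_cv: float = 0.1,
) -> SimulationConfig:
    """Build the generative config for a named benchmark panel.

    ``overlap`` (default) mimics a realistic screening panel: a latent
    antibody quality q ~ U(0,1) drives the AP effect phi*rho =
    clip(0.15 + 0.8 q + N(0, 0.15)), the amplitude, and the poor-spot rate,
    with independent 8%-defect visual gates; the true label is q >= 0.5 with
    both gates intact, so the logFC/label relation is strong but overlapping.
    ``clean`` separates Good and Bad effects completely (AUC 1 by
    construction).  ``separation`` gives every phospho antibody phi*rho >=
    0.6, the regime in which AP and untreated arms cluster apart.
    """
    if preset not in PRESETS:
        raise ValidationError(f"unknown preset {preset!r}; choose from {PRESETS}")
    rng = np.random.default_rng(seed)
    antibodies: list[AntibodyParams] = []

    def _amplitude(q: float) -> float:
        qa = float(np.clip(q + rng.normal(0, 0.2), 0, 1))
        return 300.0 + 1700.0 * qa

    for i in range(n_phospho):
        name = f"pAb{i + 1:03d}"
        if preset == "overlap":
            q = float(rng.uniform(0, 1))
            rho = float(rng.uniform(0.85, 0.99))
            e = float(np.clip(0.15 + 0.8 * q + rng.normal(0, 0.15), 0.01, 0.97))
            e = min(e, rho * 0.995)
            qpp = float(np.clip(q + rng.normal(0, 0.2), 0, 1))
            antibodies.append(
                AntibodyParams(
                    antibody_id=name,
                    is_phospho=True,
                    phospho_fraction=e / rho,
                    ap_efficiency=rho,
                    amplitude=_amplitude(q),
                    noise_cv=noise_cv,
                    p_poor=0.02 + 0.2 * (1 - qpp),
                    gate_defect_prob=0.08,
                    true_label="Good" if q >= 0.5 else "Bad",
                    latent_quality=q,
                )
            )
        elif preset == "clean":
            good = i < n_phospho // 2
            e = float(rng.uniform(0.7, 0.9)) if good else float(rng.uniform(0.05, 0.35))
            q = float(rng.uniform(0.75, 1.0)) if good else float(rng.uniform(0.0, 0.25))
            antibodies.append(
                AntibodyParams(
                    antibody_id=name,
                    is_phospho=True,
                    phospho_fraction=e / 0.95,
                    ap_efficiency=0.95,
                    amplitude=_amplitude(q),
                    noise_cv=noise_cv,
                    p_poor=0.02,
                    b5=1,
                    b6=1,
                    true_label="Good" if good else "Bad",
                    latent_quality=q,
                )
            )
        else:  # separation
            e = float(rng.uniform(0.6, 0.95))
            antibodies.append(
                AntibodyParams(
                    antibody_id=name,
                    is_phospho=True,
                    phospho_fraction=e / 0.95,
                    ap_efficiency=0.95,
                    amplitude=float(rng.uniform(500, 2000)),
                    noise_cv=noise_cv,
                    p_poor=0.02,
                    b5=1,
                    b6=1,
                    latent_quality=e,
                )
            )

    for i in range(n_total):
        name = f"tAb{i + 1:02d}"
        q = float(rng.uniform(0.6, 1.0))
        antibodies.append(
            AntibodyParams(
                antibody_id=name,
                is_phospho=False,
                phospho_fraction=0.0,
                ap_efficiency=0.0,
                amplitude=_amplitude(q),
                noise_cv=noise_cv,
                p_poor=0.02,
                gate_defect_prob=0.08 if preset == "overlap" else 0.0,
                b5=None if preset == "overlap" else 1,
                b6=None if preset == "overlap" else 1,
                true_label="Good",
                latent_quality=q,
            )
        )

    return SimulationConfig(
        antibodies=antibodies,
        n_samples=n_samples,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def make_benchmark_panel(
    preset: str = "overlap", seed: int = 0, **kwargs
) -> tuple[RPPADataset, pd.DataFrame]:
    """Generate a seeded benchmark panel (default: 106 phospho + 7 total
    antibodies across 8 samples, mixed quality with overlapping logFC
    distributions)."""
    config = benchmark_config(preset, seed=seed, **kwargs)
    return generate_dataset(config)


def rescale_noise(config: SimulationConfig, noise_cv: float) -> SimulationConfig:
    """A copy of the config with every antibody's noise CV replaced."""
    return replace(
        config, antibodies=[replace(ab, noise_cv=noise_cv) for ab in config.antibodies]
    )
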