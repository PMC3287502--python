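"""Seeded synthetic fixtures with planted ground truth.

The generator emulates the structure of a two-class breast-cancer microarray
cohort: a binary endpoint with class imbalance (default positive fraction
0.25, echoing a 33/130 split), *informative* probes whose class-conditional
Gaussian means differ by a chosen effect size (in pooled-SD units),
*redundant* probes correlated rho with an informative probe, pure *noise*
probes, and additive per-(batch, probe) offsets modelling array-generation
batch effects.  A companion generator draws signature collections over that
ground truth, as if several analysis teams had each reported a probe list.

Gaussian class-conditional intensities keep classifier behaviour
predictable; real microarray noise is heavier-tailed, so recovery rates
measured here are optimistic relative to real cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataset import (
    LabeledExpressionDataset,
    Signature,
    SignatureCollection,
    ValidationError,
)

ROLE_INFORMATIVE = "informative"
ROLE_REDUNDANT = "redundant"
ROLE_NOISE = "noise"


@dataclass
class FixtureSpec:
    """Shape and strength parameters of one synthetic cohort."""

    n_samples: int = 130
    positive_fraction: float = 0.25
    n_informative: int = 5
    effect_size: float = 2.0
    n_redundant: int = 0
    redundancy_rho: float = 0.8
    n_noise: int = 20
    n_batches: int = 1
    batch_shift_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValidationError("need at least 4 samples")
        if not 0 < self.positive_fraction < 1:
            raise ValidationError("positive_fraction must lie in (0, 1)")
        for f in ("n_informative", "n_redundant", "n_noise"):
            if getattr(self, f) < 0:
                raise ValidationError(f"{f} must be >= 0")
        if self.n_informative + self.n_redundant + self.n_noise < 1:
            raise ValidationError("at least one probe required")
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ValidationError("redundant probes need an informative parent")
        if not 0 <= self.redundancy_rho <= 1:
            raise ValidationError("redundancy_rho must lie in [0, 1]")
        if self.n_batches < 1:
            raise ValidationError("n_batches must be >= 1")


def generate_dataset(
    spec: FixtureSpec,
) -> tuple[LabeledExpressionDataset, dict[str, str]]:
    """Draw one cohort; returns (dataset, probe -> role ground truth)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    n_pos = max(1, min(n - 1, int(round(spec.positive_fraction * n))))
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    rng.shuffle(y)

    probe_ids: list[str] = []
    roles: dict[str, str] = {}
    cols: list[np.ndarray] = []

    informative_cols: list[np.ndarray] = []
    for i in range(spec.n_informative):
        pid = f"inf_{i:03d}"
        base = rng.normal(0.0, 1.0, size=n)
        col = base + spec.effect_size * y
        probe_ids.append(pid)
        roles[pid] = ROLE_INFORMATIVE
        cols.append(col)
        informative_cols.append(col)
    for i in range(spec.n_redundant):
        pid = f"red_{i:03d}"
        parent = informative_cols[i % spec.n_informative]
        rho = spec.redundancy_rho
        col = rho * parent + np.sqrt(1 - rho**2) * rng.normal(0.0, 1.0, size=n)
        probe_ids.append(pid)
        roles[pid] = ROLE_REDUNDANT
        cols.append(col)
    for i in range(spec.n_noise):
        pid = f"noise_{i:03d}"
        probe_ids.append(pid)
        roles[pid] = ROLE_NOISE
        cols.append(rng.normal(0.0, 1.0, size=n))

    values = np.column_stack(cols)

    batch = None
    if spec.n_batches > 1 or spec.batch_shift_sd > 0:
        assign = rng.integers(0, spec.n_batches, size=n)
        batch = [f"b{b}" for b in assign]
        offsets = rng.normal(
            0.0, spec.batch_shift_sd, size=(spec.n_batches, len(probe_ids))
        )
        values = values + offsets[assign]

    labels = ["pos" if v == 1 else "neg" for v in y]
    ds = LabeledExpressionDataset(
        sample_ids=[f"s{i:03d}" for i in range(n)],
        probe_ids=probe_ids,
        values=values,
        labels=labels,
        positive_class="pos",
        batch=batch,
    )
    return ds, roles


@dataclass
class SignatureCollectionSpec:
    """How many mock models to draw and how faithfully each reports probes."""

    n_models: int = 20
    hit_rate: float = 0.8
    noise_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValidationError("n_models must be >= 1")
        for f in ("hit_rate", "noise_rate"):
            if not 0 <= getattr(self, f) <= 1:
                raise ValidationError(f"{f} must lie in [0, 1]")


def generate_signature_collection(
    truth: dict[str, str],
    spec: SignatureCollectionSpec,
    endpoint_id: str = "synthetic",
) -> SignatureCollection:
    """Draw mock submitted signatures over a ground-truth probe-role map.

    Each model independently includes each informative (and redundant) probe
    with probability ``hit_rate`` and each noise probe with probability
    ``noise_rate``; an empty draw is resampled with a warning.
    """
    rng = np.random.default_rng(spec.seed)
    signal = sorted(
        p for p, r in truth.items() if r in (ROLE_INFORMATIVE, ROLE_REDUNDANT)
    )
    noise = sorted(p for p, r in truth.items() if r == ROLE_NOISE)
    sigs = []
    for m in range(spec.n_models):
        probes: list[str] = []
        for _ in range(100):  # resample guard
            probes = [p for p in signal if rng.random() < spec.hit_rate]
            probes += [p for p in noise if rng.random() < spec.noise_rate]
            if probes:
                break
            warnings.warn(f"model {m}: empty draw resampled", stacklevel=2)
        if not probes:
            probes = signal[:1] or noise[:1]
        sigs.append(
            Signature(
                model_id=f"model_{m:03d}",
                endpoint_id=endpoint_id,
                probes=probes,
            )
        )
    return SignatureCollection(endpoint_id=endpoint_id, signatures=sigs)
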