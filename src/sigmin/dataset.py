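"""Core data containers for labeled expression matrices and gene signatures.

A :class:`LabeledExpressionDataset` is a samples x probes real-valued matrix
with a binary endpoint label per sample and an optional categorical batch
label (e.g. the array generation a sample was hybridized on).  Probe
identifiers are opaque, case-sensitive strings; an Affymetrix-style id such
as ``"205225_at"`` carries no special meaning here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


@dataclass
class LabeledExpressionDataset:
    """Expression matrix with binary endpoint labels.

    Parameters
    ----------
    sample_ids : sequence of str
        Unique sample identifiers, ordered as the matrix rows.
    probe_ids : sequence of str
        Unique probe identifiers, ordered as the matrix columns.
    values : ndarray of shape (n_samples, n_probes)
        Expression intensities on any consistent scale.
    labels : sequence of str
        Endpoint status per sample; exactly two distinct classes overall.
    positive_class : str
        Which label value counts as the positive endpoint outcome.
    batch : sequence of str, optional
        Batch label per sample; if given must cover every sample.
    """

    sample_ids: list[str]
    probe_ids: list[str]
    values: np.ndarray
    labels: list[str]
    positive_class: str
    batch: list[str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.labels = [str(l) for l in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        if self.batch is not None:
            self.batch = [str(b) for b in self.batch]
        self._validate()

    def _validate(self) -> None:
        n, p = len(self.sample_ids), len(self.probe_ids)
        if self.values.shape != (n, p):
            raise ValidationError(
                f"matrix shape {self.values.shape} != ({n}, {p})"
            )
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample identifiers")
        if len(set(self.probe_ids)) != p:
            raise ValidationError("duplicate probe identifiers")
        if len(self.labels) != n:
            raise ValidationError("one label required per sample")
        classes = sorted(set(self.labels))
        if len(classes) > 2:
            raise ValidationError(f"label is not binary: classes {classes}")
        if self.positive_class not in classes and n > 0:
            raise ValidationError(
                f"positive class {self.positive_class!r} absent from labels"
            )
        if np.isnan(self.values).any():
            raise ValidationError("missing expression values are not supported")
        if self.batch is not None and len(self.batch) != n:
            raise ValidationError("batch labels must cover every sample")

    # -- basic views -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def y(self) -> np.ndarray:
        """Labels as a 0/1 vector (1 = positive class)."""
        return np.array([1 if l == self.positive_class else 0 for l in self.labels])

    def has_both_classes(self) -> bool:
        return len(set(self.labels)) == 2

    def probe_index(self, probes: Sequence[str]) -> np.ndarray:
        pos = {p: i for i, p in enumerate(self.probe_ids)}
        idx = []
        for p in probes:
            if p not in pos:
                raise KeyError(f"probe {p!r} not in dataset")
            idx.append(pos[p])
        return np.asarray(idx, dtype=int)

    def equals(self, other: "LabeledExpressionDataset") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.probe_ids == other.probe_ids
            and self.labels == other.labels
            and self.batch == other.batch
            and self.positive_class == other.positive_class
            and np.array_equal(self.values, other.values)
        )


def subset_features(
    ds: LabeledExpressionDataset, probes: Sequence[str]
) -> LabeledExpressionDataset:
    """Column-subset a dataset to ``probes``, preserving sample order.

    Raises :class:`KeyError` naming the first probe absent from the dataset.
    """
    idx = ds.probe_index(probes)
    return LabeledExpressionDataset(
        sample_ids=list(ds.sample_ids),
        probe_ids=[ds.probe_ids[i] for i in idx],
        values=ds.values[:, idx].copy(),
        labels=list(ds.labels),
        positive_class=ds.positive_class,
        batch=list(ds.batch) if ds.batch is not None else None,
    )


@dataclass
class Signature:
    """One model's probe list with optional weights and performance metadata."""

    model_id: str
    endpoint_id: str
    probes: list[str]
    weights: list[float] | None = None
    metadata: dict = field(default_factory=dict)
    n_duplicates_collapsed: int = 0

    def __post_init__(self) -> None:
        if not self.probes:
            raise ValidationError(f"signature {self.model_id!r} has no probes")
        seen: dict[str, None] = {}
        dupes = 0
        kept_w: list[float] = []
        if self.weights is not None and len(self.weights) != len(self.probes):
            raise ValidationError(
                f"signature {self.model_id!r}: {len(self.weights)} weights "
                f"for {len(self.probes)} probes"
            )
        for i, p in enumerate(self.probes):
            if p in seen:
                dupes += 1
                continue
            seen[p] = None
            if self.weights is not None:
                kept_w.append(self.weights[i])
        if dupes:
            self.probes = list(seen)
            if self.weights is not None:
                self.weights = kept_w
            self.n_duplicates_collapsed += dupes
        if self.weights is not None and any(w < 0 for w in self.weights):
            raise ValidationError(
                f"signature {self.model_id!r} has negative probe weights"
            )

    @property
    def probe_set(self) -> frozenset[str]:
        return frozenset(self.probes)

    def __len__(self) -> int:
        return len(self.probes)


@dataclass
class SignatureCollection:
    """All signatures submitted for one clinical endpoint."""

    endpoint_id: str
    signatures: list[Signature]
    n_discarded: int = 0

    def __post_init__(self) -> None:
        ids = [s.model_id for s in self.signatures]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate model_id in collection")
        for s in self.signatures:
            if s.endpoint_id != self.endpoint_id:
                raise ValidationError(
                    f"signature {s.model_id!r} endpoint {s.endpoint_id!r} "
                    f"!= collection endpoint {self.endpoint_id!r}"
                )

    def __len__(self) -> int:
        return len(self.signatures)

    def __iter__(self):
        return iter(self.signatures)

    def model_ids(self) -> list[str]:
        return [s.model_id for s in self.signatures]

    def get(self, model_id: str) -> Signature:
        for s in self.signatures:
            if s.model_id == model_id:
                return s
        raise KeyError(model_id)


# Gene classes an annotation entry may carry.  Pseudogenes and hypothetical
# genes are excluded during probe->gene mapping; alias-group members are
# collapsed to a single symbol.
GENE_CLASSES = ("protein-coding", "pseudogene", "hypothetical", "alias-group")


@dataclass
class AnnotationMap:
    """Probe -> [(gene symbol, gene class)] platform annotation."""

    entries: Mapping[str, list[tuple[str, str]]]

    def __post_init__(self) -> None:
        for probe, genes in self.entries.items():
            for _, cls in genes:
                if cls not in GENE_CLASSES:
                    raise ValidationError(
                        f"probe {probe!r}: unknown gene class {cls!r}"
                    )

    def get(self, probe: str) -> list[tuple[str, str]]:
        return list(self.entries.get(probe, []))

    def __contains__(self, probe: str) -> bool:
        return probe in self.entries
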