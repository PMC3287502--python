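"""Multi-signature similarity analysis at probe and gene level.

Given the signature collections that many analysis teams submitted for one
endpoint, these operations build pairwise overlap matrices, probe support
(frequency) tables, support-thresholded consensus sets ("identified by at
least two sources"), weighted merges of signature probe lists, and the
common/unique partition of two endpoints' consensus sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from .dataset import AnnotationMap, SignatureCollection, ValidationError


@dataclass
class OverlapMatrix:
    """Pairwise probe-intersection counts between signatures."""

    model_ids: list[str]
    counts: np.ndarray  # square, symmetric; diagonal = signature sizes

    def as_dict(self) -> dict[tuple[str, str], int]:
        return {
            (a, b): int(self.counts[i, j])
            for i, a in enumerate(self.model_ids)
            for j, b in enumerate(self.model_ids)
        }


@dataclass
class FrequencyTable:
    """Probe (or gene) -> number of supporting signatures/occurrences."""

    support: dict[str, int]

    def ranked(self) -> list[tuple[str, int]]:
        """Descending support, ties broken lexicographically by id."""
        return sorted(self.support.items(), key=lambda kv: (-kv[1], kv[0]))

    def max_support(self) -> int:
        return max(self.support.values()) if self.support else 0


@dataclass
class PartitionSummary:
    """Common/unique split of two endpoints' consensus sets."""

    common: frozenset[str]
    unique_a: frozenset[str]
    unique_b: frozenset[str]

    @property
    def union_size(self) -> int:
        return len(self.common) + len(self.unique_a) + len(self.unique_b)

    @property
    def percentages(self) -> tuple[float, float, float]:
        """(common %, unique-A %, unique-B %) of the union, 2 decimals."""
        n = self.union_size
        return (
            round_percent(len(self.common), n),
            round_percent(len(self.unique_a), n),
            round_percent(len(self.unique_b), n),
        )


def round_percent(part: int, whole: int) -> float:
    """100*part/whole rounded half-up to 2 decimals (report convention)."""
    if whole == 0:
        raise ValidationError("cannot take a percentage of an empty whole")
    pct = Decimal(100 * part) / Decimal(whole)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def overlap_matrix(coll: SignatureCollection) -> OverlapMatrix:
    """All pairwise probe intersections; diagonal holds signature sizes."""
    if len(coll) < 2:
        raise ValidationError("overlap matrix needs at least 2 signatures")
    sets = [s.probe_set for s in coll]
    n = len(sets)
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        counts[i, i] = len(sets[i])
        for j in range(i + 1, n):
            counts[i, j] = counts[j, i] = len(sets[i] & sets[j])
    return OverlapMatrix(model_ids=coll.model_ids(), counts=counts)


def probe_frequency(coll: SignatureCollection) -> FrequencyTable:
    """Number of signatures containing each probe."""
    if len(coll) == 0:
        raise ValidationError("empty signature collection")
    support: dict[str, int] = {}
    for sig in coll:
        for p in sig.probe_set:
            support[p] = support.get(p, 0) + 1
    return FrequencyTable(support=support)


def gene_frequency(
    coll: SignatureCollection, ann: AnnotationMap, policy: str = "exclude"
) -> FrequencyTable:
    """Gene -> total probe occurrences across signatures.

    A gene is counted once per probe per signature: several probes of the
    same gene inside one signature each contribute.
    """
    support: dict[str, int] = {}
    for sig in coll:
        for p in sig.probe_set:
            genes, _ = map_probes_to_genes([p], ann, policy=policy)
            for g in genes:
                support[g] = support.get(g, 0) + 1
    return FrequencyTable(support=support)


def consensus_set(freq: FrequencyTable, min_support: int = 2) -> frozenset[str]:
    """Probes supported by at least ``min_support`` signatures."""
    if min_support < 1:
        raise ValidationError("min_support must be >= 1")
    out = frozenset(p for p, s in freq.support.items() if s >= min_support)
    if not out:
        warnings.warn(
            f"consensus at min_support={min_support} is empty", stacklevel=2
        )
    return out


def overlap_rate(total: int, overlapped: int) -> float:
    """Overlapped share of the total probe/gene pool, in %, 2 decimals."""
    if total <= 0:
        raise ValidationError("total must be positive")
    if not 0 <= overlapped <= total:
        raise ValidationError("overlapped must lie in [0, total]")
    return round_percent(overlapped, total)


def weighted_merge(
    coll: SignatureCollection, weights: Mapping[str, float]
) -> list[tuple[str, float]]:
    """Merge signature probe lists into one weighted set.

    Each probe's weight is the sum of the weights of the signatures that
    contain it (a signature's weight is typically its MCC-robustness).
    Output is sorted by weight descending, ties lexicographic by probe id.
    """
    for mid in coll.model_ids():
        if mid not in weights:
            raise ValidationError(f"no weight for model {mid!r}")
        if weights[mid] < 0:
            raise ValidationError(f"negative weight for model {mid!r}")
    acc: dict[str, float] = {}
    for sig in coll:
        w = float(weights[sig.model_id])
        for p in sig.probe_set:
            acc[p] = acc.get(p, 0.0) + w
    return sorted(acc.items(), key=lambda kv: (-kv[1], kv[0]))


def endpoint_partition(
    set_a: frozenset[str] | set[str],
    set_b: frozenset[str] | set[str],
) -> PartitionSummary:
    """Partition the union of two endpoints' consensus sets.

    Returns the probes/genes common to both endpoints and those unique to
    each, with each block's share of the union.
    """
    a, b = frozenset(set_a), frozenset(set_b)
    if not a | b:
        raise ValidationError("both endpoint sets are empty")
    return PartitionSummary(
        common=a & b, unique_a=a - b, unique_b=b - a
    )


def endpoint_partition_from_collections(
    coll_a: SignatureCollection,
    coll_b: SignatureCollection,
    min_support_a: int = 2,
    min_support_b: int = 2,
    level: str = "probe",
    ann: AnnotationMap | None = None,
    policy: str = "exclude",
) -> PartitionSummary:
    """Consensus each collection, optionally map to genes, then partition."""
    set_a = consensus_set(probe_frequency(coll_a), min_support_a)
    set_b = consensus_set(probe_frequency(coll_b), min_support_b)
    if level == "gene":
        if ann is None:
            raise ValidationError("gene-level partition requires an annotation map")
        set_a, _ = map_probes_to_genes(sorted(set_a), ann, policy=policy)
        set_b, _ = map_probes_to_genes(sorted(set_b), ann, policy=policy)
    elif level != "probe":
        raise ValidationError(f"unknown level {level!r}")
    return endpoint_partition(set_a, set_b)


def map_probes_to_genes(
    probes: Sequence[str],
    ann: AnnotationMap,
    policy: str = "exclude",
) -> tuple[frozenset[str], dict[str, list[str]]]:
    """Map probes to gene symbols under the exclusion rules.

    Pseudogenes and hypothetical genes are dropped.  A probe whose genes are
    all alias-group members is collapsed to the first-listed symbol.  A probe
    left with several distinct genes is handled per ``policy``: ``"exclude"``
    drops it (default), ``"first"`` keeps the first-listed gene.  Unannotated
    probes and every exclusion are returned in the ambiguity report.
    """
    if policy not in ("exclude", "first"):
        raise ValidationError(f"unknown multi-gene policy {policy!r}")
    genes: set[str] = set()
    report: dict[str, list[str]] = {
        "unannotated": [],
        "all_excluded_classes": [],
        "ambiguous_excluded": [],
        "alias_collapsed": [],
    }
    for p in probes:
        entries = ann.get(p)
        if not entries:
            report["unannotated"].append(p)
            continue
        kept = [(g, c) for g, c in entries if c not in ("pseudogene", "hypothetical")]
        if not kept:
            report["all_excluded_classes"].append(p)
            continue
        if len(kept) > 1 and all(c == "alias-group" for _, c in kept):
            report["alias_collapsed"].append(p)
            genes.add(kept[0][0])
            continue
        distinct = list(dict.fromkeys(g for g, _ in kept))
        if len(distinct) == 1:
            genes.add(distinct[0])
        elif policy == "first":
            genes.add(distinct[0])
        else:
            report["ambiguous_excluded"].append(p)
    return frozenset(genes), report
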