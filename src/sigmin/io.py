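"""Readers and writers for expression datasets, signature tables, annotation.

Two dataset formats are supported: a dense ARFF dialect (numeric feature
attributes, a nominal binary class attribute last, optionally a leading
``sample_id`` string attribute and a nominal ``batch`` attribute) and a TSV
with one header row.  Sparse ARFF and missing values are rejected.  The
class listed first in the file's metadata is the positive class unless
overridden.
"""

from __future__ import annotations

import csv
import io as _io
import re
from pathlib import Path

import pandas as pd

from .dataset import (
    AnnotationMap,
    LabeledExpressionDataset,
    Signature,
    SignatureCollection,
    ValidationError,
)


class ParseError(ValueError):
    """Malformed input file; message carries path and line number."""


# --------------------------------------------------------------------------
# ARFF
# --------------------------------------------------------------------------

_NOMINAL_RE = re.compile(r"^\{(.*)\}$")


def _parse_arff_attribute(line: str, path: str, lineno: int):
    body = line[len("@attribute"):].strip()
    if body.startswith("'"):
        end = body.index("'", 1)
        name = body[1:end]
        rest = body[end + 1:].strip()
    else:
        parts = body.split(None, 1)
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: malformed @attribute line")
        name, rest = parts
    rest = rest.strip()
    m = _NOMINAL_RE.match(rest)
    if m:
        values = [v.strip().strip("'") for v in m.group(1).split(",")]
        return name, ("nominal", values)
    kind = rest.lower()
    if kind in ("numeric", "real", "integer"):
        return name, ("numeric", None)
    if kind == "string":
        return name, ("string", None)
    raise ParseError(f"{path}:{lineno}: unsupported attribute type {rest!r}")


def _read_arff(
    path: str,
    label_attribute: str | None,
    batch_attribute: str | None,
    positive_class: str | None,
) -> LabeledExpressionDataset:
    attrs: list[tuple[str, tuple]] = []
    rows: list[list[str]] = []
    in_data = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if not in_data:
                if low.startswith("@relation"):
                    continue
                if low.startswith("@attribute"):
                    attrs.append(_parse_arff_attribute(line, path, lineno))
                    continue
                if low.startswith("@data"):
                    in_data = True
                    continue
                raise ParseError(f"{path}:{lineno}: unexpected line {line!r}")
            if line.startswith("{"):
                raise ParseError(
                    f"{path}:{lineno}: sparse ARFF is not supported"
                )
            values = next(csv.reader([line]))
            if len(values) != len(attrs):
                raise ParseError(
                    f"{path}:{lineno}: {len(values)} values for "
                    f"{len(attrs)} attributes"
                )
            if any(v.strip() == "?" for v in values):
                raise ParseError(
                    f"{path}:{lineno}: missing values ('?') are not supported"
                )
            rows.append([v.strip() for v in values])
    if not attrs:
        raise ParseError(f"{path}: no @attribute declarations found")

    names = [n for n, _ in attrs]
    kinds = dict(attrs)
    if label_attribute is None:
        label_attribute = names[-1]
    if label_attribute not in kinds:
        raise ValidationError(f"label attribute {label_attribute!r} not in file")
    if kinds[label_attribute][0] != "nominal":
        raise ValidationError(
            f"label attribute {label_attribute!r} must be nominal"
        )
    label_classes = kinds[label_attribute][1]
    if len(label_classes) != 2:
        raise ValidationError(
            f"label attribute {label_attribute!r} has {len(label_classes)} "
            "classes; exactly 2 required"
        )
    if batch_attribute is None and "batch" in kinds and "batch" != label_attribute:
        batch_attribute = "batch" if kinds["batch"][0] == "nominal" else None

    id_attr = None
    if names and names[0] == "sample_id" and kinds["sample_id"][0] == "string":
        id_attr = "sample_id"
    special = {label_attribute, batch_attribute, id_attr} - {None}
    probe_ids = [n for n in names if n not in special]
    for p in probe_ids:
        if kinds[p][0] != "numeric":
            raise ValidationError(f"feature attribute {p!r} must be numeric")
    col = {n: i for i, n in enumerate(names)}
    sample_ids = (
        [r[col[id_attr]] for r in rows]
        if id_attr
        else [f"s{i}" for i in range(len(rows))]
    )
    labels = [r[col[label_attribute]] for r in rows]
    for i, l in enumerate(labels):
        if l not in label_classes:
            raise ValidationError(
                f"{path}: row {i + 1}: label {l!r} not among declared classes"
            )
    batch = [r[col[batch_attribute]] for r in rows] if batch_attribute else None
    try:
        values = [[float(r[col[p]]) for p in probe_ids] for r in rows]
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric feature value: {exc}") from exc
    return LabeledExpressionDataset(
        sample_ids=sample_ids,
        probe_ids=probe_ids,
        values=values,
        labels=labels,
        positive_class=positive_class or label_classes[0],
        batch=batch,
    )


def _write_arff(ds: LabeledExpressionDataset, path: str) -> None:
    classes = ds.classes
    # Positive class first, so that read's default polarity matches.
    ordered = [ds.positive_class] + [c for c in classes if c != ds.positive_class]
    buf = _io.StringIO()
    buf.write("@relation sigmin\n\n")
    buf.write("@attribute sample_id string\n")
    for p in ds.probe_ids:
        buf.write(f"@attribute '{p}' numeric\n")
    if ds.batch is not None:
        bvals = ",".join(sorted(set(ds.batch)))
        buf.write(f"@attribute batch {{{bvals}}}\n")
    buf.write(f"@attribute class {{{','.join(ordered)}}}\n\n@data\n")
    for i, sid in enumerate(ds.sample_ids):
        cells = [sid] + [repr(float(v)) for v in ds.values[i]]
        if ds.batch is not None:
            cells.append(ds.batch[i])
        cells.append(ds.labels[i])
        buf.write(",".join(cells) + "\n")
    Path(path).write_text(buf.getvalue())


# --------------------------------------------------------------------------
# TSV
# --------------------------------------------------------------------------

def _read_tsv(
    path: str,
    label_attribute: str | None,
    batch_attribute: str | None,
    positive_class: str | None,
) -> LabeledExpressionDataset:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise ParseError(f"{path}: first column must be 'sample_id'")
    label_attribute = label_attribute or "label"
    if label_attribute not in df.columns:
        raise ValidationError(f"label column {label_attribute!r} not in file")
    if batch_attribute is None and "batch" in df.columns:
        batch_attribute = "batch"
    special = {"sample_id", label_attribute, batch_attribute} - {None}
    probe_ids = [c for c in df.columns if c not in special]
    labels = df[label_attribute].tolist()
    distinct = list(dict.fromkeys(labels))
    if len(distinct) > 2:
        raise ValidationError(f"{path}: label column has {len(distinct)} classes")
    try:
        values = df[probe_ids].astype(float).to_numpy()
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric feature value: {exc}") from exc
    return LabeledExpressionDataset(
        sample_ids=df["sample_id"].tolist(),
        probe_ids=probe_ids,
        values=values,
        labels=labels,
        positive_class=positive_class or distinct[0],
        batch=df[batch_attribute].tolist() if batch_attribute else None,
    )


def _write_tsv(ds: LabeledExpressionDataset, path: str) -> None:
    with open(path, "w") as fh:
        cols = ["sample_id", *ds.probe_ids]
        if ds.batch is not None:
            cols.append("batch")
        cols.append("label")
        fh.write("\t".join(cols) + "\n")
        for i, sid in enumerate(ds.sample_ids):
            cells = [sid] + [repr(float(v)) for v in ds.values[i]]
            if ds.batch is not None:
                cells.append(ds.batch[i])
            cells.append(ds.labels[i])
            fh.write("\t".join(cells) + "\n")


# --------------------------------------------------------------------------
# public dataset API
# --------------------------------------------------------------------------

def read_dataset(
    path: str,
    format: str = "arff",
    label_attribute: str | None = None,
    batch_attribute: str | None = None,
    positive_class: str | None = None,
) -> LabeledExpressionDataset:
    """Load an expression dataset from ARFF or TSV.

    The positive class defaults to the first class in the file's metadata
    (ARFF nominal declaration order; first occurrence in a TSV).
    """
    if format == "arff":
        return _read_arff(path, label_attribute, batch_attribute, positive_class)
    if format == "tsv":
        return _read_tsv(path, label_attribute, batch_attribute, positive_class)
    raise ValidationError(f"unknown dataset format {format!r}")


def write_dataset(
    ds: LabeledExpressionDataset, path: str, format: str = "arff"
) -> None:
    """Serialize a dataset so that ``read_dataset`` recovers it exactly."""
    if ds.n_probes == 0:
        raise ValidationError("refusing to write a dataset with no probes")
    if format == "arff":
        _write_arff(ds, path)
    elif format == "tsv":
        _write_tsv(ds, path)
    else:
        raise ValidationError(f"unknown dataset format {format!r}")


# --------------------------------------------------------------------------
# signature tables
# --------------------------------------------------------------------------

_META_COLUMNS = ("mcc_mean", "mcc_sd", "val_mcc")


def read_signatures(path: str, endpoint_id: str) -> SignatureCollection:
    """Read a signature table (long or wide form) for one endpoint.

    Long form has one row per (model_id, probe) with an optional ``weight``
    column; wide form has one row per model with semicolon-joined
    ``probes``.  Records missing a key attribute (model_id or probe list)
    are discarded and counted, not fatal; zero surviving signatures is an
    error.  Extra numeric columns (``mcc_mean``, ``mcc_sd``, ``val_mcc``)
    become per-model metadata.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "model_id" not in df.columns:
        raise ParseError(f"{path}: missing 'model_id' column")
    wide = "probes" in df.columns
    if not wide and "probe" not in df.columns:
        raise ParseError(f"{path}: need a 'probe' or 'probes' column")

    discarded = 0
    sigs: list[Signature] = []
    if wide:
        for _, row in df.iterrows():
            mid = row.get("model_id")
            plist = row.get("probes")
            if _blank(mid) or _blank(plist):
                discarded += 1
                continue
            probes = [p.strip() for p in str(plist).split(";") if p.strip()]
            if not probes:
                discarded += 1
                continue
            weights = None
            if "weights" in df.columns and not _blank(row.get("weights")):
                weights = [float(w) for w in str(row["weights"]).split(";")]
                if len(weights) != len(str(plist).split(";")):
                    raise ValidationError(
                        f"{path}: model {mid!r}: weights/probes length mismatch"
                    )
            sigs.append(
                Signature(
                    model_id=str(mid),
                    endpoint_id=endpoint_id,
                    probes=probes,
                    weights=weights,
                    metadata=_metadata(row, df.columns),
                )
            )
    else:
        for mid, group in df.groupby("model_id", sort=False, dropna=False):
            if _blank(mid):
                discarded += len(group)
                continue
            rows = group[~group["probe"].map(_blank)]
            n_dropped_rows = len(group) - len(rows)
            if rows.empty:
                discarded += 1
                continue
            probes = rows["probe"].astype(str).tolist()
            weights = None
            if "weight" in df.columns and rows["weight"].notna().all():
                weights = rows["weight"].astype(float).tolist()
            elif "weight" in df.columns and rows["weight"].notna().any():
                raise ValidationError(
                    f"{path}: model {mid!r}: weight column partially filled"
                )
            sigs.append(
                Signature(
                    model_id=str(mid),
                    endpoint_id=endpoint_id,
                    probes=probes,
                    weights=weights,
                    metadata=_metadata(rows.iloc[0], df.columns),
                )
            )
            discarded += 0 if n_dropped_rows == 0 else 0
    if not sigs:
        raise ValidationError(f"{path}: no surviving signatures")
    return SignatureCollection(
        endpoint_id=endpoint_id, signatures=sigs, n_discarded=discarded
    )


def write_signatures(coll: SignatureCollection, path: str) -> None:
    """Write a collection in wide form (semicolon-joined probes)."""
    meta_cols = sorted(
        {k for s in coll for k in s.metadata if k in _META_COLUMNS}
    )
    with open(path, "w") as fh:
        fh.write("\t".join(["model_id", "probes", *meta_cols]) + "\n")
        for s in coll:
            cells = [s.model_id, ";".join(s.probes)]
            cells += [str(s.metadata.get(k, "")) for k in meta_cols]
            fh.write("\t".join(cells) + "\n")


def _blank(v) -> bool:
    return v is None or (isinstance(v, float) and pd.isna(v)) or str(v).strip() == ""


def _metadata(row, columns) -> dict:
    out = {}
    for k in _META_COLUMNS:
        if k in columns and not _blank(row.get(k)):
            out[k] = float(row[k])
    return out


# --------------------------------------------------------------------------
# annotation
# --------------------------------------------------------------------------

def read_annotation(path: str) -> AnnotationMap:
    """Read a probe->gene TSV with an optional gene-class third column.

    Several rows per probe accumulate into that probe's gene list; the
    class defaults to ``protein-coding``.
    """
    entries: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("probe"):
            raise ParseError(f"{path}:1: header must start with 'probe'")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ParseError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            probe, gene = parts[0], parts[1]
            cls = parts[2] if len(parts) == 3 and parts[2] else "protein-coding"
            entries.setdefault(probe, [])
            if gene:
                entries[probe].append((gene, cls))
    return AnnotationMap(entries=entries)
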