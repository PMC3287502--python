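"""End-to-end workflow: similarity -> consensus/weights -> (AGC) -> MFS ->
validation -> PPI topology comparison.

Every stage writes plain-text artifacts into the output directory and the
whole run is a pure function of (inputs, config): re-running the same
config reproduces all artifacts byte-identically.  Optional stages (PPI,
external validation, cross-endpoint prediction) are skipped with an
explicit "skipped" status when their inputs are not configured.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .cv import (
    ClassifierSpec,
    cross_endpoint_validate,
    evaluate_cv,
    external_validate,
    train_model,
)
from .dataset import LabeledExpressionDataset, ValidationError
from .io import read_dataset, read_signatures
from .mfs import MFSConfig, prepare_mfs_input, run_mfs
from .ppi import (
    compare_topology,
    distance_matrix,
    load_network,
    summary_table_row,
    topology_summary,
)
from .preprocess import agc_center
from .similarity import (
    consensus_set,
    overlap_matrix,
    overlap_rate,
    probe_frequency,
)


@dataclass
class RunConfig:
    """Paths and knobs of one full pipeline run."""

    train_path: str
    signatures_path: str
    endpoint_id: str
    output_dir: str
    data_format: str = "arff"
    validation_path: str | None = None
    alternate_labels_path: str | None = None  # TSV sample_id/label for cross-endpoint
    network_edges_path: str | None = None
    network_probe_map_path: str | None = None
    min_support: int = 2
    agc: bool = False
    swap: bool = False
    fitting_index: str = "mcc"
    criteria_value: float = 0.6
    min_size: int = 5
    classifier: str = "svm-linear"
    folds: int = 5
    repeats: int = 10
    seed: int = 0

    def mfs_config(self, weights=None) -> MFSConfig:
        return MFSConfig(
            fitting_index=self.fitting_index,
            criteria_value=self.criteria_value,
            min_size=self.min_size,
            classifier=ClassifierSpec(name=self.classifier, seed=self.seed),
            folds=self.folds,
            repeats=self.repeats,
            seed=self.seed,
            weights=weights,
        )


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")


def _metric_rows(prefix: str, bundle: dict) -> list[list]:
    order = ["mcc", "acc", "sen", "spe"]
    return [[f"{prefix}_{m.upper()}", f"{bundle[m]:.4f}"] for m in order]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every configured stage; returns the run report."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    train = read_dataset(cfg.train_path, format=cfg.data_format)
    validation = (
        read_dataset(cfg.validation_path, format=cfg.data_format)
        if cfg.validation_path
        else None
    )
    if cfg.swap:
        if validation is None:
            raise ValidationError("--swap requires a validation dataset")
        train, validation = validation, train
    coll = read_signatures(cfg.signatures_path, cfg.endpoint_id)

    # -- similarity --------------------------------------------------------
    freq = probe_frequency(coll)
    cons = sorted(consensus_set(freq, cfg.min_support))
    total = len(freq.support)
    rate = overlap_rate(total, len(cons))
    rows = [[p, s] for p, s in freq.ranked()]
    _write_tsv(out / "frequency.tsv", ["probe", "support"], rows)
    (out / "consensus_probes.txt").write_text("".join(p + "\n" for p in cons))
    if len(coll) >= 2:
        om = overlap_matrix(coll)
        _write_tsv(
            out / "overlap_matrix.tsv",
            ["model_id", *om.model_ids],
            [
                [mid, *om.counts[i].tolist()]
                for i, mid in enumerate(om.model_ids)
            ],
        )
    _write_tsv(
        out / "similarity_report.tsv",
        ["Endpoint", "ModelNumber", "Total", "Overlapped", "Rate(%)"],
        [[cfg.endpoint_id, len(coll), total, len(cons), f"{rate:.2f}"]],
    )
    report["stages"]["similarity"] = {
        "status": "ok", "total_probes": total,
        "consensus_size": len(cons), "rate_percent": rate,
    }

    # -- preprocessing -----------------------------------------------------
    if cfg.agc:
        train = agc_center(train)
        if validation is not None and validation.batch is not None:
            validation = agc_center(validation)
        report["stages"]["agc"] = {"status": "ok"}
    else:
        report["stages"]["agc"] = {"status": "skipped"}

    # -- MFS ---------------------------------------------------------------
    features, weights, prep_report = prepare_mfs_input(
        coll, train, min_support=cfg.min_support
    )
    mfs_cfg = cfg.mfs_config(weights=weights)
    result = run_mfs(train, features, mfs_cfg)
    best_probes = list(result.best_features)
    (out / "best_signature.txt").write_text(
        "".join(p + "\n" for p in best_probes)
    )
    _write_tsv(
        out / "intermediates.tsv",
        ["iteration", "size", "index_value", "probes"],
        [
            [i + 1, len(fs), f"{v:.4f}", ";".join(fs)]
            for i, (fs, v) in enumerate(result.intermediates)
        ],
    )
    trace = {
        "input_features": features,
        "termination_reason": result.termination_reason,
        "best": {"features": best_probes, "value": result.best_value},
        "iterations": [
            {
                "iteration": t.iteration,
                "start_value": t.start_value,
                "end_value": t.end_value,
                "start_size": len(t.start_features),
                "end_size": len(t.end_features),
                "decisions": [
                    {
                        "probe": d.probe,
                        "candidate_value": d.candidate_value,
                        "action": d.action,
                    }
                    for d in t.decisions
                ],
            }
            for t in result.iterations
        ],
    }
    (out / "mfs_trace.json").write_text(json.dumps(trace, indent=2, sort_keys=True))
    report["stages"]["mfs"] = {
        "status": "ok",
        "input_size": len(features),
        "best_size": len(best_probes),
        "best_value": result.best_value,
        "termination_reason": result.termination_reason,
    }

    # -- validation --------------------------------------------------------
    spec = ClassifierSpec(name=cfg.classifier, seed=cfg.seed)
    cv = evaluate_cv(
        train, best_probes, spec, folds=cfg.folds, repeats=cfg.repeats,
        seed=cfg.seed,
    )
    metric_rows = []
    for m in ("mcc", "acc", "sen", "spe"):
        metric_rows.append([f"CV_{m.upper()}", f"{cv.metrics[m].mean:.4f}"])
    for m in ("mcc", "acc", "sen", "spe"):
        metric_rows.append(
            [f"{m.upper()}_Std Dev", f"{cv.metrics[m].sd:.4f}"]
        )
    model = train_model(train, best_probes, spec)
    if validation is not None:
        _, val_bundle = external_validate(model, validation)
        metric_rows += _metric_rows("Val", val_bundle)
        report["stages"]["external_validation"] = {
            "status": "ok", "val_mcc": val_bundle["mcc"],
        }
    else:
        report["stages"]["external_validation"] = {"status": "skipped"}
    if cfg.alternate_labels_path:
        alt = _read_alternate_labels(cfg.alternate_labels_path, train)
        _, cross = cross_endpoint_validate(model, train, alt["labels"],
                                           alt["positive"])
        metric_rows += _metric_rows("Cross", cross)
        report["stages"]["cross_endpoint"] = {
            "status": "ok", "cross_mcc": cross["mcc"],
        }
    else:
        report["stages"]["cross_endpoint"] = {"status": "skipped"}
    _write_tsv(out / "validation_metrics.tsv", ["metric", "value"], metric_rows)
    report["stages"]["internal_validation"] = {
        "status": "ok", "cv_mcc": cv.metrics["mcc"].mean,
    }

    # -- PPI ---------------------------------------------------------------
    if cfg.network_edges_path and cfg.network_probe_map_path:
        net = load_network(cfg.network_edges_path, cfg.network_probe_map_path)
        before = topology_summary(distance_matrix(net, features))
        if len(best_probes) >= 2:
            after = topology_summary(distance_matrix(net, best_probes))
            delta = compare_topology(before, after)
            rows = [
                ["before", *summary_table_row(before).values()],
                ["after", *summary_table_row(after).values()],
            ]
            _write_tsv(
                out / "ppi_summary.tsv",
                ["signature", *summary_table_row(before).keys()],
                rows,
            )
            report["stages"]["ppi"] = {
                "status": "ok",
                "average_length_delta": delta.average_length_delta,
            }
        else:
            report["stages"]["ppi"] = {
                "status": "skipped", "reason": "best signature has < 2 probes",
            }
    else:
        report["stages"]["ppi"] = {"status": "skipped"}

    # -- manifest & summary ------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    summary_lines = [
        f"endpoint: {cfg.endpoint_id}",
        f"signatures: {len(coll)} (discarded on load: {coll.n_discarded})",
        f"consensus probes (support >= {cfg.min_support}): {len(cons)} "
        f"of {total} ({rate:.2f}%)",
        f"MFS: {len(features)} -> {len(best_probes)} probes "
        f"({cfg.fitting_index} = {result.best_value:.4f}, "
        f"stopped: {result.termination_reason})",
        f"internal CV MCC: {cv.metrics['mcc'].mean:.4f} "
        f"(SD {cv.metrics['mcc'].sd:.4f})",
    ]
    (out / "summary.txt").write_text("".join(l + "\n" for l in summary_lines))
    report["best_signature"] = best_probes
    report["cv_mcc_mean"] = cv.metrics["mcc"].mean
    return report


def _read_alternate_labels(path: str, ds: LabeledExpressionDataset) -> dict:
    """TSV sample_id/label aligned by sample id to ``ds``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping = dict(zip(df["sample_id"], df["label"]))
    missing = [s for s in ds.sample_ids if s not in mapping]
    if missing:
        raise ValidationError(
            f"alternate labels missing for {len(missing)} sample(s)"
        )
    labels = [mapping[s] for s in ds.sample_ids]
    positive = list(dict.fromkeys(df["label"]))[0]
    return {"labels": labels, "positive": positive}
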