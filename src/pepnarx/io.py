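"""Readers, writers and the end-to-end pipeline runner.

Peptide tables are TSV-first (CSV accepted) with fixed columns
``id``, ``sequence``, ``ec50``; sequences may alternatively come from a
FASTA file with activities joined from a sidecar table by id.  Every
artifact the pipeline writes embeds the hash of the resolved run
configuration, so provenance is reconstructible from the output bundle
alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .classify import SegmentScheme, assign_labels, featurize_records, train_svm
from .codec import PeptideRecord, encode_sequence
from .fractal import estimate_hurst
from .narx import NarxConfig, fit_narx
from .predict import evaluate_method, fit_bpnn_baseline
from .series import SeriesGroup, autocorrelation, build_series

logger = logging.getLogger("pepnarx")

__all__ = ["RunConfig", "read_peptide_table", "write_peptide_table", "run_pipeline"]

_REQUIRED_COLUMNS = ("id", "sequence", "ec50")


class TableValidationError(ValueError):
    """Raised with a per-row summary when a peptide table fails validation."""


def read_peptide_table(
    path: str | Path,
    fmt: str | None = None,
    activities: str | Path | None = None,
) -> list[PeptideRecord]:
    """Read and validate a peptide-activity table.

    ``fmt`` is 'csv', 'tsv' or 'fasta' (guessed from the suffix when None).
    FASTA input requires ``activities``: a CSV/TSV with id and ec50 columns
    joined by record id.  Malformed rows are collected and reported together
    with their line numbers before the run aborts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".csv": "csv", ".tsv": "tsv", ".fasta": "fasta", ".fa": "fasta"}.get(
            suffix, "tsv"
        )
    if fmt == "fasta":
        if activities is None:
            raise ValueError("FASTA input requires an activities table (id, ec50)")
        act = _read_frame(Path(activities))
        if not {"id", "ec50"}.issubset(act.columns):
            raise TableValidationError(
                f"{activities}: activities table must have columns id, ec50"
            )
        ec50_by_id = dict(zip(act["id"].astype(str), act["ec50"]))
        rows = []
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id not in ec50_by_id:
                raise TableValidationError(
                    f"{path}: sequence {rec.id!r} has no activity entry"
                )
            rows.append({"id": rec.id, "sequence": str(rec.seq), "ec50": ec50_by_id[rec.id]})
        frame = pd.DataFrame(rows)
    else:
        frame = _read_frame(path, sep="," if fmt == "csv" else "\t")
        missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise TableValidationError(f"{path}: missing column(s) {', '.join(missing)}")
    records: list[PeptideRecord] = []
    errors: list[str] = []
    for i, row in frame.iterrows():
        try:
            ec50 = float(row["ec50"])
            records.append(
                PeptideRecord(id=str(row["id"]), sequence=str(row["sequence"]), ec50=ec50)
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i + 2}: {exc}")  # +2: header + 1-based
    if errors:
        raise TableValidationError(
            f"{path}: {len(errors)} invalid row(s):\n  " + "\n  ".join(errors)
        )
    return records


def _read_frame(path: Path, sep: str | None = None) -> pd.DataFrame:
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, comment="#")


def write_peptide_table(records: list[PeptideRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "sequence": [r.sequence for r in records],
            "ec50": [r.ec50 for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    input_path: str
    output_dir: str
    seed: int = 0
    input_format: str | None = None
    activities_path: str | None = None
    k: int = 3
    n_train: int | None = None
    classification: str = "oracle"
    hurst_scales: list[int] | None = None
    run_fractal: bool = True
    run_baseline: bool = True
    baseline_resamples: int = 20
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        # Identifies the analysis configuration: where the output lands and
        # how verbosely we log do not change the results, so they are
        # excluded and reruns into different directories share a hash.
        payload = {
            k: v for k, v in self.to_dict().items() if k not in ("output_dir", "log_level")
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_json(payload: dict, path: Path, config_hash: str) -> None:
    payload = {"config_hash": config_hash, **payload}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow: encode, build series, fractal diagnostics,
    train both NARX models, classify, evaluate.

    Returns the artifact bundle as a dict and writes every piece (plus the
    resolved config) into ``config.output_dir``.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash
    stage = "read"
    try:
        records = read_peptide_table(
            config.input_path, fmt=config.input_format, activities=config.activities_path
        )
        logger.info("read %d records from %s", len(records), config.input_path)

        stage = "encode"
        encoded = [encode_sequence(r.sequence) for r in records]
        enc_frame = pd.DataFrame(
            {
                "id": [r.id for r in records],
                "sequence": [r.sequence for r in records],
                "digits": ["-".join(map(str, e.digits)) for e in encoded],
                "code": [str(e.code) for e in encoded],
                "log_code": [e.log_code for e in encoded],
            }
        )
        enc_frame.to_csv(out / "encoded.tsv", sep="\t", index=False)

        stage = "series"
        bundle: dict = {"config": config.to_dict(), "config_hash": h}
        pairs = {}
        for group in SeriesGroup:
            pair = build_series(records, group)
            pairs[group] = pair
            pd.DataFrame(
                {"index": np.arange(pair.n), "y": pair.y, "u": pair.u, "source_id": pair.ids}
            ).to_csv(out / f"series_{group.value}.tsv", sep="\t", index=False)

        if config.run_fractal:
            stage = "fractal"
            est = estimate_hurst(pairs[SeriesGroup.BY_ACTIVITY].y, scales=config.hurst_scales)
            fractal = {
                "hurst": est.H,
                "slope": est.slope,
                "scales": list(est.scales),
                "log2_variances": list(est.log2_variances),
                "acf1_by_activity": float(
                    autocorrelation(pairs[SeriesGroup.BY_ACTIVITY].y, 1)[1]
                ),
                "acf1_by_code": float(autocorrelation(pairs[SeriesGroup.BY_CODE].y, 1)[1]),
            }
            _write_json(fractal, out / "fractal.json", h)
            bundle["fractal"] = fractal

        stage = "narx"
        models = {}
        for group, pair in pairs.items():
            cfg = NarxConfig.for_group(group, seed=config.seed)
            model = fit_narx(pair.y, pair.u, cfg)
            models[group] = model
            _write_json(model.to_dict(), out / f"narx_{group.value}.json", h)
        bundle["narx_errors"] = {
            g.value: {
                "train_mse": m.train_mse,
                "validation_mse": m.validation_mse,
                "test_mse": m.test_mse,
            }
            for g, m in models.items()
        }

        stage = "classify"
        scheme = SegmentScheme.from_records(records, k=config.k)
        labels = assign_labels(records, scheme)
        clf, accuracy = train_svm(featurize_records(records), labels, seed=config.seed)
        pd.DataFrame(
            {"id": [r.id for r in records], "label": labels}
        ).to_csv(out / "labels.tsv", sep="\t", index=False)
        bundle["classification"] = {
            "k": config.k,
            "boundaries": list(scheme.boundaries),
            "svm_accuracy": accuracy,
        }

        stage = "evaluate"
        n_train = config.n_train or max(2, int(round(len(records) * 200 / 231)))
        evaluation = evaluate_method(
            records, n_train, classification=config.classification, seeds=[config.seed]
        )
        if config.run_baseline:
            evaluation["bpnn_baseline"] = fit_bpnn_baseline(
                records, n_resamples=config.baseline_resamples
            )
        _write_json(evaluation, out / "evaluation.json", h)
        bundle["evaluation"] = evaluation
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _write_json({"config": config.to_dict()}, out / "run_config.json", h)
    _write_json(
        {k: v for k, v in bundle.items() if k not in ("config",)},
        out / "bundle.json",
        h,
    )
    return bundle
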