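"""Convenience drivers tying the pipeline stages together.

These helpers read a dataset directory (WFDB/CSV signals plus per-minute
annotations), run preprocessing and feature extraction, and hand back the
per-record feature tables the windowing and evaluation stages consume.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .ecg_io import (
    check_annotation_consistency,
    read_csv_signal,
    read_minute_annotations,
    read_wfdb_record,
)
from .features import BandDefinition, SpectralEstimatorSpec, extract_recording_features
from .preprocess import DetectorSpec, FilterSpec, preprocess_record
from .synth import SynthRecord

__all__ = ["load_dataset_features", "features_from_synth_records", "extract_features_for_record"]


def extract_features_for_record(
    record,
    labels,
    filter_spec: FilterSpec = FilterSpec(),
    detector_spec: DetectorSpec = DetectorSpec(),
    estimator: SpectralEstimatorSpec = SpectralEstimatorSpec(),
    bands: BandDefinition = BandDefinition(),
    min_beats: int = 10,
) -> pd.DataFrame:
    """Signal + labels -> per-minute feature table (full preprocessing chain)."""
    check_annotation_consistency(record, labels)
    series = preprocess_record(record, filter_spec, detector_spec)
    return extract_recording_features(series, labels, estimator, bands, min_beats)


def load_dataset_features(
    directory: str | Path,
    sampling_rate: float = 100.0,
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """Feature tables for every record in a dataset directory.

    Records are discovered from ``<id>.hea`` (WFDB) or ``<id>.csv`` signal
    files; annotations are ``<id>.ann``, ``<id>.apn`` or ``<id>.txt``.
    """
    directory = Path(directory)
    out: dict[str, pd.DataFrame] = {}
    signal_paths: dict[str, Path] = {}
    for p in sorted(directory.glob("*.hea")):
        signal_paths[p.stem] = p
    for p in sorted(directory.glob("*.csv")):
        signal_paths.setdefault(p.stem, p)
    if not signal_paths:
        raise FileNotFoundError(f"no signal files (*.hea or *.csv) found in {directory}")
    for rid, sig_path in signal_paths.items():
        ann_path = next(
            (directory / f"{rid}{ext}" for ext in (".ann", ".apn", ".txt")
             if (directory / f"{rid}{ext}").exists()),
            None,
        )
        if ann_path is None:
            raise FileNotFoundError(f"no annotation file for record {rid} in {directory}")
        if sig_path.suffix == ".hea":
            record = read_wfdb_record(sig_path)
        else:
            record = read_csv_signal(sig_path, sampling_rate)
        labels = read_minute_annotations(ann_path)
        labels.record_id = record.record_id
        out[rid] = extract_features_for_record(record, labels, **kwargs)
    return out


def features_from_synth_records(
    records: Mapping[str, SynthRecord] | list[SynthRecord], **kwargs
) -> dict[str, pd.DataFrame]:
    """Run the full preprocessing + feature chain on in-memory synthetic records."""
    if not isinstance(records, Mapping):
        records = {r.record.record_id: r for r in records}
    return {
        rid: extract_features_for_record(rec.record, rec.labels, **kwargs)
        for rid, rec in records.items()
    }
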