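"""CSV dataset and template-set persistence.

Datasets are stored long-format — one row per sample with columns
``sequence_id, sample_index, value, label`` — because the sequences have
unequal lengths and ragged wide rows are dialect-fragile.  ``sample_index``
is 1-based and must be contiguous within each sequence; a sequence carries
exactly one label.

Template sets are a pair of files: a CSV of template points
(``category, sample_index, value``) plus a small JSON metadata header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence import MotionSequence
from .templates import TemplateSet

__all__ = ["read_dataset", "write_dataset", "read_templates",
           "write_templates", "read_stream", "write_events"]

_COLUMNS = ["sequence_id", "sample_index", "value", "label"]


class DatasetFormatError(ValueError):
    """A dataset file violates the expected schema or its invariants."""


def read_dataset(path) -> list:
    """Load labeled motion sequences from a long-format CSV.

    Raises :class:`DatasetFormatError` on a missing column, a non-contiguous
    ``sample_index`` within a sequence, or inconsistent labels.
    """
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"missing column(s): {', '.join(missing)}")
    sequences = []
    for sid, grp in df.groupby("sequence_id", sort=True):
        grp = grp.sort_values("sample_index")
        idx = grp["sample_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise DatasetFormatError(
                f"sequence {sid!r}: sample_index not contiguous from 1")
        labels = grp["label"].unique()
        if len(labels) != 1:
            raise DatasetFormatError(
                f"sequence {sid!r}: more than one label")
        sequences.append(MotionSequence(grp["value"].to_numpy(dtype=float),
                                        label=labels[0].item()
                                        if hasattr(labels[0], "item")
                                        else labels[0]))
    return sequences


def write_dataset(sequences, path) -> None:
    """Write sequences to long-format CSV with deterministic ordering."""
    rows = []
    for i, seq in enumerate(sequences):
        sid = f"seq{i:04d}"
        for j, v in enumerate(np.asarray(seq.samples), start=1):
            rows.append((sid, j, float(v), seq.label))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df.to_csv(path, index=False, lineterminator="\n")


def write_templates(template_set: TemplateSet, csv_path, meta_path=None) -> None:
    """Serialize a template set to CSV plus a JSON metadata header."""
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".json")
    rows = []
    for label in template_set.labels:
        for j, v in enumerate(template_set.templates[label], start=1):
            rows.append((label, j, float(v)))
    pd.DataFrame(rows, columns=["category", "sample_index", "value"]).to_csv(
        csv_path, index=False, lineterminator="\n")
    meta = {"method": template_set.method,
            "template_length": template_set.template_length,
            "source_count": {str(k): v
                             for k, v in template_set.source_count.items()}}
    meta_path.write_text(json.dumps(meta, indent=1) + "\n")


def read_templates(csv_path, meta_path=None) -> TemplateSet:
    """Load a template set written by :func:`write_templates`."""
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".json")
    df = pd.read_csv(csv_path)
    templates = {}
    for label, grp in df.groupby("category", sort=True):
        grp = grp.sort_values("sample_index")
        key = label.item() if hasattr(label, "item") else label
        templates[key] = grp["value"].to_numpy(dtype=float)
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return TemplateSet(templates=templates,
                       method=meta.get("method", "unknown"),
                       template_length=meta.get("template_length"),
                       source_count=meta.get("source_count", {}))


def read_stream(path) -> np.ndarray:
    """Load a continuous stream from a CSV with a ``value`` column."""
    df = pd.read_csv(path)
    if "value" not in df.columns:
        raise DatasetFormatError("stream file must have a 'value' column")
    return df["value"].to_numpy(dtype=float)


def write_events(events, path) -> None:
    """Write segment events as CSV (start, end, label, cost)."""
    rows = [(e.start_index, e.end_index, e.label,
             None if e.cost is None else float(e.cost)) for e in events]
    pd.DataFrame(rows, columns=["start", "end", "label", "cost"]).to_csv(
        path, index=False, lineterminator="\n")
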