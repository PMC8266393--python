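"""Report bundle writer: TSV tables, a versioned summary JSON, and an
audit trail of filtering steps with gene counts (the analysis funnel).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

SCHEMA_VERSION = 1


class ReportError(ValueError):
    pass


def _jsonable(obj):
    """JSON fallback for numpy scalars and other number-likes."""
    if hasattr(obj, "item"):
        return obj.item()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


@dataclass
class FilterStep:
    """One filtering stage: what it did and how many genes survived."""

    name: str
    n_in: int
    n_out: int
    detail: str = ""


def write_report(
    outdir: str | Path,
    tables: Mapping[str, pd.DataFrame],
    summary: Optional[dict] = None,
    filter_log: Sequence[FilterStep] = (),
    force: bool = False,
) -> Path:
    """Write one report directory: TSVs, summary.json, manifest.json.

    The manifest lists every table with its row/column counts and every
    filter stage with input/output gene counts, so a reader can follow
    the gene-count funnel without re-running anything. Refuses to write
    into an existing directory unless ``force`` is set.
    """
    out = Path(outdir)
    if out.exists() and any(out.iterdir()) and not force:
        raise ReportError(f"{out} exists and is not empty; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"schema_version": SCHEMA_VERSION, "tables": {}, "filters": []}
    for name, df in tables.items():
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", float_format="%.6g")
        manifest["tables"][name] = {
            "file": path.name,
            "n_rows": int(df.shape[0]),
            "n_cols": int(df.shape[1]),
        }
    for step in filter_log:
        manifest["filters"].append(
            {"name": step.name, "n_in": step.n_in, "n_out": step.n_out, "detail": step.detail}
        )
    if summary is not None:
        (out / "summary.json").write_text(
            json.dumps({"schema_version": SCHEMA_VERSION, **summary}, indent=1,
                       sort_keys=True, default=_jsonable)
        )
        manifest["summary"] = "summary.json"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
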