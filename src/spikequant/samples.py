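"""Sample metadata for dual-genome spike-in experiments.

Every sequencing sample carries two read totals: reads mapped to the
experimental (S. cerevisiae) genome and reads mapped to the spike-in
genome (S. pombe for RNA-seq/ChIP-seq, D. melanogaster for ChEC-seq).
The spike totals drive all normalization; ChIP-seq samples additionally
link to their chromatin input sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

ASSAYS = ("rnaseq", "chec", "chip")
CONDITIONS = ("DMSO", "IAA")


class SampleError(ValueError):
    """Invalid or inconsistent sample metadata."""


@dataclass(frozen=True)
class SampleMeta:
    """One sequencing sample of a spike-in experiment.

    Parameters
    ----------
    sample_id : unique identifier, also the column name in count tables.
    assay : one of ``rnaseq``, ``chec``, ``chip``.
    condition : ``DMSO`` (vehicle) or ``IAA`` (auxin-induced depletion).
    replicate : 1-based biological replicate index.
    spike_reads : total reads mapped to the spike-in genome.
    experimental_reads : total reads mapped to the experimental genome.
    input_link : sample_id of the paired chromatin input (ChIP-seq only).
    """

    sample_id: str
    assay: str
    condition: str
    replicate: int
    spike_reads: int
    experimental_reads: int
    input_link: Optional[str] = None

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise SampleError(f"unknown assay {self.assay!r} for sample {self.sample_id}")
        if self.condition not in CONDITIONS:
            raise SampleError(
                f"unknown condition {self.condition!r} for sample {self.sample_id}"
            )
        if self.spike_reads < 0 or self.experimental_reads < 0:
            raise SampleError(f"negative read totals for sample {self.sample_id}")


def check_unique_pairs(metas: list[SampleMeta]) -> None:
    """Condition/replicate pairs must be unique within one experiment."""
    seen: set[tuple[str, str, int]] = set()
    for m in metas:
        key = (m.assay, m.condition, m.replicate)
        if key in seen:
            raise SampleError(f"duplicate condition/replicate pair {key}")
        seen.add(key)


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read a tab-separated sample sheet into SampleMeta records."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "input_link": str})
    metas = []
    for row in df.itertuples(index=False):
        link = getattr(row, "input_link", None)
        if pd.isna(link):
            link = None
        metas.append(
            SampleMeta(
                sample_id=str(row.sample_id),
                assay=str(row.assay),
                condition=str(row.condition),
                replicate=int(row.replicate),
                spike_reads=int(row.spike_reads),
                experimental_reads=int(row.experimental_reads),
                input_link=link,
            )
        )
    return metas


def write_sample_sheet(metas: list[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metas],
            "assay": [m.assay for m in metas],
            "condition": [m.condition for m in metas],
            "replicate": [m.replicate for m in metas],
            "spike_reads": [m.spike_reads for m in metas],
            "experimental_reads": [m.experimental_reads for m in metas],
            "input_link": [m.input_link or "" for m in metas],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def by_condition(metas: list[SampleMeta]) -> dict[str, list[SampleMeta]]:
    """Group samples by condition, replicate-sorted."""
    out: dict[str, list[SampleMeta]] = {}
    for m in metas:
        out.setdefault(m.condition, []).append(m)
    for v in out.values():
        v.sort(key=lambda m: m.replicate)
    return out
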