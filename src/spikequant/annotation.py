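"""Gene models, promoter windows and TATA classification.

Coordinate conventions
----------------------
All internal coordinates are 0-based, half-open. GFF3 input (1-based,
inclusive) is converted on read; the package's gene TSV dialect and
bedGraph are already 0-based half-open.

TSS and PAS are stored as *transcription-direction boundaries* of the
half-open transcribed interval: for a ``+`` strand gene the TSS is the
first transcribed base and the PAS the exclusive end; for a ``-`` strand
gene the TSS is the exclusive end of the interval and the PAS its start.
Under this single convention, strand-aware windows mirror exactly (a
``-`` strand gene with tss=5000 has promoter window [4900, 5300)) and
``[min(tss, pas), max(tss, pas))`` is always the transcribed interval.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

BIOTYPES = ("verified", "uncharacterized", "dubious", "pseudogene", "transposable_element")
EXCLUDED_BIOTYPES = ("dubious", "pseudogene", "transposable_element")

TATA_CONSENSUS = re.compile("TATA[AT]A[AT]")

GENE_TSV_COLUMNS = [
    "gene_id", "chrom", "strand", "start", "end",
    "cds_start", "tss", "pas", "class", "biotype",
]


class AnnotationError(ValueError):
    """Malformed annotation input."""


@dataclass
class GeneModel:
    """One gene: coordinates, strand, TSS/PAS and class labels."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds_start: int
    tss: Optional[int] = None
    pas: Optional[int] = None
    biotype: str = "verified"
    class_label: str = "unassigned"
    tata: Optional[bool] = None
    tss_fallback: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise AnnotationError(f"{self.gene_id}: invalid interval [{self.start}, {self.end})")
        if self.biotype not in BIOTYPES:
            raise AnnotationError(f"{self.gene_id}: unknown biotype {self.biotype!r}")

    @property
    def length(self) -> int:
        """Transcribed length when TSS/PAS are known, else footprint length."""
        if self.tss is not None and self.pas is not None:
            return abs(self.tss - self.pas)
        return self.end - self.start

    def transcribed_interval(self) -> tuple[int, int]:
        if self.tss is None or self.pas is None:
            raise AnnotationError(f"{self.gene_id}: TSS/PAS required")
        return min(self.tss, self.pas), max(self.tss, self.pas)


@dataclass(frozen=True)
class PromoterWindow:
    """Strand-aware half-open promoter interval around a TSS."""

    gene_id: str
    chrom: str
    start: int
    end: int
    tss: int
    strand: str
    upstream_bp: int = 300
    downstream_bp: int = 100
    clipped: bool = False


def _none_if_missing(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "" or value == ".":
        return None
    return int(value)


def _genes_from_tsv(path: Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    if df.empty:
        return []
    genes = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            genes.append(
                GeneModel(
                    gene_id=str(row["gene_id"]),
                    chrom=str(row["chrom"]),
                    strand=str(row["strand"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    cds_start=int(row["cds_start"]),
                    tss=_none_if_missing(row.get("tss")),
                    pas=_none_if_missing(row.get("pas")),
                    biotype=str(row.get("biotype", "verified")),
                    class_label=str(row.get("class", row.get("class_label", "unassigned"))),
                )
            )
        except (TypeError, ValueError, KeyError) as exc:
            raise AnnotationError(f"{path}, data line {i + 1}: {exc}") from exc
    return genes


_GFF_ATTR = re.compile(r"(\w+)=([^;]*)")


def _genes_from_gff3(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start1, end1, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            try:
                start = int(start1) - 1  # GFF3 is 1-based inclusive
                end = int(end1)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: malformed coordinates") from exc
            a = dict(_GFF_ATTR.findall(attrs))
            if "ID" not in a:
                raise AnnotationError(f"{path}:{lineno}: gene feature lacks ID attribute")
            cds_default = start if strand == "+" else end
            genes.append(
                GeneModel(
                    gene_id=a["ID"],
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    cds_start=int(a.get("cds_start", cds_default)),
                    tss=_none_if_missing(a.get("tss")),
                    pas=_none_if_missing(a.get("pas")),
                    biotype=a.get("biotype", "verified"),
                    class_label=a.get("gene_class", "unassigned"),
                )
            )
    return genes


def load_genes(
    annotation_file: str | Path,
    excluded_biotypes: Sequence[str] = EXCLUDED_BIOTYPES,
) -> list[GeneModel]:
    """Load gene models from GFF3 or the package's gene TSV dialect.

    Genes with biotype ``dubious``, ``pseudogene`` or ``transposable_element``
    (case-insensitive; configurable) are excluded, mirroring the standard
    yeast annotation filters. Output is stably sorted by (chrom, start).
    """
    path = Path(annotation_file)
    if path.suffix.lower() in (".gff", ".gff3"):
        genes = _genes_from_gff3(path)
    else:
        genes = _genes_from_tsv(path)
    excluded = {b.lower() for b in excluded_biotypes}
    kept = [g for g in genes if g.biotype.lower() not in excluded]
    n_removed = len(genes) - len(kept)
    if n_removed:
        logger.info("load_genes: removed %d genes with excluded biotypes", n_removed)
    kept.sort(key=lambda g: (g.chrom, g.start))
    return kept


def write_genes_tsv(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
            "start": g.start, "end": g.end, "cds_start": g.cds_start,
            "tss": "" if g.tss is None else g.tss,
            "pas": "" if g.pas is None else g.pas,
            "class": g.class_label, "biotype": g.biotype,
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def write_genes_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 gene features (attributes carry TSS/PAS/class)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = [f"ID={g.gene_id}", f"biotype={g.biotype}", f"cds_start={g.cds_start}"]
            if g.tss is not None:
                attrs.append(f"tss={g.tss}")
            if g.pas is not None:
                attrs.append(f"pas={g.pas}")
            attrs.append(f"gene_class={g.class_label}")
            fh.write(
                f"{g.chrom}\tspikequant\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{';'.join(attrs)}\n"
            )


def assign_tss(
    genes: list[GeneModel],
    tss_table: Optional[Mapping[str, int] | pd.DataFrame] = None,
    fallback_offset: int = 100,
) -> list[GeneModel]:
    """Fill TSS per gene from an annotation table, with a positional fallback.

    Genes missing from the table get a TSS placed ``fallback_offset`` bp
    upstream of the start codon in the transcription direction (the standard
    −100 bp convention); the ``tss_fallback`` flag records the provenance.
    A table TSS on the wrong chromosome is rejected with a warning and the
    fallback applied.
    """
    table: dict[str, tuple[int, Optional[str]]] = {}
    if isinstance(tss_table, pd.DataFrame):
        for row in tss_table.itertuples(index=False):
            table[str(row.gene_id)] = (int(row.tss), getattr(row, "chrom", None))
    elif tss_table is not None:
        table = {k: (int(v), None) for k, v in tss_table.items()}

    for g in genes:
        entry = table.get(g.gene_id)
        if entry is not None:
            tss, chrom = entry
            if chrom is not None and chrom != g.chrom:
                logger.warning(
                    "assign_tss: TSS for %s on %s, gene on %s; fallback applied",
                    g.gene_id, chrom, g.chrom,
                )
            else:
                g.tss = tss
                g.tss_fallback = False
                continue
        g.tss = g.cds_start - fallback_offset if g.strand == "+" else g.cds_start + fallback_offset
        g.tss_fallback = True
    return genes


def promoter_window(
    gene: GeneModel,
    upstream: int = 300,
    downstream: int = 100,
    chrom_length: Optional[int] = None,
) -> PromoterWindow:
    """Strand-aware half-open promoter interval (default −300..+100 bp of TSS)."""
    if gene.tss is None:
        raise AnnotationError(f"{gene.gene_id}: promoter_window requires a TSS")
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream, gene.tss + upstream
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if chrom_length is not None and end > chrom_length:
        end, clipped = chrom_length, True
    return PromoterWindow(
        gene_id=gene.gene_id, chrom=gene.chrom, start=start, end=end,
        tss=gene.tss, strand=gene.strand,
        upstream_bp=upstream, downstream_bp=downstream, clipped=clipped,
    )


def load_genome(fasta_path: str | Path):
    """Open a genome FASTA as a chrom -> sequence mapping (lazy, indexed).

    Returns a ``pyfaidx.Fasta`` with raw string slicing, usable wherever a
    plain ``{chrom: sequence}`` dict is accepted (e.g. :func:`classify_tata`).
    """
    from pyfaidx import Fasta

    return Fasta(str(fasta_path), as_raw=True)


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_tata(
    genes: list[GeneModel],
    genome: Mapping[str, str],
    scan_upstream: int = 200,
    scan_downstream: int = 0,
) -> list[GeneModel]:
    """Flag promoters containing a TATA-box consensus (TATAWAW, W = A/T).

    The scan covers ``scan_upstream`` bp upstream to ``scan_downstream`` bp
    downstream of the TSS on the sense strand (default −200..TSS). ``N``
    bases never match. ``genome`` maps chromosome name to sequence; a
    ``pyfaidx.Fasta`` works unchanged (slices stringify).
    """
    for g in genes:
        if g.tss is None:
            raise AnnotationError(f"{g.gene_id}: classify_tata requires a TSS")
        if g.strand == "+":
            lo, hi = g.tss - scan_upstream, g.tss + scan_downstream
        else:
            lo, hi = g.tss - scan_downstream, g.tss + scan_upstream
        chrom_seq = genome[g.chrom]
        lo = max(lo, 0)
        window = str(chrom_seq[lo:hi]).upper()
        if g.strand == "-":
            window = reverse_complement(window)
        g.tata = TATA_CONSENSUS.search(window) is not None
    return genes


def filter_detectable(
    counts: pd.DataFrame,
    genes: Sequence[GeneModel] | Sequence[str],
    reference_genes: Optional[Iterable[str]] = None,
) -> list[str]:
    """Genes with a raw count > 0 in every sample, in annotation order.

    Genes present in the count table but absent from the annotation are
    dropped with a warning. When ``reference_genes`` is given (an external
    pre-classified gene list), the result is intersected with it.
    """
    gene_ids = [g.gene_id if isinstance(g, GeneModel) else str(g) for g in genes]
    annotated = set(gene_ids)
    unknown = [g for g in counts.index if g not in annotated]
    if unknown:
        logger.warning("filter_detectable: %d count-table genes not in annotation, dropped", len(unknown))
    detectable = set(counts.index[(counts > 0).all(axis=1)]) & annotated
    if reference_genes is not None:
        detectable &= set(reference_genes)
    return [g for g in gene_ids if g in detectable]
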