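"""Batch FASTA scanning, per-protein summaries, and enrichment curves.

The scanner runs the full pipeline (windows -> labels -> distances ->
regions -> potential) over every record of a FASTA file and emits:

* a summary table, one row per processed sequence, listing the base
  phase-separation potential and the longest predicted PS-ID, ID and
  folded region (sorting by potential or PS-IDR length ranks candidate
  phase separators);
* a FASTA of the predicted PS-IDRs of at least 50 residues;
* cumulative-distribution tables of longest-PS-IDR length and PS
  potential, plus recall curves with AUC against an optional reference
  set -- an AUC above 0.5 means the query set is enriched in
  phase-separation potential relative to the reference;
* a processing log listing skipped records and why.

Sequences shorter than one window plus one residue, or containing
non-canonical residues, are skipped (and logged), not fatal.  UniProt
FASTA headers (``db|ACCESSION|ENTRY Protein name ... GN=gene``) are parsed
into structured identifier fields; any other header is kept verbatim with
the structured fields empty.
"""

from __future__ import annotations

import hashlib
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .potential import (
    PRESETS,
    PotentialParams,
    expanded_potential,
    ps_potential,
    window_contributions,
)
from .segment import (
    Region,
    find_regions,
    longest_region_per_class,
    residue_labels,
)
from .windows import WINDOW_SIZE, encode_sequence, window_table

__all__ = [
    "SequenceRecord",
    "SummaryRow",
    "RecallCurve",
    "ScanConfig",
    "ScanResult",
    "read_fasta",
    "summarize_sequence",
    "scan_fasta",
    "cumulative_curve",
    "recall_auc",
    "build_reference_table",
]


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry with its header parsed where possible."""

    raw_header: str
    sequence: str
    accession: str = ""
    gene: str = ""
    protein_name: str = ""

    @property
    def id(self) -> str:
        """Best identifier: accession if parsed, else first header token."""
        if self.accession:
            return self.accession
        return self.raw_header.split()[0] if self.raw_header else "unnamed"


@dataclass(frozen=True)
class SummaryRow:
    """Per-protein scan output (one row of the summary table)."""

    id: str
    length: int
    ps_potential: float
    longest_ps_idr: int
    longest_idr: int
    longest_folded: int
    accession: str = ""
    gene: str = ""
    protein_name: str = ""
    expanded_potential: float | None = None


@dataclass(frozen=True)
class RecallCurve:
    """Query-vs-reference enrichment curve over a shared threshold grid."""

    thresholds: np.ndarray
    query_fraction: np.ndarray
    reference_fraction: np.ndarray
    auc: float


_UNIPROT_HEADER = re.compile(
    r"^(?:sp|tr|[a-z]{2,3})\|(?P<accession>[^|\s]+)\|(?P<entry>\S+)"
    r"(?:\s+(?P<rest>.*))?$"
)
_FIELD_MARK = re.compile(r"\s+[A-Z]{2}=")
_GENE_MARK = re.compile(r"\bGN=(\S+)")


def _parse_header(header: str) -> tuple[str, str, str]:
    """(accession, gene, protein_name) from a UniProt-style header."""
    match = _UNIPROT_HEADER.match(header)
    if not match:
        return "", "", ""
    accession = match.group("accession")
    rest = match.group("rest") or ""
    gene_match = _GENE_MARK.search(rest)
    gene = gene_match.group(1) if gene_match else ""
    mark = _FIELD_MARK.search(rest)
    protein_name = (rest[: mark.start()] if mark else rest).strip()
    return accession, gene, protein_name


def read_fasta(source) -> list[SequenceRecord]:
    """Read a (possibly multi-line, possibly lowercase) FASTA file.

    ``source`` is a path or an open text handle.  Sequences are upper-
    cased; headers are preserved verbatim and additionally parsed into
    accession/gene/protein-name when they follow the UniProt dialect.
    Raises ``ValueError`` on an empty file.  No residue/length validation
    happens here; the scanner skips and logs invalid records.
    """
    if isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    else:
        handle = source
        close = False
    try:
        records = []
        for rec in SeqIO.parse(handle, "fasta"):
            header = rec.description
            accession, gene, name = _parse_header(header)
            records.append(
                SequenceRecord(
                    raw_header=header,
                    sequence=str(rec.seq).upper(),
                    accession=accession,
                    gene=gene,
                    protein_name=name,
                )
            )
    finally:
        if close:
            handle.close()
    if not records:
        raise ValueError("empty FASTA input: no records found")
    return records


@dataclass(frozen=True)
class ScanConfig:
    """Knobs of a batch scan.

    ``params`` selects the published weight preset for the expanded
    potential; ``expanded`` adds the expanded-potential column to the
    summary; ``segment_on_promoted`` segments regions from labels after
    D-to-P promotion instead of the base labels; ``min_psidr_length``
    is the export threshold for the PS-IDR FASTA.
    """

    window_size: int = WINDOW_SIZE
    params: str = "csat"
    expanded: bool = False
    include_pi: bool = True
    include_q: bool = True
    segment_on_promoted: bool = False
    min_psidr_length: int = 50
    high_potential: float = 100.0

    @property
    def potential_params(self) -> PotentialParams:
        return PRESETS[self.params]

    def digest(self) -> str:
        payload = repr(sorted(self.__dict__.items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


DEFAULT_CONFIG = ScanConfig()


def _analyze(
    record: SequenceRecord, config: ScanConfig
) -> tuple[SummaryRow, list[Region]]:
    table = window_table(
        record.sequence,
        window_size=config.window_size,
        params=config.potential_params,
    )
    base = ps_potential(table)
    expanded: float | None = None
    if config.expanded:
        expanded = expanded_potential(
            table,
            include_pi=config.include_pi,
            include_q=config.include_q,
        )
    labels = table["label"].to_numpy(dtype="U1")
    if config.segment_on_promoted:
        _, promoted = window_contributions(
            table,
            include_pi=config.include_pi,
            include_q=config.include_q,
        )
        labels = labels.copy()
        labels[promoted] = "P"
        table = table.assign(label=labels)
    res_labels = residue_labels(
        table, len(record.sequence), config.window_size
    )
    regions = find_regions(res_labels)
    longest = longest_region_per_class(regions)
    row = SummaryRow(
        id=record.id,
        length=len(record.sequence),
        ps_potential=base,
        longest_ps_idr=longest["PS_ID"],
        longest_idr=longest["ID"],
        longest_folded=longest["FOLDED"],
        accession=record.accession,
        gene=record.gene,
        protein_name=record.protein_name,
        expanded_potential=expanded,
    )
    return row, regions


def summarize_sequence(
    record: SequenceRecord, config: ScanConfig = DEFAULT_CONFIG
) -> SummaryRow:
    """Run the full pipeline on one record and fill a summary row."""
    row, _ = _analyze(record, config)
    return row


def cumulative_curve(
    values: Sequence[float], thresholds: Sequence[float] | None = None
) -> pd.DataFrame:
    """Survival-style table: fraction of values >= each threshold.

    Thresholds default to the distinct observed values, ascending; the
    fraction column is then non-increasing from 1.0.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("empty value list")
    if not np.isfinite(vals).all():
        raise ValueError("values must be finite")
    thr = (
        np.unique(vals)
        if thresholds is None
        else np.asarray(list(thresholds), dtype=float)
    )
    svals = np.sort(vals)
    frac = 1.0 - np.searchsorted(svals, thr, side="left") / vals.size
    return pd.DataFrame({"threshold": thr, "fraction": frac})


def recall_auc(
    query: Sequence[float], reference: Sequence[float]
) -> RecallCurve:
    """Recall curve of a query metric list against a reference list.

    Over the merged grid of distinct observed values, each threshold t
    yields the point (fraction of reference >= t, fraction of query >=
    t); the curve runs from (1, 1) down to (0, 0) (endpoints padded) and
    the AUC is its trapezoidal integral over the reference-fraction axis.
    A set identical to the reference traces the diagonal (AUC 0.5);
    enrichment in the metric pushes the AUC toward 1.
    """
    q = np.asarray(list(query), dtype=float)
    r = np.asarray(list(reference), dtype=float)
    if q.size == 0 or r.size == 0:
        raise ValueError("empty metric list")
    thr = np.unique(np.concatenate([q, r]))
    qs, rs = np.sort(q), np.sort(r)
    qf = 1.0 - np.searchsorted(qs, thr, side="left") / q.size
    rf = 1.0 - np.searchsorted(rs, thr, side="left") / r.size
    # pad endpoints: everything qualifies below min, nothing above max
    qf = np.concatenate(([1.0], qf, [0.0]))
    rf = np.concatenate(([1.0], rf, [0.0]))
    auc = float(np.trapezoid(qf[::-1], rf[::-1]))
    return RecallCurve(
        thresholds=thr,
        query_fraction=qf[1:-1],
        reference_fraction=rf[1:-1],
        auc=auc,
    )


def _provenance(config: ScanConfig) -> str:
    return f"# parse2 v{__version__} config={config.digest()}\n"


def _summary_frame(rows: list[SummaryRow], config: ScanConfig) -> pd.DataFrame:
    data = {
        "id": [r.id for r in rows],
        "length": [r.length for r in rows],
        "ps_potential": [r.ps_potential for r in rows],
        "longest_ps_idr": [r.longest_ps_idr for r in rows],
        "longest_idr": [r.longest_idr for r in rows],
        "longest_folded": [r.longest_folded for r in rows],
        "accession": [r.accession for r in rows],
        "gene": [r.gene for r in rows],
        "protein_name": [r.protein_name for r in rows],
    }
    frame = pd.DataFrame(data)
    if config.expanded:
        frame["expanded_potential"] = [r.expanded_potential for r in rows]
    return frame


@dataclass
class ScanResult:
    """In-memory outputs of a batch scan."""

    summary: pd.DataFrame
    ps_idrs: list[tuple[str, int, int, str]]  # (id, start, end, subseq)
    length_curve: pd.DataFrame
    potential_curve: pd.DataFrame
    log: list[str] = field(default_factory=list)
    length_recall: RecallCurve | None = None
    potential_recall: RecallCurve | None = None
    config: ScanConfig = DEFAULT_CONFIG

    def psidr_fasta(self) -> str:
        out = io.StringIO()
        for rec_id, start, end, subseq in self.ps_idrs:
            out.write(f">{rec_id}|{start}-{end}|PS_IDR\n")
            for k in range(0, len(subseq), 60):
                out.write(subseq[k : k + 60] + "\n")
        return out.getvalue()


def _validate(record: SequenceRecord, window_size: int) -> str | None:
    """Reason the record must be skipped, or None if processable."""
    if len(record.sequence) <= window_size:
        return f"sequence too short (length {len(record.sequence)} <= {window_size})"
    try:
        encode_sequence(record.sequence)
    except ValueError as err:
        return str(err)
    return None


def scan_fasta(
    source,
    config: ScanConfig = DEFAULT_CONFIG,
    reference: pd.DataFrame | None = None,
    output_dir: str | Path | None = None,
) -> ScanResult:
    """Scan a FASTA file (path, handle, or list of records).

    ``reference`` is an optional metric table with columns
    ``longest_ps_idr`` and ``ps_potential`` (see
    :func:`build_reference_table`); when given, recall curves and AUCs of
    the scanned set against it are computed.  When ``output_dir`` is
    given, all outputs are written there as TSV/FASTA/log text with
    deterministic content (identical inputs give byte-identical files).
    """
    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        probe = output_dir / ".write_probe"
        try:
            probe.write_text("")
        finally:
            if probe.exists():
                probe.unlink()

    records = (
        source
        if isinstance(source, list)
        else read_fasta(source)
    )
    rows: list[SummaryRow] = []
    ps_idrs: list[tuple[str, int, int, str]] = []
    log: list[str] = []
    for record in records:
        reason = _validate(record, config.window_size)
        if reason is not None:
            log.append(f"skipped {record.id}: {reason}")
            continue
        row, regions = _analyze(record, config)
        rows.append(row)
        for region in regions:
            if (
                region.klass == "PS_ID"
                and region.length >= config.min_psidr_length
            ):
                subseq = record.sequence[region.start - 1 : region.end]
                ps_idrs.append((record.id, region.start, region.end, subseq))
    log.append(f"processed {len(rows)} of {len(records)} records")

    summary = _summary_frame(rows, config)
    if rows:
        length_curve = cumulative_curve(summary["longest_ps_idr"])
        potential_curve = cumulative_curve(summary["ps_potential"])
    else:
        length_curve = pd.DataFrame({"threshold": [], "fraction": []})
        potential_curve = pd.DataFrame({"threshold": [], "fraction": []})

    length_recall = potential_recall = None
    if reference is not None and rows:
        length_recall = recall_auc(
            summary["longest_ps_idr"], reference["longest_ps_idr"]
        )
        potential_recall = recall_auc(
            summary["ps_potential"], reference["ps_potential"]
        )

    result = ScanResult(
        summary=summary,
        ps_idrs=ps_idrs,
        length_curve=length_curve,
        potential_curve=potential_curve,
        log=log,
        length_recall=length_recall,
        potential_recall=potential_recall,
        config=config,
    )
    if output_dir is not None:
        _write_outputs(result, output_dir)
    return result


def _curve_tsv(curve: pd.DataFrame, recall: RecallCurve | None) -> str:
    out = io.StringIO()
    if recall is not None:
        out.write(f"# recall_auc={recall.auc:.6f}\n")
        frame = pd.DataFrame(
            {
                "threshold": recall.thresholds,
                "query_fraction": recall.query_fraction,
                "reference_fraction": recall.reference_fraction,
            }
        )
        frame.to_csv(out, sep="\t", index=False, float_format="%.6g")
        out.write("#\n")
    curve.to_csv(out, sep="\t", index=False, float_format="%.6g")
    return out.getvalue()


def _write_outputs(result: ScanResult, output_dir: Path) -> None:
    prov = _provenance(result.config)
    with open(output_dir / "summary.tsv", "w") as fh:
        fh.write(prov)
        result.summary.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    (output_dir / "ps_idrs.fasta").write_text(result.psidr_fasta())
    (output_dir / "curve_psidr_length.tsv").write_text(
        prov + _curve_tsv(result.length_curve, result.length_recall)
    )
    (output_dir / "curve_ps_potential.tsv").write_text(
        prov + _curve_tsv(result.potential_curve, result.potential_recall)
    )
    (output_dir / "scan_log.txt").write_text("\n".join(result.log) + "\n")


def build_reference_table(
    source, config: ScanConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Precompute the per-protein metrics of a reference set.

    Returns a table with columns ``id``, ``longest_ps_idr``,
    ``ps_potential`` usable as the ``reference`` of :func:`scan_fasta`
    (the web deployment hard-wires the human proteome here; this package
    accepts any reference set instead).
    """
    result = scan_fasta(source, config=config)
    return result.summary[["id", "longest_ps_idr", "ps_potential"]].copy()
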