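"""FASTA / GFF3 input and primary-transcript selection.

Coding gene structures are read from GFF3 CDS features grouped by their
Parent chain (CDS -> mRNA -> gene).  All coordinates stay 1-based inclusive
(the GFF3 convention) until sequence slicing in :mod:`scubkit.codon_extraction`.
Where a gene carries more than one transcript, a single primary transcript is
retained: the one with the longest total CDS, ties broken by transcript id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO

logger = logging.getLogger(__name__)


@dataclass
class RawTranscript:
    """CDS segments of one transcript, in genomic coordinates.

    ``cds_segments`` are (start, end) pairs, 1-based inclusive, sorted by
    start regardless of strand.  ``source_phase`` keeps the GFF3 phase column
    for reference only; reading frame is always recomputed from segment
    lengths downstream.
    """

    gene_id: str
    transcript_id: str
    seq_id: str
    strand: str
    cds_segments: list[tuple[int, int]]
    source_phase: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(
                f"transcript {self.transcript_id}: strand must be + or -, "
                f"got {self.strand!r}"
            )
        if not self.cds_segments:
            raise ValueError(f"transcript {self.transcript_id}: no CDS segments")
        order = sorted(range(len(self.cds_segments)), key=lambda i: self.cds_segments[i])
        self.cds_segments = [self.cds_segments[i] for i in order]
        if self.source_phase:
            self.source_phase = [self.source_phase[i] for i in order]
        for (s1, e1), (s2, e2) in zip(self.cds_segments, self.cds_segments[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping CDS "
                    f"segments ({s1},{e1}) and ({s2},{e2})"
                )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)


@dataclass
class GffReadReport:
    """Tally of CDS features and transcripts dropped while reading GFF3."""

    n_cds_read: int = 0
    n_cds_ungrouped: int = 0
    n_transcripts: int = 0
    n_dropped_unstranded: int = 0
    n_dropped_multi_seqid: int = 0
    n_dropped_mixed_strand: int = 0


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA into ``{seq_id: upper-case sequence}``.

    The id is the first whitespace-delimited header token.  Duplicate ids and
    empty files are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs


def _grouping_ids(feature, db, dialect_key: str | None) -> tuple[str, str] | None:
    """Resolve (gene_id, transcript_id) for one CDS feature.

    Default: follow Parent to the mRNA, then the mRNA's Parent to the gene.
    Falls back to gene_id / locus_tag attributes on the CDS itself, or to the
    transcript id when no gene-level grouping exists.
    """
    attrs = feature.attributes
    if dialect_key is not None:
        vals = attrs.get(dialect_key)
        if vals:
            return vals[0], vals[0]
        return None
    parents = attrs.get("Parent") or attrs.get("ID")
    if not parents:
        for key in ("gene_id", "locus_tag"):
            vals = attrs.get(key)
            if vals:
                return vals[0], vals[0]
        return None
    tid = parents[0]
    gene = tid
    try:
        parent_feat = db[tid]
        gp = parent_feat.attributes.get("Parent")
        if gp:
            gene = gp[0]
        elif parent_feat.featuretype == "gene":
            gene = tid
    except gffutils.FeatureNotFoundError:
        gvals = attrs.get("gene_id") or attrs.get("locus_tag")
        if gvals:
            gene = gvals[0]
    return gene, tid


def read_gff3_transcripts(
    path: str | Path,
    dialect_key: str | None = None,
) -> tuple[list[RawTranscript], GffReadReport]:
    """Read GFF3 CDS features and group them into :class:`RawTranscript`.

    Parameters
    ----------
    path
        GFF3 file (9 tab-delimited columns, ``Parent``-attributed CDS).
    dialect_key
        Optional attribute key to group CDS features by instead of the
        Parent chain (e.g. ``"locus_tag"`` for bacterial-style annotation).

    Returns
    -------
    transcripts, report
        Transcripts with >= 1 CDS segment, and a tally of dropped features
        (ungrouped, unstranded, multi-contig, mixed-strand).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises heterogeneous parse errors
        raise ValueError(f"cannot parse GFF3 {path}: {exc}") from exc

    report = GffReadReport()
    by_tid: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        report.n_cds_read += 1
        ids = _grouping_ids(cds, db, dialect_key)
        if ids is None:
            report.n_cds_ungrouped += 1
            continue
        gene_id, tid = ids
        entry = by_tid.setdefault(
            tid,
            {"gene": gene_id, "seqids": set(), "strands": set(), "segs": [], "phases": []},
        )
        entry["seqids"].add(cds.seqid)
        entry["strands"].add(cds.strand)
        entry["segs"].append((cds.start, cds.end))
        entry["phases"].append(cds.frame if cds.frame in {"0", "1", "2"} else None)

    transcripts: list[RawTranscript] = []
    for tid in sorted(by_tid):
        entry = by_tid[tid]
        if len(entry["seqids"]) > 1:
            report.n_dropped_multi_seqid += 1
            continue
        if len(entry["strands"]) > 1:
            report.n_dropped_mixed_strand += 1
            continue
        strand = next(iter(entry["strands"]))
        if strand not in {"+", "-"}:
            report.n_dropped_unstranded += 1
            continue
        transcripts.append(
            RawTranscript(
                gene_id=entry["gene"],
                transcript_id=tid,
                seq_id=next(iter(entry["seqids"])),
                strand=strand,
                cds_segments=entry["segs"],
                source_phase=entry["phases"],
            )
        )
    report.n_transcripts = len(transcripts)
    if report.n_cds_ungrouped:
        logger.warning("%d CDS features lacked a grouping attribute", report.n_cds_ungrouped)
    return transcripts, report


def select_primary_transcript(transcripts: list[RawTranscript]) -> list[RawTranscript]:
    """Keep one transcript per gene: longest total CDS, ties by transcript id.

    The choice is deterministic and annotation-agnostic (no reliance on
    "canonical" tags).
    """
    by_gene: dict[str, list[RawTranscript]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    primary = [
        min(ts, key=lambda t: (-t.cds_length, t.transcript_id))
        for ts in by_gene.values()
    ]
    primary.sort(key=lambda t: (t.seq_id, t.cds_segments[0][0], t.gene_id))
    return primary


def write_gff3(transcripts: list[RawTranscript], path: str | Path) -> None:
    """Write transcripts back out as normalized GFF3 (CDS features only)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            phases = t.source_phase or [None] * len(t.cds_segments)
            for (start, end), phase in zip(t.cds_segments, phases):
                fh.write(
                    "\t".join(
                        [
                            t.seq_id,
                            "scubkit",
                            "CDS",
                            str(start),
                            str(end),
                            ".",
                            t.strand,
                            phase if phase is not None else ".",
                            f"Parent={t.transcript_id};gene_id={t.gene_id}",
                        ]
                    )
                    + "\n"
                )
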