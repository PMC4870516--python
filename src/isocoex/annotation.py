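"""Gene-model parsing and cataloging of alternative 3'-terminal exon events.

An event pairs an upstream alternative 3'-terminal exon (UA3E) -- the last
exon of a short isoform -- with the first downstream exon of a longer
isoform (AIDE) that shares the same splice donor.  The UA3E must lie wholly
inside the intron of the long isoform, its acceptor must not double as an
internal-exon acceptor anywhere in the gene (which would make it a cassette
exon), and the two acceptors must differ (tandem alternative-polyadenylation
variants share one acceptor and are excluded).

Coordinates are 0-based half-open internally; GTF input is 1-based
inclusive; BED-style output is 0-based half-open.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import gffutils
import pandas as pd

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "UA3EEvent",
    "WindowSet",
    "GTFParseError",
    "parse_gene_models",
    "catalog_ua3e_events",
    "extract_3ss_windows",
    "events_to_frame",
    "events_from_frame",
    "windows_to_fasta",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class GTFParseError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    strand: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def donor(self) -> int:
        """Genomic coordinate of the exon's 3' edge (splice-donor side)."""
        return self.end if self.strand == "+" else self.start

    @property
    def acceptor(self) -> int:
        """Genomic coordinate of the exon's 5' edge (3' splice site)."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    gene_id: str
    exons: tuple  # GenomicInterval, ordered 5'->3' in transcript orientation

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"transcript {self.transcript_id} spans chrom/strand")

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    def exon_chain(self) -> tuple:
        return tuple((e.start, e.end) for e in self.exons)


@dataclass(frozen=True)
class UA3EEvent:
    event_id: str
    gene_id: str
    chrom: str
    strand: str
    shared_donor: int
    ua3e: GenomicInterval
    aide_first: GenomicInterval
    ua3e_3ss: int
    aide_3ss: int


@dataclass(frozen=True)
class WindowSet:
    """Strand-corrected RNA sequence around a UA3E 3' splice site.

    ``intronic_seq`` (region R4) lies immediately upstream of the acceptor,
    ``exonic_seq`` (R5) immediately downstream, both written 5'->3' on the
    transcript sense strand with T already converted to U.
    """

    event_id: str
    intronic_seq: str
    exonic_seq: str
    width: int

    @property
    def sequence(self) -> str:
        return self.intronic_seq + self.exonic_seq


def parse_gene_models(annotation) -> dict:
    """Parse GTF exon features into per-gene transcript models.

    ``annotation`` may be a path or a string/stream of GTF text.  Exons are
    returned 5'->3' in transcript orientation with 0-based half-open
    coordinates.  Malformed lines raise :class:`GTFParseError` naming the
    line number; transcripts without exon features are dropped with a
    warning.
    """
    if hasattr(annotation, "read"):
        text = annotation.read()
    elif isinstance(annotation, (str, os.PathLike)) and os.path.exists(str(annotation)):
        with open(annotation) as fh:
            text = fh.read()
    else:
        text = str(annotation)

    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 9:
            raise GTFParseError(
                f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
        if fields[2].lower() == "exon":
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise GTFParseError(f"line {lineno}: non-integer coordinates") from None
            if start > end:
                raise GTFParseError(f"line {lineno}: start > end")
            if fields[6] not in ("+", "-"):
                raise GTFParseError(f"line {lineno}: strand must be + or -")

    if not text.strip():
        return {}
    db = gffutils.create_db(
        text, ":memory:", from_string=True, force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True)

    by_transcript: dict = {}
    for feat in db.features_of_type("exon"):
        try:
            gene_id = feat.attributes["gene_id"][0]
            tx_id = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise GTFParseError(f"exon at {feat.seqid}:{feat.start} missing {exc}")
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        by_transcript.setdefault((gene_id, tx_id), []).append(iv)

    genes: dict = {}
    for (gene_id, tx_id), exons in by_transcript.items():
        exons.sort(key=lambda e: e.start)
        if exons[0].strand == "-":
            exons = exons[::-1]
        tm = TranscriptModel(transcript_id=tx_id, gene_id=gene_id,
                             exons=tuple(exons))
        genes.setdefault(gene_id, []).append(tm)
    for gene_id, txs in genes.items():
        txs.sort(key=lambda t: t.transcript_id)
    return genes


def _dedupe_transcripts(transcripts) -> list:
    seen = {}
    for t in transcripts:
        key = (t.chrom, t.strand, t.exon_chain())
        seen.setdefault(key, t)
    return list(seen.values())


def catalog_ua3e_events(genes: Mapping[str, list]) -> list:
    """Catalog UA3E/AIDE event pairs from parsed gene models.

    Emits one event per (terminal exon, longer isoform) pair sharing the
    upstream splice donor, after removing cassette-exon and shared-acceptor
    (tandem APA) configurations.  Duplicate events with the same donor and
    acceptor pair are collapsed.
    """
    events = []
    for gene_id in sorted(genes):
        transcripts = _dedupe_transcripts(genes[gene_id])
        internal_acceptors = set()
        for t in transcripts:
            for e in t.exons[1:-1]:
                internal_acceptors.add(e.acceptor)
        seen = set()
        for s in transcripts:
            if len(s.exons) < 2:
                continue
            terminal = s.exons[-1]
            upstream = s.exons[-2]
            donor = upstream.donor
            if terminal.acceptor in internal_acceptors:
                continue  # cassette-exon configuration
            for l in transcripts:
                if l is s:
                    continue
                for i, exon in enumerate(l.exons[:-1]):
                    if exon.donor != donor:
                        continue
                    aide = l.exons[i + 1]
                    if terminal.acceptor == aide.acceptor:
                        continue  # shared acceptor: tandem APA, not an A3E choice
                    lo, hi = ((donor, aide.start) if s.strand == "+"
                              else (aide.end, donor))
                    if not (lo < terminal.start and terminal.end < hi):
                        continue  # UA3E must sit wholly inside the intron
                    key = (s.chrom, s.strand, donor,
                           terminal.acceptor, aide.acceptor)
                    if key in seen:
                        continue
                    seen.add(key)
                    events.append(UA3EEvent(
                        event_id=(f"{gene_id}|{s.chrom}:{donor}:"
                                  f"{terminal.acceptor}:{aide.acceptor}:{s.strand}"),
                        gene_id=gene_id, chrom=s.chrom, strand=s.strand,
                        shared_donor=donor, ua3e=terminal, aide_first=aide,
                        ua3e_3ss=terminal.acceptor, aide_3ss=aide.acceptor))
    events.sort(key=lambda e: (e.chrom, e.shared_donor, e.ua3e_3ss, e.aide_3ss))
    return events


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[start:end) handling pyfaidx objects and plain mappings."""
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not present in the genome")
    seq = genome[chrom]
    if hasattr(seq, "__getitem__") and not isinstance(seq, str):
        piece = seq[start:end]
        return str(piece.seq if hasattr(piece, "seq") else piece)
    return str(seq)[start:end]


def _contig_length(genome, chrom: str) -> int:
    seq = genome[chrom]
    return len(seq)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_3ss_windows(event: UA3EEvent, genome, width: int = 250,
                        intronic_fraction: float = 0.5) -> WindowSet:
    """Sequence window centered on the UA3E 3' splice site.

    ``width * intronic_fraction`` nt of intron (R4) followed by the
    remaining exonic nucleotides (R5), strand-corrected and T->U converted.
    Windows running off the contig are truncated with a warning; the
    recorded lengths reflect the truncation.
    """
    if width < 2:
        raise ValueError("width must be at least 2 nt")
    up = int(round(width * intronic_fraction))
    down = width - up
    chrom_len = _contig_length(genome, event.chrom)
    ss = event.ua3e_3ss
    if event.strand == "+":
        istart, iend = ss - up, ss
        estart, eend = ss, ss + down
    else:
        istart, iend = ss, ss + up
        estart, eend = ss - down, ss
    lo = min(istart, estart)
    hi = max(iend, eend)
    if lo < 0 or hi > chrom_len:
        warnings.warn(
            f"window for {event.event_id} truncated at contig boundary")
    istart, iend = max(0, istart), min(chrom_len, iend)
    estart, eend = max(0, estart), min(chrom_len, eend)
    intronic = _fetch(genome, event.chrom, istart, iend)
    exonic = _fetch(genome, event.chrom, estart, eend)
    if event.strand == "-":
        intronic = reverse_complement(intronic)
        exonic = reverse_complement(exonic)
    intronic = intronic.upper().replace("T", "U")
    exonic = exonic.upper().replace("T", "U")
    return WindowSet(event_id=event.event_id, intronic_seq=intronic,
                     exonic_seq=exonic, width=len(intronic) + len(exonic))


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = ["chrom", "start", "end", "event_id", "score", "strand",
                  "gene_id", "donor", "ua3e_3ss", "aide_3ss",
                  "aide_start", "aide_end"]


def events_to_frame(events: Iterable[UA3EEvent]) -> pd.DataFrame:
    """Events as a BED-style table (0-based half-open, UA3E exon interval)."""
    rows = [
        (e.chrom, e.ua3e.start, e.ua3e.end, e.event_id, 0, e.strand,
         e.gene_id, e.shared_donor, e.ua3e_3ss, e.aide_3ss,
         e.aide_first.start, e.aide_first.end)
        for e in events
    ]
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def events_from_frame(df: pd.DataFrame) -> list:
    events = []
    for row in df.itertuples(index=False):
        ua3e = GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)
        aide = GenomicInterval(row.chrom, int(row.aide_start),
                               int(row.aide_end), row.strand)
        events.append(UA3EEvent(
            event_id=row.event_id, gene_id=row.gene_id, chrom=row.chrom,
            strand=row.strand, shared_donor=int(row.donor), ua3e=ua3e,
            aide_first=aide, ua3e_3ss=int(row.ua3e_3ss),
            aide_3ss=int(row.aide_3ss)))
    return events


def windows_to_fasta(windows: Iterable[WindowSet]) -> str:
    """FASTA text with ``event_id|R4`` and ``event_id|R5`` records."""
    out = []
    for w in windows:
        out.append(f">{w.event_id}|R4\n{w.intronic_seq}")
        out.append(f">{w.event_id}|R5\n{w.exonic_seq}")
    return "\n".join(out) + "\n"
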