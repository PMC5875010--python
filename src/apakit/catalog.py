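"""Poly(A)-site catalogs, terminal exons, and genomic window sequences.

Alternative polyadenylation is quantified per *terminal exon with tandem
poly(A) sites* (TETPS): a transcript's last exon that carries at least two
cleavage sites from a poly(A)-site catalog.  This module parses the two
annotation inputs (a BED6 site catalog and a BED12 transcript annotation),
builds TETPS records with their sites ordered 5'->3' in transcript
orientation, and extracts strand-aware sequence windows around sites.

Coordinates are 0-based half-open throughout, as in BED.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger("apakit")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: nt appended past the annotated exon end when assigning sites and building
#: coverage profiles; distal cleavage sites frequently map just past the
#: annotated 3' end.
DISTAL_EXTENSION = 200


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PolyASite:
    """A single cleavage/polyadenylation site.

    ``position`` is the 0-based genomic coordinate of the cleavage base.
    """

    chrom: str
    position: int
    strand: str
    site_id: str
    score: float = 0.0
    exon_id: str | None = None

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"site {self.site_id}: negative position")
        if self.strand not in ("+", "-"):
            raise ValueError(f"site {self.site_id}: invalid strand {self.strand!r}")


@dataclass
class TerminalExon:
    """A terminal exon and its assigned poly(A) sites (5'->3')."""

    chrom: str
    start: int
    end: int
    strand: str
    exon_id: str
    transcript_ids: list[str] = field(default_factory=list)
    sites: list[PolyASite] = field(default_factory=list)

    @property
    def is_tetps(self) -> bool:
        return len(self.sites) >= 2

    @property
    def length(self) -> int:
        return self.end - self.start

    def site_offset(self, site: PolyASite) -> int:
        """Transcript-oriented offset of a site's cleavage base from exon start."""
        if self.strand == "+":
            return site.position - self.start
        return (self.end - 1) - site.position


class WindowSpec(NamedTuple):
    """A sequence window relative to a cleavage site, transcript-oriented.

    Offsets are in nt relative to the cleavage base (offset 0); negative
    values are upstream.  The window covers offsets
    ``[upstream_offset, downstream_offset)``.
    """

    upstream_offset: int
    downstream_offset: int

    @property
    def width(self) -> int:
        w = self.downstream_offset - self.upstream_offset
        if w <= 0:
            raise ValueError("window width must be positive")
        return w


class WindowSequence(NamedTuple):
    sequence: str
    truncated: bool


# ---------------------------------------------------------------------------
# BED parsing
# ---------------------------------------------------------------------------

def read_pas_catalog(path: str, genome_assembly_tag: str = "") -> list[PolyASite]:
    """Read a poly(A)-site catalog from BED (>=6 columns).

    The cleavage position of a record is its 3'-most base in transcript
    orientation: catalogs store single-base cleavage sites, and wider records
    are clusters whose representative site is the cleavage end.  Input order
    is preserved.
    """
    sites: list[PolyASite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: BED catalog needs >=6 columns "
                    f"(chrom,start,end,name,score,strand), got {len(fields)}"
                )
            chrom, start_s, end_s, name, score_s, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            position = end - 1 if strand == "+" else start
            try:
                score = float(score_s)
            except ValueError:
                score = 0.0
            sites.append(PolyASite(chrom, position, strand, name, score))
    if genome_assembly_tag:
        logger.info("read %d poly(A) sites (%s) from %s",
                    len(sites), genome_assembly_tag, path)
    return sites


def write_catalog(sites: Iterable[PolyASite], path: str) -> None:
    """Write sites as single-base BED6 records (round-trips coordinates)."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.position}\t{s.position + 1}\t"
                     f"{s.site_id}\t{s.score:g}\t{s.strand}\n")


@dataclass
class TranscriptModel:
    """Minimal transcript structure from one BED12 record."""

    chrom: str
    start: int
    end: int
    name: str
    strand: str
    exons: list[tuple[int, int]]  # genomic order

    @property
    def terminal_exon(self) -> tuple[int, int]:
        """Genomic interval of the 3'-most exon in transcript orientation."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]

    @property
    def upstream_exons(self) -> list[tuple[int, int]]:
        """Exons 5' of the terminal exon, nearest first."""
        if self.strand == "+":
            return list(reversed(self.exons[:-1]))
        return self.exons[1:]


def read_bed12(path: str) -> list[TranscriptModel]:
    """Parse a BED12 transcript annotation."""
    models: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 columns, got {len(f)}")
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}:{lineno}: block count mismatch")
            exons = [(start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)]
            models.append(TranscriptModel(chrom, start, end, name, strand, exons))
    return models


# ---------------------------------------------------------------------------
# TETPS identification
# ---------------------------------------------------------------------------

def _exon_key(chrom: str, start: int, end: int, strand: str) -> str:
    return f"{chrom}:{start}-{end}:{strand}"


def find_tetps(
    annotation: Sequence[TranscriptModel],
    catalog: Sequence[PolyASite],
    stranded_protocol: bool = True,
    extension: int = DISTAL_EXTENSION,
    gene_of: Mapping[str, str] | None = None,
) -> list[TerminalExon]:
    """Identify terminal exons with tandem poly(A) sites.

    Terminal exons overlapping another annotated transcript on the same
    strand are dropped; with an unstranded protocol, exons overlapping a
    transcript on the opposite strand are dropped as well (their coverage
    cannot be attributed to one strand).  Sites are assigned to the exon
    interval extended by ``extension`` nt at the 3' end; a site falling into
    two same-strand exon windows goes to the exon whose annotated 3' end is
    nearest.  Only exons with >=2 assigned sites are returned.

    ``gene_of`` optionally maps transcript names to gene ids; when given,
    overlap with transcripts of the *same* gene is ignored (by default any
    other transcript counts).
    """
    # group transcripts by identical terminal exon
    exon_map: dict[str, TerminalExon] = {}
    for tm in annotation:
        es, ee = tm.terminal_exon
        key = _exon_key(tm.chrom, es, ee, tm.strand)
        te = exon_map.get(key)
        if te is None:
            te = TerminalExon(tm.chrom, es, ee, tm.strand, key)
            exon_map[key] = te
        te.transcript_ids.append(tm.name)

    # transcript-span interval trees per (chrom, strand)
    trees: dict[tuple[str, str], IntervalTree] = {}
    for tm in annotation:
        trees.setdefault((tm.chrom, tm.strand), IntervalTree()).addi(
            tm.start, tm.end, tm.name)

    def overlaps_foreign(te: TerminalExon, strand: str) -> bool:
        tree = trees.get((te.chrom, strand))
        if tree is None:
            return False
        own = set(te.transcript_ids)
        own_genes = ({gene_of[t] for t in own if t in gene_of}
                     if gene_of is not None else None)
        for iv in tree.overlap(te.start, te.end):
            name = iv.data
            if strand == te.strand and name in own:
                continue
            if own_genes is not None and gene_of.get(name) in own_genes:
                continue
            return True
        return False

    kept: list[TerminalExon] = []
    for te in exon_map.values():
        if overlaps_foreign(te, te.strand):
            logger.debug("dropping %s: same-strand transcript overlap", te.exon_id)
            continue
        if not stranded_protocol and overlaps_foreign(
                te, "-" if te.strand == "+" else "+"):
            logger.debug("dropping %s: antisense overlap (unstranded data)", te.exon_id)
            continue
        kept.append(te)

    # site assignment: partition, nearest-3'-end tie-break
    windows: dict[tuple[str, str], IntervalTree] = {}
    for i, te in enumerate(kept):
        if te.strand == "+":
            lo, hi = te.start, te.end + extension
        else:
            lo, hi = te.start - extension, te.end
        windows.setdefault((te.chrom, te.strand), IntervalTree()).addi(
            max(lo, 0), hi, i)

    for site in catalog:
        tree = windows.get((site.chrom, site.strand))
        if tree is None:
            continue
        hits = [iv.data for iv in tree.overlap(site.position, site.position + 1)]
        if not hits:
            continue
        if len(hits) > 1:
            def end_dist(i: int) -> int:
                te = kept[i]
                three_p = te.end - 1 if te.strand == "+" else te.start
                return abs(site.position - three_p)
            hits.sort(key=lambda i: (end_dist(i), kept[i].exon_id))
            logger.info("site %s falls in %d terminal exons; assigned to %s",
                        site.site_id, len(hits), kept[hits[0]].exon_id)
        te = kept[hits[0]]
        site.exon_id = te.exon_id
        te.sites.append(site)

    result = []
    for te in kept:
        if len(te.sites) < 2:
            continue
        te.sites.sort(key=lambda s: s.position, reverse=(te.strand == "-"))
        result.append(te)
    return result


def write_tetps_table(exons: Iterable[TerminalExon], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("exon_id\tchrom\tstart\tend\tstrand\tn_sites\tsite_ids\n")
        for te in exons:
            ids = ",".join(s.site_id for s in te.sites)
            fh.write(f"{te.exon_id}\t{te.chrom}\t{te.start}\t{te.end}\t"
                     f"{te.strand}\t{len(te.sites)}\t{ids}\n")


# ---------------------------------------------------------------------------
# Window sequences
# ---------------------------------------------------------------------------

def fetch_window_sequence(site: PolyASite, window: WindowSpec, genome) -> WindowSequence:
    """Fetch the transcript-oriented sequence of a window around a site.

    ``genome`` is a ``pyfaidx.Fasta``-like mapping of chromosome name to an
    indexable sequence.  Minus-strand windows are reverse-complemented so the
    returned string reads 5'->3' along the transcript.  Windows overhanging a
    contig edge are truncated and flagged.
    """
    width = window.width  # validates
    if site.chrom not in genome:
        raise KeyError(f"chromosome {site.chrom!r} not present in genome FASTA")
    contig = genome[site.chrom]
    contig_len = len(contig)
    if site.strand == "+":
        lo = site.position + window.upstream_offset
        hi = lo + width
    else:
        hi = site.position - window.upstream_offset + 1
        lo = hi - width
    clo, chi = max(lo, 0), min(hi, contig_len)
    truncated = (clo, chi) != (lo, hi)
    if chi <= clo:
        return WindowSequence("", True)
    seq = str(contig[clo:chi]).upper()
    if site.strand == "-":
        seq = reverse_complement(seq)
    return WindowSequence(seq, truncated)
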