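"""Quantification of tandem poly(A)-site usage from RNA-seq read coverage.

The approach rests on a simple observation: when an internal (proximal)
poly(A) site of a terminal exon is used, read coverage drops at that site,
because only the longer isoforms extend past it.  A terminal exon's coverage
profile is therefore approximately piecewise constant, with one step per used
site.  The pipeline:

1. sample integrity — samples with non-uniform coverage along transcript
   bodies (low median transcript integrity number, TIN) are excluded;
2. coverage profiles — nucleotide-wise coverage over each terminal exon with
   tandem poly(A) sites (TETPS), extended 200 nt past the 3' end, with
   mate-overlap-aware counting and optional upstream-exon extension;
3. distal-site identification on the pooled (all-samples) profile;
4. recursive segmentation at catalog sites by the mean-squared-error (MSE)
   ratio criterion, with replicate consistency and clustering of closely
   spaced sites;
5. a validity check comparing catalog-restricted breakpoints with the best
   unrestricted breakpoints;
6. relative usage per site from segment-mean differences, and
   reads-per-million (RPM) normalization.

All quantification is deterministic; coordinates inside profiles are array
indices oriented 5'->3' along the transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .catalog import DISTAL_EXTENSION, PolyASite, TerminalExon

logger = logging.getLogger("apakit")

# default tunables
MSE_THRESHOLD = 0.5      # max (MSE_u + MSE_d) / MSE_t for a used site
MIN_SEGMENT = 100        # nt; minimum segment length on either side of a breakpoint
CLUSTER_SPAN = 200       # nt; sites closer than this compete as one cluster
DISTAL_DOWN_WINDOW = 200  # nt downstream of a candidate distal site
MIN_MEAN_COVERAGE = 5.0  # pooled mean coverage gate over exon start..distal site
MIN_TIN = 70.0           # median TIN gate per sample
VALID_CHECK_TOLERANCE = 200  # nt; max distance of a global breakpoint upstream of a used site


# ---------------------------------------------------------------------------
# Sample integrity (TIN)
# ---------------------------------------------------------------------------

def tin_score(coverage: np.ndarray) -> float:
    """Transcript integrity number: coverage uniformity along one transcript.

    Defined as 100 * exp(H) / L, where H is the Shannon entropy of the
    per-base coverage distribution and L the transcript length.  Uniform
    coverage gives 100; coverage concentrated on a single base tends to 0
    as L grows.  Returns NaN for all-zero coverage.
    """
    c = np.asarray(coverage, dtype=float)
    total = c.sum()
    if total <= 0 or c.size == 0:
        return float("nan")
    p = c / total
    p = p[p > 0]
    h = -(p * np.log(p)).sum()
    return float(100.0 * np.exp(h) / c.size)


@dataclass
class SampleIntegrity:
    sample_id: str
    median_tin: float
    passed: bool
    n_transcripts: int
    reason: str = ""


def assess_sample_integrity(
    per_transcript_coverage: Mapping[str, np.ndarray],
    sample_id: str = "",
    min_tin: float = MIN_TIN,
) -> SampleIntegrity:
    """Median TIN over transcripts; the sample passes iff it is >= ``min_tin``.

    Transcripts with all-zero coverage have undefined TIN and are excluded
    from the median; a sample with no valid transcript fails explicitly.
    """
    tins = [t for t in (tin_score(c) for c in per_transcript_coverage.values())
            if not np.isnan(t)]
    if not tins:
        return SampleIntegrity(sample_id, float("nan"), False, 0,
                               "no transcript with nonzero coverage")
    med = float(np.median(tins))
    passed = med >= min_tin
    return SampleIntegrity(sample_id, med, passed, len(tins),
                           "" if passed else f"median TIN {med:.1f} < {min_tin:g}")


# ---------------------------------------------------------------------------
# Coverage profiles
# ---------------------------------------------------------------------------

@dataclass
class CoverageProfile:
    """Per-sample nucleotide coverage over an extended terminal exon.

    ``values`` is oriented 5'->3' in transcript direction: index
    ``extended_5p`` is the first base of the annotated exon, and the final
    ``extended_3p`` entries lie past the annotated 3' end.
    """

    exon_id: str
    sample_id: str
    values: np.ndarray
    strand: str
    extended_5p: int = 0
    extended_3p: int = DISTAL_EXTENSION
    exon: TerminalExon | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError(f"{self.exon_id}/{self.sample_id}: negative coverage")
        if self.extended_3p < DISTAL_DOWN_WINDOW:
            raise ValueError("3' extension must cover the distal test window "
                             f"({DISTAL_DOWN_WINDOW} nt)")
        if self.exon is not None:
            expect = self.extended_5p + self.exon.length + self.extended_3p
            if self.values.size != expect:
                raise ValueError(
                    f"{self.exon_id}/{self.sample_id}: profile length "
                    f"{self.values.size} != exon+extensions {expect}")

    def site_index(self, site: PolyASite) -> int:
        """Array index of a site's cleavage base."""
        if self.exon is None:
            raise ValueError("profile has no exon attached")
        idx = self.extended_5p + self.exon.site_offset(site)
        if not 0 <= idx < self.values.size:
            raise ValueError(f"site {site.site_id} outside profile of {self.exon_id}")
        return idx

    @property
    def exon_start_index(self) -> int:
        return self.extended_5p


def pool_profiles(profiles: Sequence[CoverageProfile]) -> CoverageProfile:
    """Sum coverage over samples (the joint profile used for distal-site calls)."""
    first = profiles[0]
    values = np.sum([p.values for p in profiles], axis=0)
    return CoverageProfile(first.exon_id, "pooled", values, first.strand,
                           first.extended_5p, first.extended_3p, first.exon)


def read_coverage_tsv(path: str) -> dict[tuple[str, str], tuple[np.ndarray, int, int]]:
    """Read per-exon coverage arrays from TSV.

    Columns: exon_id, sample_id, comma-separated per-nucleotide values
    (5'->3' in transcript orientation), and optionally extended_5p and
    extended_3p (defaults 0 and 200).  Comment lines start with '#'.
    """
    out: dict[tuple[str, str], tuple[np.ndarray, int, int]] = {}
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if header is None and f[0] == "exon_id":
                header = f
                continue
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns")
            values = np.array([float(x) for x in f[2].split(",")])
            e5 = int(f[3]) if len(f) > 3 else 0
            e3 = int(f[4]) if len(f) > 4 else DISTAL_EXTENSION
            out[(f[0], f[1])] = (values, e5, e3)
    return out


def write_coverage_tsv(profiles: Iterable[CoverageProfile], path: str,
                       header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("exon_id\tsample_id\tvalues\textended_5p\textended_3p\n")
        for p in profiles:
            vals = ",".join(f"{v:g}" for v in p.values)
            fh.write(f"{p.exon_id}\t{p.sample_id}\t{vals}\t"
                     f"{p.extended_5p}\t{p.extended_3p}\n")


# --- alignment-backed coverage ---------------------------------------------

def _reopen(alignments) -> "pysam.AlignmentFile":
    """Fresh handle on the same file (plain SAM cannot be rewound)."""
    name = alignments.filename
    if isinstance(name, bytes):
        name = name.decode()
    return pysam.AlignmentFile(name)


def _fragment_strand(read) -> str:
    # forward-stranded library convention: read1 (or a single-end read) maps
    # to the transcript strand, read2 to the opposite strand
    reverse = bool(read.is_reverse)
    if read.is_paired and read.is_read2:
        reverse = not reverse
    return "-" if reverse else "+"


def coverage_from_alignments(alignments, chrom: str, start: int, end: int,
                             strand: str, stranded: bool = True) -> np.ndarray:
    """Per-base coverage over [start, end) from a pysam AlignmentFile.

    Overlapping mates of a pair contribute one count per base (the union of
    their aligned blocks is used).  With an unstranded protocol all reads at
    the locus are counted; otherwise only fragments on ``strand``.
    Works with or without an index (full scan when none is available).
    """
    if chrom not in alignments.references:
        raise ValueError(f"chromosome {chrom!r} absent from alignment header")
    handle = None
    try:
        it = alignments.fetch(chrom, max(start, 0), end)
    except ValueError:  # no random access (e.g. plain SAM): full scan
        handle = _reopen(alignments)
        it = (r for r in handle.fetch(until_eof=True)
              if r.reference_name == chrom and not r.is_unmapped
              and r.reference_start < end and r.reference_end is not None
              and r.reference_end > start)
    fragments: dict[str, list[tuple[int, int]]] = {}
    for read in it:
        if read.is_unmapped or read.is_secondary or read.is_supplementary \
                or read.is_qcfail or read.is_duplicate:
            continue
        if stranded and _fragment_strand(read) != strand:
            continue
        fragments.setdefault(read.query_name, []).extend(read.get_blocks())
    if handle is not None:
        handle.close()
    cov = np.zeros(end - start, dtype=float)
    for blocks in fragments.values():
        blocks.sort()
        merged: list[list[int]] = []
        for b0, b1 in blocks:
            b0, b1 = max(b0, start), min(b1, end)
            if b1 <= b0:
                continue
            if merged and b0 <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b1)
            else:
                merged.append([b0, b1])
        for b0, b1 in merged:
            cov[b0 - start:b1 - start] += 1
    return cov


def _junction_support(alignments, chrom: str, boundary: int, strand: str,
                      candidates: Sequence[tuple[int, int]],
                      stranded: bool = True) -> dict[tuple[int, int], int]:
    """Count spliced reads joining each candidate upstream exon to ``boundary``.

    ``boundary`` is the genomic coordinate of the current 5' end of the
    region being extended (exon start for '+', exon end for '-').
    """
    counts: dict[tuple[int, int], int] = {c: 0 for c in candidates}
    lo, hi = boundary - 1, boundary + 1
    handle = None
    try:
        it = alignments.fetch(chrom, max(lo - 500000, 0), hi + 500000)
    except ValueError:
        handle = _reopen(alignments)
        it = handle.fetch(until_eof=True)
    for read in it:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.reference_name != chrom:
            continue
        if stranded and _fragment_strand(read) != strand:
            continue
        blocks = read.get_blocks()
        for (a0, a1), (b0, b1) in zip(blocks, blocks[1:]):
            if a1 == b0:
                continue
            if strand == "+" and b0 == boundary:
                for c in candidates:
                    if c[1] == a1:
                        counts[c] += 1
            elif strand == "-" and a1 == boundary:
                for c in candidates:
                    if c[0] == b0:
                        counts[c] += 1
    if handle is not None:
        handle.close()
    return counts


def build_coverage_profile(
    exon: TerminalExon,
    alignments,
    sample_id: str,
    read_length: int,
    stranded: bool = True,
    extension_3p: int = DISTAL_EXTENSION,
    upstream_exons: Sequence[tuple[int, int]] | None = None,
    min_upstream_dist: int = 250,
) -> CoverageProfile:
    """Build the transcript-oriented coverage profile of one TETPS.

    The locus is extended ``extension_3p`` nt past the annotated 3' end.  If
    the 5'-most assigned site lies within ``min_upstream_dist`` nt of the
    exon start, coverage from the upstream exon with most spliced-read
    support into the exon is prepended (repeatedly, while short of
    ``min_upstream_dist`` and junction evidence remains), so that proximal
    sites have enough upstream signal to be evaluated.
    """
    if exon.strand == "+":
        g_lo, g_hi = exon.start, exon.end + extension_3p
    else:
        g_lo, g_hi = exon.start - extension_3p, exon.end
    cov = coverage_from_alignments(alignments, exon.chrom, g_lo, g_hi,
                                   exon.strand, stranded)
    if exon.strand == "-":
        cov = cov[::-1]

    extended_5p = 0
    if exon.sites and upstream_exons:
        proximal_off = min(exon.site_offset(s) for s in exon.sites)
        boundary = exon.start if exon.strand == "+" else exon.end
        remaining = list(upstream_exons)
        while proximal_off + extended_5p < min_upstream_dist and remaining:
            support = _junction_support(alignments, exon.chrom, boundary,
                                        exon.strand, remaining, stranded)
            best = max(remaining, key=lambda c: support[c])
            if support[best] <= 0:
                break
            up_cov = coverage_from_alignments(alignments, exon.chrom, best[0],
                                              best[1], exon.strand, stranded)
            if exon.strand == "-":
                up_cov = up_cov[::-1]
            cov = np.concatenate([up_cov, cov])
            extended_5p += best[1] - best[0]
            boundary = best[0] if exon.strand == "+" else best[1]
            remaining.remove(best)
    return CoverageProfile(exon.exon_id, sample_id, cov, exon.strand,
                           extended_5p, extension_3p, exon)


# ---------------------------------------------------------------------------
# Distal-site identification
# ---------------------------------------------------------------------------

def identify_distal_site(
    exon: TerminalExon,
    pooled_profile: CoverageProfile,
    read_length: int,
    down_window: int = DISTAL_DOWN_WINDOW,
    start_fraction: float = 0.1,
) -> PolyASite | None:
    """Most distal site with pooled-coverage evidence of being processed.

    Walking 3'->5' over the catalog sites, a site qualifies if (1) mean
    coverage in the ``down_window`` nt downstream is strictly lower than in
    the 2*read_length nt upstream, and (2) it is at most ``start_fraction``
    of the mean coverage within one read length of the exon start.  Returns
    None when no site qualifies.
    """
    v = pooled_profile.values
    s0 = pooled_profile.exon_start_index
    start_mean = float(v[s0:s0 + read_length].mean())
    for site in reversed(exon.sites):
        i = pooled_profile.site_index(site)
        down = v[i + 1:i + 1 + down_window]
        if down.size == 0:
            continue
        up = v[max(i + 1 - 2 * read_length, 0):i + 1]
        if up.size == 0:
            continue
        dmean = float(down.mean())
        if dmean < float(up.mean()) and dmean <= start_fraction * start_mean:
            return site
    return None


def passes_coverage_gate(
    exon: TerminalExon,
    pooled_profile: CoverageProfile,
    distal: PolyASite,
    min_mean_coverage: float = MIN_MEAN_COVERAGE,
) -> tuple[bool, str]:
    """Retain an exon only with >=1 internal site and sufficient pooled coverage.

    Mean raw coverage between the exon start and the distal site must exceed
    ``min_mean_coverage``.
    """
    di = pooled_profile.site_index(distal)
    internal = [s for s in exon.sites
                if s is not distal and pooled_profile.site_index(s) < di]
    if not internal:
        return False, "no_internal_site"
    region = pooled_profile.values[pooled_profile.exon_start_index:di + 1]
    if not float(region.mean()) > min_mean_coverage:
        return False, "low_coverage"
    return True, ""


# ---------------------------------------------------------------------------
# MSE-ratio segmentation
# ---------------------------------------------------------------------------

@dataclass
class SegmentationDecision:
    """Outcome of evaluating one breakpoint in one sample's profile."""

    breakpoint: int
    mse_total: float
    mse_up: float
    mse_down: float
    ratio: float
    used: bool
    reason: str  # used | ratio_above_threshold | segment_too_short | downstream_not_lower
    zero_variance: bool = False


class _Cumsums:
    """Prefix sums enabling O(1) segment means and MSEs."""

    def __init__(self, values: np.ndarray):
        v = np.asarray(values, dtype=float)
        self.s1 = np.concatenate([[0.0], np.cumsum(v)])
        self.s2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def mean(self, lo: int, hi: int) -> float:
        return (self.s1[hi] - self.s1[lo]) / (hi - lo)

    def mse(self, lo: int, hi: int) -> float:
        n = hi - lo
        m = (self.s1[hi] - self.s1[lo]) / n
        return max((self.s2[hi] - self.s2[lo]) / n - m * m, 0.0)


def _evaluate_breakpoint(cum: _Cumsums, lo: int, hi: int, bp: int,
                         min_segment: int, threshold: float) -> SegmentationDecision:
    if bp - lo < min_segment or hi - bp < min_segment:
        return SegmentationDecision(bp, float("nan"), float("nan"), float("nan"),
                                    float("inf"), False, "segment_too_short")
    mse_t = cum.mse(lo, hi)
    mse_u = cum.mse(lo, bp)
    mse_d = cum.mse(bp, hi)
    if not cum.mean(bp, hi) < cum.mean(lo, bp):
        return SegmentationDecision(bp, mse_t, mse_u, mse_d, float("inf"),
                                    False, "downstream_not_lower")
    if mse_t <= 0.0:
        # zero-variance region: splitting cannot improve anything
        return SegmentationDecision(bp, mse_t, mse_u, mse_d, 1.0, False,
                                    "ratio_above_threshold", zero_variance=True)
    ratio = (mse_u + mse_d) / mse_t
    used = ratio <= threshold
    return SegmentationDecision(bp, mse_t, mse_u, mse_d, ratio, used,
                                "used" if used else "ratio_above_threshold")


def mse_ratio(profile_segment: np.ndarray, breakpoint: int,
              min_segment: int = MIN_SEGMENT,
              threshold: float = MSE_THRESHOLD) -> SegmentationDecision:
    """Evaluate a single candidate breakpoint on a coverage segment.

    The upstream segment is ``segment[:breakpoint]`` and the downstream
    segment ``segment[breakpoint:]``; a cleavage site at array index i
    corresponds to breakpoint i+1.  The site is a candidate used site iff
    both segments are at least ``min_segment`` nt, the downstream mean is
    lower than the upstream mean, and (MSE_u + MSE_d) / MSE_t <= threshold.
    """
    seg = np.asarray(profile_segment, dtype=float)
    if not 0 < breakpoint < seg.size:
        raise ValueError("breakpoint must lie strictly inside the segment")
    return _evaluate_breakpoint(_Cumsums(seg), 0, seg.size, breakpoint,
                                min_segment, threshold)


@dataclass
class SiteCall:
    """Aggregated multi-sample evaluation of one candidate site."""

    site: PolyASite
    accepted: bool
    reason: str
    per_sample: list[SegmentationDecision] = field(default_factory=list)

    @property
    def support(self) -> int:
        return sum(d.used for d in self.per_sample)


def segment_exon(
    exon: TerminalExon,
    profiles: Sequence[CoverageProfile],
    distal_site: PolyASite,
    threshold: float = MSE_THRESHOLD,
    min_segment: int = MIN_SEGMENT,
    cluster_span: int = CLUSTER_SPAN,
) -> tuple[list[PolyASite], dict[str, SiteCall]]:
    """Recursively identify used internal sites from replicate profiles.

    At each step, every catalog site inside the current region is evaluated
    in every sample.  A site needs candidate-level support (MSE ratio <=
    threshold, lower downstream mean, both segments >= min_segment) in at
    least two replicates when two or more exist (one otherwise).  Closely
    spaced sites (within ``cluster_span`` of each other) form clusters from
    which only the best representative competes.  The candidate with the
    smallest median MSE ratio over its supporting samples is accepted
    (5'-most on ties), the region splits at it, and recursion continues
    until no candidate qualifies.  Returns used internal sites 5'->3' plus
    the last evaluation of every candidate.
    """
    ref = profiles[0]
    cums = [_Cumsums(p.values) for p in profiles]
    need = 2 if len(profiles) >= 2 else 1
    distal_bp = ref.site_index(distal_site) + 1
    cand_sites = [(s, ref.site_index(s) + 1) for s in exon.sites
                  if s is not distal_site and ref.site_index(s) < distal_bp - 1]
    cand_sites.sort(key=lambda t: t[1])

    used: list[tuple[PolyASite, int]] = []
    calls: dict[str, SiteCall] = {}

    def recurse(lo: int, hi: int) -> None:
        evals = []
        for site, bp in cand_sites:
            if not lo < bp < hi:
                continue
            decs = [_evaluate_breakpoint(c, lo, hi, bp, min_segment, threshold)
                    for c in cums]
            support = sum(d.used for d in decs)
            med = (median(d.ratio for d in decs if d.used)
                   if support else float("inf"))
            if support >= need:
                reason = "candidate"
            elif support > 0:
                reason = "insufficient_replicates"
            else:
                reason = decs[0].reason if len(decs) == 1 else "no_replicate_support"
            calls[site.site_id] = SiteCall(site, False, reason, decs)
            evals.append((site, bp, support, med, decs))
        viable = [e for e in evals if e[2] >= need]
        if not viable:
            return
        # chain-cluster closely spaced candidates; best representative per cluster
        clusters: list[list[tuple]] = []
        for e in viable:  # already sorted by bp
            if clusters and e[1] - clusters[-1][-1][1] <= cluster_span:
                clusters[-1].append(e)
            else:
                clusters.append([e])
        reps = []
        for cl in clusters:
            best = min(cl, key=lambda e: (e[3], e[1]))
            for e in cl:
                if e is not best:
                    calls[e[0].site_id].reason = "cluster_superseded"
            reps.append(best)
        site, bp, support, med, decs = min(reps, key=lambda e: (e[3], e[1]))
        calls[site.site_id] = SiteCall(site, True, "used", decs)
        used.append((site, bp))
        recurse(lo, bp)
        recurse(bp, hi)

    recurse(0, distal_bp)
    used.sort(key=lambda t: t[1])
    return [s for s, _ in used], calls


# ---------------------------------------------------------------------------
# Global breakpoint validity check
# ---------------------------------------------------------------------------

def _best_unrestricted_breakpoint(cum: _Cumsums, lo: int, hi: int,
                                  min_segment: int, threshold: float
                                  ) -> tuple[int, float] | None:
    bps = np.arange(lo + min_segment, hi - min_segment + 1)
    if bps.size == 0:
        return None
    n1 = bps - lo
    n2 = hi - bps
    s1, s2 = cum.s1, cum.s2
    m1 = (s1[bps] - s1[lo]) / n1
    m2 = (s1[hi] - s1[bps]) / n2
    mse_u = (s2[bps] - s2[lo]) / n1 - m1 * m1
    mse_d = (s2[hi] - s2[bps]) / n2 - m2 * m2
    mse_t = cum.mse(lo, hi)
    if mse_t <= 0.0:
        return None
    ratio = (np.maximum(mse_u, 0.0) + np.maximum(mse_d, 0.0)) / mse_t
    ratio = np.where(m2 < m1, ratio, np.inf)
    k = int(np.argmin(ratio))  # first minimum -> 5'-most on ties
    if ratio[k] <= threshold:
        return int(bps[k]), float(ratio[k])
    return None


def global_breakpoints(values: np.ndarray, region_end: int,
                       min_segment: int = MIN_SEGMENT,
                       threshold: float = MSE_THRESHOLD) -> list[int]:
    """Recursive segmentation considering *all* positions as breakpoints."""
    cum = _Cumsums(np.asarray(values, dtype=float)[:region_end])
    found: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        best = _best_unrestricted_breakpoint(cum, lo, hi, min_segment, threshold)
        if best is None:
            return
        bp, _ = best
        found.append(bp)
        recurse(lo, bp)
        recurse(bp, hi)

    recurse(0, region_end)
    return sorted(found)


def global_breakpoint_check(
    exon: TerminalExon,
    profile: CoverageProfile,
    used_sites: Sequence[PolyASite],
    distal_site: PolyASite,
    tolerance: int = VALID_CHECK_TOLERANCE,
    min_segment: int = MIN_SEGMENT,
    threshold: float = MSE_THRESHOLD,
) -> tuple[bool, list[int]]:
    """Check that unrestricted breakpoints match the used catalog sites.

    The same recursive segmentation is run over all array positions of this
    sample's profile (up to the distal site).  The exon x sample passes iff
    every recovered breakpoint falls within ``tolerance`` nt upstream of
    (or at) some used site's breakpoint; otherwise the coverage steps are
    driven by positions missing from the catalog and the exon is excluded
    for this sample.
    """
    distal_bp = profile.site_index(distal_site) + 1
    bps = global_breakpoints(profile.values, distal_bp, min_segment, threshold)
    site_bps = [profile.site_index(s) + 1 for s in used_sites]
    ok = all(any(sbp - tolerance <= bp <= sbp for sbp in site_bps) for bp in bps)
    return ok, bps


# ---------------------------------------------------------------------------
# Usage quantification
# ---------------------------------------------------------------------------

def quantify_usage(
    exon: TerminalExon,
    profile: CoverageProfile,
    used_sites: Sequence[PolyASite],
    support: Mapping[str, bool] | None = None,
) -> list[dict]:
    """Raw and relative usage of each used site in one sample.

    ``used_sites`` must include the distal site and be ordered 5'->3'.
    Each isoform's raw usage is the mean coverage of the segment ending at
    its site minus the mean of the segment immediately 3' of it; the distal
    isoform's raw usage is its own segment mean.  For sites without
    candidate-level support in this sample (``support`` false), a negative
    difference is set to 0 (their usage cannot be negative just because
    longer isoforms dominate here).  Relative usage normalizes raw values to
    sum to 1; when the total is 0 relative usage is undefined (NaN).
    """
    bps = [profile.site_index(s) + 1 for s in used_sites]
    if bps != sorted(bps):
        raise ValueError("used_sites must be ordered 5'->3'")
    bounds = [0] + bps
    v = profile.values
    seg_means = [float(v[a:b].mean()) for a, b in zip(bounds, bounds[1:])]
    tail = v[bps[-1]:bps[-1] + profile.extended_3p]
    next_means = seg_means[1:] + [float(tail.mean()) if tail.size else 0.0]

    raws = []
    for j, site in enumerate(used_sites):
        if j == len(used_sites) - 1:
            raw = seg_means[j]
        else:
            raw = seg_means[j] - next_means[j]
        supported = True if support is None else support.get(site.site_id, False)
        if raw < 0.0:
            if supported:
                logger.debug("%s/%s: negative raw usage at supported site %s",
                             exon.exon_id, profile.sample_id, site.site_id)
            raw = 0.0
        raws.append(raw)
    total = sum(raws)
    rows = []
    for site, raw in zip(used_sites, raws):
        rel = raw / total if total > 0 else float("nan")
        rows.append(dict(exon_id=exon.exon_id, site_id=site.site_id,
                         chrom=exon.chrom, site_pos=site.position,
                         strand=exon.strand, sample=profile.sample_id,
                         raw=raw, relative=rel))
    return rows


def rpm_normalize(usage: pd.DataFrame) -> pd.DataFrame:
    """Fill the ``rpm`` column: per sample, raw / library size * 1e6.

    The library size is the summed raw usage over all quantified sites of
    the sample.
    """
    usage = usage.copy()
    lib = usage.groupby("sample")["raw"].transform("sum")
    if (lib <= 0).any():
        bad = usage.loc[lib <= 0, "sample"].unique()
        raise ValueError(f"zero library size for sample(s): {', '.join(map(str, bad))}")
    usage["rpm"] = usage["raw"] / lib * 1e6
    return usage


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

USAGE_COLUMNS = ["exon_id", "site_id", "chrom", "site_pos", "strand",
                 "sample", "raw", "relative", "rpm"]


def run_paqr(
    exons: Sequence[TerminalExon],
    profiles_by_sample: Mapping[str, Mapping[str, CoverageProfile]],
    read_length: int,
    threshold: float = MSE_THRESHOLD,
    min_segment: int = MIN_SEGMENT,
    cluster_span: int = CLUSTER_SPAN,
    min_mean_coverage: float = MIN_MEAN_COVERAGE,
    valid_check_tolerance: int = VALID_CHECK_TOLERANCE,
    skip_global_check: bool = False,
) -> tuple[pd.DataFrame, list[tuple[str, str, str]]]:
    """Quantify relative poly(A)-site usage for every exon and sample.

    ``profiles_by_sample`` maps sample id -> (exon id -> CoverageProfile).
    Returns the tidy usage table (one row per exon x site x sample, with
    raw, relative and RPM columns) and an exclusion log of
    (exon_id, sample_or_*, reason) tuples.
    """
    samples = list(profiles_by_sample)
    rows: list[dict] = []
    exclusions: list[tuple[str, str, str]] = []
    for exon in exons:
        profs = [profiles_by_sample[s][exon.exon_id] for s in samples
                 if exon.exon_id in profiles_by_sample[s]]
        if not profs:
            exclusions.append((exon.exon_id, "*", "no_coverage_profile"))
            continue
        pooled = pool_profiles(profs)
        distal = identify_distal_site(exon, pooled, read_length)
        if distal is None:
            exclusions.append((exon.exon_id, "*", "no_distal_site"))
            continue
        ok, reason = passes_coverage_gate(exon, pooled, distal, min_mean_coverage)
        if not ok:
            exclusions.append((exon.exon_id, "*", reason))
            continue
        used_internal, calls = segment_exon(exon, profs, distal, threshold,
                                            min_segment, cluster_span)
        used_all = used_internal + [distal]
        for prof in profs:
            si = [p.sample_id for p in profs].index(prof.sample_id)
            if not skip_global_check:
                passed, _ = global_breakpoint_check(
                    exon, prof, used_all, distal, valid_check_tolerance,
                    min_segment, threshold)
                if not passed:
                    exclusions.append((exon.exon_id, prof.sample_id,
                                       "global_breakpoint_mismatch"))
                    continue
            support = {s.site_id: calls[s.site_id].per_sample[si].used
                       for s in used_internal}
            support[distal.site_id] = True
            rows.extend(quantify_usage(exon, prof, used_all, support))
    if not rows:
        return pd.DataFrame(columns=USAGE_COLUMNS), exclusions
    usage = rpm_normalize(pd.DataFrame(rows))
    return usage[USAGE_COLUMNS], exclusions
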