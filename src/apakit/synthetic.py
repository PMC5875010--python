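"""Seeded generators with planted ground truth.

Two generators mirror the two quantification paths:

* ``simulate_coverage`` builds piecewise-constant terminal-exon coverage
  profiles whose level drops at each planted used site by that isoform's
  raw usage, plus per-nucleotide Poisson (or truncated Gaussian) noise —
  the signal shape the RNA-seq segmentation detects;
* ``simulate_counts`` draws 3'-end-sequencing count tables from the
  exponential usage model R = alpha * 2**(N*A) with a planted k-mer of
  known per-condition activity inserted into a controlled window of each
  site's sequence, plus multinomial sampling noise at a given depth.

Every generator is deterministic under a fixed seed, and each returns a
truth record for parameter-recovery tests.

By default, planted proximal usage fractions are drawn from a regime where
the coverage step is well above the sampling noise of the default base
coverage (signal-to-noise around five or more); recovery statements about
the segmentation refer to this detectable regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import DISTAL_EXTENSION, PolyASite, TerminalExon, WindowSpec
from .kapac import normalize_kmer
from .paqr import CoverageProfile

SYNTH_CHROM = "chrS"


# ---------------------------------------------------------------------------
# Coverage with planted steps
# ---------------------------------------------------------------------------

@dataclass
class CoverageExonTruth:
    exon_id: str
    site_offsets: list[int]      # transcript-oriented offsets of sites, 5'->3'
    usages: list[float]          # relative usage per site, sums to 1
    base_coverage: float
    strand: str = "+"


@dataclass
class CoverageTruth:
    exons: list[CoverageExonTruth]
    seed: int
    noise: str = "poisson"
    n_replicates: int = 2


def make_coverage_truth(
    n_exons: int = 200,
    base_coverage: float = 20.0,
    proximal_usage_range: tuple[float, float] = (0.7, 0.9),
    segment_length_range: tuple[int, int] = (300, 600),
    n_sites: int = 2,
    seed: int = 0,
    strand: str = "+",
) -> CoverageTruth:
    """Random two-level (or multi-level) exon truths with detectable steps.

    Each inter-site segment length is uniform over ``segment_length_range``
    and each non-distal site consumes a fraction of the remaining coverage
    drawn from ``proximal_usage_range``; the distal site takes the rest.
    """
    rng = np.random.default_rng(seed)
    exons = []
    for e in range(n_exons):
        offsets = []
        pos = 0
        for _ in range(n_sites):
            pos += int(rng.integers(*segment_length_range))
            offsets.append(pos - 1)  # cleavage base is segment's last base
        usages: list[float] = []
        remaining = 1.0
        for _ in range(n_sites - 1):
            u = float(rng.uniform(*proximal_usage_range)) * remaining
            usages.append(u)
            remaining -= u
        usages.append(remaining)
        st = strand if strand in ("+", "-") else ("+" if e % 2 == 0 else "-")
        exons.append(CoverageExonTruth(f"synth_exon_{e}", offsets, usages,
                                       base_coverage, st))
    return CoverageTruth(exons, seed)


def _mean_profile(truth: CoverageExonTruth, extension_3p: int) -> np.ndarray:
    length = truth.site_offsets[-1] + 1
    arr = np.zeros(length + extension_3p)
    level = truth.base_coverage
    prev = 0
    for off, f in zip(truth.site_offsets, truth.usages):
        if level < -1e-9:
            raise ValueError(f"{truth.exon_id}: negative mean coverage requested")
        arr[prev:off + 1] = level
        level -= truth.base_coverage * f
        prev = off + 1
    return arr


def simulate_coverage(
    truth: CoverageTruth,
    noise: str | None = "poisson",
    gaussian_sd: float = 3.0,
    n_replicates: int | None = None,
    seed: int | None = None,
    extension_3p: int = DISTAL_EXTENSION,
) -> tuple[list[TerminalExon], dict[str, dict[str, CoverageProfile]]]:
    """Materialize exon objects and noisy replicate coverage profiles.

    Replicates share the planted truth and differ only in the noise stream.
    ``noise`` is 'poisson', 'gaussian' (truncated at 0), or None for exact
    piecewise-constant profiles.  Returns (exons, profiles_by_sample) ready
    for the segmentation pipeline.
    """
    n_rep = truth.n_replicates if n_replicates is None else n_replicates
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    exons: list[TerminalExon] = []
    offset = 1000
    gap = 5000
    for t in truth.exons:
        length = t.site_offsets[-1] + 1
        start = offset
        end = start + length
        exon = TerminalExon(SYNTH_CHROM, start, end, t.strand, t.exon_id)
        for j, off in enumerate(t.site_offsets):
            pos = start + off if t.strand == "+" else end - 1 - off
            exon.sites.append(PolyASite(SYNTH_CHROM, pos, t.strand,
                                        f"{t.exon_id}_s{j}", exon_id=t.exon_id))
        exons.append(exon)
        offset = end + extension_3p + gap

    profiles: dict[str, dict[str, CoverageProfile]] = {
        f"rep{r + 1}": {} for r in range(n_rep)}
    for t, exon in zip(truth.exons, exons):
        mean = _mean_profile(t, extension_3p)
        for r in range(n_rep):
            if noise is None:
                values = mean.copy()
            elif noise == "poisson":
                values = rng.poisson(mean).astype(float)
            elif noise == "gaussian":
                values = np.clip(mean + rng.normal(0.0, gaussian_sd, mean.size),
                                 0.0, None)
            else:
                raise ValueError(f"unknown noise model {noise!r}")
            profiles[f"rep{r + 1}"][exon.exon_id] = CoverageProfile(
                exon.exon_id, f"rep{r + 1}", values, t.strand,
                0, extension_3p, exon)
    return exons, profiles


def write_truth_tsv(truth: CoverageTruth, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={truth.seed} noise={truth.noise} "
                 f"n_replicates={truth.n_replicates}\n")
        fh.write("exon_id\tstrand\tbase_coverage\tsite_offsets\tusages\n")
        for t in truth.exons:
            fh.write(f"{t.exon_id}\t{t.strand}\t{t.base_coverage:g}\t"
                     + ",".join(map(str, t.site_offsets)) + "\t"
                     + ",".join(f"{u:.6g}" for u in t.usages) + "\n")


# ---------------------------------------------------------------------------
# 3'-end counts from the exponential usage model
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCounts:
    """A planted k-mer activity data set for the regression model."""

    counts: pd.DataFrame                  # site x sample reads
    sequences: dict[str, str]             # site_id -> span sequence
    seq_offset: int                       # offset of sequence[0] from the site
    sites: dict[str, PolyASite]
    exon_of: pd.Series
    design: pd.DataFrame                  # sample, condition, pair_id
    pairs: list[tuple[str, str]]          # (first, second) per replicate
    kmer: str
    window: WindowSpec
    activities: dict[str, float]          # condition -> planted activity
    true_copies: pd.Series                # planted motif copies per site
    seed: int = 0


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def _count_occurrences(seq: str, kmer: str) -> int:
    k = len(kmer)
    return sum(1 for i in range(len(seq) - k + 1) if seq[i:i + k] == kmer)


def _window_with_copies(rng: np.random.Generator, width: int, kmer: str,
                        copies: int, max_tries: int = 200) -> str:
    """A window sequence containing exactly ``copies`` motif occurrences.

    Background letters are redrawn (rejection sampling) until no accidental
    occurrence remains, then the requested copies are inserted at random
    non-overlapping positions and the final count verified.
    """
    k = len(kmer)
    if copies * k > width:
        raise ValueError("window too small for requested motif copies")
    for _ in range(max_tries):
        seq = _random_seq(rng, width)
        if _count_occurrences(seq, kmer) != 0:
            continue
        chars = list(seq)
        slots = sorted(rng.choice(width - k + 1, size=copies, replace=False)) \
            if copies else []
        if any(b - a < k for a, b in zip(slots, slots[1:])):
            continue
        for s in slots:
            chars[s:s + k] = kmer
        cand = "".join(chars)
        if _count_occurrences(cand, kmer) == copies:
            return cand
    raise RuntimeError("rejection sampling failed to build motif window")


def simulate_counts(
    n_exons: int = 200,
    sites_per_exon: int = 2,
    depth: int = 100,
    kmer: str = "TGTA",
    window: WindowSpec = WindowSpec(-50, 0),
    activities: Mapping[str, float] | None = None,
    n_replicates: int = 2,
    span: tuple[int, int] = (-200, 200),
    copy_probs: Sequence[float] = (0.45, 0.40, 0.15),
    seed: int = 0,
) -> SimulatedCounts:
    """Draw a 3'-end count table from the exponential usage model.

    Each site gets a random number of planted motif copies (0, 1, 2 with
    ``copy_probs``) inside ``window``; relative usage within each exon
    follows weights 2**(copies * A_condition) and reads are multinomial at
    ``depth`` per exon and sample.  Default conditions are a control with
    the planted activity and a knock-down without it
    (``{"ctrl": 0.3, "kd": 0.0}``); pairs are (ctrl, kd) per replicate, so
    an activating motif in the control yields positive z-scores.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    kmer = normalize_kmer(kmer)
    if activities is None:
        activities = {"ctrl": 0.3, "kd": 0.0}
    rng = np.random.default_rng(seed)
    span_lo, span_hi = span
    if not (span_lo <= window.upstream_offset
            and window.downstream_offset <= span_hi):
        raise ValueError("planted window must lie inside the sequence span")

    conditions = list(activities)
    samples = [f"{c}_rep{r + 1}" for c in conditions for r in range(n_replicates)]
    cond_of = {f"{c}_rep{r + 1}": c for c in conditions for r in range(n_replicates)}
    pairs = [(f"{conditions[0]}_rep{r + 1}", f"{conditions[1]}_rep{r + 1}")
             for r in range(n_replicates)] if len(conditions) >= 2 else []

    site_ids: list[str] = []
    sites: dict[str, PolyASite] = {}
    exon_of: dict[str, str] = {}
    sequences: dict[str, str] = {}
    copies: dict[str, int] = {}
    w_lo = window.upstream_offset - span_lo
    w_hi = w_lo + window.width
    pos = 10_000
    for e in range(n_exons):
        exon_id = f"kexon_{e}"
        for j in range(sites_per_exon):
            sid = f"{exon_id}_s{j}"
            c = int(rng.choice(len(copy_probs), p=np.asarray(copy_probs)))
            left = _random_seq(rng, w_lo)
            mid = _window_with_copies(rng, window.width, kmer, c)
            right = _random_seq(rng, span_hi - span_lo - w_hi)
            sequences[sid] = left + mid + right
            sites[sid] = PolyASite(SYNTH_CHROM, pos, "+", sid, exon_id=exon_id)
            exon_of[sid] = exon_id
            copies[sid] = c
            site_ids.append(sid)
            pos += 1000
        pos += 10_000

    counts = pd.DataFrame(0.0, index=pd.Index(site_ids, name="site_id"),
                          columns=samples)
    copies_s = pd.Series(copies)
    for e in range(n_exons):
        sids = [f"kexon_{e}_s{j}" for j in range(sites_per_exon)]
        n = copies_s[sids].to_numpy(dtype=float)
        for s in samples:
            a = activities[cond_of[s]]
            w = np.exp2(n * a)
            u = w / w.sum()
            counts.loc[sids, s] = rng.multinomial(depth, u).astype(float)

    design = pd.DataFrame({
        "sample": samples,
        "condition": [cond_of[s] for s in samples],
        "pair_id": [s.split("_rep")[1] for s in samples],
    })
    return SimulatedCounts(counts, sequences, span_lo, sites,
                           pd.Series(exon_of), design, pairs, kmer, window,
                           dict(activities), copies_s, seed)


# ---------------------------------------------------------------------------
# Writers (pipeline interchange dialects)
# ---------------------------------------------------------------------------

def write_counts_tsv(counts: pd.DataFrame, exon_of: pd.Series, path: str,
                     header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("site_id\texon_id\t" + "\t".join(counts.columns) + "\n")
        for sid, row in counts.iterrows():
            fh.write(f"{sid}\t{exon_of[sid]}\t"
                     + "\t".join(f"{v:g}" for v in row) + "\n")


def write_design_tsv(design: pd.DataFrame, path: str) -> None:
    design.to_csv(path, sep="\t", index=False)


def write_site_fasta(sequences: Mapping[str, str], path: str,
                     seq_offset: int = -200) -> None:
    """FASTA of per-site spans; the header records the span's start offset."""
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid} offset={seq_offset}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
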