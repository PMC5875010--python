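"""Exon-level summaries: weighted 3' UTR lengths, fold-change target
selection, and motif-density profiles around poly(A) sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import PolyASite, WindowSpec, fetch_window_sequence

TOP_N_SENSITIVE = 750
MIN_RPM_SENSITIVE = 3.0


# ---------------------------------------------------------------------------
# Average terminal-exon length
# ---------------------------------------------------------------------------

@dataclass
class ExonLengthSummary:
    """Usage-weighted average terminal-exon length for one exon x sample."""

    exon_id: str
    sample_id: str
    avg_length_nt: float
    avg_length_pct: float


def average_exon_length(usage_fractions: Sequence[float],
                        isoform_lengths: Sequence[float],
                        exon_id: str = "", sample_id: str = "") -> ExonLengthSummary:
    """Weighted average length l_bar = sum_p f_p * l_p, and percent of max.

    ``usage_fractions`` are the relative usages of the exon's sites (summing
    to 1) and ``isoform_lengths`` the exon lengths when each site is used,
    increasing 5'->3'.  Exclusive distal usage gives 100%; exclusive usage
    of a very proximal site approaches 0.
    """
    f = np.asarray(usage_fractions, dtype=float)
    l = np.asarray(isoform_lengths, dtype=float)
    if f.shape != l.shape:
        raise ValueError("usage fractions and isoform lengths differ in length")
    nt = float(f @ l)
    pct = 100.0 * nt / float(l.max())
    return ExonLengthSummary(exon_id, sample_id, nt, pct)


def length_difference(summary_a: ExonLengthSummary | float,
                      summary_b: ExonLengthSummary | float) -> float:
    """Signed length difference b - a (in the units of the inputs).

    With a = control/normal and b = treatment/tumor, 3' UTR shortening shows
    as a negative difference.  Swapping the arguments negates the value.
    """
    a = summary_a.avg_length_pct if isinstance(summary_a, ExonLengthSummary) else float(summary_a)
    b = summary_b.avg_length_pct if isinstance(summary_b, ExonLengthSummary) else float(summary_b)
    return b - a


def exon_length_table(usage: pd.DataFrame) -> pd.DataFrame:
    """Per exon x sample weighted average lengths from a tidy usage table.

    Isoform length is measured from the exon's 5' end to each cleavage site
    inclusive.  Exon x sample entries with undefined relative usage are
    skipped.
    """
    rows = []
    for (exon_id, sample), grp in usage.groupby(["exon_id", "sample"]):
        grp = grp.sort_values("site_pos",
                              ascending=(grp["strand"].iloc[0] == "+"))
        f = grp["relative"].to_numpy(dtype=float)
        if not np.isfinite(f).all():
            continue
        pos = grp["site_pos"].to_numpy(dtype=float)
        start = pos[0]
        lengths = np.abs(pos - start) + 1.0
        # normalize f defensively (quantification already sums to 1)
        s = average_exon_length(f / f.sum() if f.sum() else f, lengths,
                                exon_id, sample)
        rows.append(dict(exon_id=exon_id, sample=sample,
                         avg_length_nt=s.avg_length_nt,
                         avg_length_pct=s.avg_length_pct))
    return pd.DataFrame(rows, columns=["exon_id", "sample",
                                       "avg_length_nt", "avg_length_pct"])


def aggregate_exon_lengths(length_table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample median (primary) and mean average exon length across exons."""
    g = length_table.groupby("sample")
    return pd.DataFrame({
        "median_pct": g["avg_length_pct"].median(),
        "mean_pct": g["avg_length_pct"].mean(),
        "median_nt": g["avg_length_nt"].median(),
        "mean_nt": g["avg_length_nt"].mean(),
    }).reset_index()


# ---------------------------------------------------------------------------
# Regulator-sensitive exon selection
# ---------------------------------------------------------------------------

def select_sensitive_exons(
    usage: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    top_n: int = TOP_N_SENSITIVE,
    min_rpm: float = MIN_RPM_SENSITIVE,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Split two-site exons into regulator-sensitive and insensitive sets.

    Considers exons with exactly two quantified sites, each expressed at
    >= ``min_rpm`` RPM in all samples.  The per-sample proximal/distal
    usage ratio is computed; ``pairs`` lists (knock-down, control) samples,
    and the average log10 fold change of the ratio across pairs ranks the
    exons: the ``top_n`` largest changes are "sensitive", the ``top_n``
    closest to zero "insensitive".  Returns (sensitive ids, insensitive
    ids, per-exon table with the fold changes).
    """
    ok_rpm = usage.groupby("exon_id")["rpm"].transform(lambda s: (s >= min_rpm).all())
    two_site = usage.groupby("exon_id")["site_id"].transform("nunique") == 2
    df = usage[ok_rpm & two_site]
    rows = []
    for exon_id, grp in df.groupby("exon_id"):
        grp = grp.sort_values("site_pos",
                              ascending=(grp["strand"].iloc[0] == "+"))
        wide = grp.pivot_table(index="site_id", columns="sample",
                               values="relative", aggfunc="first")
        prox_id, dist_id = grp["site_id"].drop_duplicates().tolist()
        ratio = wide.loc[prox_id] / wide.loc[dist_id]
        fcs = [np.log10(ratio[kd] / ratio[ctl]) for kd, ctl in pairs]
        rows.append(dict(exon_id=exon_id, log10_fc=float(np.mean(fcs))))
    table = pd.DataFrame(rows, columns=["exon_id", "log10_fc"]).dropna()
    if len(table) < top_n:
        import logging
        logging.getLogger("apakit").warning(
            "only %d qualifying exons for top_n=%d", len(table), top_n)
    sensitive = table.sort_values("log10_fc", ascending=False) \
                     .head(top_n)["exon_id"].tolist()
    insensitive = table.reindex(table["log10_fc"].abs().sort_values().index) \
                       .head(top_n)["exon_id"].tolist()
    return sensitive, insensitive, table


# ---------------------------------------------------------------------------
# Motif-density profiles
# ---------------------------------------------------------------------------

@dataclass
class MotifDensityProfile:
    """Smoothed per-position motif start frequency around poly(A) sites."""

    motif: str
    positions: np.ndarray   # nt relative to the cleavage site
    density: np.ndarray     # smoothed start frequency, in [0, 1]
    sd: np.ndarray          # binomial standard deviation of the mean
    n: int                  # number of contributing sites


def _is_repeat(motif: str) -> bool:
    for period in range(1, len(motif)):
        if len(motif) % period == 0 and motif == motif[:period] * (len(motif) // period):
            return True
    return False


def _match_positions(seq: str, motif: str, non_overlapping: bool) -> list[int]:
    out = []
    i = 0
    m = len(motif)
    while i <= len(seq) - m:
        if seq[i:i + m] == motif:
            out.append(i)
            i += m if non_overlapping else 1
        else:
            i += 1
    return out


def motif_density(
    sequences: Sequence[str] | None = None,
    motif: str = "",
    sites: Sequence[PolyASite] | None = None,
    genome=None,
    span: int = 200,
    smooth: int = 7,
    non_overlapping: bool | None = None,
) -> MotifDensityProfile:
    """Positional density of a motif around poly(A) sites.

    Either pass transcript-oriented ``sequences`` covering [-span, +span)
    around each cleavage site, or ``sites`` plus an indexed ``genome`` to
    extract them.  Start positions of motif matches are tabulated per
    position, converted to frequencies over the contributing sites,
    smoothed over ``smooth`` nt centered on each position, with the
    binomial standard deviation sqrt(f(1-f)/n).  Matches of repeat motifs
    (period < length) are counted non-overlapping by default; sequences
    truncated at contig edges are dropped from n at the missing positions.
    """
    motif = motif.upper().replace("U", "T")
    if not motif:
        raise ValueError("motif must be non-empty")
    if non_overlapping is None:
        non_overlapping = _is_repeat(motif)
    if sequences is None:
        if sites is None or genome is None:
            raise ValueError("pass sequences, or sites plus genome")
        window = WindowSpec(-span, span)
        sequences = [fetch_window_sequence(s, window, genome).sequence
                     for s in sites]
    width = 2 * span
    n_positions = width - len(motif) + 1
    counts = np.zeros(n_positions)
    coverage = np.zeros(n_positions)  # sites covering each start position
    n = 0
    for seq in sequences:
        seq = seq.upper().replace("U", "T")
        if not seq:
            continue
        n += 1
        usable = min(len(seq), width) - len(motif) + 1
        if usable <= 0:
            continue
        coverage[:usable] += 1
        for i in _match_positions(seq[:width], motif, non_overlapping):
            counts[i] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(coverage > 0, counts / np.maximum(coverage, 1), 0.0)
    half = smooth // 2
    smoothed = np.empty_like(freq)
    for i in range(freq.size):
        lo, hi = max(i - half, 0), min(i + half + 1, freq.size)
        smoothed[i] = freq[lo:hi].mean()
    n_eff = np.maximum(coverage, 1)
    sd = np.sqrt(smoothed * (1.0 - smoothed) / n_eff)
    positions = np.arange(-span, -span + n_positions)
    return MotifDensityProfile(motif, positions, smoothed, sd, n)
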