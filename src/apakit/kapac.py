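"""Inference of position-dependent k-mer activities on poly(A)-site choice.

The generative picture: the read count of poly(A) site *i* in sample *s* is
``R[i,s] = alpha * 2**(N[i,k] * A[k,s])``, where ``N[i,k]`` is the
(background-corrected) count of k-mer *k* in a window at a fixed distance
from the site and ``A[k,s]`` its per-copy activity (base-2 log scale) in the
sample.  Within a terminal exon the overall transcription level ``alpha``
cancels from the relative usage ``U[i,s] = R[i,s] / sum_p R[p,s]``, so

    log2 U[i,s] = N[i,k] * A[k,s] - log2 sum_p 2**(N[p,k] * A[k,s]).

Centering log2 U per site across samples and per exon within each sample
absorbs the site affinity and the log-sum normalizer to first order, leaving
a linear model y ~ Ntilde * A fit by least squares per sample, one k-mer at
a time.  K-mers are ranked by the absolute z-score of the mean activity
difference across condition pairs; empirical p-values come from shuffling
the site-to-count association.

Windows are scanned over a grid around the poly(A) site (default width 50,
step 25, spanning -200..+200 nt) to build an "impact map" of motif activity
versus position.  Sequences are genomic, so k-mers use the DNA alphabet;
``U`` in a motif is accepted as a synonym for ``T``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import PolyASite, WindowSpec, fetch_window_sequence

logger = logging.getLogger("apakit")

KMER_LENGTHS = (3, 4, 5, 6)
MIN_RPM_3PSEQ = 1.0
MIN_SITE_SPACING = 400
N_SHUFFLES = 100
_ALPHABET = "ACGT"
_SE_FLOOR = 1e-12


def normalize_kmer(kmer: str) -> str:
    return kmer.upper().replace("U", "T")


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(_ALPHABET, repeat=k)]


# ---------------------------------------------------------------------------
# Relative usage from 3'-end counts
# ---------------------------------------------------------------------------

def relative_usage_from_counts(
    counts: pd.DataFrame,
    exon_of: Mapping[str, str] | pd.Series,
    zero_pseudocount: float | None = 0.5,
) -> pd.DataFrame:
    """Relative usage U[p,s] = R[p,s] / sum over the sites of p's exon.

    ``counts`` is a site x sample read-count table; ``exon_of`` maps site id
    to exon id.  Exons with all-zero counts in a sample are excluded (NaN)
    for that sample.  ``zero_pseudocount`` reads are added to zero-count
    sites of otherwise expressed exons so that downstream log-transforms are
    defined (set None to disable, e.g. when the caller excludes zeros).
    """
    exon = pd.Series(exon_of).reindex(counts.index)
    if exon.isna().any():
        missing = counts.index[exon.isna()]
        raise KeyError(f"no exon for site(s): {', '.join(map(str, missing[:5]))}")
    r = counts.astype(float)
    total = r.groupby(exon).transform("sum")
    if zero_pseudocount is not None:
        r = r.where(~((r == 0) & (total > 0)), zero_pseudocount)
        total = r.groupby(exon).transform("sum")
    u = r / total.where(total > 0)
    return u


def counts_to_usage_table(counts: pd.DataFrame, sites: Mapping[str, PolyASite],
                          exon_of: Mapping[str, str] | pd.Series,
                          zero_pseudocount: float | None = 0.5) -> pd.DataFrame:
    """Build a tidy usage table (same dialect as the RNA-seq path) from counts."""
    u = relative_usage_from_counts(counts, exon_of, zero_pseudocount)
    lib = counts.sum(axis=0)
    rows = []
    for site_id in counts.index:
        s = sites[site_id]
        for sample in counts.columns:
            rows.append(dict(exon_id=pd.Series(exon_of)[site_id], site_id=site_id,
                             chrom=s.chrom, site_pos=s.position, strand=s.strand,
                             sample=sample, raw=float(counts.at[site_id, sample]),
                             relative=float(u.at[site_id, sample]),
                             rpm=float(counts.at[site_id, sample] / lib[sample] * 1e6)))
    return pd.DataFrame(rows)


def filter_exons_for_kapac(
    usage: pd.DataFrame,
    min_rpm: float = MIN_RPM_3PSEQ,
    min_spacing: int = MIN_SITE_SPACING,
    source: str = "3pseq",
) -> pd.DataFrame:
    """Restrict a tidy usage table to exons suitable for windowed k-mer scans.

    In ``3pseq`` mode, sites must reach ``min_rpm`` in at least one sample
    to count as expressed (others are dropped); in ``paqr`` mode all
    quantified sites count (usage was already restricted to used sites).
    Exons whose retained sites lie closer than ``min_spacing`` nt to one
    another are excluded entirely, since windows of +-200 nt around their
    sites would overlap; exons left with fewer than two sites are dropped.
    """
    if source not in ("3pseq", "paqr"):
        raise ValueError(f"unknown source {source!r}")
    df = usage.copy()
    if source == "3pseq":
        max_rpm = df.groupby("site_id")["rpm"].transform("max")
        df = df[max_rpm >= min_rpm]
    pos = df.groupby(["exon_id", "site_id"])["site_pos"].first()
    bad_exons = set()
    for exon_id, grp in pos.groupby(level=0):
        p = np.sort(grp.to_numpy())
        if p.size >= 2 and np.diff(p).min() < min_spacing:
            bad_exons.add(exon_id)
    df = df[~df["exon_id"].isin(bad_exons)]
    n_sites = df.groupby("exon_id")["site_id"].transform("nunique")
    return df[n_sites >= 2].copy()


def usage_to_wide(usage: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Pivot a tidy usage table to site x sample relative usage + exon map."""
    wide = usage.pivot_table(index="site_id", columns="sample",
                             values="relative", aggfunc="first")
    exon_of = usage.groupby("site_id")["exon_id"].first().reindex(wide.index)
    return wide, exon_of


# ---------------------------------------------------------------------------
# Background-corrected k-mer counts
# ---------------------------------------------------------------------------

def _mono_frequencies(seqs: Sequence[str]) -> dict[str, float]:
    counts = {c: 0 for c in _ALPHABET}
    total = 0
    for s in seqs:
        for c in s:
            if c in counts:
                counts[c] += 1
                total += 1
    if total == 0:
        return {c: 0.25 for c in _ALPHABET}
    return {c: counts[c] / total for c in counts}


def _observed_count(seq: str, kmer: str) -> int:
    k = len(kmer)
    return sum(1 for i in range(len(seq) - k + 1) if seq[i:i + k] == kmer)


def count_kmers_excess(sequence: str, kmer: str,
                       mono_freq: Mapping[str, float] | None = None,
                       clamp: bool = True) -> tuple[float, bool]:
    """Excess count of one k-mer in a window over the mononucleotide background.

    Expected count is (L-k+1) * prod of the mononucleotide frequencies of
    the k-mer's letters; frequencies default to the window's own composition
    (pass pooled frequencies to share a background across sites).  Returns
    (excess, short_window_flag); windows shorter than k count 0 and are
    flagged.  Negative excess is clamped to 0 unless ``clamp`` is False.
    """
    kmer = normalize_kmer(kmer)
    seq = sequence.upper().replace("U", "T")
    k = len(kmer)
    if not 3 <= k <= 6:
        raise ValueError("k-mer length must be within 3..6")
    if len(seq) < k:
        return 0.0, True
    f = mono_freq if mono_freq is not None else _mono_frequencies([seq])
    expected = (len(seq) - k + 1) * float(np.prod([f[c] for c in kmer]))
    excess = _observed_count(seq, kmer) - expected
    if clamp:
        excess = max(excess, 0.0)
    return excess, False


def build_kmer_count_matrix(sequences: Mapping[str, str], k: int,
                            background: str = "pooled",
                            clamp: bool = True) -> pd.DataFrame:
    """Background-corrected counts of all k-mers of length k per site.

    ``background='pooled'`` estimates mononucleotide frequencies from all
    window sequences of the analysis set (one shared expectation), while
    ``'per-sequence'`` uses each window's own composition.
    """
    ids = list(sequences)
    seqs = [sequences[i].upper().replace("U", "T") for i in ids]
    kmers = all_kmers(k)
    idx = {m: j for j, m in enumerate(kmers)}
    obs = np.zeros((len(ids), len(kmers)))
    for r, seq in enumerate(seqs):
        for i in range(len(seq) - k + 1):
            j = idx.get(seq[i:i + k])
            if j is not None:
                obs[r, j] += 1
    pooled = _mono_frequencies(seqs) if background == "pooled" else None
    exp = np.zeros_like(obs)
    kmer_base_counts = np.array([[m.count(c) for c in _ALPHABET] for m in kmers])
    for r, seq in enumerate(seqs):
        f = pooled if pooled is not None else _mono_frequencies([seq])
        fv = np.array([f[c] for c in _ALPHABET])
        logf = np.where(fv > 0, np.log(np.where(fv > 0, fv, 1.0)), 0.0)
        prob = np.exp(kmer_base_counts @ logf)
        # a k-mer containing a letter absent from the background has prob 0
        prob[(kmer_base_counts[:, fv == 0] > 0).any(axis=1)] = 0.0
        exp[r] = max(len(seq) - k + 1, 0) * prob
    n = obs - exp
    if clamp:
        n = np.maximum(n, 0.0)
    return pd.DataFrame(n, index=pd.Index(ids, name="site_id"), columns=kmers)


# ---------------------------------------------------------------------------
# Activity model
# ---------------------------------------------------------------------------

class _GroupCenterer:
    """Fast within-group (per-exon) column-wise mean centering."""

    def __init__(self, codes: np.ndarray):
        self.codes = np.asarray(codes)
        self.order = np.argsort(self.codes, kind="stable")
        sorted_codes = self.codes[self.order]
        self.n_groups = int(sorted_codes[-1]) + 1 if sorted_codes.size else 0
        self.starts = np.searchsorted(sorted_codes, np.arange(self.n_groups))
        self.counts = np.bincount(self.codes, minlength=self.n_groups)

    def group_means(self, x: np.ndarray) -> np.ndarray:
        xs = x[self.order]
        sums = np.add.reduceat(xs, self.starts, axis=0)
        return sums / self.counts[:, None]

    def center(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float).T).T
        return x - self.group_means(x)[self.codes]


@dataclass
class PreparedUsage:
    """Centred log2-usage response shared by all k-mer fits."""

    y: np.ndarray                # sites x samples, NaN where excluded
    site_ids: list[str]
    samples: list[str]
    exon_codes: np.ndarray       # per site
    centerer: _GroupCenterer
    n_exons_per_sample: np.ndarray

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.y)


def prepare_usage(usage_wide: pd.DataFrame, exon_of: pd.Series) -> PreparedUsage:
    """Two-way centering of log2 relative usage.

    Per site, the mean over samples (the site's intrinsic affinity) is
    removed; per exon within each sample, the exon-sample mean is removed
    (absorbing the within-exon normalizer).  Non-positive or missing usage
    is excluded (NaN) from all means and from the fit.
    """
    u = usage_wide.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logu = np.log2(u.where(u > 0))
    logu = logu.dropna(how="all")
    exon = pd.Series(exon_of).reindex(logu.index)
    c_p = logu.mean(axis=1)
    d = logu.sub(c_p, axis=0)
    c_se = d.groupby(exon).transform("mean")
    y = (d - c_se).to_numpy()
    codes = pd.Categorical(exon).codes.astype(np.int64)
    mask = np.isfinite(y)
    n_exons = np.array([
        len(np.unique(codes[mask[:, j]])) for j in range(y.shape[1])])
    return PreparedUsage(y, list(logu.index), list(logu.columns), codes,
                         _GroupCenterer(codes), n_exons)


def _fit_core(prep: PreparedUsage, nmat: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample OLS through the origin of y on exon-centered counts.

    Returns activities and standard errors, both (n_kmers, n_samples).
    """
    ntilde = prep.centerer.center(nmat)
    mask = prep.mask
    y0 = np.where(mask, prep.y, 0.0)
    num = ntilde.T @ y0                       # K x S
    den = (ntilde ** 2).T @ mask              # K x S (mask-aware)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(den > 0, num / den, np.nan)
    sy2 = (y0 ** 2).sum(axis=0)               # per sample
    with np.errstate(divide="ignore", invalid="ignore"):
        rss = np.maximum(
            sy2[None, :] - np.where(den > 0, num ** 2 / den, 0.0), 0.0)
    dof = mask.sum(axis=0) - prep.n_exons_per_sample - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = np.where(dof > 0, rss / np.maximum(dof, 1), np.nan)
        se = np.sqrt(np.where(den > 0, sigma2 / den, np.nan))
    return a, se


@dataclass
class ActivityResult:
    """Fitted activities of one k-mer in one window."""

    kmer: str
    window: WindowSpec | None
    activities: pd.Series        # per sample, base-2 log scale per motif copy
    se: pd.Series
    residuals: pd.DataFrame | None = None
    zscore: float | None = None
    pvalue: float | None = None


def fit_activities(usage_wide: pd.DataFrame, counts: pd.Series,
                   exon_of: pd.Series, kmer: str = "",
                   window: WindowSpec | None = None,
                   prep: PreparedUsage | None = None) -> ActivityResult:
    """Fit per-sample activities of a single k-mer by least squares.

    ``counts`` holds the (excess) k-mer count per site.  Activities are
    undefined (NaN) when the counts show no within-exon contrast.
    """
    if prep is None:
        prep = prepare_usage(usage_wide, exon_of)
    n = counts.reindex(prep.site_ids).to_numpy(dtype=float)[:, None]
    a, se = _fit_core(prep, n)
    ntilde = prep.centerer.center(n)
    resid = prep.y - ntilde @ a
    return ActivityResult(
        kmer=normalize_kmer(kmer) if kmer else "",
        window=window,
        activities=pd.Series(a[0], index=prep.samples, name="activity"),
        se=pd.Series(se[0], index=prep.samples, name="se"),
        residuals=pd.DataFrame(resid, index=prep.site_ids, columns=prep.samples),
    )


# ---------------------------------------------------------------------------
# Z-scores and randomization p-values
# ---------------------------------------------------------------------------

def _pair_indices(samples: Sequence[str],
                  pairs: Sequence[tuple[str, str]]) -> list[tuple[int, int]]:
    index = {s: i for i, s in enumerate(samples)}
    try:
        return [(index[t], index[c]) for t, c in pairs]
    except KeyError as exc:
        raise KeyError(f"sample {exc.args[0]!r} not in activity table") from exc


def _zscores(a: np.ndarray, se: np.ndarray, idx: list[tuple[int, int]],
             se_mode: str = "propagated") -> np.ndarray:
    diffs = np.stack([a[:, t] - a[:, c] for t, c in idx], axis=1)  # K x m
    mean_d = diffs.mean(axis=1)
    m = len(idx)
    if se_mode == "empirical" and m >= 3:
        sem = diffs.std(axis=1, ddof=1) / np.sqrt(m)
    else:
        var = np.stack([se[:, t] ** 2 + se[:, c] ** 2 for t, c in idx], axis=1)
        sem = np.sqrt(var.sum(axis=1)) / m
    sem = np.maximum(sem, _SE_FLOOR)
    return mean_d / sem


def activity_zscores(activities: pd.DataFrame, se: pd.DataFrame,
                     pairs: Sequence[tuple[str, str]],
                     se_mode: str = "propagated") -> pd.Series:
    """Mean activity-difference z-score per k-mer across condition pairs.

    ``pairs`` lists (first, second) sample ids; the z-score is the mean of
    first-minus-second activity differences divided by its standard error
    (propagated from the per-sample OLS errors, or the empirical standard
    error of the pair differences with ``se_mode='empirical'`` and >=3
    pairs).  To match the published sign convention for knock-down designs,
    put the control sample first.  Swapping every pair negates z exactly.
    """
    if not pairs:
        raise ValueError("at least one (first, second) sample pair is required")
    idx = _pair_indices(list(activities.columns), pairs)
    z = _zscores(activities.to_numpy(), se.to_numpy(), idx, se_mode)
    return pd.Series(z, index=activities.index, name="zscore")


def randomization_pvalues(prep: PreparedUsage, nmat: np.ndarray,
                          kmers: Sequence[str],
                          pairs: Sequence[tuple[str, str]],
                          real_z: np.ndarray,
                          n_shuffles: int = N_SHUFFLES,
                          seed: int | np.random.Generator = 0,
                          se_mode: str = "propagated") -> np.ndarray:
    """Empirical p-values from shuffling the site-to-count association.

    Rows of the count matrix are permuted over the site universe
    ``n_shuffles`` times (one shared permutation per shuffle for all
    k-mers); p = (1 + #{null |z| >= real |z|}) / (n_shuffles + 1).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    idx = _pair_indices(prep.samples, pairs)
    real = np.abs(np.asarray(real_z))
    exceed = np.zeros(len(kmers))
    n_sites = nmat.shape[0]
    for _ in range(n_shuffles):
        perm = rng.permutation(n_sites)
        a, se = _fit_core(prep, nmat[perm])
        z_null = np.abs(_zscores(a, se, idx, se_mode))
        exceed += np.where(np.isfinite(z_null) & (z_null >= real), 1.0, 0.0)
    return (1.0 + exceed) / (n_shuffles + 1.0)


# ---------------------------------------------------------------------------
# Impact map
# ---------------------------------------------------------------------------

def default_window_grid(span: tuple[int, int] = (-200, 200), width: int = 50,
                        step: int = 25) -> list[WindowSpec]:
    return [WindowSpec(s, s + width)
            for s in range(span[0], span[1] - width + 1, step)]


def window_sequences(sites: Mapping[str, PolyASite], window: WindowSpec,
                     genome=None, site_sequences: Mapping[str, str] | None = None,
                     seq_offset: int = -200) -> dict[str, str]:
    """Per-site window sequence, from a genome FASTA or precut spans.

    ``site_sequences`` may hold transcript-oriented sequences whose first
    base sits at offset ``seq_offset`` relative to the cleavage site; the
    window is then sliced in memory.
    """
    out = {}
    for site_id, site in sites.items():
        if site_sequences is not None:
            seq = site_sequences[site_id]
            lo = window.upstream_offset - seq_offset
            hi = lo + window.width
            out[site_id] = seq[max(lo, 0):hi]
        else:
            out[site_id] = fetch_window_sequence(site, window, genome).sequence
    return out


def impact_map(
    usage_wide: pd.DataFrame,
    exon_of: pd.Series,
    sites: Mapping[str, PolyASite],
    pairs: Sequence[tuple[str, str]],
    genome=None,
    site_sequences: Mapping[str, str] | None = None,
    seq_offset: int = -200,
    window_grid: Sequence[WindowSpec] | None = None,
    kmer_lengths: Sequence[int] = KMER_LENGTHS,
    n_shuffles: int = N_SHUFFLES,
    seed: int = 0,
    background: str = "pooled",
    clamp: bool = True,
    compute_pvalues: bool = True,
    se_mode: str = "propagated",
) -> pd.DataFrame:
    """Scan k-mers (3-6 nt) over a window grid around poly(A) sites.

    For every window placement and k-mer, per-sample activities are fitted,
    the mean activity-difference z-score over ``pairs`` computed, and
    (optionally) an empirical p-value estimated by randomization.  The
    result has one row per (kmer, window), sorted by |z| descending, with
    per-sample activity columns.
    """
    if window_grid is None:
        window_grid = default_window_grid()
    prep = prepare_usage(usage_wide, exon_of)
    site_subset = {sid: sites[sid] for sid in prep.site_ids}
    idx = _pair_indices(prep.samples, pairs)
    rng = np.random.default_rng(seed)
    rows = []
    for window in window_grid:
        seqs = window_sequences(site_subset, window, genome,
                                site_sequences, seq_offset)
        for k in kmer_lengths:
            nmat_df = build_kmer_count_matrix(
                {sid: seqs[sid] for sid in prep.site_ids}, k,
                background=background, clamp=clamp)
            nmat = nmat_df.to_numpy()
            a, se = _fit_core(prep, nmat)
            z = _zscores(a, se, idx, se_mode)
            if compute_pvalues:
                p = randomization_pvalues(prep, nmat, list(nmat_df.columns),
                                          pairs, z, n_shuffles, rng, se_mode)
            else:
                p = np.full(z.shape, np.nan)
            for j, kmer in enumerate(nmat_df.columns):
                row = dict(kmer=kmer, k=k,
                           window_start=window.upstream_offset,
                           window_end=window.downstream_offset,
                           zscore=float(z[j]), pvalue=float(p[j]))
                for si, sample in enumerate(prep.samples):
                    row[f"activity_{sample}"] = float(a[j, si])
                rows.append(row)
    df = pd.DataFrame(rows)
    df["abs_z"] = df["zscore"].abs()
    df = df.sort_values("abs_z", ascending=False, kind="mergesort") \
           .drop(columns="abs_z").reset_index(drop=True)
    return df


def top_motifs(impact: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """Top-n motif table (motif, z, window), mirroring published motif tables."""
    cols = ["kmer", "zscore", "pvalue", "window_start", "window_end"]
    return impact.loc[:, cols].head(n).reset_index(drop=True)
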