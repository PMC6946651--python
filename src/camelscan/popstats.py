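"""Windowed diversity and differentiation statistics.

Implements the classical windowed estimators on genotype matrices:

* per-site allele frequencies by population (or pooled group),
* nucleotide diversity pi (average pairwise difference per bp),
* Watterson's theta (segregating sites / harmonic number / bp),
* the Weir & Cockerham (1984) variance-components Fst estimator for two
  populations, combined as a ratio of sums within windows,
* identity-by-state distances between individuals, and
* classical (Torgerson) metric multidimensional scaling.

Window denominators use the full window length in bp, matching the common
VCF-based tooling convention; windows are non-overlapping by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .popmap import PopulationMap
from .variants import MISSING, GenotypeMatrix


class Window(NamedTuple):
    chrom: str
    start: int   # 0-based, inclusive
    end: int     # exclusive

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class FrequencyTable:
    """Per-site, per-population alternate-allele frequency and allele count.

    ``p`` is nan where a population has no called allele (``n`` = 0).  For
    tables of *parametric* (simulated, noise-free) frequencies ``n`` is None.
    """

    chrom: np.ndarray
    pos: np.ndarray
    populations: list[str]
    p: np.ndarray                 # sites x populations, nan = undefined
    n: np.ndarray | None = None   # sites x populations allele counts

    @property
    def n_sites(self) -> int:
        return int(self.pos.shape[0])

    def column(self, label: str) -> np.ndarray:
        return self.p[:, self.populations.index(label)]

    def take(self, index) -> "FrequencyTable":
        index = np.asarray(index)
        return FrequencyTable(
            chrom=self.chrom[index],
            pos=self.pos[index],
            populations=list(self.populations),
            p=self.p[index],
            n=None if self.n is None else self.n[index],
        )


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")
        self.values = v

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.values[self.labels.index(a), self.labels.index(b)])


# ----------------------------------------------------------------- windows

def tile_windows(
    chromosome_lengths: dict[str, int], size: int, step: int | None = None
) -> list[Window]:
    """Non-overlapping (default) windows tiling each chromosome."""
    step = step or size
    out = []
    for c, length in chromosome_lengths.items():
        for start in range(0, length, step):
            out.append(Window(c, start, min(start + size, length)))
    return out


def windows_from_matrix(matrix: GenotypeMatrix, size: int, step: int | None = None) -> list[Window]:
    lengths = {}
    for c in dict.fromkeys(matrix.chrom.tolist()):
        lengths[c] = int(matrix.pos[matrix.chrom == c].max())
    return tile_windows(lengths, size, step)


def sites_in_window(matrix_or_freqs, window: Window) -> np.ndarray:
    """Boolean mask of sites falling in a 0-based half-open window."""
    chrom = matrix_or_freqs.chrom
    pos0 = matrix_or_freqs.pos - 1
    return (chrom == window.chrom) & (pos0 >= window.start) & (pos0 < window.end)


# ----------------------------------------------------------- frequencies

def _pop_counts(matrix: GenotypeMatrix, idx: np.ndarray):
    g = matrix.geno[:, idx]
    called = g != MISSING
    n = 2 * called.sum(axis=1)
    alt = np.where(called, g, 0).sum(axis=1)
    return alt.astype(float), n.astype(float)


def allele_frequencies(
    matrix: GenotypeMatrix, popmap: PopulationMap, labels: Sequence[str] | None = None
) -> FrequencyTable:
    """Alternate-allele frequency and allele count per site per label.

    ``labels`` may mix population and group names; a group pools all
    non-missing alleles across its member populations.  Cells with no called
    allele get p = nan, n = 0.
    """
    labels = list(labels) if labels is not None else popmap.populations
    p = np.empty((matrix.n_sites, len(labels)))
    n = np.empty((matrix.n_sites, len(labels)))
    for j, label in enumerate(labels):
        idx = popmap.sample_indices(label, matrix.samples)
        alt, nn = _pop_counts(matrix, idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[:, j] = np.where(nn > 0, alt / np.maximum(nn, 1), np.nan)
        n[:, j] = nn
    return FrequencyTable(chrom=matrix.chrom, pos=matrix.pos, populations=labels, p=p, n=n)


# ------------------------------------------------------------- diversity

def _window_frame(windows: Sequence[Window], stat: str, values, n_sites) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "statistic": stat,
            "value": values,
            "n_sites": n_sites,
        }
    )


def nucleotide_diversity(
    matrix: GenotypeMatrix, popmap: PopulationMap, label: str, windows: Sequence[Window]
) -> pd.DataFrame:
    """Windowed pi: sum of per-site heterozygosity 2x(n-x)/(n(n-1)) over bp.

    Sites with fewer than two called alleles are skipped; monomorphic sites
    contribute zero.  The window denominator is the full window size in bp.
    """
    idx = popmap.sample_indices(label, matrix.samples)
    alt, n = _pop_counts(matrix, idx)
    usable = n >= 2
    pi_site = np.zeros(matrix.n_sites)
    nn, x = n[usable], alt[usable]
    pi_site[usable] = 2.0 * x * (nn - x) / (nn * (nn - 1.0))
    values, counts = [], []
    for w in windows:
        m = sites_in_window(matrix, w)
        values.append(pi_site[m].sum() / w.size)
        counts.append(int((m & usable).sum()))
    return _window_frame(windows, "pi", values, counts)


def _harmonic(k: int) -> float:
    return float(np.sum(1.0 / np.arange(1, k + 1))) if k >= 1 else float("nan")


def watterson_theta(
    matrix: GenotypeMatrix, popmap: PopulationMap, label: str, windows: Sequence[Window]
) -> pd.DataFrame:
    """Windowed Watterson's theta: S / a_{n-1} / L.

    S counts segregating sites within the population in the window; n is the
    modal non-missing allele count over the window's usable sites (ties broken
    toward the larger count); L is the window size in bp.  Windows with no
    usable site report 0 when S = 0, and nan when the modal allele count is
    below 2.
    """
    idx = popmap.sample_indices(label, matrix.samples)
    alt, n = _pop_counts(matrix, idx)
    usable = n >= 2
    seg = usable & (alt > 0) & (alt < n)
    values, counts = [], []
    for w in windows:
        m = sites_in_window(matrix, w)
        s = int((m & seg).sum())
        if s == 0:
            values.append(0.0)
        else:
            tally = np.bincount(n[m & usable].astype(int))
            modal = int(np.flatnonzero(tally == tally.max()).max())
            values.append(s / _harmonic(modal - 1) / w.size)
        counts.append(int((m & usable).sum()))
    return _window_frame(windows, "theta_w", values, counts)


# ------------------------------------------------------------------- Fst

def pop_site_stats(matrix: GenotypeMatrix, idx: np.ndarray):
    """Per-site (n diploids called, alt frequency, het proportion) for the
    sample columns ``idx``; frequency/heterozygosity are nan where n = 0."""
    g = matrix.geno[:, idx]
    called = g != MISSING
    ni = called.sum(axis=1).astype(float)
    alt = np.where(called, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(ni > 0, alt / (2.0 * np.maximum(ni, 1)), np.nan)
        hi = np.where(ni > 0, (g == 1).sum(axis=1) / np.maximum(ni, 1), np.nan)
    return ni, pi, hi


def wc_pair_components(stats_a, stats_b) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham components from two ``pop_site_stats`` triples.

    Returns (a, a+b+c, usable) over all sites; ``usable`` marks sites where
    both populations have at least two non-missing diploids.
    """
    (n1, p1, h1), (n2, p2, h2) = stats_a, stats_b
    comp_a = np.zeros(n1.shape[0])
    comp_abc = np.zeros(n1.shape[0])
    usable = (n1 >= 2) & (n2 >= 2)
    n1, p1, h1 = n1[usable], p1[usable], h1[usable]
    n2, p2, h2 = n2[usable], p2[usable], h2[usable]
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (n1 + n2) - (n1**2 + n2**2) / (n1 + n2)       # r - 1 = 1
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
    )
    c = hbar / 2.0
    comp_a[usable] = a
    comp_abc[usable] = a + b + c
    return comp_a, comp_abc, usable


def weir_fst(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    label_a: str,
    label_b: str,
    windows: Sequence[Window] | None = None,
) -> tuple[pd.DataFrame | None, float]:
    """Windowed and overall Weir & Cockerham Fst (ratio of sums).

    The per-window and overall estimates are sum(a)/sum(a+b+c) over the usable
    sites; windows whose denominator is zero report nan.  Raw (possibly
    negative) estimates are returned.
    """
    sa = pop_site_stats(matrix, popmap.sample_indices(label_a, matrix.samples))
    sb = pop_site_stats(matrix, popmap.sample_indices(label_b, matrix.samples))
    comp_a, comp_abc, usable = wc_pair_components(sa, sb)
    overall_den = comp_abc[usable].sum()
    overall = comp_a[usable].sum() / overall_den if overall_den != 0 else float("nan")
    if windows is None:
        return None, float(overall)
    values, counts = [], []
    for w in windows:
        m = sites_in_window(matrix, w) & usable
        den = comp_abc[m].sum()
        values.append(comp_a[m].sum() / den if den != 0 else float("nan"))
        counts.append(int(m.sum()))
    return _window_frame(windows, "fst", values, counts), float(overall)


# ------------------------------------------------------------------- IBS

def ibs_distance_matrix(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise IBS distance: mean |g_i - g_j| / 2 over shared called sites."""
    g = matrix.geno
    m = (g != MISSING).astype(float)
    a = [(g == k).astype(float) for k in (0, 1, 2)]
    n_shared = m.T @ m
    # sum |gi - gj| decomposed over genotype categories
    diff = (
        2.0 * (a[0].T @ a[2] + a[2].T @ a[0])
        + a[0].T @ a[1] + a[1].T @ a[0]
        + a[1].T @ a[2] + a[2].T @ a[1]
    )
    if np.any(n_shared == 0):
        bad = np.argwhere(n_shared == 0)
        pairs = [(matrix.samples[i], matrix.samples[j]) for i, j in bad if i < j]
        raise ValueError(f"sample pairs share no called site: {pairs}")
    d = diff / (2.0 * n_shared)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(labels=list(matrix.samples), values=d)


# ------------------------------------------------------------------- MDS

def classical_mds(dist: DistanceMatrix, k: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) MDS: double-center -D^2/2, top-k eigenpairs.

    Returns (coordinates n x k', eigenvalues) with k' <= k: axes with a
    negative eigenvalue are dropped with a warning (zero eigenvalues stay as
    zero coordinate columns).  Axes are ordered by eigenvalue; each axis is
    sign-fixed so its first nonzero loading is positive.
    """
    import warnings

    d = dist.values
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1][:k]
    evals_k = evals[order]
    keep = evals_k > -1e-9 * max(1.0, float(np.abs(evals).max()))
    if not np.all(keep):
        warnings.warn("dropping negative MDS eigenvalues")
    evals_k = np.maximum(evals_k[keep], 0.0)
    coords = evecs[:, order[keep]] * np.sqrt(evals_k)
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, axis] = -col
    return coords, evals_k
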