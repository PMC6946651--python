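"""Four-taxon introgression statistics and window scanning.

For a population configuration (Y, Z; W, X) — two ingroups Y and Z, their
outgroup W, and a candidate donor X — Patterson's D measures the genome-wide
imbalance of shared derived alleles:

    D = E[(p_Y − p_Z)(p_W − p_X)] / E[(p_Y + p_Z − 2 p_Y p_Z)(p_W + p_X − 2 p_W p_X)]

with E[] the mean over the sites considered.  The window-local, bounded
variant f_d replaces the denominator by the expectation of the larger of the
two "complete replacement" terms, choosing the branch by the sign of D:

    D > 0:  E[max((p_X − p_Y)(p_X − p_W), (p_Z − p_Y)(p_Z − p_W))]
    D < 0:  E[max((p_X − p_Z)(p_X − p_W), (p_Y − p_Z)(p_Y − p_W))]

so that f_d approximates the locally introgressed ancestry proportion.  Window
significance comes from a delete-one block jackknife: with f̂_i the statistic
recomputed with block i removed,

    Z = mean(f̂) / sqrt(var(f̂) · n),  n = number of blocks,

a deliberately conservative standardization (the textbook delete-one
jackknife variance would use (n−1)²/n; a flag switches conventions).

The scan classifies non-overlapping 100 kb windows as introgressed into Z
(Z-score > threshold), into Y (< −threshold), or neither, and the masking
step removes all sites in windows significant in either direction before
distances are recomputed.  F3/F4 admixture tests over SNP-count blocks and
the total-migration-rate helper M = m·τ_m round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .popmap import PopulationMap
from .popstats import FrequencyTable, Window, allele_frequencies, sites_in_window
from .variants import GenotypeMatrix


@dataclass(frozen=True)
class QuartetConfig:
    """Labels of the (Y, Z; W, X) configuration; each may name a population
    or a group pooled from several populations."""

    Y: str
    Z: str
    W: str
    X: str

    def __post_init__(self) -> None:
        if len({self.Y, self.Z, self.W, self.X}) != 4:
            raise ValueError("quartet labels must be distinct")

    @property
    def labels(self) -> tuple[str, str, str, str]:
        return (self.Y, self.Z, self.W, self.X)


@dataclass
class AdmixtureTestResult:
    test: str                     # "F3" or "F4"
    configuration: tuple[str, ...]
    statistic: float
    z_score: float
    n_blocks: int
    n_sites: int


def _quartet_columns(freqs: FrequencyTable, quartet: QuartetConfig):
    cols = [freqs.column(lbl) for lbl in quartet.labels]
    usable = ~np.any(np.isnan(np.column_stack(cols)), axis=1)
    return cols, usable


def _d_terms(py, pz, pw, px):
    num = (py - pz) * (pw - px)
    den = (py + pz - 2 * py * pz) * (pw + px - 2 * pw * px)
    return num, den


def patterson_d(
    freqs: FrequencyTable, quartet: QuartetConfig, site_mask: np.ndarray | None = None
) -> float:
    """Patterson's D over the (masked) sites; nan when undefined."""
    (py, pz, pw, px), usable = _quartet_columns(freqs, quartet)
    mask = usable if site_mask is None else (usable & site_mask)
    if not mask.any():
        return float("nan")
    num, den = _d_terms(py[mask], pz[mask], pw[mask], px[mask])
    d_sum = den.sum()
    if d_sum == 0:
        return float("nan")
    return float(num.sum() / d_sum)


def _fd_denominators(py, pz, pw, px):
    """Per-site f_d denominator terms for the D>0 and D<0 branches."""
    pos = np.maximum((px - py) * (px - pw), (pz - py) * (pz - pw))
    neg = np.maximum((px - pz) * (px - pw), (py - pz) * (py - pw))
    return pos, neg


def f_d_statistic(
    freqs: FrequencyTable, quartet: QuartetConfig, site_mask: np.ndarray | None = None
) -> float:
    """The branch-selected f_d statistic; 0 when D = 0 exactly, nan when
    the denominator (or D itself) is undefined."""
    (py, pz, pw, px), usable = _quartet_columns(freqs, quartet)
    mask = usable if site_mask is None else (usable & site_mask)
    if not mask.any():
        return float("nan")
    py, pz, pw, px = py[mask], pz[mask], pw[mask], px[mask]
    num, dden = _d_terms(py, pz, pw, px)
    d_sum = dden.sum()
    if d_sum == 0:
        return float("nan")
    d = num.sum() / d_sum
    if d == 0:
        return 0.0
    pos, neg = _fd_denominators(py, pz, pw, px)
    den = pos.sum() if d > 0 else neg.sum()
    if den == 0:
        return float("nan")
    return float(num.sum() / den)


# ---------------------------------------------------------------- jackknife

def block_jackknife_z(
    statistic_fn: Callable[[np.ndarray], float],
    block_labels: np.ndarray,
    convention: str = "times-n",
) -> tuple[float, np.ndarray]:
    """Delete-one block jackknife Z-score.

    ``statistic_fn`` receives a boolean keep-mask over sites and returns the
    statistic on that subset; ``block_labels`` assigns each site to a block.
    The pseudo-estimates f̂_i are the statistic with block i removed and

        Z = mean(f̂) / sqrt(var(f̂) · n)        (convention "times-n")
        Z = mean(f̂) / sqrt(var(f̂) · (n−1)²/n) (convention "delete-one")

    with var the sample variance (n−1 denominator).  All-zero pseudo-values
    give Z = 0 by convention; zero variance with nonzero mean gives ±inf.
    """
    block_labels = np.asarray(block_labels)
    blocks = np.unique(block_labels)
    if blocks.size < 2:
        raise ValueError("block jackknife requires at least 2 blocks")
    pseudo = np.array([statistic_fn(block_labels != b) for b in blocks])
    if np.any(np.isnan(pseudo)):
        return float("nan"), pseudo
    mean = pseudo.mean()
    var = pseudo.var(ddof=1)
    n = blocks.size
    scale = float(n) if convention == "times-n" else (n - 1.0) ** 2 / n
    if var == 0:
        if mean == 0:
            return 0.0, pseudo
        return float(np.sign(mean) * np.inf), pseudo
    return float(mean / np.sqrt(var * scale)), pseudo


# --------------------------------------------------------------------- scan

def introgression_scan(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    quartet: QuartetConfig,
    window_size: int = 100_000,
    block_size: int = 10_000,
    z_threshold: float = 2.0,
    chromosome_lengths: dict[str, int] | None = None,
    jackknife_convention: str = "times-n",
) -> pd.DataFrame:
    """Windowed f_d introgression scan with per-window jackknife Z-scores.

    Non-overlapping ``window_size`` windows (a trailing partial window is kept
    if at least half-size); within each window the Z-score comes from the
    delete-one jackknife over ``block_size`` sub-blocks.  Classification:
    Z > threshold → "into_Z", Z < −threshold → "into_Y", else "none";
    windows with an undefined statistic or fewer than two usable blocks are
    "undefined".  Returns one row per window (chrom, start, end, D, f_d, Z,
    n_sites, n_blocks, classification).
    """
    if window_size < block_size:
        raise ValueError("window_size must be at least block_size")
    freqs = allele_frequencies(matrix, popmap, list(quartet.labels))
    _, usable = _quartet_columns(freqs, quartet)
    if chromosome_lengths is None:
        chromosome_lengths = {
            c: int(matrix.pos[matrix.chrom == c].max())
            for c in dict.fromkeys(matrix.chrom.tolist())
        }
    windows = []
    for c, length in chromosome_lengths.items():
        full = length // window_size
        for i in range(full):
            windows.append(Window(c, i * window_size, (i + 1) * window_size))
        tail = length - full * window_size
        if tail >= window_size / 2:
            windows.append(Window(c, full * window_size, length))

    rows = []
    pos0 = freqs.pos - 1
    for w in windows:
        in_w = sites_in_window(freqs, w)
        m = in_w & usable
        n_sites = int(m.sum())
        d = patterson_d(freqs, quartet, in_w)
        fd = f_d_statistic(freqs, quartet, in_w)
        block_ids = (pos0 - w.start) // block_size
        usable_blocks = np.unique(block_ids[m])
        z = float("nan")
        n_blocks = int(usable_blocks.size)
        if n_blocks >= 2 and np.isfinite(fd):
            sub = freqs.take(np.flatnonzero(m))
            sub_blocks = block_ids[m]

            def stat(keep: np.ndarray) -> float:
                return f_d_statistic(sub, quartet, keep)

            z, _ = block_jackknife_z(stat, sub_blocks, convention=jackknife_convention)
        if np.isnan(z):
            cls = "undefined"
        elif z > z_threshold:
            cls = "into_Z"
        elif z < -z_threshold:
            cls = "into_Y"
        else:
            cls = "none"
        rows.append(
            {
                "chrom": w.chrom, "start": w.start, "end": w.end,
                "D": d, "f_d": fd, "Z": z,
                "n_sites": n_sites, "n_blocks": n_blocks, "classification": cls,
            }
        )
    return pd.DataFrame(rows)


def mask_introgressed(
    matrix: GenotypeMatrix,
    scan: pd.DataFrame,
    z_threshold: float = 2.0,
    directions: str = "both",
) -> tuple[GenotypeMatrix, list[tuple[str, int, int]]]:
    """Remove all sites inside windows whose scan |Z| exceeds the threshold.

    ``directions`` is "both" (default: |Z| > threshold in either direction),
    "into_Z" or "into_Y".  Returns the complementary matrix and the removed
    windows as 0-based half-open intervals.
    """
    z = scan["Z"].to_numpy()
    if directions == "both":
        hit = np.abs(z) > z_threshold
    elif directions == "into_Z":
        hit = z > z_threshold
    elif directions == "into_Y":
        hit = z < -z_threshold
    else:
        raise ValueError(f"unknown directions {directions!r}")
    hit &= np.isfinite(z) | np.isinf(z)
    removed = [
        (str(r.chrom), int(r.start), int(r.end))
        for r in scan.loc[hit].itertuples()
    ]
    keep = np.ones(matrix.n_sites, dtype=bool)
    pos0 = matrix.pos - 1
    for c, s, e in removed:
        keep &= ~((matrix.chrom == c) & (pos0 >= s) & (pos0 < e))
    return matrix.take(keep), removed


# ------------------------------------------------------------------ F3 / F4

def _snp_blocks(n_sites: int, block_size: int) -> np.ndarray:
    return np.arange(n_sites) // block_size


def f3_test(
    freqs: FrequencyTable, Z: str, X: str, Y: str, block_size: int = 500
) -> AdmixtureTestResult:
    """F3(Z; X, Y) = mean (p_Z − p_X)(p_Z − p_Y) with a SNP-block jackknife.

    A strongly negative Z-score indicates Z is a mixture of X-like and Y-like
    sources.
    """
    pz, px, py = freqs.column(Z), freqs.column(X), freqs.column(Y)
    usable = ~(np.isnan(pz) | np.isnan(px) | np.isnan(py))
    terms = ((pz - px) * (pz - py))[usable]
    blocks = _snp_blocks(terms.size, block_size)
    if np.unique(blocks).size < 2:
        raise ValueError("fewer than 2 jackknife blocks; reduce block_size")
    z, _ = block_jackknife_z(lambda keep: float(terms[keep].mean()), blocks)
    return AdmixtureTestResult(
        test="F3", configuration=(Z, X, Y), statistic=float(terms.mean()),
        z_score=z, n_blocks=int(np.unique(blocks).size), n_sites=int(terms.size),
    )


def f4_test(
    freqs: FrequencyTable, Y: str, Z: str, W: str, X: str, block_size: int = 500
) -> AdmixtureTestResult:
    """F4(Y, Z; W, X) = mean (p_Y − p_Z)(p_W − p_X) with a SNP-block jackknife.

    A significantly negative Z-score means Y shares more ancestry with X than
    Z does; positive means Z does.
    """
    py, pz, pw, px = (freqs.column(l) for l in (Y, Z, W, X))
    usable = ~np.any(np.isnan(np.column_stack([py, pz, pw, px])), axis=1)
    terms = ((py - pz) * (pw - px))[usable]
    blocks = _snp_blocks(terms.size, block_size)
    if np.unique(blocks).size < 2:
        raise ValueError("fewer than 2 jackknife blocks; reduce block_size")
    z, _ = block_jackknife_z(lambda keep: float(terms[keep].mean()), blocks)
    return AdmixtureTestResult(
        test="F4", configuration=(Y, Z, W, X), statistic=float(terms.mean()),
        z_score=z, n_blocks=int(np.unique(blocks).size), n_sites=int(terms.size),
    )


def total_migration_rate(m: float, tau_m: float) -> float:
    """Total migration rate M = m · τ_m (mutation-scaled rate × time span)."""
    if m < 0 or tau_m < 0:
        raise ValueError("migration rate and time span must be nonnegative")
    return float(m) * float(tau_m)
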