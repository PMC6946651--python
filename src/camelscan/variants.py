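"""Genotype matrices, VCF I/O, variant filtering and site selection.

The central container is :class:`GenotypeMatrix`: a sites x samples array of
diploid alternate-allele dosages (0, 1, 2; -1 for missing) together with the
per-site metadata that the filtering rules consume (variant quality, summed
depth, RMS mapping quality, allele lists).  Filtering follows the conjunction
of per-variant rules standard in joint-calling pipelines: quality, total-depth
band, minor allele frequency, per-variant missingness, mapping quality, and
biallelicity; each rule can be disabled or re-thresholded independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .popmap import PopulationMap

MISSING = -1

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = {"A", "C", "G", "T"}


@dataclass
class GenotypeMatrix:
    """Sites x samples diploid dosage matrix with per-site metadata.

    Positions are 1-based (VCF convention) and must be strictly increasing
    within each chromosome.  ``geno`` holds alternate-allele dosages in
    {0, 1, 2} with ``MISSING`` (-1) for any genotype containing a missing or
    half-called allele.  ``alt`` stores the full alternate-allele tuple so
    multiallelic and indel records survive I/O even though downstream
    statistics exclude them.
    """

    chrom: np.ndarray          # str, per site
    pos: np.ndarray            # int64, 1-based
    ref: np.ndarray            # str
    alt: np.ndarray            # object: tuple of alt alleles
    qual: np.ndarray           # float
    depth: np.ndarray          # float: DP summed over samples
    mq: np.ndarray             # float: RMS mapping quality
    geno: np.ndarray           # int8, sites x samples
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.qual = np.asarray(self.qual, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        self.mq = np.asarray(self.mq, dtype=float)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.ndim != 2 or self.geno.shape[0] != self.pos.shape[0]:
            raise ValueError("geno must be sites x samples with one row per site")
        if self.samples and len(self.samples) != self.geno.shape[1]:
            raise ValueError("sample list length does not match genotype columns")
        self._check_sorted()

    def _check_sorted(self) -> None:
        for c in dict.fromkeys(self.chrom.tolist()):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return int(self.pos.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.geno.shape[1])

    def biallelic_snp_mask(self) -> np.ndarray:
        return np.array(
            [
                len(a) == 1 and len(r) == 1 and len(a[0]) == 1
                and r in _BASES and a[0] in _BASES
                for r, a in zip(self.ref, self.alt)
            ],
            dtype=bool,
        )

    def take(self, index) -> "GenotypeMatrix":
        """Row subset by boolean mask or integer index (order-preserving)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            qual=self.qual[index],
            depth=self.depth[index],
            mq=self.mq[index],
            geno=self.geno[index],
            samples=list(self.samples),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and all(tuple(a) == tuple(b) for a, b in zip(self.alt, other.alt))
            and np.allclose(self.qual, other.qual, equal_nan=True)
            and np.allclose(self.depth, other.depth, equal_nan=True)
            and np.allclose(self.mq, other.mq, equal_nan=True)
            and np.array_equal(self.geno, other.geno)
        )


# --------------------------------------------------------------------- VCF IO

def read_vcf(path) -> tuple[GenotypeMatrix, list[str]]:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Genotypes with any missing allele (including half-calls like ``./1``) are
    coded missing.  Multiallelic records keep their full alternate-allele list;
    their dosage counts any non-reference allele.  Positions must be strictly
    increasing within each chromosome.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom, pos, ref, alt, qual, depth, mq, rows = [], [], [], [], [], [], [], []
    for i, v in enumerate(vcf):
        try:
            chrom.append(v.CHROM)
            pos.append(v.POS)
            ref.append(v.REF)
            alt.append(tuple(v.ALT))
            qual.append(v.QUAL if v.QUAL is not None else np.nan)
            info_dp = v.INFO.get("DP")
            info_mq = v.INFO.get("MQ")
            depth.append(float(info_dp) if info_dp is not None else np.nan)
            mq.append(float(info_mq) if info_mq is not None else np.nan)
            if samples:
                g = np.asarray([gt[:2] for gt in v.genotypes], dtype=np.int64)
                dosage = np.where((g < 0).any(axis=1), MISSING, (g > 0).sum(axis=1))
            else:
                dosage = np.empty(0, dtype=np.int64)
            rows.append(dosage.astype(np.int8))
        except Exception as exc:  # pragma: no cover - malformed record context
            raise ValueError(f"{path}: malformed VCF record #{i + 1}") from exc
    geno = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    matrix = GenotypeMatrix(
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        qual=np.asarray(qual),
        depth=np.asarray(depth),
        mq=np.asarray(mq),
        geno=geno,
        samples=samples,
    )
    return matrix, samples


def write_vcf(matrix: GenotypeMatrix, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a minimal VCF v4.2 with GT genotypes and DP/MQ INFO fields."""
    contigs: dict[str, int] = dict(contig_lengths or {})
    for c, p in zip(matrix.chrom, matrix.pos):
        contigs[c] = max(contigs.get(c, 0), int(p))
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=camelscan\n")
        for c, ln in contigs.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth summed over samples">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for i in range(matrix.n_sites):
            alt = ",".join(matrix.alt[i]) if len(matrix.alt[i]) else "."
            qual = "." if np.isnan(matrix.qual[i]) else f"{matrix.qual[i]:.6g}"
            info = []
            if not np.isnan(matrix.depth[i]):
                info.append(f"DP={int(round(matrix.depth[i]))}")
            if not np.isnan(matrix.mq[i]):
                info.append(f"MQ={matrix.mq[i]:.6g}")
            fh.write(
                "\t".join(
                    [
                        str(matrix.chrom[i]),
                        str(int(matrix.pos[i])),
                        ".",
                        str(matrix.ref[i]),
                        alt,
                        qual,
                        "PASS",
                        ";".join(info) or ".",
                        "GT",
                    ]
                    + [gt_str[int(g)] for g in matrix.geno[i]]
                )
                + "\n"
            )


# ------------------------------------------------------------------ filtering

@dataclass
class FilterThresholds:
    """Per-rule thresholds; set a field to ``None`` to disable that rule.

    Defaults are the standard joint-calling values: QUAL > 40, total depth in
    (200, 5000), MAF > 1%, fraction of individuals with a missing genotype
    < 20%, RMS mapping quality > 30, and exactly one alternate allele.
    """

    min_qual: float | None = 40.0
    min_depth: float | None = 200.0
    max_depth: float | None = 5000.0
    min_maf: float | None = 0.01
    max_missing: float | None = 0.20
    min_mq: float | None = 30.0
    biallelic: bool = True


@dataclass
class FilterReport:
    input_count: int
    output_count: int
    removed_per_rule: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "output_count": self.output_count,
            "removed_per_rule": dict(self.removed_per_rule),
        }


def filter_variants(
    matrix: GenotypeMatrix, thresholds: FilterThresholds | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the conjunctive per-variant filters; report removals per rule.

    A variant failing several rules is tallied in every rule it fails; the
    survivors are the variants passing all enabled rules, so the filter is
    idempotent and rule-order invariant.  MAF is computed from non-missing
    alleles across all samples jointly.
    """
    t = thresholds or FilterThresholds()
    n = matrix.n_sites
    masks: dict[str, np.ndarray] = {}

    def _need(name: str, arr: np.ndarray) -> np.ndarray:
        if n > 0 and np.all(np.isnan(arr)):
            raise ValueError(f"filter rule requires per-site field {name!r} which is absent")
        return arr

    if t.min_qual is not None:
        masks["qual"] = _need("qual", matrix.qual) > t.min_qual
    if t.min_depth is not None or t.max_depth is not None:
        dp = _need("depth", matrix.depth)
        lo = dp > t.min_depth if t.min_depth is not None else np.ones(n, bool)
        hi = dp < t.max_depth if t.max_depth is not None else np.ones(n, bool)
        masks["depth"] = lo & hi
    if t.min_maf is not None:
        called = matrix.geno != MISSING
        n_alleles = 2 * called.sum(axis=1)
        alt = np.where(called, matrix.geno, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), 0.0)
        maf = np.minimum(p, 1.0 - p)
        masks["maf"] = maf > t.min_maf
    if t.max_missing is not None:
        if matrix.n_samples == 0:
            masks["missing"] = np.ones(n, bool)
        else:
            frac = (matrix.geno == MISSING).mean(axis=1)
            masks["missing"] = frac < t.max_missing
    if t.min_mq is not None:
        masks["mq"] = _need("mq", matrix.mq) > t.min_mq
    if t.biallelic:
        masks["biallelic"] = np.array([len(a) == 1 for a in matrix.alt], dtype=bool)

    keep = np.ones(n, dtype=bool)
    removed = {}
    for rule, mask in masks.items():
        removed[rule] = int((~mask).sum())
        keep &= mask
    out = matrix.take(keep)
    return out, FilterReport(input_count=n, output_count=out.n_sites, removed_per_rule=removed)


# --------------------------------------------------------------- Ts/Tv, counts

class TsTv(NamedTuple):
    ratio: float          # nan when no transversions were observed
    n_transitions: int
    n_transversions: int
    n_skipped: int        # non-SNP or multiallelic records excluded


def ts_tv_ratio(matrix: GenotypeMatrix) -> TsTv:
    """Transition:transversion ratio over biallelic SNPs.

    Transitions are A<->G and C<->T; every other single-base substitution is a
    transversion.  Indels and multiallelic records are skipped and counted in
    ``n_skipped``.  With zero transversions the ratio is undefined (nan).
    """
    snp = matrix.biallelic_snp_mask()
    ts = sum(
        1
        for r, a in zip(matrix.ref[snp], matrix.alt[snp])
        if (r, a[0]) in _TRANSITIONS
    )
    n_snp = int(snp.sum())
    tv = n_snp - ts
    ratio = float(ts) / tv if tv > 0 else float("nan")
    return TsTv(ratio, ts, tv, matrix.n_sites - n_snp)


@dataclass
class SharedPrivateCounts:
    totals: dict[str, int]                       # variants identified per group
    shared: dict[tuple[str, str], int]           # |A & B|, unordered pairs stored both ways
    shared_fraction: dict[tuple[str, str], float]  # |A & B| / |A|  (keyed (A, B))
    private: dict[str, int]                      # in A and in no other group


def shared_private_counts(
    matrix: GenotypeMatrix, popmap: PopulationMap, groupings: Sequence[str]
) -> SharedPrivateCounts:
    """Count variants identified in each group, shared between groups, private.

    A variant is "identified in" a group iff at least one non-missing alternate
    allele is called among the group's samples.
    """
    identified: dict[str, np.ndarray] = {}
    for label in groupings:
        idx = popmap.sample_indices(label, matrix.samples)
        g = matrix.geno[:, idx]
        identified[label] = (np.where(g != MISSING, g, 0) > 0).any(axis=1)
    totals = {k: int(v.sum()) for k, v in identified.items()}
    shared, frac = {}, {}
    for a in groupings:
        for b in groupings:
            if a == b:
                continue
            inter = int((identified[a] & identified[b]).sum())
            shared[(a, b)] = inter
            frac[(a, b)] = inter / totals[a] if totals[a] else float("nan")
    private = {}
    for a in groupings:
        others = np.zeros(matrix.n_sites, dtype=bool)
        for b in groupings:
            if b != a:
                others |= identified[b]
        private[a] = int((identified[a] & ~others).sum())
    return SharedPrivateCounts(totals, shared, frac, private)


# ------------------------------------------------------------------ LD pruning

def _pairwise_r2(g: np.ndarray) -> np.ndarray:
    """Pairwise dosage-correlation r^2 with missing entries excluded pairwise.

    ``g`` is variants x samples float with nan for missing.  Pairs with fewer
    than two shared calls or zero variance are given r^2 = 0 (unassessable).
    """
    m = ~np.isnan(g)
    x = np.nan_to_num(g)
    mf = m.astype(float)
    n = mf @ mf.T
    sx = x @ mf.T          # sum of variant i over samples shared with j
    sxx = (x * x) @ mf.T
    sxy = x @ x.T
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_i = sx / n
        mean_j = sx.T / n
        cov = sxy / n - mean_i * mean_j
        var_i = sxx / n - mean_i**2
        var_j = sxx.T / n - mean_j**2
        r2 = cov**2 / (var_i * var_j)
    r2 = np.where((n >= 2) & np.isfinite(r2), r2, 0.0)
    np.fill_diagonal(r2, 0.0)
    return r2


def ld_prune(
    matrix: GenotypeMatrix,
    window_size: int = 50,
    step: int = 5,
    r2_threshold: float = 0.5,
) -> np.ndarray:
    """Greedy windowed LD pruning on genotype-dosage correlation.

    Scans windows of ``window_size`` variants advancing by ``step``; within a
    window, while any kept pair exceeds ``r2_threshold`` the later variant of
    the worst (highest r^2) pair is dropped.  Returns the kept variant indices.
    """
    n = matrix.n_sites
    g = matrix.geno.astype(float)
    g[g == MISSING] = np.nan
    kept = np.ones(n, dtype=bool)
    for start in range(0, max(n - 1, 1), step):
        idx = np.flatnonzero(kept[start : start + window_size]) + start
        if idx.size < 2:
            continue
        r2 = _pairwise_r2(g[idx])
        alive = np.ones(idx.size, dtype=bool)
        while True:
            sub = r2[np.ix_(alive, alive)]
            if sub.size == 0 or sub.max() <= r2_threshold:
                break
            ai = np.flatnonzero(alive)
            k = int(np.argmax(sub))
            i, j = divmod(k, sub.shape[1])
            drop = ai[max(i, j)]  # later variant of the worst pair
            alive[drop] = False
        kept[idx[~alive]] = False
    return np.flatnonzero(kept)


# -------------------------------------------------------------- locus selection

def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def select_neutral_loci(
    chromosome_lengths: dict[str, int],
    exclusion_intervals: Sequence[tuple[str, int, int]] = (),
    locus_length: int = 1000,
    min_gap: int = 30_000,
    max_count: int = 10_000,
    seed: int = 0,
) -> list[tuple[str, int, int]]:
    """Randomly place fixed-length loci outside exclusions, min_gap apart.

    Intervals are 0-based half-open.  Candidate start positions are drawn
    uniformly over the free space, then accepted greedily in coordinate order
    subject to the gap constraint (end of one locus to start of the next),
    stopping at ``max_count``.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    excl: dict[str, list[tuple[int, int]]] = {c: [] for c in chromosome_lengths}
    for c, s, e in exclusion_intervals:
        if c in excl:
            excl[c].append((int(s), int(e)))
    loci: list[tuple[str, int, int]] = []
    for c, length in chromosome_lengths.items():
        free: list[tuple[int, int]] = []
        cursor = 0
        for s, e in _merge_intervals(excl[c]):
            if s > cursor:
                free.append((cursor, min(s, length)))
            cursor = max(cursor, e)
        if cursor < length:
            free.append((cursor, length))
        free = [(s, e) for s, e in free if e - s >= locus_length]
        if not free:
            continue
        starts_space = np.array([e - s - locus_length + 1 for s, e in free])
        total = int(starts_space.sum())
        n_cand = min(total, max(4 * max_count, 1000))
        offsets = np.sort(rng.choice(total, size=n_cand, replace=False)) if total > n_cand else np.arange(total)
        bounds = np.cumsum(starts_space)
        prev_end = -min_gap - 1
        for off in offsets:
            k = int(np.searchsorted(bounds, off, side="right"))
            start = free[k][0] + int(off - (bounds[k - 1] if k else 0))
            if start < prev_end + min_gap:
                continue
            if start + locus_length > free[k][1]:
                continue
            loci.append((c, start, start + locus_length))
            prev_end = start + locus_length
            if len(loci) >= max_count:
                return loci
    if not loci:
        warnings.warn("no locus of the requested length fits outside the exclusions")
    return loci


# ------------------------------------------------------------------- BED output

def write_bed(intervals: Sequence[tuple[str, int, int]], path) -> None:
    """Write 0-based half-open intervals as BED, in coordinate order."""
    with open(path, "w") as fh:
        for c, s, e in sorted(intervals):
            fh.write(f"{c}\t{int(s)}\t{int(e)}\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                c, s, e = line.split()[:3]
                out.append((c, int(s), int(e)))
    return out
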