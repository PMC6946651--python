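"""Synthetic multi-population genotype data with known demographic truth.

The generator models allele-frequency evolution on a rooted population tree
under Balding–Nichols drift: along each branch with drift coefficient F, the
child frequency is Beta-distributed with mean equal to the parent frequency
and variance F·p·(1−p).  Boundary frequencies (0 or 1) are absorbing — drift
cannot resurrect a lost allele.  After all drift, admixture pulses mix donor
into recipient frequencies, q' = (1−f)·q + f·p_donor, at sites inside a
configured set of genomic windows only; everything outside those windows is
untouched, giving a ground truth for window-scan recovery tests.

Genotypes are then drawn per diploid individual as two Bernoulli(p) allele
draws, with independent missingness and per-site quality/depth/mapping-quality
covariates, and written out as VCF + population map + truth BED.

All randomness flows from the single scenario seed: the frequency stage uses
``default_rng(seed)`` with a documented draw order — (1) ancestral
frequencies, (2) per-branch drift in preorder — and the genotype stage uses a
substream derived from the same seed, drawing (3) per-population genotype
uniforms in leaf preorder, (4) the missingness mask, (5) ref/alt allele
assignment, (6) quality, depth and mapping quality.  Admixture pulses consume
no random draws, so a pulse and a no-pulse scenario with the same seed share
all randomness at unaffected sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .popmap import PopulationMap
from .popstats import FrequencyTable, tile_windows
from .variants import GenotypeMatrix, write_bed, write_vcf

Interval = tuple[str, int, int]

_TS_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]
_TV_PAIRS = [
    ("A", "C"), ("C", "A"), ("A", "T"), ("T", "A"),
    ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
]


@dataclass
class Pulse:
    """One admixture pulse: donor frequency mixed into the recipient at
    proportion ``proportion`` inside ``windows`` (0-based half-open)."""

    donor: str
    recipient: str
    proportion: float
    windows: list[Interval]


@dataclass
class ScenarioConfig:
    """Full description of a synthetic scenario; validated on construction.

    ``population_tree`` is a nested dict {"name", "F", "children"} with the
    per-branch drift coefficient F in [0, 1) (root F ignored).  Ancestral
    frequencies are drawn from a Beta(a, b) rescaled to (lo, hi).
    """

    population_tree: dict
    samples_per_population: dict[str, int]
    chromosome_lengths: dict[str, int]
    site_spacing: int = 100
    n_sites: int | None = None
    admixture_pulses: list[Pulse] = field(default_factory=list)
    population_group: dict[str, str] = field(default_factory=dict)
    ancestral_freq: dict = field(
        default_factory=lambda: {"a": 0.8, "b": 0.8, "lo": 0.02, "hi": 0.98}
    )
    target_ts_tv: float = 2.4
    missing_rate: float = 0.02
    depth_model: dict = field(default_factory=lambda: {"mean_per_sample": 13.0})
    quality_model: dict = field(
        default_factory=lambda: {"qual_mean": 80.0, "qual_sd": 15.0,
                                 "mq_mean": 55.0, "mq_sd": 5.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.population_tree or "name" not in self.population_tree:
            raise ValueError("population_tree must be a non-empty rooted tree")
        names = [n["name"] for n in self._nodes()]
        if len(names) != len(set(names)):
            raise ValueError("population names in the tree must be unique")
        for node in self._nodes():
            f = float(node.get("F", 0.0))
            if not (0.0 <= f < 1.0):
                raise ValueError(f"drift coefficient F={f} outside [0, 1) at {node['name']}")
        leaves = set(self.leaf_names())
        for pulse in self.admixture_pulses:
            if not (0.0 <= pulse.proportion <= 1.0):
                raise ValueError(f"pulse proportion {pulse.proportion} outside [0, 1]")
            if pulse.donor not in leaves or pulse.recipient not in leaves:
                raise ValueError("pulse donor/recipient must be leaf populations")
            for c, s, e in pulse.windows:
                if c not in self.chromosome_lengths or not (0 <= s < e <= self.chromosome_lengths[c]):
                    raise ValueError(f"pulse window ({c},{s},{e}) outside the genome")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate outside [0, 1]")
        for pop in self.samples_per_population:
            if pop not in leaves:
                raise ValueError(f"samples requested for unknown population {pop!r}")

    def _nodes(self) -> Iterable[dict]:
        stack = [self.population_tree]
        while stack:
            node = stack.pop(0)
            yield node
            stack = list(node.get("children", [])) + stack

    def leaf_names(self) -> list[str]:
        return [n["name"] for n in self._nodes() if not n.get("children")]

    def positions(self) -> tuple[np.ndarray, np.ndarray]:
        """(chrom, pos) arrays: sites evenly spaced by site_spacing, 1-based."""
        chroms, positions = [], []
        for c, length in self.chromosome_lengths.items():
            p = np.arange(self.site_spacing, length + 1, self.site_spacing, dtype=np.int64)
            chroms.append(np.full(p.shape, c, dtype=object))
            positions.append(p)
        chrom = np.concatenate(chroms)
        pos = np.concatenate(positions)
        if self.n_sites is not None:
            if self.n_sites > pos.shape[0]:
                raise ValueError("n_sites exceeds the number of spaced positions")
            chrom, pos = chrom[: self.n_sites], pos[: self.n_sites]
        return chrom, pos

    def popmap(self) -> PopulationMap:
        sample_population = {}
        for pop in self.leaf_names():
            for i in range(self.samples_per_population.get(pop, 0)):
                sample_population[f"{pop}_{i:03d}"] = pop
        return PopulationMap(sample_population, self.population_group)

    def without_pulses(self) -> "ScenarioConfig":
        import copy

        cfg = copy.deepcopy(self)
        cfg.admixture_pulses = []
        return cfg


@dataclass
class TruthTrack:
    """Ground truth of a simulated scenario: which windows carry introgression
    and the exact post-drift, post-pulse population frequencies."""

    introgressed_windows: list[Interval]
    frequencies: FrequencyTable


# ------------------------------------------------------------------ simulate

def _draw_ancestral(rng: np.random.Generator, n: int, spec: Mapping) -> np.ndarray:
    a, b = float(spec.get("a", 0.8)), float(spec.get("b", 0.8))
    lo, hi = float(spec.get("lo", 0.02)), float(spec.get("hi", 0.98))
    return lo + (hi - lo) * rng.beta(a, b, size=n)


def _drift(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Balding–Nichols transition: Beta with mean p, variance f·p·(1−p)."""
    if f == 0.0:
        return p.copy()
    child = p.copy()
    interior = (p > 0.0) & (p < 1.0)
    scale = (1.0 - f) / f
    child[interior] = rng.beta(p[interior] * scale, (1.0 - p[interior]) * scale)
    return child


def simulate_frequencies(config: ScenarioConfig) -> tuple[FrequencyTable, TruthTrack]:
    """Drift ancestral frequencies down the tree, then apply admixture pulses.

    Deterministic given the config seed.  Pulses are applied after all drift,
    in their listed order, each only at sites inside its windows.
    """
    rng = np.random.default_rng(config.seed)
    chrom, pos = config.positions()
    n = pos.shape[0]
    ancestral = _draw_ancestral(rng, n, config.ancestral_freq)

    leaf_freqs: dict[str, np.ndarray] = {}

    def descend(node: dict, p: np.ndarray) -> None:
        children = node.get("children", [])
        if not children:
            leaf_freqs[node["name"]] = p
            return
        for child in children:
            q = _drift(rng, p, float(child.get("F", 0.0)))
            descend(child, q)

    descend(config.population_tree, ancestral)

    pops = config.leaf_names()
    p = np.column_stack([leaf_freqs[name] for name in pops])
    pos0 = pos - 1
    for pulse in config.admixture_pulses:
        jr = pops.index(pulse.recipient)
        jd = pops.index(pulse.donor)
        mask = np.zeros(n, dtype=bool)
        for c, s, e in pulse.windows:
            mask |= (chrom == c) & (pos0 >= s) & (pos0 < e)
        p[mask, jr] = (1.0 - pulse.proportion) * p[mask, jr] + pulse.proportion * p[mask, jd]

    table = FrequencyTable(chrom=chrom, pos=pos, populations=pops, p=p, n=None)
    truth_windows = sorted({(c, int(s), int(e)) for pu in config.admixture_pulses for c, s, e in pu.windows})
    truth = TruthTrack(introgressed_windows=truth_windows, frequencies=table)
    return table, truth


def sample_genotypes(
    freqs: FrequencyTable,
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Draw diploid genotypes, missingness and per-site covariates.

    Each genotype is the sum of two Bernoulli(p) allele draws (fixed-shape
    uniforms, so draws at a site are unaffected by pulse edits elsewhere).
    Ref/alt base pairs are drawn so the expected transition:transversion
    ratio equals ``target_ts_tv``.
    """
    if rng is None:
        rng = np.random.default_rng((config.seed, 0x6E07))
    n = freqs.n_sites
    pops = freqs.populations
    cols: list[np.ndarray] = []
    samples: list[str] = []
    for j, pop in enumerate(pops):
        n_ind = config.samples_per_population.get(pop, 0)
        if n_ind == 0:
            continue
        u = rng.random((2, n, n_ind))
        pj = freqs.p[:, j][:, None]
        g = ((u[0] < pj).astype(np.int8) + (u[1] < pj).astype(np.int8))
        cols.append(g)
        samples.extend(f"{pop}_{i:03d}" for i in range(n_ind))
    geno = np.concatenate(cols, axis=1) if cols else np.empty((n, 0), dtype=np.int8)
    if config.missing_rate > 0 and geno.shape[1]:
        miss = rng.random(geno.shape) < config.missing_rate
        geno = np.where(miss, np.int8(-1), geno)

    t = config.target_ts_tv
    is_ts = rng.random(n) < t / (1.0 + t)
    ts_idx = rng.integers(0, len(_TS_PAIRS), size=n)
    tv_idx = rng.integers(0, len(_TV_PAIRS), size=n)
    ref = np.empty(n, dtype=object)
    alt = np.empty(n, dtype=object)
    for i in range(n):
        r, a = _TS_PAIRS[ts_idx[i]] if is_ts[i] else _TV_PAIRS[tv_idx[i]]
        ref[i], alt[i] = r, (a,)

    qm = config.quality_model
    qual = np.maximum(rng.normal(qm.get("qual_mean", 80.0), qm.get("qual_sd", 15.0), n), 0.0)
    n_total = geno.shape[1]
    depth = rng.poisson(config.depth_model.get("mean_per_sample", 13.0) * max(n_total, 1), n).astype(float)
    mq = np.maximum(rng.normal(qm.get("mq_mean", 55.0), qm.get("mq_sd", 5.0), n), 0.0)

    return GenotypeMatrix(
        chrom=freqs.chrom, pos=freqs.pos, ref=ref, alt=alt,
        qual=qual, depth=depth, mq=mq, geno=geno, samples=samples,
    )


def simulate(config: ScenarioConfig) -> tuple[GenotypeMatrix, PopulationMap, TruthTrack, FrequencyTable]:
    """Convenience: frequencies + genotypes + popmap for one scenario."""
    freqs, truth = simulate_frequencies(config)
    matrix = sample_genotypes(freqs, config)
    return matrix, config.popmap(), truth, freqs


# ------------------------------------------------------------ default scenario

#: Per-branch drift coefficients calibrated (via the compounding rule
#: F_total = 1 - prod(1 - F_i) and pairwise Fst ~ mean compound F since the
#: MRCA) so realized pairwise Weir–Cockerham Fst lands in the observed ranges:
#: dromedary-Bactrian ~0.54-0.64, wild-domestic ~0.27-0.31, Iran-other
#: domestics ~0.05-0.06, shallow splits (<0.03) among the remaining domestics.
_CAMEL_TREE = {
    "name": "root", "F": 0.0, "children": [
        {"name": "drom", "F": 0.59},
        {"name": "bactrian_anc", "F": 0.423, "children": [
            {"name": "wild", "F": 0.29},
            {"name": "domestic_anc", "F": 0.2487, "children": [
                {"name": "IRAN", "F": 0.055},
                {"name": "domestic_core", "F": 0.030, "children": [
                    {"name": "central_core", "F": 0.010, "children": [
                        {"name": "KAZA", "F": 0.015},
                        {"name": "RUS", "F": 0.015},
                    ]},
                    {"name": "east_core", "F": 0.010, "children": [
                        {"name": "MG", "F": 0.015},
                        {"name": "IMG", "F": 0.015},
                        {"name": "XJ", "F": 0.015},
                    ]},
                ]},
            ]},
        ]},
    ],
}

#: Study-like cohort: 4 dromedaries, 19 wild Bactrian camels, and domestic
#: Bactrian camels from Iran (6), Kazakhstan (6), Russia (10), Mongolia (28)
#: and two Chinese regions (30 + 25), 128 diploids in total.
_CAMEL_COHORT = {
    "drom": 4, "wild": 19, "IRAN": 6, "KAZA": 6,
    "RUS": 10, "MG": 28, "IMG": 30, "XJ": 25,
}

_CAMEL_GROUPS = {
    "drom": "dromedary", "wild": "wild_bactrian",
    "IRAN": "central_asian", "KAZA": "central_asian", "RUS": "central_asian",
    "MG": "east_asian", "IMG": "east_asian", "XJ": "east_asian",
}

#: Dromedary-into-Central-Asian admixture proportions (1-10% range).
_CAMEL_PULSES = {"IRAN": 0.06, "KAZA": 0.05, "RUS": 0.04}


def make_camel_scenario(
    chromosome_length: int = 10_000_000,
    site_spacing: int = 100,
    samples_per_population: dict[str, int] | None = None,
    pulse_proportions: dict[str, float] | None = None,
    pulse_window_fraction: float = 0.2,
    pulse_window_size: int = 100_000,
    missing_rate: float = 0.02,
    seed: int = 0,
) -> ScenarioConfig:
    """Default eight-population camel-like scenario.

    One drift tree (dromedary outgroup; wild vs domestic Bactrian; Iran as the
    earliest-splitting domestic; shallow Central/East Asian structure) with
    dromedary→{IRAN, KAZA, RUS} admixture pulses confined to a random
    ``pulse_window_fraction`` of non-overlapping ``pulse_window_size`` windows
    (the same window set for all recipients, chosen deterministically from
    ``seed``).  Pass ``pulse_proportions={}`` for a pulse-free scenario.
    """
    lengths = {"chr1": int(chromosome_length)}
    props = _CAMEL_PULSES if pulse_proportions is None else pulse_proportions
    pulses: list[Pulse] = []
    if props:
        all_windows = tile_windows(lengths, pulse_window_size)
        k = max(1, round(pulse_window_fraction * len(all_windows)))
        wrng = np.random.default_rng((seed, 0xA11E))
        chosen = sorted(wrng.choice(len(all_windows), size=k, replace=False).tolist())
        windows = [(all_windows[i].chrom, all_windows[i].start, all_windows[i].end) for i in chosen]
        for recipient, f in props.items():
            pulses.append(Pulse(donor="drom", recipient=recipient, proportion=float(f), windows=windows))
    return ScenarioConfig(
        population_tree=_CAMEL_TREE,
        samples_per_population=dict(samples_per_population or _CAMEL_COHORT),
        chromosome_lengths=lengths,
        site_spacing=site_spacing,
        admixture_pulses=pulses,
        population_group=dict(_CAMEL_GROUPS),
        missing_rate=missing_rate,
        seed=seed,
    )


# ------------------------------------------------------------------- outputs

def write_outputs(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    truth: TruthTrack,
    out_prefix: str,
    contig_lengths: dict[str, int] | None = None,
) -> dict[str, str]:
    """Write VCF + population-map TSV + truth-window BED with a common prefix."""
    paths = {
        "vcf": f"{out_prefix}.vcf",
        "popmap": f"{out_prefix}.popmap.tsv",
        "truth_bed": f"{out_prefix}.truth.bed",
    }
    write_vcf(matrix, paths["vcf"], contig_lengths=contig_lengths)
    popmap.write_tsv(paths["popmap"])
    write_bed(truth.introgressed_windows, paths["truth_bed"])
    return paths
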