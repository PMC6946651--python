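"""Small builders shared across tests."""

from __future__ import annotations

import numpy as np

from camelscan import FrequencyTable, GenotypeMatrix, PopulationMap


def make_matrix(
    geno,
    chrom="chr1",
    pos=None,
    qual=100.0,
    depth=1000.0,
    mq=60.0,
    ref="A",
    alt=("G",),
    samples=None,
) -> GenotypeMatrix:
    """GenotypeMatrix from a nested list of dosages with passing metadata."""
    g = np.asarray(geno, dtype=np.int8)
    n_sites, n_samples = g.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 10
    scal = np.broadcast_to
    return GenotypeMatrix(
        chrom=np.full(n_sites, chrom, dtype=object),
        pos=np.asarray(pos),
        ref=np.full(n_sites, ref, dtype=object) if isinstance(ref, str) else np.asarray(ref, dtype=object),
        alt=np.array([alt] * n_sites, dtype=object) if isinstance(alt, tuple) else np.asarray(alt, dtype=object),
        qual=scal(np.float64(qual), (n_sites,)) if np.isscalar(qual) else np.asarray(qual),
        depth=scal(np.float64(depth), (n_sites,)) if np.isscalar(depth) else np.asarray(depth),
        mq=scal(np.float64(mq), (n_sites,)) if np.isscalar(mq) else np.asarray(mq),
        geno=g,
        samples=samples or [f"s{i}" for i in range(n_samples)],
    )


def make_popmap(assignments: dict[str, int], groups: dict[str, str] | None = None) -> PopulationMap:
    """PopulationMap with ``assignments`` populations of given sizes; sample
    names follow the s0, s1, ... column order of :func:`make_matrix`."""
    sample_population = {}
    i = 0
    for pop, count in assignments.items():
        for _ in range(count):
            sample_population[f"s{i}"] = pop
            i += 1
    return PopulationMap(sample_population, groups)


def freq_table(columns: dict[str, np.ndarray]) -> FrequencyTable:
    """FrequencyTable from per-population frequency arrays (parametric)."""
    pops = list(columns)
    p = np.column_stack([np.asarray(columns[k], dtype=float) for k in pops])
    n = p.shape[0]
    return FrequencyTable(
        chrom=np.full(n, "chr1", dtype=object),
        pos=np.arange(1, n + 1, dtype=np.int64),
        populations=pops,
        p=p,
    )
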