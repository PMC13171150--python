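"""Shared fixtures: small hand-built genotype matrices and simulated data."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hermetia.vcfio import GenotypeMatrix, PopulationMap


def make_matrix(
    dosage,
    pos=None,
    chrom="S1",
    samples=None,
    qual=100.0,
    dp=None,
    ad=None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a (samples x sites) dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_samples, n_sites = dosage.shape
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 1000
    if np.isscalar(chrom):
        chrom = [chrom] * n_sites
    qual_arr = np.full(n_sites, qual, dtype=float) if np.isscalar(qual) else np.asarray(qual, float)
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": "A", "alt": "C", "qual": qual_arr}
    )
    return GenotypeMatrix(
        samples=list(samples),
        sites=sites,
        dosage=dosage,
        dp=None if dp is None else np.asarray(dp, dtype=np.int32),
        ad=None if ad is None else np.asarray(ad, dtype=np.int32),
    )


def make_popmap(assignment, status=None, lineage=None) -> PopulationMap:
    """assignment: sample -> population; status/lineage default to wild/'l'."""
    return PopulationMap(
        population=dict(assignment),
        status={s: (status or {}).get(s, "wild") for s in assignment},
        lineage={s: (lineage or {}).get(s, "l") for s in assignment},
    )


@pytest.fixture
def four_pop_trio():
    """One sample per taxon, dosages chosen per test; popmap P1/P2/P3/O."""
    pm = make_popmap(
        {"a": "P1", "b": "P2", "c": "P3", "o": "O"},
    )
    return pm
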