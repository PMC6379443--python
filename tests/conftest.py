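"""Shared fixtures. The expensive end-to-end simulations (30x WGS of the
edited and unedited locus, aligned with the built-in aligner) are built once
per session and shared across module and acceptance tests."""

from __future__ import annotations

import pytest

from bystander_scan import align_depth, locus_forge


@pytest.fixture(scope="session")
def default_locus():
    return locus_forge.build_locus()


@pytest.fixture(scope="session")
def idfl_allele(default_locus):
    return locus_forge.make_idfl_allele(default_locus)


@pytest.fixture(scope="session")
def edel_allele(default_locus):
    return locus_forge.make_edel_allele(default_locus)


@pytest.fixture(scope="session")
def idfl_wgs(default_locus, idfl_allele):
    """Homozygous-duplication 30x simulation, aligned: (locus, readset, records)."""
    rps = locus_forge.simulate_wgs_readpairs(idfl_allele, depth=30.0, seed=1)
    index = align_depth.ReferenceIndex(default_locus.sequence, default_locus.name)
    records = align_depth.align_readpair_set(index, rps)
    return default_locus, rps, records


@pytest.fixture(scope="session")
def control_wgs(default_locus):
    """Unedited-locus 30x simulation, aligned: (locus, readset, records)."""
    rps = locus_forge.simulate_wgs_readpairs(default_locus, depth=30.0, seed=1)
    index = align_depth.ReferenceIndex(default_locus.sequence, default_locus.name)
    records = align_depth.align_readpair_set(index, rps)
    return default_locus, rps, records
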