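"""Shared fixtures: simulated studies reused across the suite.

The full-scale study (3 x 30-Mb chromosomes, 2M DamID reads per sample) is
built once per session; cheap unit tests use small inline genomes instead.
"""
from __future__ import annotations

from dataclasses import replace
from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import nucleodomain as nd
from nucleodomain.damid import FragmentCounts

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

STUDY_SEED = 7


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """Default-scale simulated study: genome, truth, GATC fragment map."""
    outdir = tmp_path_factory.mktemp("study")
    cfg = nd.SimConfig(seed=STUDY_SEED)
    truth = nd.simulate_genome(cfg, outdir)
    fragments = nd.build_gatc_fragments(str(outdir / "genome.fa"))
    return SimpleNamespace(cfg=cfg, truth=truth, fragments=fragments,
                           outdir=outdir)


def _replicate_track(truth, fragments, seed, bin_size):
    nols, dam = nd.simulate_damid(truth, fragments, seed=seed)
    scores = nd.damid_ratio(FragmentCounts(fragments, nols),
                            FragmentCounts(fragments, dam))
    return nd.bin_track(scores, bin_size)


@pytest.fixture(scope="session")
def replicate_tracks(study):
    """Two independent-noise DamID replicate tracks from the same truth."""
    return tuple(
        _replicate_track(study.truth, study.fragments, STUDY_SEED + rep,
                         study.cfg.bin_size)
        for rep in (1, 2))


@pytest.fixture(scope="session")
def called_nads(replicate_tracks, study):
    """Replicate-intersected NAD calls at the study's standard parameters."""
    calls = [nd.call_peaks(t, fdr_max=0.01, min_quant=0.70, n_shuffles=100,
                           seed=STUDY_SEED + 10 + i)
             for i, t in enumerate(replicate_tracks)]
    merged = nd.intersect_replicates(calls[0].domains, calls[1].domains,
                                     min_out=study.cfg.bin_size)
    return SimpleNamespace(calls=calls, nads=merged)


@pytest.fixture(scope="session")
def npc_called_nads(study):
    """NAD calls for the second (NPC-like) cell type on the same genome."""
    layout2 = nd.design_paired_layouts()[1]
    cfg2 = replace(study.cfg, domain_layout=layout2)
    truth2 = nd.SimTruth(study.truth.genome, cfg2, study.truth.rdna_interval)
    tracks = [_replicate_track(truth2, study.fragments, STUDY_SEED + 20 + rep,
                               cfg2.bin_size) for rep in (1, 2)]
    calls = [nd.call_peaks(t, seed=STUDY_SEED + 30 + i)
             for i, t in enumerate(tracks)]
    merged = nd.intersect_replicates(calls[0].domains, calls[1].domains,
                                     min_out=cfg2.bin_size)
    return SimpleNamespace(truth=truth2, nads=merged)


@pytest.fixture(scope="session")
def hic_pairs(study, tmp_path_factory):
    """Simulated Hi-C pairs under the study's default boosts."""
    path = tmp_path_factory.mktemp("hic") / "sim.pairs"
    pairs = nd.simulate_hic_pairs(study.truth, path, seed=STUDY_SEED + 40)
    return SimpleNamespace(pairs=pairs, path=path)


@pytest.fixture
def toy_genome():
    return nd.Genome({"chrA": 1_000_000, "chrB": 500_000})


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """Small fast study (3 x 5 Mb) for mid-weight simulation checks."""
    outdir = tmp_path_factory.mktemp("small")
    layout = [("chr1", 500_000, 1_000_000, "NAD-only"),
              ("chr1", 3_000_000, 3_500_000, "NAD/LAD"),
              ("chr2", 1_000_000, 1_600_000, "NAD/LAD"),
              ("chr2", 3_000_000, 3_400_000, "LAD-only"),
              ("chr3", 1_200_000, 1_800_000, "NAD-only")]
    cfg = nd.SimConfig(
        chrom_lengths=[("chr1", 5_000_000), ("chr2", 5_000_000),
                       ("chr3", 5_000_000)],
        domain_layout=layout, damid_depth=600_000, hic_n_pairs=200_000,
        seed=11)
    truth = nd.simulate_genome(cfg, outdir)
    fragments = nd.build_gatc_fragments(str(outdir / "genome.fa"))
    return SimpleNamespace(cfg=cfg, truth=truth, fragments=fragments,
                           outdir=outdir)
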