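"""Shared fixtures: small hand-built annotations and one full-scale
synthetic study run reused by the integration tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from beecage.io_core import GeneModel, GenomeAnnotation, MappedPair
from beecage import diffexp, synthetic_data as sd, tag_pipeline as tp, tss_analysis as ta


def make_pair(
    sample_id="s1",
    qname="q",
    scaffold="scf1",
    strand1="+",
    strand2="-",
    m1=(100, 179),
    m2=(700, 779),
    mapq=60,
    scaffold2=None,
    mate1_unmapped=False,
    mate2_unmapped=False,
):
    return MappedPair(
        sample_id=sample_id,
        qname=qname,
        scaffold_1=None if mate1_unmapped else scaffold,
        scaffold_2=None if mate2_unmapped else (scaffold2 or scaffold),
        strand_1=None if mate1_unmapped else strand1,
        strand_2=None if mate2_unmapped else strand2,
        mate1_start=None if mate1_unmapped else m1[0],
        mate1_end=None if mate1_unmapped else m1[1],
        mate2_start=None if mate2_unmapped else m2[0],
        mate2_end=None if mate2_unmapped else m2[1],
        mapq=mapq,
        mate1_unmapped=mate1_unmapped,
        mate2_unmapped=mate2_unmapped,
    )


@pytest.fixture
def two_gene_annotation():
    """Two + strand genes 3 kb apart plus one - strand pair."""
    return GenomeAnnotation(
        [
            GeneModel("gA", "scf1", "+", 1000, 2000),
            GeneModel("gB", "scf1", "+", 5000, 6000),
            GeneModel("gC", "scf1", "-", 9000, 10000),
            GeneModel("gD", "scf1", "-", 13000, 14000),
        ]
    )


@pytest.fixture(scope="session")
def study_sim():
    """One synthetic study at the design conditions: 8 nurses + 8 foragers,
    5e4 tag pairs per sample, NB dispersion 0.1, 5 bp TSS peaks, alternative
    offsets 150-400 bp.  Runs the full pipeline once for all integration
    tests."""
    cfg = sd.SimConfig()
    truth = sd.simulate_truth(cfg, seed=11)
    tags = sd.simulate_tags(truth, seed=12)
    all_pairs = [p for ps in tags.pairs_by_sample.values() for p in ps]
    mean, sdev = tp.estimate_inner_distance(all_pairs)
    kept, report = tp.filter_pairs(all_pairs, inner_max=mean + sdev)
    assoc = tp.associate_tags(kept, truth.annotation)
    matrix = tp.build_count_matrix(assoc, truth.groups())
    de = diffexp.de_pipeline(matrix)
    by_sample: dict[str, list] = {}
    for p in kept:
        by_sample.setdefault(p.sample_id, []).append(p)
    tss = ta.tss_pipeline(by_sample, truth.annotation, truth.groups())
    return {
        "truth": truth,
        "tags": tags,
        "report": report,
        "matrix": matrix,
        "de": de,
        "tss": tss,
    }
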