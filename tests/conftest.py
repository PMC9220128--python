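from __future__ import annotations

import pytest

from cdrhmine.data_model import CDRH, GeneModel, HomologyHit, load_default_registry
from cdrhmine.classify import superclass_of
from cdrhmine.pipeline import run_pipeline
from cdrhmine.simulate import default_study_config, generate_genome

#: Seed of the standard recovery scenario used across the suite.
STUDY_SEED = 0


@pytest.fixture(scope="session")
def registry():
    return load_default_registry()


@pytest.fixture(scope="session")
def study_run():
    """One full synthetic-study simulation + pipeline run, shared by all
    tests that inspect end-to-end behaviour (it is the expensive step)."""
    sim = generate_genome(default_study_config(STUDY_SEED))
    result = run_pipeline(sim.registry, sim.species_data)
    return sim, result


def make_hit(
    query_id="q",
    target_id="t",
    evalue=1e-50,
    sim=85.0,
    ident=None,
    length=200,
    chrom=None,
    t_start=1,
    t_end=None,
    score=500.0,
):
    return HomologyHit(
        query_id=query_id,
        target_id=target_id,
        target_chrom=chrom or target_id,
        t_start=t_start,
        t_end=t_end if t_end is not None else t_start + length - 1,
        aln_len_aa=length,
        pct_similarity=sim,
        pct_identity=ident if ident is not None else min(sim, 100.0),
        raw_score=score,
        evalue=evalue,
    )


def make_cdrh(
    gene_id,
    chrom="A01",
    start=1,
    end=None,
    rga_class="TNL",
    queries=("q1",),
    species="Bna",
    length=1000,
):
    gene = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        start=start,
        end=end if end is not None else start + length - 1,
        subgenome="A" if chrom.startswith("A") else "U",
        species_code=species,
    )
    cdrh = CDRH(gene=gene, source_queries=list(queries))
    cdrh.rga_class = rga_class
    cdrh.superclass = superclass_of(rga_class)
    return cdrh
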