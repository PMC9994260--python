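import pytest

from rnaedit import (
    EditSite,
    ReadSimConfig,
    build_scenario,
    generate_reference,
    plant_decoy,
    simulate_reads,
)
from rnaedit.simulate import adenosine_offsets


def make_dataset(
    seed=7,
    n_host_mrna=10,
    n_phage_mrna=3,
    mean_depth=60.0,
    error_rate=0.001,
    indel_read_fraction=0.02,
    decoy_gene="hgene0",
    decoy_copies=2,
    edit_specs=(("trna2", 0.4, "positive-control"), ("hgene1", 0.04, "ssrA-like")),
):
    """A miniature host+phage dataset with decoys, indels and injected edits."""
    spec, genes = build_scenario(
        seed=seed, n_host_mrna=n_host_mrna, n_phage_mrna=n_phage_mrna
    )
    genome, ann = generate_reference(spec, genes)
    if decoy_gene:
        genome = plant_decoy(genome, ann, decoy_gene, decoy_copies)
    sites = []
    for gene_id, rate, label in edit_specs:
        offs = adenosine_offsets(genome, ann.by_id[gene_id])
        sites.append(EditSite(gene_id, int(offs[len(offs) // 2]), rate, label))
    cfg = ReadSimConfig(
        seed=seed + 1,
        mean_depth=mean_depth,
        error_rate=error_rate,
        indel_read_fraction=indel_read_fraction,
    )
    result = simulate_reads(genome, ann, sites, cfg)
    return genome, ann, sites, cfg, result


@pytest.fixture(scope="session")
def dataset():
    """Shared edited dataset (session-scoped; treat as read-only)."""
    return make_dataset()


@pytest.fixture(scope="session")
def clean_dataset():
    """Error-free, edit-free, decoy-free dataset: reads match the reference."""
    return make_dataset(
        seed=13,
        error_rate=0.0,
        indel_read_fraction=0.0,
        decoy_gene=None,
        edit_specs=(),
    )
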