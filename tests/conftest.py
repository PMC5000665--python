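import numpy as np
import pytest

from tagport.panel_io import HaplotypePanel, VariantRecord
from tagport.synthetic_data import (
    PopulationSpec,
    SyntheticScenario,
    generate_panel,
    paperlike_scenario,
)

TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
1\t100\trsA\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0
1\t200\trsB\tC\tT\t.\tPASS\t.\tGT\t0|0\t0|1\t1|1
1\t300\trsC\tG\tA,T\t.\tPASS\t.\tGT\t0|1\t0|2\t1|1
1\t400\trsD\tT\tC\t.\tPASS\t.\tGT\t1|0\t.|.\t0|1
1\t500\trsE\tA\tC\t.\tPASS\t.\tGT\t0|0\t1|0\t1|1
"""

TOY_PANEL_TABLE = """\
sample\tpop\tsuper_pop
s1\tPOPA\tEurope
s2\tPOPA\tEurope
s3\tPOPB\tAfrica
s4\tPOPB\tAfrica
s5\tPOPB\tAfrica
s6\tPOPC\tAtlantis
"""


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return str(path)


@pytest.fixture
def toy_panel_table(tmp_path):
    path = tmp_path / "toy.panel.tsv"
    path.write_text(TOY_PANEL_TABLE)
    return str(path)


def make_panel(columns, positions=None, phased=True, contig="1"):
    """Build a HaplotypePanel from a list of allele columns (rows = haplotypes)."""
    alleles = np.array(columns, dtype=np.int8).T
    n_hap, n_var = alleles.shape
    assert n_hap % 2 == 0
    if positions is None:
        positions = [100 * (i + 1) for i in range(n_var)]
    bases = ["A", "C", "G", "T"]
    variants = [
        VariantRecord(contig, int(p), f"v{i}", bases[i % 4], bases[(i + 1) % 4])
        for i, p in enumerate(positions)
    ]
    samples = [f"s{i}" for i in range(n_hap // 2)]
    return HaplotypePanel(
        variants=variants, sample_ids=samples, alleles=alleles, phased=phased
    )


def two_pop_scenario(
    seed=11,
    preserved_in_b=(0, 1, 2),
    n_proxies=4,
    monomorphic_b=False,
    extra_pops=(),
):
    """Small two-population scenario: proxies planted within 5 kb of the tag.

    ``preserved_in_b`` selects which of the ``n_proxies`` proxies keep
    their LD with the tag in population B.
    """
    n_variants = 41
    positions = tuple(10_000 + 1000 * i for i in range(n_variants))
    tag_index = 20
    proxy_indices = [18, 19, 21, 22, 16, 24][:n_proxies]
    proxies = []
    for k, idx in enumerate(proxy_indices):
        preserved = {"A"}
        if k in preserved_in_b:
            preserved.add("B")
        proxies.append((idx, frozenset(preserved)))
    pops = [
        PopulationSpec("A", "Europe", 15),
        PopulationSpec("B", "Africa", 15, extra_switch_rounds=1),
    ] + list(extra_pops)
    return SyntheticScenario(
        n_founders=24,
        positions=positions,
        switch_prob=0.5,
        populations=tuple(pops),
        tag_index=tag_index,
        planted_proxies=tuple(proxies),
        seed=seed,
        monomorphic_tag_pops=frozenset({"B"}) if monomorphic_b else frozenset(),
        ref_pop="A",
        windows_kb=(5, 10),
    )


@pytest.fixture(scope="session")
def paperlike_study():
    """Seed-1 paperlike scenario: (scenario, panel, pmap, truth)."""
    sc = paperlike_scenario(1)
    panel, pmap, truth = generate_panel(sc)
    return sc, panel, pmap, truth
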