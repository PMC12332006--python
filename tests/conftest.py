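import pytest

from misplice import catalog as cat
from misplice import differential as diff
from misplice import quant
from misplice.simulate import ConditionSim, SimConfig, make_toy_reference, simulate_reads


def make_intron(
    start=100,
    end=200,
    chrom="chr1",
    strand="+",
    gene_id="geneA",
    ordinal=1,
    up_exon=None,
    down_exon=None,
    intron_class="major",
    transcript_ids=None,
):
    """IntronRecord with sensible flanking-exon defaults for tests."""
    if strand == "+":
        up = up_exon or (start - 100, start)
        down = down_exon or (end, end + 100)
    else:
        up = up_exon or (end, end + 100)
        down = down_exon or (start - 100, start)
    return cat.IntronRecord(
        intron_id=cat.make_intron_id(chrom, start, end, strand),
        gene_id=gene_id,
        transcript_ids=transcript_ids or {"txA"},
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        ordinal=ordinal,
        upstream_exon=up,
        downstream_exon=down,
        intron_class=intron_class,
    )


def read(*blocks, chrom="chr1", sample="s1"):
    return quant.AlignedSegmentLite(chrom=chrom, blocks=list(blocks), sample_id=sample)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(
        n_genes=6,
        exons_per_gene=(2, 4),
        minor_intron_fraction=0.4,
        depth=80.0,
        conditions={
            "treated": ConditionSim(rho=0.3, alpha=0.1),
            "control": ConditionSim(rho=0.0, alpha=0.0),
        },
        replicates=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def toy_pipeline(tmp_path_factory, sim_config):
    """Reference + reads + catalog + quant table + design, shared per session."""
    out = tmp_path_factory.mktemp("toysim")
    reference = make_toy_reference(sim_config, out)
    sam_paths, truth = simulate_reads(reference, sim_config, out)
    introns = cat.build_catalog(reference.gtf, minor_list_path=reference.minor_list)
    quant_df = quant.quantify(introns, sam_paths)
    design = diff.ConditionDesign(
        "treated",
        "control",
        {s: ("treated" if s.startswith("treated") else "control") for s in sam_paths},
    )
    return {
        "config": sim_config,
        "reference": reference,
        "sam_paths": sam_paths,
        "truth": truth,
        "introns": introns,
        "quant_df": quant_df,
        "design": design,
        "dir": out,
    }
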