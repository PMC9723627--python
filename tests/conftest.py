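import pytest

from ironomics import io as iio, irquant, synthetic


@pytest.fixture(scope="session")
def small_config():
    return synthetic.SimulationConfig(n_genes=30, introns_per_gene=3, seed=1)


@pytest.fixture(scope="session")
def small_dataset(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim")
    return synthetic.simulate_all(small_config, outdir)


@pytest.fixture(scope="session")
def small_ir_table(small_config, small_dataset):
    ds = small_dataset
    annotation = iio.read_gtf(ds.gtf)
    fasta = iio.read_fasta(ds.fasta)
    chrom_lengths = {n: len(fasta[n]) for n in fasta.keys()}
    introns = irquant.extract_introns(annotation)
    coverage = {s: iio.read_bedgraph(p) for s, p in ds.coverage.items()}
    table = irquant.quantify_cell_types(
        introns, annotation, coverage, iio.read_junctions(ds.junctions),
        iio.read_expression(ds.expression),
        {s: ct for ct, s in small_config.samples()}, chrom_lengths)
    return table, introns


def make_intron(start=1000, end=2000, strand="+", chrom="chr1", gene="G1",
                **kw):
    defaults = dict(
        intron_id=f"{chrom}:{start}-{end}:{strand}", chrom=chrom, start=start,
        end=end, strand=strand, gene_id=gene, exon5_id="e5", exon3_id="e3",
        exon5_constitutive=True, exon3_constitutive=True,
        exon5_spliced_in=True, exon3_spliced_in=True,
        overlaps_known_exon=False,
        exon5_interval=(start - 150, start), exon3_interval=(end, end + 150),
    )
    defaults.update(kw)
    return irquant.IntronRecord(**defaults)


@pytest.fixture
def intron_factory():
    return make_intron


def measurement(irratio=0.25, depth=20.0, cov=0.95, intron_id="i1",
                sample="s1"):
    return irquant.IRMeasurement(intron_id, sample, depth, 0.0, irratio,
                                 depth, cov)


@pytest.fixture
def measurement_factory():
    return measurement
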