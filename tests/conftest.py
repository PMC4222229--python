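import pathlib

import pytest

import allopotential as ap


@pytest.fixture(scope="session")
def sim_config() -> ap.SimulationConfig:
    return ap.SimulationConfig(
        seed=7,
        n_genes=15,
        n_recipient_variants=30,
        n_donor_variants=25,
        shared_fraction=0.6,
    )


@pytest.fixture(scope="session")
def bundle(sim_config, tmp_path_factory) -> dict:
    """A complete synthetic input bundle shared across tests (read-only)."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = ap.simulate_bundle(sim_config, outdir)
    paths["outdir"] = pathlib.Path(outdir)
    return paths


@pytest.fixture(scope="session")
def sim_pair(sim_config):
    reference = ap.simulate_reference(sim_config)
    return ap.simulate_pair(reference, sim_config)


def write_vcf(path, records, sample="S1", contigs=("chr1", "chr2")):
    """Minimal single-sample VCF writer for handcrafted fixtures.

    ``records`` are (chrom, pos, ref, alt_field, genotype) tuples; alt_field
    may contain comma-separated alleles.
    """
    lines = ["##fileformat=VCFv4.2"]
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if sample:
        cols += f"\tFORMAT\t{sample}"
    lines.append(cols)
    for chrom, pos, ref, alt, gt in records:
        row = f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t."
        if sample:
            row += f"\tGT\t{gt}"
        lines.append(row)
    pathlib.Path(path).write_text("\n".join(lines) + "\n")
    return path
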