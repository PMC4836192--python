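import pytest

from aluktrio import core_io
from aluktrio.fixtures import fixture_path


@pytest.fixture(scope="session")
def paper_dataset() -> core_io.Dataset:
    """The packaged worked-example dataset (trio STR tables, synthetic
    frequencies, 30-locus Alu outcomes, locus specs, pedigree)."""
    return core_io.load_dataset(
        genotypes=fixture_path("tables_2_3.tsv"),
        alu_observations=fixture_path("alu_outcomes.tsv"),
        pedigree=fixture_path("trio.ped"),
        frequencies=fixture_path("synthetic_frequencies.tsv"),
        alu_locus_specs=fixture_path("alu_locus_specs.tsv"),
    )


@pytest.fixture()
def freq_table():
    """Factory for small in-memory allele-frequency tables."""

    def build(locus: str, freqs: dict[str, float]) -> core_io.AlleleFrequencyTable:
        table = core_io.AlleleFrequencyTable()
        for allele, f in freqs.items():
            table.add(locus, allele, f)
        return table

    return build
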