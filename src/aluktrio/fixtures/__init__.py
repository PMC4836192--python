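"""Packaged example data for the trio worked example.

``tables_2_3.tsv``
    STR genotypes for the prehistoric trio (father DO1911, mother DO3756,
    daughter DO3750) and two modern controls, transcribed from the
    published consensus fingerprint tables.  The daughter's D16S639,
    D2S1338 and D19S433 genotypes came from a second bone (DO 3994, left
    humerus) of the same individual; the locus spelling "D16S639" is kept
    verbatim (see ``aluktrio.core_io.STR_LOCUS_ALIASES``).

``synthetic_frequencies.tsv``
    SYNTHETIC European-plausible allele frequencies covering every allele
    in ``tables_2_3.tsv``.  The original study drew frequencies from an
    online database whose version is unknown; these values are a
    stand-in for running the worked example, not measured data.

``alu_outcomes.tsv``
    Per-sample flanking-primer (FAP) and internal-primer (IAP) band
    observations at 30 Alu insertion loci, reconstructed from the study's
    running-text accounting (22 loci definite from FAP alone; IAP rescues
    at Alu_3/14/19/20 and combined-result heterozygotes at Alu_16/26/27;
    Alu_2/7 incongruent; Alu_4/25 extract-depleted).  Band patterns at
    loci whose genotypes the text does not print are synthetic congruent
    placeholders.

``alu_locus_specs.tsv``
    Synthetic amplicon geometry for the 30 loci (presence 450-500 bp,
    absence ~300 bp shorter, internal-primer amplicons 118-194 bp).

``trio.ped``
    PED-subset pedigree declaring the trio and the two modern controls.
"""

from importlib import resources
from pathlib import Path

__all__ = ["fixture_path", "FIXTURES"]

FIXTURES = (
    "tables_2_3.tsv",
    "synthetic_frequencies.tsv",
    "alu_outcomes.tsv",
    "alu_locus_specs.tsv",
    "trio.ped",
)


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture file."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    return Path(str(resources.files("aluktrio.fixtures").joinpath(name)))
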