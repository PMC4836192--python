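"""Reverse Parentage Index (RPI) kinship for a father-mother-child trio.

The per-locus RPI is a likelihood ratio comparing two hypotheses for a
child with genotype observed alongside a putative mother (genotype AB) and
father (genotype CD):

* X -- the couple are random draws from the population *and* the child is
  their biological offspring:  X = P(AB) * P(CD) * T, where T is the
  Mendelian transmission probability of the child's genotype given the
  parents (each parental allele passes with probability 0.5);
* Y -- all three are unrelated random draws:  Y = P(AB) * P(CD) * P(child),
  with P(child) the Hardy-Weinberg genotype probability (2*p_a*p_b for a
  heterozygote, p_a**2 for a homozygote).

The parental genotype probabilities cancel, so RPI = T / P(child); for the
textbook AB x CD -> BC configuration this is 0.25 / (2*p_B*p_C).  Loci are
treated as independent (unlinked, no mutation or silent alleles): the
combined RPI is the product over loci, and the posterior kinship
probability follows the Essen-Moller form
W = CRPI * prior / (CRPI * prior + 1 - prior), prior 0.5 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import pandas as pd

from aluktrio.core_io import (
    AlleleFrequencyTable,
    Dataset,
    StrGenotype,
    is_sex_marker,
)

__all__ = [
    "RpiResult",
    "CombinedKinship",
    "transmission_probability",
    "trio_transmission_probability",
    "random_match_probability",
    "rpi_locus",
    "combined_rpi",
    "posterior_probability",
    "kinship_report",
]


@dataclass(frozen=True)
class RpiResult:
    """Per-locus RPI with the numerator/denominator it was derived from."""

    locus: str
    numerator_X: float
    denominator_Y: float
    rpi: float


@dataclass
class CombinedKinship:
    """Product of per-locus RPIs and the resulting posterior probability."""

    per_locus: list[RpiResult]
    combined_rpi: float
    posterior: float
    prior: float = 0.5
    excluded_loci: list[str] = field(default_factory=list)


def transmission_probability(parent: StrGenotype, allele: str) -> float:
    """P(parent transmits ``allele``): 1 if homozygous for it, 0.5 if it
    carries one copy, 0 otherwise."""
    if parent is None:
        raise ValueError("parent genotype is missing")
    copies = parent.alleles.count(allele)
    return copies / 2.0


def trio_transmission_probability(
    mother: StrGenotype, father: StrGenotype, child: StrGenotype
) -> float:
    """P(child genotype | mother, father) under Mendelian segregation.

    Each parent passes one of its two alleles with probability 0.5; the
    four equally likely gamete pairs are enumerated and those matching the
    child's unordered genotype counted.  A homozygous child corresponds to
    a single unordered outcome, so it is never double-counted.
    """
    for name, g in (("mother", mother), ("father", father), ("child", child)):
        if g is None:
            raise ValueError(f"{name} genotype is missing")
    target = child.alleles  # canonically ordered on construction
    hits = sum(
        1
        for gm, gf in product(mother.alleles, father.alleles)
        if tuple(sorted((gm, gf))) == target
    )
    return hits / 4.0


def random_match_probability(
    child: StrGenotype, freqs: AlleleFrequencyTable
) -> float:
    """Hardy-Weinberg probability that a random individual has the child's
    genotype; raises :class:`~aluktrio.core_io.MissingFrequencyError` naming
    the locus and allele when a frequency is absent."""
    a, b = child.alleles
    pa = freqs.frequency(child.locus, a)
    if a == b:
        return pa * pa
    pb = freqs.frequency(child.locus, b)
    return 2.0 * pa * pb


def rpi_locus(
    mother: StrGenotype,
    father: StrGenotype,
    child: StrGenotype,
    freqs: AlleleFrequencyTable,
) -> RpiResult:
    """Per-locus Reverse Parentage Index.

    The ratio is computed as T / P(child) directly -- the parental
    Hardy-Weinberg factors cancel algebraically, so the result is exactly
    invariant to the frequencies of alleles carried only by the parents.
    The X and Y fields are reported with the parental factors included for
    traceability.
    """
    transmission = trio_transmission_probability(mother, father, child)
    match = random_match_probability(child, freqs)
    if match <= 0.0:
        raise ValueError(
            f"{child.locus}: zero random-match probability for {child}"
        )
    p_parents = random_match_probability(mother, freqs) * random_match_probability(
        father, freqs
    )
    return RpiResult(
        locus=child.locus,
        numerator_X=p_parents * transmission,
        denominator_Y=p_parents * match,
        rpi=transmission / match,
    )


def posterior_probability(combined_rpi: float, prior: float = 0.5) -> float:
    """Essen-Moller posterior W = CRPI*prior / (CRPI*prior + 1 - prior)."""
    if combined_rpi < 0:
        raise ValueError("combined RPI must be non-negative")
    if not (0.0 < prior < 1.0):
        raise ValueError("prior must lie in (0, 1)")
    odds = combined_rpi * prior
    return odds / (odds + (1.0 - prior))


def combined_rpi(
    results: Iterable[RpiResult],
    prior: float = 0.5,
    excluded_loci: Sequence[str] = (),
) -> CombinedKinship:
    """Multiply per-locus RPIs into a combined index and posterior.

    Each locus may appear at most once (independence assumption); an empty
    list gives the neutral CRPI of 1 (posterior = prior).
    """
    results = list(results)
    seen: set[str] = set()
    for r in results:
        if r.locus in seen:
            raise ValueError(f"duplicate locus {r.locus!r} in RPI combination")
        seen.add(r.locus)
    crpi = 1.0
    for r in results:
        crpi *= r.rpi
    return CombinedKinship(
        per_locus=results,
        combined_rpi=crpi,
        posterior=posterior_probability(crpi, prior),
        prior=prior,
        excluded_loci=list(excluded_loci),
    )


def kinship_report(
    dataset: Dataset,
    prior: float = 0.5,
    exclude: Sequence[str] = (),
) -> tuple[pd.DataFrame, CombinedKinship]:
    """Run the full RPI analysis on a dataset's trio.

    The sex marker (amelogenin) is always excluded -- it is not an
    autosomal STR.  Loci with a missing genotype for any trio member are
    excluded from the product and listed in ``excluded_loci`` rather than
    imputed.  Returns a per-locus table and the combined result.
    """
    if dataset.pedigree is None:
        raise ValueError("dataset has no pedigree")
    if dataset.frequency_table is None:
        raise ValueError("dataset has no allele-frequency table")
    exclude_set = {e.lower() for e in exclude}
    results: list[RpiResult] = []
    excluded: list[str] = []
    for locus in dataset.str_loci():
        if is_sex_marker(locus) or locus.lower() in exclude_set:
            continue
        mother, father, child = dataset.trio_genotypes(locus)
        if mother is None or father is None or child is None:
            excluded.append(locus)
            continue
        results.append(rpi_locus(mother, father, child, dataset.frequency_table))
    combined = combined_rpi(results, prior=prior, excluded_loci=excluded)
    table = pd.DataFrame(
        {
            "locus": [r.locus for r in results],
            "numerator_X": [r.numerator_X for r in results],
            "denominator_Y": [r.denominator_Y for r in results],
            "rpi": [r.rpi for r in results],
        }
    )
    return table, combined
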