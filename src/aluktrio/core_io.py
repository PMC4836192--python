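"""Domain types, TSV readers/writers and dataset validation.

All tabular inputs are tab-separated files with a header row; lines starting
with ``#`` are comments.  STR allele labels are opaque strings ("12",
"30.2", "9.3", "X") and are never converted to numbers: microvariant
nomenclature such as "30.2" must survive a round trip verbatim.

Alu presence/absence observations distinguish the two amplification
strategies used on insertion polymorphisms in degraded samples:

* FAP -- flanking-primer amplification; the long amplicon (~450-500 bp)
  reports the presence allele, the short one the absence allele.
* IAP -- one flanking primer paired with an Alu-subfamily-internal primer;
  a ~118-194 bp amplicon that proves a presence allele exists but cannot
  distinguish heterozygotes from presence homozygotes.

Genotype calls for ancient samples follow the dropout-aware convention:
a single FAP band is recorded as "+" (``P_any``) or "-" (``A_only``), never
as a definite homozygote, because the longer presence fragment is the one
allelic dropout preferentially removes.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "FormatError",
    "MissingFrequencyError",
    "StrGenotype",
    "AlleleFrequencyTable",
    "TrioPedigree",
    "AluLocusSpec",
    "FapObservation",
    "IapObservation",
    "Call",
    "AluCall",
    "Sample",
    "Dataset",
    "ValidationReport",
    "normalize_allele",
    "is_sex_marker",
    "STR_LOCUS_ALIASES",
    "read_genotype_table",
    "read_alu_observation_table",
    "read_frequency_table",
    "read_alu_locus_table",
    "read_pedigree",
    "write_genotype_table",
    "write_alu_observation_table",
    "write_frequency_table",
    "write_alu_locus_table",
    "write_pedigree",
    "load_dataset",
    "validate_dataset",
]


class FormatError(ValueError):
    """Malformed input file; message names the file and 1-based line."""

    def __init__(self, path: str | Path, line: int | None, message: str):
        self.path = str(path)
        self.line = line
        where = f"{self.path}:{line}" if line is not None else self.path
        super().__init__(f"{where}: {message}")


class MissingFrequencyError(KeyError):
    """An allele referenced by a genotype has no population frequency."""

    def __init__(self, locus: str, allele: str):
        self.locus = locus
        self.allele = allele
        super().__init__(f"no frequency for allele {allele!r} at locus {locus!r}")

    def __str__(self) -> str:  # KeyError.__str__ would repr() the message
        return self.args[0]


def normalize_allele(token: str) -> str:
    """Trim whitespace; allele labels are otherwise kept verbatim."""
    label = token.strip()
    if not label:
        raise ValueError("empty allele label")
    return label


#: Known locus-name alias: one published table spells D16S539 as "D16S639".
#: Pass as the ``aliases`` argument of :func:`read_genotype_table` to
#: normalize; the default is verbatim ingestion.
STR_LOCUS_ALIASES: Mapping[str, str] = {"D16S639": "D16S539"}

_AMELOGENIN_NAMES = {"amelogenin", "amelo", "amel"}


def is_sex_marker(locus: str) -> bool:
    """True for the amelogenin X/Y sex marker under its common spellings."""
    return locus.strip().lower() in _AMELOGENIN_NAMES


@dataclass(frozen=True)
class StrGenotype:
    """Unordered diploid allele pair at one STR system.

    ``StrGenotype("vWA", "17", "19") == StrGenotype("vWA", "19", "17")``;
    the allele pair is canonically ordered on construction.
    """

    locus: str
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        a = normalize_allele(self.allele1)
        b = normalize_allele(self.allele2)
        if (b, a) < (a, b):
            a, b = b, a
        object.__setattr__(self, "allele1", a)
        object.__setattr__(self, "allele2", b)
        object.__setattr__(self, "locus", self.locus.strip())

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele1, self.allele2)

    @property
    def is_homozygous(self) -> bool:
        return self.allele1 == self.allele2

    def carries(self, allele: str) -> bool:
        return allele in self.alleles

    def __str__(self) -> str:
        return f"{self.allele1}/{self.allele2}"


class AlleleFrequencyTable:
    """Per-locus map from allele label to population frequency.

    Frequencies must lie in (0, 1]; a locus may be incomplete (rare alleles
    omitted, per-locus sum < 1) but may not exceed 1 + 1e-6.  Looking up an
    allele the table does not carry raises :class:`MissingFrequencyError` --
    likelihood ratios are undefined without a frequency, and silence would
    hide the problem.
    """

    SUM_TOLERANCE = 1e-6

    def __init__(self) -> None:
        self._freqs: dict[str, dict[str, float]] = {}

    def add(self, locus: str, allele: str, frequency: float) -> None:
        locus = locus.strip()
        allele = normalize_allele(allele)
        if not (0.0 < frequency <= 1.0):
            raise ValueError(
                f"frequency {frequency!r} for {locus}/{allele} outside (0, 1]"
            )
        per_locus = self._freqs.setdefault(locus, {})
        if allele in per_locus:
            raise ValueError(f"duplicate frequency entry for {locus}/{allele}")
        per_locus[allele] = frequency

    def frequency(self, locus: str, allele: str) -> float:
        try:
            return self._freqs[locus][allele]
        except KeyError:
            raise MissingFrequencyError(locus, allele) from None

    def __contains__(self, key: tuple[str, str]) -> bool:
        locus, allele = key
        return allele in self._freqs.get(locus, {})

    def loci(self) -> list[str]:
        return sorted(self._freqs)

    def alleles(self, locus: str) -> dict[str, float]:
        return dict(self._freqs.get(locus, {}))

    def check_sums(self) -> None:
        for locus, per_locus in self._freqs.items():
            total = sum(per_locus.values())
            if total > 1.0 + self.SUM_TOLERANCE:
                raise ValueError(
                    f"frequencies at locus {locus!r} sum to {total:.6f} > 1"
                )

    def items(self) -> Iterator[tuple[str, str, float]]:
        for locus in sorted(self._freqs):
            for allele, freq in sorted(self._freqs[locus].items()):
                yield locus, allele, freq

    def __len__(self) -> int:
        return sum(len(v) for v in self._freqs.values())


@dataclass(frozen=True)
class TrioPedigree:
    """Father-mother-child trio with the child's reported sex."""

    father_id: str
    mother_id: str
    child_id: str
    child_sex: str = "unknown"  # {female, male, unknown}

    def __post_init__(self) -> None:
        ids = {self.father_id, self.mother_id, self.child_id}
        if len(ids) != 3:
            raise ValueError("pedigree requires three distinct sample ids")
        if self.child_sex not in {"female", "male", "unknown"}:
            raise ValueError(f"invalid child_sex {self.child_sex!r}")

    @property
    def members(self) -> tuple[str, str, str]:
        return (self.father_id, self.mother_id, self.child_id)


@dataclass(frozen=True)
class AluLocusSpec:
    """Amplicon geometry of one Alu insertion polymorphism.

    The presence amplicon spans the ~300 bp insert plus flanks; the absence
    amplicon is the same flanks without it, so their difference must be an
    Alu-insert-sized 250-400 bp.  The internal-primer amplicon is short
    (>= 100 bp, below the presence length) by design -- short enough to
    survive in degraded templates.
    """

    locus_id: str
    subfamily: str  # {AluYa5, AluYb8, other}
    presence_len: int
    absence_len: int
    iap_len: int
    orientation: str  # {forward, reverse}

    def __post_init__(self) -> None:
        if self.subfamily not in {"AluYa5", "AluYb8", "other"}:
            raise ValueError(f"unknown Alu subfamily {self.subfamily!r}")
        if self.orientation not in {"forward", "reverse"}:
            raise ValueError(f"invalid orientation {self.orientation!r}")
        if not (self.presence_len > self.absence_len > 0):
            raise ValueError(
                f"{self.locus_id}: need presence_len > absence_len > 0, "
                f"got {self.presence_len}/{self.absence_len}"
            )
        if not (100 <= self.iap_len < self.presence_len):
            raise ValueError(
                f"{self.locus_id}: iap_len {self.iap_len} outside "
                f"[100, presence_len)"
            )
        insert = self.presence_len - self.absence_len
        if not (250 <= insert <= 400):
            raise ValueError(
                f"{self.locus_id}: presence - absence = {insert} bp is not "
                "an Alu-insert-sized difference (250-400 bp)"
            )


@dataclass(frozen=True)
class FapObservation:
    """Which of the two flanking-primer bands appeared on the gel."""

    presence_band: bool
    absence_band: bool

    @property
    def no_band(self) -> bool:
        """The paper-table 'n.b.' state: total amplification failure."""
        return not (self.presence_band or self.absence_band)


class IapObservation(str, enum.Enum):
    """Outcome of the internal-primer amplification for one sample/locus."""

    BAND = "band"
    NO_BAND = "no_band"
    NOT_TESTED = "not_tested"
    EXTRACT_DEPLETED = "extract_depleted"


class Call(str, enum.Enum):
    """Reconciled presence/absence genotype call.

    ``PP``/``PA``/``AA`` are definite genotypes; ``P_ANY`` ("+") means at
    least one presence allele with zygosity unknown, ``A_ONLY`` ("-") means
    only absence bands were seen -- for an ancient sample this leaves a
    dropped presence allele possible.
    """

    PP = "PP"
    PA = "PA"
    AA = "AA"
    P_ANY = "P_any"
    A_ONLY = "A_only"
    MISSING = "missing"


@dataclass(frozen=True)
class AluCall:
    """Per-sample, per-locus Alu observation and (optionally) its call.

    ``call`` is ``None`` until :func:`aluktrio.mendel_reconcile.
    reconcile_fap_iap` has been applied; ``reason`` records why a call is
    missing (e.g. a depleted extract).
    """

    sample_id: str
    locus_id: str
    fap: FapObservation
    iap: IapObservation
    ancient: bool = True
    call: Call | None = None
    reason: str | None = None

    def with_call(self, call: Call, reason: str | None = None) -> "AluCall":
        return replace(self, call=call, reason=reason)


@dataclass(frozen=True)
class Sample:
    sample_id: str
    ancient: bool = True


@dataclass
class Dataset:
    """Everything one analysis run needs, with referential bookkeeping."""

    pedigree: TrioPedigree | None = None
    samples: dict[str, Sample] = field(default_factory=dict)
    str_genotypes: dict[tuple[str, str], StrGenotype] = field(default_factory=dict)
    alu_calls: list[AluCall] = field(default_factory=list)
    frequency_table: AlleleFrequencyTable | None = None
    alu_locus_specs: dict[str, AluLocusSpec] = field(default_factory=dict)

    def genotype(self, sample_id: str, locus: str) -> StrGenotype | None:
        return self.str_genotypes.get((sample_id, locus))

    def str_loci(self) -> list[str]:
        return sorted({locus for _, locus in self.str_genotypes})

    def autosomal_str_loci(self) -> list[str]:
        return [l for l in self.str_loci() if not is_sex_marker(l)]

    def trio_genotypes(
        self, locus: str
    ) -> tuple[StrGenotype | None, StrGenotype | None, StrGenotype | None]:
        """(mother, father, child) genotypes at ``locus``; None if absent."""
        if self.pedigree is None:
            raise ValueError("dataset has no pedigree")
        p = self.pedigree
        return (
            self.genotype(p.mother_id, locus),
            self.genotype(p.father_id, locus),
            self.genotype(p.child_id, locus),
        )

    def alu_loci(self) -> list[str]:
        if self.alu_locus_specs:
            return sorted(self.alu_locus_specs)
        return sorted({c.locus_id for c in self.alu_calls})

    def alu_call(self, sample_id: str, locus_id: str) -> AluCall | None:
        for call in self.alu_calls:
            if call.sample_id == sample_id and call.locus_id == locus_id:
                return call
        return None


# ---------------------------------------------------------------------------
# TSV plumbing


def _iter_rows(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-comment, non-blank lines."""
    with open(path, "r", encoding="utf-8", newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or (row[0].lstrip().startswith("#")):
                continue
            if all(not cell.strip() for cell in row):
                continue
            yield lineno, [cell.strip() for cell in row]


def _read_header(
    path: str | Path,
    rows: Iterator[tuple[int, list[str]]],
    required: Sequence[str],
) -> tuple[list[str], dict[str, int]]:
    try:
        _, header = next(rows)
    except StopIteration:
        raise FormatError(path, None, "empty file (no header row)") from None
    columns = [c.lower() for c in header]
    index = {name: i for i, name in enumerate(columns)}
    missing = [c for c in required if c not in index]
    if missing:
        raise FormatError(
            path, 1, f"missing required column(s): {', '.join(missing)}"
        )
    return columns, index


def _get(fields: list[str], index: dict[str, int], column: str) -> str:
    i = index[column]
    return fields[i] if i < len(fields) else ""


_TRUE_TOKENS = {"1", "true", "yes", "ancient"}
_FALSE_TOKENS = {"0", "false", "no", "modern"}
_MISSING_TOKENS = {"", "n.b.", "nb", "na", "-", "."}
_SEEN_TOKENS = {"seen", "band", "+", "1", "true", "yes"}
_NOT_SEEN_TOKENS = {"not_seen", "no_band", "n.b.", "", "0", "false", "no"}


def read_genotype_table(
    path: str | Path,
    dialect: str = "str",
    aliases: Mapping[str, str] | None = None,
) -> dict[tuple[str, str], StrGenotype] | list[AluCall]:
    """Read a genotype table in either the STR or the Alu dialect.

    STR dialect columns: ``sample_id, locus, allele1, allele2`` (extra
    columns such as a source-bone annotation are ignored).  A blank allele
    cell makes the genotype missing: the row is skipped.  Alu dialect is
    delegated to :func:`read_alu_observation_table`.
    """
    if dialect == "alu":
        return read_alu_observation_table(path)
    if dialect != "str":
        raise ValueError(f"unknown dialect {dialect!r}")
    aliases = aliases or {}
    genotypes: dict[tuple[str, str], StrGenotype] = {}
    rows = _iter_rows(path)
    _, index = _read_header(path, rows, ["sample_id", "locus", "allele1", "allele2"])
    for lineno, fields in rows:
        sample = _get(fields, index, "sample_id")
        locus = _get(fields, index, "locus")
        if not sample or not locus:
            raise FormatError(path, lineno, "blank sample_id or locus")
        locus = aliases.get(locus, locus)
        a1 = _get(fields, index, "allele1")
        a2 = _get(fields, index, "allele2")
        if a1.lower() in _MISSING_TOKENS or a2.lower() in _MISSING_TOKENS:
            continue  # missing genotype
        key = (sample, locus)
        if key in genotypes:
            raise FormatError(path, lineno, f"duplicate genotype for {key}")
        try:
            genotypes[key] = StrGenotype(locus, a1, a2)
        except ValueError as exc:
            raise FormatError(path, lineno, str(exc)) from exc
    return genotypes


def _parse_band(path: str | Path, lineno: int, token: str) -> bool:
    low = token.lower()
    if low in _SEEN_TOKENS:
        return True
    if low in _NOT_SEEN_TOKENS:
        return False
    raise FormatError(path, lineno, f"unknown band token {token!r}")


def read_alu_observation_table(path: str | Path) -> list[AluCall]:
    """Read per-sample FAP/IAP band observations.

    Columns: ``sample_id, locus, fap_presence, fap_absence, iap`` with an
    optional ``ancient`` column (default true).  ``iap`` tokens are
    ``band``/``no_band``/``not_tested``/``extract_depleted``; an empty cell
    means not tested.
    """
    calls: list[AluCall] = []
    rows = _iter_rows(path)
    columns, index = _read_header(
        path, rows, ["sample_id", "locus", "fap_presence", "fap_absence", "iap"]
    )
    has_ancient = "ancient" in index
    seen: set[tuple[str, str]] = set()
    for lineno, fields in rows:
        sample = _get(fields, index, "sample_id")
        locus = _get(fields, index, "locus")
        if not sample or not locus:
            raise FormatError(path, lineno, "blank sample_id or locus")
        key = (sample, locus)
        if key in seen:
            raise FormatError(path, lineno, f"duplicate observation for {key}")
        seen.add(key)
        fap = FapObservation(
            presence_band=_parse_band(path, lineno, _get(fields, index, "fap_presence")),
            absence_band=_parse_band(path, lineno, _get(fields, index, "fap_absence")),
        )
        iap_token = _get(fields, index, "iap").lower()
        if iap_token == "":
            iap = IapObservation.NOT_TESTED
        else:
            try:
                iap = IapObservation(iap_token)
            except ValueError:
                raise FormatError(
                    path, lineno, f"unknown iap token {iap_token!r}"
                ) from None
        ancient = True
        if has_ancient:
            token = _get(fields, index, "ancient").lower()
            if token in _TRUE_TOKENS:
                ancient = True
            elif token in _FALSE_TOKENS:
                ancient = False
            elif token:
                raise FormatError(path, lineno, f"unknown ancient token {token!r}")
        calls.append(AluCall(sample, locus, fap, iap, ancient=ancient))
    return calls


def read_frequency_table(path: str | Path) -> AlleleFrequencyTable:
    """Read a ``locus, allele, frequency`` table; validates invariants."""
    table = AlleleFrequencyTable()
    rows = _iter_rows(path)
    _, index = _read_header(path, rows, ["locus", "allele", "frequency"])
    for lineno, fields in rows:
        locus = _get(fields, index, "locus")
        allele = _get(fields, index, "allele")
        raw = _get(fields, index, "frequency")
        try:
            freq = float(raw)
        except ValueError:
            raise FormatError(path, lineno, f"non-numeric frequency {raw!r}") from None
        try:
            table.add(locus, allele, freq)
        except ValueError as exc:
            raise FormatError(path, lineno, str(exc)) from exc
    try:
        table.check_sums()
    except ValueError as exc:
        raise FormatError(path, None, str(exc)) from exc
    return table


def read_alu_locus_table(path: str | Path) -> list[AluLocusSpec]:
    """Read Alu locus metadata (amplicon lengths, subfamily, orientation)."""
    specs: list[AluLocusSpec] = []
    rows = _iter_rows(path)
    required = [
        "locus_id",
        "subfamily",
        "presence_len",
        "absence_len",
        "iap_len",
        "orientation",
    ]
    _, index = _read_header(path, rows, required)
    seen: set[str] = set()
    for lineno, fields in rows:
        locus_id = _get(fields, index, "locus_id")
        if locus_id in seen:
            raise FormatError(path, lineno, f"duplicate locus {locus_id!r}")
        seen.add(locus_id)
        try:
            spec = AluLocusSpec(
                locus_id=locus_id,
                subfamily=_get(fields, index, "subfamily"),
                presence_len=int(_get(fields, index, "presence_len")),
                absence_len=int(_get(fields, index, "absence_len")),
                iap_len=int(_get(fields, index, "iap_len")),
                orientation=_get(fields, index, "orientation"),
            )
        except ValueError as exc:
            raise FormatError(path, lineno, str(exc)) from exc
        specs.append(spec)
    return specs


_PED_SEX = {"1": "male", "2": "female"}


def read_pedigree(path: str | Path) -> tuple[TrioPedigree, dict[str, Sample]]:
    """Read a PED-subset pedigree and return (trio, declared samples).

    Whitespace- or tab-delimited columns: family_id, individual_id,
    father_id, mother_id, sex, phenotype (phenotype ignored).  Exactly one
    individual with both parents declared is expected -- the trio child.
    An optional 7th column flags each sample as ancient/modern.
    """
    samples: dict[str, Sample] = {}
    children: list[tuple[str, str, str, str]] = []
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(path, lineno, "expected >= 6 PED columns")
            _, indiv, father, mother, sex = fields[:5]
            ancient = True
            if len(fields) >= 7 and fields[6].lower() in _FALSE_TOKENS:
                ancient = False
            if indiv in samples:
                raise FormatError(path, lineno, f"duplicate individual {indiv!r}")
            samples[indiv] = Sample(indiv, ancient=ancient)
            if father != "0" and mother != "0":
                children.append((indiv, father, mother, sex))
    if len(children) != 1:
        raise FormatError(
            path, None, f"expected exactly one trio child, found {len(children)}"
        )
    child, father, mother, sex = children[0]
    for parent in (father, mother):
        if parent not in samples:
            raise FormatError(path, None, f"parent {parent!r} not declared")
    trio = TrioPedigree(
        father_id=father,
        mother_id=mother,
        child_id=child,
        child_sex=_PED_SEX.get(sex, "unknown"),
    )
    return trio, samples


# ---------------------------------------------------------------------------
# Writers (round-trip counterparts of the readers)


def _write_rows(path: str | Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for row in rows:
            writer.writerow(row)


def write_genotype_table(
    path: str | Path, genotypes: Mapping[tuple[str, str], StrGenotype]
) -> None:
    _write_rows(
        path,
        ["sample_id", "locus", "allele1", "allele2"],
        (
            (sample, locus, g.allele1, g.allele2)
            for (sample, locus), g in sorted(genotypes.items())
        ),
    )


def write_alu_observation_table(path: str | Path, calls: Sequence[AluCall]) -> None:
    def band(b: bool) -> str:
        return "seen" if b else "not_seen"

    _write_rows(
        path,
        ["sample_id", "locus", "fap_presence", "fap_absence", "iap", "ancient"],
        (
            (
                c.sample_id,
                c.locus_id,
                band(c.fap.presence_band),
                band(c.fap.absence_band),
                c.iap.value,
                "true" if c.ancient else "false",
            )
            for c in sorted(calls, key=lambda c: (c.sample_id, c.locus_id))
        ),
    )


def write_frequency_table(path: str | Path, table: AlleleFrequencyTable) -> None:
    _write_rows(
        path,
        ["locus", "allele", "frequency"],
        ((locus, allele, repr(freq)) for locus, allele, freq in table.items()),
    )


def write_alu_locus_table(path: str | Path, specs: Sequence[AluLocusSpec]) -> None:
    _write_rows(
        path,
        ["locus_id", "subfamily", "presence_len", "absence_len", "iap_len", "orientation"],
        (
            (s.locus_id, s.subfamily, s.presence_len, s.absence_len, s.iap_len, s.orientation)
            for s in sorted(specs, key=lambda s: s.locus_id)
        ),
    )


def write_pedigree(
    path: str | Path,
    trio: TrioPedigree,
    samples: Mapping[str, Sample] | None = None,
    family_id: str = "FAM1",
) -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    samples = samples or {
        s: Sample(s) for s in trio.members
    }
    lines = []
    for sid in sorted(samples):
        sample = samples[sid]
        if sid == trio.child_id:
            father, mother = trio.father_id, trio.mother_id
            sex = sex_code[trio.child_sex]
        else:
            father = mother = "0"
            sex = "1" if sid == trio.father_id else ("2" if sid == trio.mother_id else "0")
        lines.append(
            "\t".join(
                [family_id, sid, father, mother, sex, "0",
                 "ancient" if sample.ancient else "modern"]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Dataset assembly and validation


def load_dataset(
    genotypes: str | Path | None = None,
    alu_observations: str | Path | None = None,
    pedigree: str | Path | None = None,
    frequencies: str | Path | None = None,
    alu_locus_specs: str | Path | None = None,
    aliases: Mapping[str, str] | None = None,
) -> Dataset:
    """Assemble a :class:`Dataset` from any subset of the input files."""
    ds = Dataset()
    if pedigree is not None:
        ds.pedigree, ds.samples = read_pedigree(pedigree)
    if genotypes is not None:
        ds.str_genotypes = read_genotype_table(genotypes, "str", aliases=aliases)
    if alu_observations is not None:
        ds.alu_calls = read_alu_observation_table(alu_observations)
    if frequencies is not None:
        ds.frequency_table = read_frequency_table(frequencies)
    if alu_locus_specs is not None:
        ds.alu_locus_specs = {
            s.locus_id: s for s in read_alu_locus_table(alu_locus_specs)
        }
    if not ds.samples:
        ids = {s for s, _ in ds.str_genotypes} | {c.sample_id for c in ds.alu_calls}
        ds.samples = {s: Sample(s) for s in sorted(ids)}
    return ds


@dataclass
class ValidationReport:
    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, issue: str) -> None:
        self.issues.append(issue)

    def __str__(self) -> str:
        return "OK" if self.ok else "\n".join(self.issues)


def validate_dataset(ds: Dataset) -> ValidationReport:
    """Cross-check referential integrity and call conventions (report-only).

    An empty report means every downstream stage can run: no dangling
    sample/locus references, no ancient sample carrying a definite
    homozygote call straight from a single-band FAP result, and a
    population frequency for every autosomal STR allele in the genotype
    table (when a frequency table is attached).
    """
    report = ValidationReport()
    declared = set(ds.samples)
    if ds.pedigree is not None:
        for member in ds.pedigree.members:
            if member not in declared:
                report.add(f"pedigree member {member!r} not declared as a sample")
    for (sample, locus), _ in ds.str_genotypes.items():
        if declared and sample not in declared:
            report.add(f"STR genotype for undeclared sample {sample!r} ({locus})")
    for call in ds.alu_calls:
        if declared and call.sample_id not in declared:
            report.add(
                f"Alu observation for undeclared sample {call.sample_id!r} "
                f"({call.locus_id})"
            )
        if ds.alu_locus_specs and call.locus_id not in ds.alu_locus_specs:
            report.add(
                f"Alu observation for unknown locus {call.locus_id!r} "
                f"({call.sample_id})"
            )
        if (
            call.ancient
            and call.call in (Call.PP, Call.AA)
            and call.fap.presence_band != call.fap.absence_band
        ):
            # a single FAP band on an ancient sample must stay "+" / "-"
            report.add(
                f"ancient sample {call.sample_id!r} carries definite "
                f"homozygote {call.call.value} from a single-band FAP at "
                f"{call.locus_id}"
            )
        if call.iap is IapObservation.EXTRACT_DEPLETED and not (
            call.fap.presence_band or call.fap.absence_band or call.fap.no_band
        ):  # pragma: no cover - fap.no_band is total, kept for symmetry
            report.add(
                f"{call.sample_id}/{call.locus_id}: extract_depleted without "
                "a prior FAP attempt"
            )
    if ds.frequency_table is not None:
        for (sample, locus), g in sorted(ds.str_genotypes.items()):
            if is_sex_marker(locus):
                continue
            for allele in g.alleles:
                if (locus, allele) not in ds.frequency_table:
                    report.add(
                        f"no frequency for allele {allele!r} at locus "
                        f"{locus!r} (sample {sample})"
                    )
        try:
            ds.frequency_table.check_sums()
        except ValueError as exc:
            report.add(str(exc))
    return report
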