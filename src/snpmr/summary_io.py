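"""Read, validate and write single-variant GWAS summary statistics.

The unit of data is one variant's association in one study
(:class:`GwasAssociation`); a :class:`StudyTable` is an ordered set of such
records with unique study labels. Files are delimited text (TSV by default,
comma accepted) with a mandatory header row; column names are mapped through
a configurable dialect so GWAS-SSF-like, PLINK-like and bespoke headers all
load.

Betas for binary outcomes are kept on the log-odds scale internally. If the
input carries an odds-ratio column instead, it is log-transformed at load
time with a warning, because every downstream computation (Wald ratio,
inverse-variance weights, meta-analysis) operates on log-odds.

:func:`builtin_study_fixture` returns the packaged seven-study table of
rs4988235 (the LCT-13910 C>T lactase-persistence variant) T-allele
associations with four neurodegenerative diseases, the worked dataset used
throughout the documentation and tests.
"""

from __future__ import annotations

import csv
import logging
import math
import warnings
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterator, Mapping

from scipy.stats import norm

__all__ = [
    "VALID_BASES",
    "GwasAssociation",
    "StudyTable",
    "ValidationWarning",
    "DEFAULT_DIALECT",
    "read_associations",
    "write_associations",
    "builtin_study_fixture",
]

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: Default header-name → field-name mapping (identity on canonical names).
DEFAULT_DIALECT: dict[str, str] = {
    "study_label": "study_label",
    "variant_id": "variant_id",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "p": "p",
    "n_cases": "n_cases",
    "n_controls": "n_controls",
}

_MANDATORY = ("study_label", "variant_id", "effect_allele", "other_allele", "beta", "se")
_OPTIONAL = ("eaf", "p", "n_cases", "n_controls")

#: Relative tolerance for the p-versus-z consistency check. Compared on the
#: z scale (|beta|/se against the quantile implied by p): summary tables
#: round beta and se to few decimals, which distorts p far more than z.
_P_CONSISTENCY_RTOL = 0.10


class ValidationWarning(UserWarning):
    """Non-fatal inconsistency detected while validating summary statistics."""


@dataclass(frozen=True)
class GwasAssociation:
    """One variant's summary statistics in one study.

    ``beta`` is on the log-odds scale for binary outcomes (per effect
    allele) and in trait units per allele otherwise. ``eaf`` is the effect
    allele frequency; optional fields are ``None`` when the source does not
    report them.
    """

    study_label: str
    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    p: float | None = None
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_BASES:
            raise ValueError(f"effect_allele must be one of A/C/G/T, got {self.effect_allele!r}")
        if self.other_allele not in VALID_BASES:
            raise ValueError(f"other_allele must be one of A/C/G/T, got {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect_allele and other_allele must differ")
        if not math.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValueError(f"se must be a positive real, got {self.se!r}")
        if self.eaf is not None and not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"eaf must lie in [0, 1], got {self.eaf!r}")
        if self.p is not None:
            if not 0.0 < self.p <= 1.0:
                raise ValueError(f"p must lie in (0, 1], got {self.p!r}")
            self._check_p_consistency()
        for name in ("n_cases", "n_controls"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be non-negative, got {value!r}")

    def _check_p_consistency(self) -> None:
        # Warn (never raise) when the reported p disagrees with |beta|/se
        # under a two-sided normal reference.
        z_obs = abs(self.beta) / self.se
        z_imp = float(norm.isf(self.p / 2.0))
        ref = max(z_obs, z_imp)
        if ref > 0 and abs(z_obs - z_imp) / ref > _P_CONSISTENCY_RTOL:
            warnings.warn(
                f"{self.study_label}: reported p={self.p:g} implies |z|={z_imp:.3f} "
                f"but |beta|/se={z_obs:.3f}; values disagree by more than "
                f"{_P_CONSISTENCY_RTOL:.0%} under a two-sided normal reference",
                ValidationWarning,
                stacklevel=4,
            )

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass(frozen=True)
class StudyTable:
    """Ordered collection of :class:`GwasAssociation` with unique study labels."""

    records: tuple[GwasAssociation, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        labels = [r.study_label for r in self.records]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate study labels: {dupes}")

    def __iter__(self) -> Iterator[GwasAssociation]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, label: str) -> GwasAssociation:
        for record in self.records:
            if record.study_label == label:
                return record
        raise KeyError(label)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.study_label for r in self.records)


def _invert_dialect(dialect: Mapping[str, str] | None) -> dict[str, str]:
    """Map canonical field name → file column name."""
    if dialect is None:
        return dict(DEFAULT_DIALECT)
    inverted = dict(DEFAULT_DIALECT)
    inverted.update({canonical: column for column, canonical in dialect.items()})
    return inverted


def _sniff_delimiter(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "," if ("," in header and "\t" not in header) else "\t"


def read_associations(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    *,
    or_column: str | None = None,
) -> StudyTable:
    """Read a :class:`StudyTable` from delimited text.

    Parameters
    ----------
    path
        TSV (or CSV) file with a header row.
    dialect
        Optional mapping of *file column name* → *canonical field name*
        for headers that deviate from the defaults
        (``variant_id, effect_allele, other_allele, eaf, beta, se, p,
        n_cases, n_controls, study_label``).
    or_column
        Name of a column carrying odds ratios instead of log-odds betas;
        values are log-transformed at load with a warning.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If a mandatory column is missing (configuration error) or a row
        fails validation; row errors carry the 1-based line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    field_to_column = _invert_dialect(dialect)
    delimiter = _sniff_delimiter(path)

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: file has no header row")
        header = set(reader.fieldnames)
        missing = [
            field_to_column[name]
            for name in _MANDATORY
            if field_to_column[name] not in header and (or_column is None or name != "beta")
        ]
        if missing:
            raise ValueError(f"{path}: missing mandatory column(s) {missing}; header is {sorted(header)}")

        records: list[GwasAssociation] = []
        errors: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_parse_row(row, field_to_column, or_column))
            except (ValueError, KeyError) as exc:
                errors.append(f"line {lineno}: {exc}")
        if errors:
            raise ValueError(f"{path}: {len(errors)} row(s) rejected:\n" + "\n".join(errors))

    if not records:
        warnings.warn(f"{path}: no data rows (header only)", ValidationWarning, stacklevel=2)
    table = StudyTable(records=tuple(records), provenance=str(path))
    logger.info("read %d association record(s) from %s", len(table), path)
    return table


def _parse_row(
    row: Mapping[str, str], field_to_column: Mapping[str, str], or_column: str | None
) -> GwasAssociation:
    def cell(name: str) -> str | None:
        value = row.get(field_to_column[name])
        return value.strip() if value is not None and value.strip() != "" else None

    kwargs: dict[str, object] = {}
    for name in _MANDATORY:
        if name == "beta" and or_column is not None:
            raw = row.get(or_column)
            if raw is None or raw.strip() == "":
                raise ValueError(f"odds-ratio column {or_column!r} is empty")
            odds_ratio = _parse_float("beta", raw)
            if odds_ratio <= 0:
                raise ValueError(f"odds ratio must be positive, got {odds_ratio!r}")
            warnings.warn(
                f"column {or_column!r} read as odds ratios and log-transformed",
                ValidationWarning,
                stacklevel=5,
            )
            kwargs["beta"] = math.log(odds_ratio)
            continue
        raw = cell(name)
        if raw is None:
            raise ValueError(f"mandatory field {name!r} is empty")
        if name in ("beta", "se"):
            kwargs[name] = _parse_float(name, raw)
        elif name in ("effect_allele", "other_allele"):
            kwargs[name] = raw.upper()
        else:
            kwargs[name] = raw
    for name in _OPTIONAL:
        raw = cell(name)
        if raw is None:
            kwargs[name] = None
        elif name in ("n_cases", "n_controls"):
            kwargs[name] = _parse_int(name, raw)
        else:
            kwargs[name] = _parse_float(name, raw)
    return GwasAssociation(**kwargs)  # type: ignore[arg-type]


def _parse_float(name: str, raw: str) -> float:
    try:
        # tolerate the Unicode minus that copy-pasted tables often carry
        return float(raw.replace("−", "-"))
    except ValueError:
        raise ValueError(f"field {name!r}: cannot parse {raw!r} as a number") from None


def _parse_int(name: str, raw: str) -> int:
    try:
        return int(raw.replace(",", ""))
    except ValueError:
        raise ValueError(f"field {name!r}: cannot parse {raw!r} as an integer") from None


def write_associations(table: StudyTable, path: str | Path, *, delimiter: str = "\t") -> None:
    """Write a :class:`StudyTable` as delimited text.

    Floats are serialised with ``repr`` so that ``read(write(x))`` is the
    identity at full precision; absent optional fields become empty cells.
    """
    path = Path(path)
    names = [f.name for f in fields(GwasAssociation)]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(names)
        for record in table:
            writer.writerow(
                "" if (value := getattr(record, name)) is None else repr(value) if isinstance(value, float) else value
                for name in names
            )
    logger.info("wrote %d association record(s) to %s", len(table), path)


# The packaged seven-study dataset: T-allele (vs C) log-odds associations of
# rs4988235 with multiple sclerosis, Alzheimer's disease, Parkinson's disease
# and amyotrophic lateral sclerosis, with the source studies' case/control
# counts. Effect-allele frequencies were not published and are stored absent.
_FIXTURE_ROWS: tuple[tuple[str, str, float, float, float, int, int], ...] = (
    ("MS GWAS", "Multiple sclerosis", -0.054, 0.025, 2.93e-2, 14802, 26703),
    ("MS Immunochip", "Multiple sclerosis", -0.063, 0.020, 1.97e-3, 14498, 24091),
    ("IGAP", "Alzheimer's disease", -0.028, 0.016, 7.88e-2, 21982, 41944),
    ("FinnGen", "Alzheimer's disease", -0.048, 0.029, 9.76e-2, 3060, 173839),
    ("PDWBS", "Parkinson's disease", 0.048, 0.021, 2.37e-2, 6476, 302042),
    ("PDGene", "Parkinson's disease", 0.117, 0.020, 7.41e-9, 13708, 95282),
    ("ALS GWAS", "Amyotrophic lateral sclerosis", -0.028, 0.019, 1.35e-1, 20806, 59804),
)

#: Disease → member study labels, as grouped in the packaged dataset.
FIXTURE_DISEASE_GROUPS: dict[str, tuple[str, ...]] = {
    "Multiple sclerosis": ("MS GWAS", "MS Immunochip"),
    "Alzheimer's disease": ("IGAP", "FinnGen"),
    "Parkinson's disease": ("PDWBS", "PDGene"),
    "Amyotrophic lateral sclerosis": ("ALS GWAS",),
}


def builtin_study_fixture() -> StudyTable:
    """Packaged rs4988235 neurodegenerative-disease summary statistics.

    Returns the seven-study table (log-odds per T allele, standard error,
    reported p, case/control counts) that the worked examples and the
    ``reproduce-paper`` command operate on. The table is constructed fresh
    on every call and is always identical.
    """
    records = tuple(
        GwasAssociation(
            study_label=label,
            variant_id="rs4988235",
            effect_allele="T",
            other_allele="C",
            beta=beta,
            se=se,
            p=p,
            n_cases=n_cases,
            n_controls=n_controls,
        )
        for label, _disease, beta, se, p, n_cases, n_controls in _FIXTURE_ROWS
    )
    return StudyTable(records=records, provenance="builtin rs4988235 neurodegenerative-disease table")


def fixture_disease_of(study_label: str) -> str:
    """Disease group of a packaged study label."""
    for label, disease, *_ in _FIXTURE_ROWS:
        if label == study_label:
            return disease
    raise KeyError(study_label)
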