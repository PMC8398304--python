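"""Align outcome summary statistics to the instrument's effect allele.

Before a Wald ratio can be formed, every outcome record must report its
beta for the same allele as the exposure instrument. Four reconciliations
are possible for a non-palindromic variant:

* **unchanged** — alleles already match;
* **sign flip** — effect/other alleles are swapped, so the beta is negated
  and the effect-allele frequency becomes ``1 - eaf``;
* **strand flip** — the record is on the opposite strand; base-complementing
  both alleles makes them match, beta untouched;
* **strand + sign flip** — both of the above.

Palindromic variants (A/T or C/G) are strand-ambiguous: complementing maps
the pair onto its own swap, so strand cannot be told from sign. They are
resolved by allele frequency when both sides report one and both are far
enough from 0.5, and dropped otherwise. Records whose alleles cannot be
reconciled at all are dropped with a note rather than raising, so batch
runs survive odd rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .summary_io import VALID_BASES, GwasAssociation, StudyTable

__all__ = ["COMPLEMENT", "HarmonizationReport", "harmonize_to_instrument", "is_palindromic"]

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default |eaf - 0.5| margin required to orient a palindromic variant.
DEFAULT_PALINDROMIC_EAF_THRESHOLD = 0.08


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True when the allele pair is its own reverse complement (A/T or C/G)."""
    return COMPLEMENT[effect_allele] == other_allele


@dataclass(frozen=True)
class HarmonizationReport:
    """Per-category record counts for one harmonization pass.

    The six counters partition the input: every record is either kept via
    exactly one of the four reconciliations or dropped for exactly one of
    the two reasons.
    """

    n_unchanged: int = 0
    n_sign_flipped: int = 0
    n_strand_flipped: int = 0
    n_strand_sign_flipped: int = 0
    n_dropped_palindromic: int = 0
    n_dropped_incompatible: int = 0
    notes: tuple[str, ...] = ()

    @property
    def n_total(self) -> int:
        return (
            self.n_unchanged
            + self.n_sign_flipped
            + self.n_strand_flipped
            + self.n_strand_sign_flipped
            + self.n_dropped_palindromic
            + self.n_dropped_incompatible
        )

    @property
    def n_kept(self) -> int:
        return self.n_unchanged + self.n_sign_flipped + self.n_strand_flipped + self.n_strand_sign_flipped

    def as_dict(self) -> dict[str, object]:
        return {
            "n_unchanged": self.n_unchanged,
            "n_sign_flipped": self.n_sign_flipped,
            "n_strand_flipped": self.n_strand_flipped,
            "n_strand_sign_flipped": self.n_strand_sign_flipped,
            "n_dropped_palindromic": self.n_dropped_palindromic,
            "n_dropped_incompatible": self.n_dropped_incompatible,
            "notes": list(self.notes),
        }


def _sign_flip(record: GwasAssociation) -> GwasAssociation:
    return replace(
        record,
        effect_allele=record.other_allele,
        other_allele=record.effect_allele,
        beta=-record.beta,
        eaf=None if record.eaf is None else 1.0 - record.eaf,
        p=record.p,
    )


def _strand_flip(record: GwasAssociation) -> GwasAssociation:
    return replace(
        record,
        effect_allele=COMPLEMENT[record.effect_allele],
        other_allele=COMPLEMENT[record.other_allele],
    )


def harmonize_to_instrument(
    table: StudyTable,
    instrument_effect_allele: str,
    instrument_other_allele: str,
    palindromic_eaf_threshold: float = DEFAULT_PALINDROMIC_EAF_THRESHOLD,
    *,
    instrument_eaf: float | None = None,
) -> tuple[StudyTable, HarmonizationReport]:
    """Reconcile every record's alleles with the instrument's.

    Parameters
    ----------
    table
        Outcome records to align.
    instrument_effect_allele, instrument_other_allele
        The exposure instrument's allele pair (e.g. T/C for rs4988235).
    palindromic_eaf_threshold
        Minimum ``|eaf - 0.5|`` required, on both the record and the
        instrument side, to orient a palindromic variant by frequency.
    instrument_eaf
        Instrument-side effect-allele frequency; without it palindromic
        records cannot be oriented and are dropped.

    Returns
    -------
    (StudyTable, HarmonizationReport)
        Surviving records, every one with ``effect_allele ==
        instrument_effect_allele``, plus the category counts.
    """
    if instrument_effect_allele not in VALID_BASES or instrument_other_allele not in VALID_BASES:
        raise ValueError("instrument alleles must be A/C/G/T")
    if instrument_effect_allele == instrument_other_allele:
        raise ValueError("instrument alleles must differ")

    target = (instrument_effect_allele, instrument_other_allele)
    target_palindromic = is_palindromic(*target)
    counts = dict.fromkeys(
        (
            "n_unchanged",
            "n_sign_flipped",
            "n_strand_flipped",
            "n_strand_sign_flipped",
            "n_dropped_palindromic",
            "n_dropped_incompatible",
        ),
        0,
    )
    notes: list[str] = []
    kept: list[GwasAssociation] = []

    for record in table:
        pair = (record.effect_allele, record.other_allele)
        if is_palindromic(*pair) or target_palindromic:
            resolved, category, note = _resolve_palindromic(
                record, target, instrument_eaf, palindromic_eaf_threshold
            )
        elif pair == target:
            resolved, category, note = record, "n_unchanged", None
        elif (pair[1], pair[0]) == target:
            resolved, category, note = _sign_flip(record), "n_sign_flipped", None
        elif (COMPLEMENT[pair[0]], COMPLEMENT[pair[1]]) == target:
            resolved, category, note = _strand_flip(record), "n_strand_flipped", None
        elif (COMPLEMENT[pair[1]], COMPLEMENT[pair[0]]) == target:
            resolved, category, note = _sign_flip(_strand_flip(record)), "n_strand_sign_flipped", None
        else:
            resolved, category = None, "n_dropped_incompatible"
            note = (
                f"{record.study_label}: allele pair {pair[0]}/{pair[1]} cannot be "
                f"reconciled with instrument {target[0]}/{target[1]}; record dropped"
            )
        counts[category] += 1
        if note is not None:
            notes.append(note)
        if resolved is not None:
            kept.append(resolved)

    report = HarmonizationReport(notes=tuple(notes), **counts)
    logger.info(
        "harmonized %d record(s): %d kept (%d unchanged, %d sign-flipped, %d strand-flipped, "
        "%d strand+sign), %d dropped",
        report.n_total,
        report.n_kept,
        report.n_unchanged,
        report.n_sign_flipped,
        report.n_strand_flipped,
        report.n_strand_sign_flipped,
        report.n_dropped_palindromic + report.n_dropped_incompatible,
    )
    return StudyTable(records=tuple(kept), provenance=table.provenance), report


def _resolve_palindromic(
    record: GwasAssociation,
    target: tuple[str, str],
    instrument_eaf: float | None,
    threshold: float,
) -> tuple[GwasAssociation | None, str, str | None]:
    pair = (record.effect_allele, record.other_allele)
    record_palindromic = is_palindromic(*pair)
    target_palindromic = is_palindromic(*target)
    if record_palindromic != target_palindromic:
        return (
            None,
            "n_dropped_incompatible",
            f"{record.study_label}: allele pair {pair[0]}/{pair[1]} cannot be reconciled "
            f"with instrument {target[0]}/{target[1]}; record dropped",
        )
    # Both sides palindromic: allele labels alone cannot distinguish a sign
    # flip from a strand flip, so orientation must come from frequency.
    if {pair[0], pair[1]} != {target[0], target[1]} and {
        COMPLEMENT[pair[0]],
        COMPLEMENT[pair[1]],
    } != {target[0], target[1]}:
        return (
            None,
            "n_dropped_incompatible",
            f"{record.study_label}: palindromic pair {pair[0]}/{pair[1]} does not match "
            f"instrument {target[0]}/{target[1]}; record dropped",
        )
    if record.eaf is None or instrument_eaf is None:
        return (
            None,
            "n_dropped_palindromic",
            f"{record.study_label}: palindromic variant without effect-allele frequency "
            "on both sides; orientation ambiguous, record dropped",
        )
    if abs(record.eaf - 0.5) <= threshold or abs(instrument_eaf - 0.5) <= threshold:
        return (
            None,
            "n_dropped_palindromic",
            f"{record.study_label}: palindromic variant with eaf too close to 0.5 "
            f"(record {record.eaf:.3f}, instrument {instrument_eaf:.3f}, "
            f"threshold {threshold}); record dropped",
        )
    # Orient by frequency: the record's effect allele is identified with the
    # instrument's effect allele iff both frequencies sit on the same side
    # of 0.5. Labels are then rewritten to the instrument pair, negating the
    # beta when the identification crosses the labels.
    same_side = (record.eaf > 0.5) == (instrument_eaf > 0.5)
    labels_match = pair == target
    if labels_match and same_side:
        return record, "n_unchanged", None
    if labels_match:  # frequency contradicts the label: other-strand record
        return _strand_flip(_sign_flip(record)), "n_strand_sign_flipped", None
    if same_side:  # swapped labels but agreeing frequency: pure strand flip
        return _strand_flip(record), "n_strand_flipped", None
    return _sign_flip(record), "n_sign_flipped", None
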