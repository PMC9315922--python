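"""Core record types shared across the pipeline.

A :class:`SequenceRecord` is one rearranged IGHV-IGHD-IGHJ nucleotide
sequence (or a germline reference).  Sequences may carry IMGT-style gap
characters (``.`` or ``-``); when a record originates from an AIRR
rearrangement row that provides both ``sequence_alignment`` and
``germline_alignment``, the germline alignment is kept on the record so the
alignment stage can be bypassed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

DNA_ALPHABET = set("ACGTN.-")
GAP_CHARS = set(".-")
BASES = "ACGT"

DAYS_PER_YEAR = 365.25


@dataclass
class SequenceRecord:
    """A single nucleotide sequence, optionally pre-aligned to its germline.

    Parameters
    ----------
    id:
        Unique sequence/patient identifier.
    nt_sequence:
        IUPAC DNA, may contain IMGT gap dots or dashes.  Stored uppercased.
    germline_call:
        Name of the germline V gene this rearrangement uses (e.g.
        ``IGHV1-69*01``), if known.
    reading_frame_offset:
        Offset (0-2) of the first complete codon in the *ungapped* sequence.
    germline_alignment:
        Gapped germline string of the same length as ``nt_sequence``; when
        present the pair is treated as pre-aligned.
    """

    id: str
    nt_sequence: str
    germline_call: str | None = None
    reading_frame_offset: int = 0
    germline_alignment: str | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        self.nt_sequence = self.nt_sequence.upper()
        bad = set(self.nt_sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: characters outside DNA alphabet: {sorted(bad)}"
            )
        if self.reading_frame_offset not in (0, 1, 2):
            raise ValueError(
                f"sequence {self.id!r}: reading_frame_offset must be 0, 1 or 2"
            )
        if self.germline_alignment is not None:
            self.germline_alignment = self.germline_alignment.upper()
            if len(self.germline_alignment) != len(self.nt_sequence):
                raise ValueError(
                    f"sequence {self.id!r}: pre-aligned germline length "
                    f"{len(self.germline_alignment)} != sequence length "
                    f"{len(self.nt_sequence)}"
                )

    @property
    def is_prealigned(self) -> bool:
        return self.germline_alignment is not None

    @property
    def ungapped(self) -> str:
        return "".join(c for c in self.nt_sequence if c not in GAP_CHARS)


@dataclass
class ClinicalRecord:
    """Time-to-first-treatment (TTFT) observation for one patient.

    ``event`` is True when the patient was treated (the TTFT event was
    observed); untreated patients are censored at last follow-up.  Times are
    in years; when constructed from dates the interval in days is divided by
    365.25.
    """

    patient_id: str
    ttft_years: float
    event: bool

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.ttft_years < 0:
            raise ValueError(
                f"patient {self.patient_id!r}: ttft_years must be non-negative"
            )

    @classmethod
    def from_dates(
        cls,
        patient_id: str,
        diagnosis_date: str | _dt.date,
        event: bool,
        first_treatment_date: str | _dt.date | None = None,
        last_followup_date: str | _dt.date | None = None,
    ) -> "ClinicalRecord":
        """Build a record from ISO dates.

        Treated patients measure diagnosis -> first treatment; untreated
        (censored) patients measure diagnosis -> last follow-up.
        """
        diag = _parse_date(patient_id, "diagnosis_date", diagnosis_date)
        if event:
            if first_treatment_date is None:
                raise ValueError(
                    f"patient {patient_id!r}: treated but first_treatment_date missing"
                )
            end = _parse_date(patient_id, "first_treatment_date", first_treatment_date)
            if end < diag:
                raise ValueError(
                    f"patient {patient_id!r}: first treatment precedes diagnosis"
                )
        else:
            if last_followup_date is None:
                raise ValueError(
                    f"patient {patient_id!r}: censored but last_followup_date missing"
                )
            end = _parse_date(patient_id, "last_followup_date", last_followup_date)
            if end < diag:
                raise ValueError(
                    f"patient {patient_id!r}: last follow-up precedes diagnosis"
                )
        years = (end - diag).days / DAYS_PER_YEAR
        return cls(patient_id=patient_id, ttft_years=years, event=event)


def _parse_date(patient_id: str, label: str, value: str | _dt.date) -> _dt.date:
    if isinstance(value, _dt.date):
        return value
    try:
        return _dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise ValueError(
            f"patient {patient_id!r}: unparseable {label} {value!r} (expect ISO 8601)"
        ) from exc
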