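"""Readers and writers for the pipeline's external formats.

Supported inputs: FASTA (germline references and patient rearrangements,
via Biopython), AIRR Rearrangement TSV (``sequence_id``/``sequence`` plus
the optional pre-aligned ``sequence_alignment``/``germline_alignment``
columns), and a clinical CSV that supplies TTFT either directly in years or
as ISO diagnosis/treatment/follow-up dates.  Output: the cohort CSV.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .records import ClinicalRecord, SequenceRecord

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n"}


def _parse_bool(value, context: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"{context}: cannot interpret {value!r} as a boolean event flag")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased and IMGT gap characters are preserved.
    Duplicate ids are rejected.
    """
    path = Path(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        first_bad = next(
            i + 1 for i, ln in enumerate(text.splitlines()) if ln.strip()
        )
        raise ValueError(f"{path}: not FASTA (line {first_bad} is not a header)")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seen:
                raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            records.append(SequenceRecord(id=rec.id, nt_sequence=str(rec.seq)))
    except ValueError as exc:
        if str(exc).startswith(str(path)):
            raise
        raise ValueError(f"{path}: malformed FASTA: {exc}") from exc
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.nt_sequence}\n")


AIRR_REQUIRED = ("sequence_id", "sequence")


def read_airr_rearrangements(path: str | Path) -> list[SequenceRecord]:
    """Read an AIRR Rearrangement TSV.

    Mandatory columns: ``sequence_id``, ``sequence``.  If both
    ``sequence_alignment`` and ``germline_alignment`` are present and
    non-empty for a row, the record is marked pre-aligned and the alignment
    stage is bypassed downstream.  ``v_call`` is preserved verbatim as the
    germline call.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in AIRR_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory AIRR columns: {missing}")
    has_aln = "sequence_alignment" in df.columns and "germline_alignment" in df.columns
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        row = row._asdict()
        sid = row["sequence_id"].strip()
        if not sid:
            raise ValueError(f"{path}: row {i}: empty sequence_id")
        if sid in seen:
            raise ValueError(f"{path}: row {i}: duplicate sequence_id {sid!r}")
        seen.add(sid)
        if not row["sequence"].strip():
            raise ValueError(f"{path}: row {i}: missing sequence")
        germ_aln = None
        seq = row["sequence"]
        if has_aln and row["sequence_alignment"].strip() and row["germline_alignment"].strip():
            seq = row["sequence_alignment"]
            germ_aln = row["germline_alignment"]
        frame = int(row.get("reading_frame_offset") or 0)
        records.append(
            SequenceRecord(
                id=sid,
                nt_sequence=seq,
                germline_call=(row.get("v_call") or None),
                reading_frame_offset=frame,
                germline_alignment=germ_aln,
            )
        )
    return records


def write_airr_rearrangements(records: list[SequenceRecord], path: str | Path) -> None:
    cols = [
        "sequence_id",
        "sequence",
        "sequence_alignment",
        "germline_alignment",
        "v_call",
        "reading_frame_offset",
    ]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for rec in records:
            ungapped = rec.ungapped
            w.writerow(
                [
                    rec.id,
                    ungapped,
                    rec.nt_sequence if rec.is_prealigned else "",
                    rec.germline_alignment or "",
                    rec.germline_call or "",
                    rec.reading_frame_offset,
                ]
            )


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read the clinical CSV.

    Two layouts are accepted: (``patient_id``, ``ttft_years``, ``event``) or
    (``patient_id``, ``diagnosis_date``, ``first_treatment_date``,
    ``last_followup_date``, ``event``) with ISO 8601 dates.  Treated
    patients (event true) measure diagnosis -> first treatment, censored
    patients diagnosis -> last follow-up; days are divided by 365.25.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "patient_id" not in df.columns or "event" not in df.columns:
        raise ValueError(f"{path}: clinical CSV needs patient_id and event columns")
    by_years = "ttft_years" in df.columns
    by_dates = "diagnosis_date" in df.columns
    if not by_years and not by_dates:
        raise ValueError(
            f"{path}: clinical CSV needs either ttft_years or diagnosis/treatment dates"
        )
    out: list[ClinicalRecord] = []
    seen: set[str] = set()
    for row in df.to_dict("records"):
        pid = row["patient_id"].strip()
        if pid in seen:
            raise ValueError(f"{path}: duplicate patient_id {pid!r}")
        seen.add(pid)
        event = _parse_bool(row["event"], f"patient {pid!r}")
        if by_years and row.get("ttft_years", "").strip():
            out.append(
                ClinicalRecord(
                    patient_id=pid, ttft_years=float(row["ttft_years"]), event=event
                )
            )
        else:
            out.append(
                ClinicalRecord.from_dates(
                    patient_id=pid,
                    diagnosis_date=row["diagnosis_date"],
                    event=event,
                    first_treatment_date=row.get("first_treatment_date") or None,
                    last_followup_date=row.get("last_followup_date") or None,
                )
            )
    return out


def write_clinical(records: list[ClinicalRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["patient_id", "ttft_years", "event"])
        for rec in records:
            w.writerow([rec.patient_id, repr(rec.ttft_years), int(rec.event)])


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write the annotated cohort table; round-trips exactly via read_cohort."""
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "event" in df.columns:
        df["event"] = df["event"].astype(bool)
    return df
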