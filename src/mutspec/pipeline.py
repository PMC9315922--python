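"""End-to-end orchestration: sequences + clinical table -> annotated cohort.

Stages: pair each rearrangement with its germline (pre-aligned pairs pass
through), call nucleotide mutations, type them S/Rc/Rnc, compute the
pseudocounted ratio and Low/High group, bin by mutation burden, join the
clinical table, and optionally write the cohort CSV, per-stratum survival
reports and a run log that records every parameter and the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as mio
from .calling import StatusParams, align_pair, call_mutations, mutation_status
from .classify import (
    CodonConvention,
    ConservativenessRule,
    MutationProfile,
    default_tables,
    profile_sequence,
)
from .ratio import RatioParams, assign_bin, assign_groups
from .records import ClinicalRecord, SequenceRecord
from .survival import format_p, report_table, ttft_report

logger = logging.getLogger(__name__)

COHORT_COLUMNS = [
    "patient_id",
    "germline_call",
    "n_S",
    "n_Rc",
    "n_Rnc",
    "n_total",
    "n_unclassifiable",
    "percent_diff",
    "status",
    "ratio",
    "log_ratio",
    "ratio_group",
    "mutation_bin",
    "ttft_years",
    "event",
]


@dataclass
class PipelineConfig:
    sequences: str | Path
    germline: str | Path
    clinical: str | Path
    sequence_format: str = "airr"  # "airr" | "fasta"
    status_params: StatusParams = field(default_factory=StatusParams)
    ratio_params: RatioParams = field(default_factory=RatioParams)
    rule: ConservativenessRule = field(default_factory=ConservativenessRule)
    convention: CodonConvention = CodonConvention.ISOLATED
    seed: int = 0
    out_dir: str | Path | None = None


def _germline_for(patient: SequenceRecord, germ_by_id: dict) -> SequenceRecord:
    if patient.is_prealigned:
        return patient  # germline travels with the record
    call = patient.germline_call
    if call is None or call not in germ_by_id:
        raise ValueError(
            f"{patient.id}: no germline call (or unknown gene {call!r}); "
            "provide v_call or pre-aligned pairs"
        )
    return germ_by_id[call]


def build_cohort(
    patient_records: list[SequenceRecord],
    germline_records: list[SequenceRecord],
    clinical_records: list[ClinicalRecord],
    status_params: StatusParams | None = None,
    ratio_params: RatioParams | None = None,
    rule: ConservativenessRule | None = None,
    convention: CodonConvention = CodonConvention.ISOLATED,
) -> pd.DataFrame:
    """Run every analysis stage in memory and return the cohort table.

    One row per patient with sequence *and* clinical data; every row lands
    in exactly one of {UNDEFINED (zero-mutation), LOW, HIGH}.
    """
    status_params = status_params or StatusParams()
    ratio_params = ratio_params or RatioParams()
    rule = rule or ConservativenessRule()
    tables = default_tables()
    germ_by_id = {g.id: g for g in germline_records}
    clin_by_id = {c.patient_id: c for c in clinical_records}

    profiles: list[MutationProfile] = []
    germline_calls: dict[str, str | None] = {}
    for patient in patient_records:
        if patient.id not in clin_by_id:
            logger.warning("%s: no clinical record; dropped", patient.id)
            continue
        germline = _germline_for(patient, germ_by_id)
        try:
            pair = align_pair(patient, germline)
        except ValueError as exc:
            raise ValueError(f"mutation_calling stage: {exc}") from exc
        sites = call_mutations(pair)
        pct = 100.0 * len(sites) / pair.compared_length
        status = mutation_status(pct, status_params)
        profiles.append(
            profile_sequence(
                patient.id, sites, pct, status, tables, rule, convention
            )
        )
        germline_calls[patient.id] = patient.germline_call

    if not profiles:
        raise ValueError("no analyzable sequences")
    ratios, threshold = assign_groups(profiles, ratio_params)

    rows = []
    for prof in profiles:
        rr = ratios[prof.patient_id]
        clin = clin_by_id[prof.patient_id]
        rows.append(
            {
                "patient_id": prof.patient_id,
                "germline_call": germline_calls[prof.patient_id],
                "n_S": prof.n_S,
                "n_Rc": prof.n_Rc,
                "n_Rnc": prof.n_Rnc,
                "n_total": prof.n_total,
                "n_unclassifiable": prof.n_unclassifiable,
                "percent_diff": prof.percent_diff,
                "status": prof.status.value,
                "ratio": rr.ratio,
                "log_ratio": rr.log_ratio,
                "ratio_group": rr.group.value,
                "mutation_bin": assign_bin(prof.n_total),
                "ttft_years": clin.ttft_years,
                "event": clin.event,
            }
        )
    cohort = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    cohort.attrs["ratio_threshold_used"] = threshold
    return cohort


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """File-based pipeline: read inputs, build the cohort, write reports.

    Deterministic given the config (the seed only matters for downstream
    matching); rerunning with the same config yields byte-identical output.
    """
    try:
        if config.sequence_format == "airr":
            patients = mio.read_airr_rearrangements(config.sequences)
        elif config.sequence_format == "fasta":
            patients = mio.read_fasta(config.sequences)
        else:
            raise ValueError(f"unknown sequence format {config.sequence_format!r}")
        germline = mio.read_fasta(config.germline)
    except ValueError as exc:
        raise ValueError(f"io stage: {exc}") from exc
    clinical = mio.read_clinical(config.clinical)

    cohort = build_cohort(
        patients,
        germline,
        clinical,
        status_params=config.status_params,
        ratio_params=config.ratio_params,
        rule=config.rule,
        convention=config.convention,
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mio.write_cohort(cohort, out / "cohort.csv")
        _write_survival_reports(cohort, out)
        log = {
            "sequences": str(config.sequences),
            "germline": str(config.germline),
            "clinical": str(config.clinical),
            "sequence_format": config.sequence_format,
            "percent_cutoff": config.status_params.percent_cutoff,
            "group_pseudocount": config.ratio_params.group_pseudocount,
            "cox_pseudocount": config.ratio_params.cox_pseudocount,
            "ratio_threshold": config.ratio_params.ratio_threshold,
            "ratio_threshold_used": cohort.attrs["ratio_threshold_used"],
            "threshold_mode": config.ratio_params.threshold_mode.value,
            "rule_mode": config.rule.mode.value,
            "codon_convention": config.convention.value,
            "seed": config.seed,
            "n_patients": int(len(cohort)),
            "n_zero_mutation": int((cohort["ratio_group"] == "UNDEFINED").sum()),
            "n_low": int((cohort["ratio_group"] == "LOW").sum()),
            "n_high": int((cohort["ratio_group"] == "HIGH").sum()),
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return cohort


def _write_survival_reports(cohort: pd.DataFrame, out: Path) -> None:
    """KM medians and pairwise log-rank p for the standard stratifications."""
    for by in ("status", "ratio_group", "mutation_bin"):
        try:
            rep = ttft_report(cohort, by)
        except ValueError:
            continue
        tab = report_table(rep)
        tab.to_csv(out / f"ttft_by_{by}.csv", index=False)
        if rep["pairwise_p"] is not None:
            rep["pairwise_p"].map(format_p).to_csv(
                out / f"logrank_by_{by}.csv"
            )
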