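"""Synthetic immunogenetic cohort generator.

Emits desk-scale cohorts with the statistical structure the analysis
assumes: ~35% of clones carry no somatic mutation, per-sequence mutation
counts span 1-36 with a burden distribution shaped like the published
mutation-number intervals, substitutions favour transitions 2:1, and
censored TTFT follows a Weibull proportional-hazards model whose hazard
decreases with mutation burden.  The S/Rc/Rnc composition of a simulated
sequence is *emergent* from random substitutions plus the classifier — it
is never imposed — so pipeline counts can be checked exactly against the
generator's truth table.

Everything is reproducible from a single seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .calling import NtMutationSite, StatusParams, mutation_status
from .classify import (
    ConservativenessRule,
    MutationProfile,
    SENSE_CODONS,
    classify_nt_mutation,
    default_tables,
)
from .ratio import RatioParams, compute_ratio
from .records import BASES, ClinicalRecord, SequenceRecord

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: published mutation-number interval sizes used as burden-distribution
#: weights: (lo, hi, n_patients) for 1-4, 5-6, ..., 19-21, >21 (capped 36)
BURDEN_BIN_WEIGHTS: list[tuple[int, int, int]] = [
    (1, 4, 389),
    (5, 6, 173),
    (7, 9, 232),
    (10, 12, 221),
    (13, 15, 257),
    (16, 18, 297),
    (19, 21, 240),
    (22, 36, 539),
]


def default_burden_pmf(max_mut: int = 36) -> np.ndarray:
    """Probability mass over 1..max_mut, uniform within each interval."""
    pmf = np.zeros(max_mut + 1)
    for lo, hi, n in BURDEN_BIN_WEIGHTS:
        hi = min(hi, max_mut)
        width = hi - lo + 1
        pmf[lo : hi + 1] += n / width
    pmf /= pmf.sum()
    return pmf


@dataclass
class SimConfig:
    """Stated world of the simulator (see docs/methods.md for rationale)."""

    n_patients: int
    seed: int
    p_zero_mut: float = 0.35
    burden_pmf: np.ndarray | None = None  # over counts 0..36; default Fig-6 shape
    transition_weight: float = 2.0  # transversions have weight 1
    hotspot_multiplier: float = 1.0  # >1 upweights WRC/GYW motif positions
    scr_weight: float = 1.0  # >1 favours S/Rc substitutions (raises E[(S+Rc)/Rnc])
    weibull_shape: float = 1.0  # k=1: exponential baseline
    weibull_scale: float = 3.2  # years; baseline median ~ 2.2 y
    beta_mut: float = -0.05  # log-hazard per mutation
    beta_group: float = 0.0  # log-hazard for High vs Low Ratio Group
    censor_rate: float = 0.12  # per-year rate of independent loss to follow-up
    admin_censor_years: float = 25.0
    n_germline_genes: int = 8
    germline_length: int = 300

    def __post_init__(self) -> None:
        if not 0 <= self.p_zero_mut <= 1:
            raise ValueError("probabilities must be in [0, 1]")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValueError("Weibull parameters must be positive")
        if self.germline_length % 3 != 0:
            raise ValueError("germline length must be divisible by 3")
        if self.hotspot_multiplier < 1:
            raise ValueError("hotspot_multiplier must be >= 1")
        if self.burden_pmf is not None:
            pmf = np.asarray(self.burden_pmf, dtype=float)
            if not math.isclose(pmf.sum(), 1.0, abs_tol=1e-9):
                raise ValueError("burden pmf must sum to 1")
            self.burden_pmf = pmf


@dataclass
class SimulatedCohort:
    germline_records: list[SequenceRecord]
    patient_records: list[SequenceRecord]  # pre-aligned to their germline
    clinical: list[ClinicalRecord]
    truth: pd.DataFrame
    config: SimConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "germline": out / "germline.fasta",
            "rearrangements": out / "rearrangements.tsv",
            "clinical": out / "clinical.csv",
            "truth": out / "truth.csv",
            "config": out / "sim_config.json",
        }
        mio.write_fasta(self.germline_records, paths["germline"])
        mio.write_airr_rearrangements(self.patient_records, paths["rearrangements"])
        mio.write_clinical(self.clinical, paths["clinical"])
        self.truth.to_csv(paths["truth"], index=False)
        cfg = asdict(self.config)
        if cfg["burden_pmf"] is not None:
            cfg["burden_pmf"] = list(map(float, cfg["burden_pmf"]))
        paths["config"].write_text(json.dumps(cfg, indent=2) + "\n")
        return paths


def make_germline(
    n_genes: int, length_nt: int = 300, seed: int = 0
) -> list[SequenceRecord]:
    """Random stop-free germline V references in reading frame 0."""
    if length_nt % 3 != 0:
        raise ValueError("germline length must be divisible by 3")
    rng = np.random.default_rng(seed)
    codons = np.array(SENSE_CODONS)
    records = []
    for i in range(n_genes):
        seq = "".join(rng.choice(codons, size=length_nt // 3))
        records.append(SequenceRecord(id=f"IGHV-SIM{i + 1}*01", nt_sequence=seq))
    return records


def _hotspot_weights(seq: str, multiplier: float) -> np.ndarray:
    """Per-position sampling weights; WRC/GYW hotspot bases get ``multiplier``.

    The hotspot base is the C of WRC and the G of GYW (W=A/T, R=A/G, Y=C/T).
    """
    w = np.ones(len(seq))
    if multiplier == 1.0:
        return w
    for i, b in enumerate(seq):
        if (
            b == "C"
            and i >= 2
            and seq[i - 1] in "AG"
            and seq[i - 2] in "AT"
        ) or (
            b == "G"
            and i + 2 < len(seq)
            and seq[i + 1] in "CT"
            and seq[i + 2] in "AT"
        ):
            w[i] = multiplier
    return w


def _is_scr(germline: str, pos: int, alt: str) -> bool:
    """Whether substituting ``alt`` at ``pos`` is silent or conservative
    (isolated effect on the germline codon, frame 0)."""
    ci = pos // 3
    codon = germline[3 * ci : 3 * ci + 3]
    site = NtMutationSite(
        alignment_pos=pos,
        germline_base=germline[pos],
        observed_base=alt,
        codon_index=ci,
        pos_in_codon=pos % 3,
        germline_codon=codon,
    )
    lab = classify_nt_mutation(site, default_tables())
    return lab is not None and lab.label in ("S", "Rc")


def mutate_sequence(
    germline: str,
    n_mut: int,
    rng: np.random.Generator,
    transition_weight: float = 2.0,
    hotspot_multiplier: float = 1.0,
    scr_weight: float = 1.0,
) -> tuple[str, list[tuple[int, str, str]]]:
    """Introduce ``n_mut`` substitutions at distinct positions (no indels).

    Returns the mutated sequence and the true site list
    [(position, from_base, to_base), ...] sorted by position.
    ``scr_weight`` > 1 upweights alternative bases whose isolated effect is
    silent or conservative, shifting the expected (S+Rc)/Rnc upward when a
    study needs the High Ratio group well populated.
    """
    if n_mut > len(germline):
        raise ValueError("cannot place more mutations than sequence positions")
    sites: list[tuple[int, str, str]] = []
    if n_mut == 0:
        return germline, sites
    weights = _hotspot_weights(germline, hotspot_multiplier)
    positions = rng.choice(
        len(germline), size=n_mut, replace=False, p=weights / weights.sum()
    )
    seq = list(germline)
    for pos in sorted(int(p) for p in positions):
        ref = germline[pos]
        alts = [b for b in BASES if b != ref]
        w = np.array(
            [transition_weight if b == TRANSITION[ref] else 1.0 for b in alts]
        )
        if scr_weight != 1.0:
            w *= np.array(
                [scr_weight if _is_scr(germline, pos, b) else 1.0 for b in alts]
            )
        alt = alts[int(rng.choice(3, p=w / w.sum()))]
        seq[pos] = alt
        sites.append((pos, ref, alt))
    return "".join(seq), sites


def true_profile(
    patient_id: str,
    germline: str,
    sites: list[tuple[int, str, str]],
    rule: ConservativenessRule | None = None,
) -> MutationProfile:
    """S/Rc/Rnc truth for engineered sites, via the same classifier and
    class tables the pipeline uses (frame offset 0)."""
    tables = default_tables()
    nt_sites = [
        NtMutationSite(
            alignment_pos=pos,
            germline_base=ref,
            observed_base=alt,
            codon_index=pos // 3,
            pos_in_codon=pos % 3,
            germline_codon=germline[3 * (pos // 3) : 3 * (pos // 3) + 3],
        )
        for pos, ref, alt in sites
    ]
    counts = {"S": 0, "Rc": 0, "Rnc": 0}
    for s in nt_sites:
        lab = classify_nt_mutation(s, tables, rule)
        counts[lab.label] += 1
    pct = 100.0 * len(sites) / len(germline)
    return MutationProfile(
        patient_id=patient_id,
        n_S=counts["S"],
        n_Rc=counts["Rc"],
        n_Rnc=counts["Rnc"],
        percent_diff=pct,
        status=mutation_status(pct, StatusParams()),
    )


def draw_survival(
    rng: np.random.Generator,
    linear_predictor: np.ndarray,
    shape: float,
    scale: float,
    censor_rate: float,
    admin_censor_years: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Censored Weibull proportional-hazards draws.

    S(t|x) = exp(-(t/scale)^shape * exp(lp)).  Censoring is independent of
    the event process: an exponential loss-to-follow-up time with rate
    ``censor_rate`` per year, truncated by administrative follow-up at
    ``admin_censor_years`` (the default rate yields roughly the untreated
    fraction seen in real TTFT cohorts, ~35-40%).
    """
    lp = np.asarray(linear_predictor, dtype=float)
    n = lp.size
    u = rng.uniform(size=n)
    t_event = scale * (-np.log(u) * np.exp(-lp)) ** (1.0 / shape)
    if censor_rate > 0:
        censor = np.minimum(
            rng.exponential(1.0 / censor_rate, size=n), admin_censor_years
        )
    else:
        censor = np.full(n, admin_censor_years)
    time = np.minimum(t_event, censor)
    event = t_event <= censor
    # guard against a zero observation time (probability ~0 but fatal)
    time = np.maximum(time, 1e-9)
    return time, event


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort (sequences, clinical table, truth)."""
    rng = np.random.default_rng(config.seed)
    germ = make_germline(
        config.n_germline_genes,
        config.germline_length,
        seed=int(rng.integers(2**31)),
    )
    pmf = (
        np.asarray(config.burden_pmf)
        if config.burden_pmf is not None
        else default_burden_pmf()
    )
    counts_support = np.arange(len(pmf))

    patients: list[SequenceRecord] = []
    rows = []
    params = RatioParams()
    n_digits = len(str(config.n_patients))
    for i in range(config.n_patients):
        pid = f"SIM{i + 1:0{n_digits}d}"
        g = germ[int(rng.integers(len(germ)))]
        if rng.uniform() < config.p_zero_mut:
            n_mut = 0
        else:
            n_mut = int(rng.choice(counts_support, p=pmf))
        seq, sites = mutate_sequence(
            g.nt_sequence,
            n_mut,
            rng,
            transition_weight=config.transition_weight,
            hotspot_multiplier=config.hotspot_multiplier,
            scr_weight=config.scr_weight,
        )
        patients.append(
            SequenceRecord(
                id=pid,
                nt_sequence=seq,
                germline_call=g.id,
                germline_alignment=g.nt_sequence,
            )
        )
        prof = true_profile(pid, g.nt_sequence, sites)
        rr = compute_ratio(prof, params)
        rows.append(
            {
                "patient_id": pid,
                "germline_call": g.id,
                "n_mut": n_mut,
                "n_S": prof.n_S,
                "n_Rc": prof.n_Rc,
                "n_Rnc": prof.n_Rnc,
                "ratio": rr.ratio,
                "log_ratio": rr.log_ratio,
                "group": rr.group.value,
            }
        )
    truth = pd.DataFrame(rows)

    lp = config.beta_mut * truth["n_mut"].to_numpy() + config.beta_group * (
        truth["group"] == "HIGH"
    ).to_numpy().astype(float)
    time, event = draw_survival(
        rng,
        lp,
        config.weibull_shape,
        config.weibull_scale,
        config.censor_rate,
        config.admin_censor_years,
    )
    truth["ttft_years"] = time
    truth["event"] = event
    clinical = [
        ClinicalRecord(patient_id=pid, ttft_years=float(t), event=bool(e))
        for pid, t, e in zip(truth["patient_id"], time, event)
    ]
    return SimulatedCohort(
        germline_records=germ,
        patient_records=patients,
        clinical=clinical,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# Deterministic hand-checkable fixture


def _engineer_sites(
    germline: str, wanted: list[str]
) -> list[tuple[int, str, str]]:
    """Find substitutions with the requested labels, one codon each.

    ``wanted`` entries are "S", "Rc", "Rnc" or "Rnc_stop"; codons are
    scanned left to right, deterministic.
    """
    tables = default_tables()
    remaining = list(wanted)
    out: list[tuple[int, str, str]] = []
    for ci in range(len(germline) // 3):
        if not remaining:
            break
        codon = germline[3 * ci : 3 * ci + 3]
        found = None
        for pc in range(3):
            for alt in BASES:
                if alt == codon[pc]:
                    continue
                site = NtMutationSite(
                    alignment_pos=3 * ci + pc,
                    germline_base=codon[pc],
                    observed_base=alt,
                    codon_index=ci,
                    pos_in_codon=pc,
                    germline_codon=codon,
                )
                lab = classify_nt_mutation(site, tables)
                key = "Rnc_stop" if lab.to_stop else lab.label
                if key == remaining[0]:
                    found = (3 * ci + pc, codon[pc], alt)
                    break
            if found:
                break
        if found:
            out.append(found)
            remaining.pop(0)
    if remaining:
        raise RuntimeError(f"could not engineer sites for labels: {remaining}")
    return sorted(out)


#: fixture compositions: patient -> list of requested site labels
_FIXTURE_PLAN: dict[str, list[str]] = {
    "P01": [],  # 0 Mut
    "P02": ["S", "S"],  # S only, n=2, HIGH
    "P03": ["Rc", "Rnc"],  # R only, n=2, ratio exactly 1.0 -> LOW
    "P04": ["S"] * 3 + ["Rc"] * 2 + ["Rnc"] * 5,  # S+R, n=10, ratio 1.0 LOW
    "P05": ["S", "Rnc_stop", "Rnc"],  # includes a nonsense mutation, n=3 LOW
    "P06": ["S"] * 6 + ["Rc"] * 2 + ["Rnc"] * 2,  # n=10 HIGH (matches P04)
    "P07": ["S", "S", "Rc"],  # n=3 HIGH (matches P05)
    "P08": ["S", "Rc"] + ["Rnc"] * 5,  # n=7 LOW, no High partner -> unmatched
    "P09": ["S"] * 10 + ["Rc"] * 5 + ["Rnc"] * 5,  # n=20 HIGH
    "P10": ["S", "S"] + ["Rc"] * 3 + ["Rnc"] * 15,  # n=20 LOW (matches P09)
    "P11": ["S"],  # n=1 HIGH, S only
    "P12": ["Rnc"],  # n=1 LOW, R only (matches P11)
}

_FIXTURE_CLINICAL: dict[str, tuple[float, bool]] = {
    "P01": (1.5, True),
    "P02": (2.0, True),
    "P03": (2.5, True),
    "P04": (6.0, False),
    "P05": (3.0, True),
    "P06": (7.5, False),
    "P07": (4.0, True),
    "P08": (5.0, True),
    "P09": (12.0, False),
    "P10": (9.0, True),
    "P11": (1.0, True),
    "P12": (2.2, True),
}

FIXTURE_SEED = 20220712


def fixture_small() -> SimulatedCohort:
    """Deterministic 12-patient cohort with hand-checkable composition.

    Covers every accounting category (0 Mut, S only, R only, S+R), two
    sequences whose pseudocounted ratio is exactly 1.0 (boundary -> LOW), a
    mutation to a stop codon, and one Low patient with no same-burden High
    partner (exercises the unmatched path).  Byte-identical across runs.
    """
    germ = make_germline(1, 300, seed=FIXTURE_SEED)[0]
    patients: list[SequenceRecord] = []
    rows = []
    params = RatioParams()
    for pid, wanted in _FIXTURE_PLAN.items():
        sites = _engineer_sites(germ.nt_sequence, wanted)
        seq = list(germ.nt_sequence)
        for pos, _ref, alt in sites:
            seq[pos] = alt
        patients.append(
            SequenceRecord(
                id=pid,
                nt_sequence="".join(seq),
                germline_call=germ.id,
                germline_alignment=germ.nt_sequence,
            )
        )
        prof = true_profile(pid, germ.nt_sequence, sites)
        rr = compute_ratio(prof, params)
        t, e = _FIXTURE_CLINICAL[pid]
        rows.append(
            {
                "patient_id": pid,
                "germline_call": germ.id,
                "n_mut": len(sites),
                "n_S": prof.n_S,
                "n_Rc": prof.n_Rc,
                "n_Rnc": prof.n_Rnc,
                "ratio": rr.ratio,
                "log_ratio": rr.log_ratio,
                "group": rr.group.value,
                "ttft_years": t,
                "event": e,
            }
        )
    truth = pd.DataFrame(rows)
    clinical = [
        ClinicalRecord(patient_id=pid, ttft_years=t, event=e)
        for pid, (t, e) in _FIXTURE_CLINICAL.items()
    ]
    config = SimConfig(n_patients=len(patients), seed=FIXTURE_SEED)
    return SimulatedCohort(
        germline_records=[germ],
        patient_records=patients,
        clinical=clinical,
        truth=truth,
        config=config,
    )
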