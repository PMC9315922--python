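"""Silent / conservative / non-conservative mutation typing.

Every nucleotide substitution is translated in its germline codon context
and labelled S (synonymous), Rc (replacement conserving physicochemical
class) or Rnc (non-conservative replacement).  Conservation is judged on
the three IMGT axes — hydropathy, volume and chemical characteristics —
loaded from a versioned data table.  Under the default ``strict`` rule a
replacement is conservative only when all three axes are conserved;
``majority`` (>= 2 of 3) is available as a sensitivity switch.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple

from Bio.Data.CodonTable import standard_dna_table

from .calling import MutationStatus, NtMutationSite
from .records import BASES

STOP = "*"

#: codon -> amino acid (one-letter) for all 61 sense codons; stops -> "*"
GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
GENETIC_CODE.update({c: STOP for c in standard_dna_table.stop_codons})

SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != STOP)


def translate_codon(codon: str) -> str:
    """Standard genetic code; returns a one-letter amino acid or ``"*"``."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"codon must be an unambiguous DNA 3-mer, got {codon!r}")
    return GENETIC_CODE[codon]


@dataclass(frozen=True)
class AminoAcidClassTables:
    hydropathy: dict[str, str]
    volume: dict[str, str]
    chemistry: dict[str, str]


def load_aa_class_tables() -> AminoAcidClassTables:
    """Load the packaged IMGT physicochemical class table."""
    text = resources.files("mutspec.data").joinpath("aa_classes.tsv").read_text()
    hyd: dict[str, str] = {}
    vol: dict[str, str] = {}
    chem: dict[str, str] = {}
    header_seen = False
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True  # column header row
            continue
        aa, h, v, c = line.split("\t")
        hyd[aa], vol[aa], chem[aa] = h, v, c
    for table in (hyd, vol, chem):
        if len(table) != 20:
            raise ValueError("class table must cover the 20 standard amino acids")
    return AminoAcidClassTables(hydropathy=hyd, volume=vol, chemistry=chem)


_DEFAULT_TABLES: AminoAcidClassTables | None = None


def default_tables() -> AminoAcidClassTables:
    global _DEFAULT_TABLES
    if _DEFAULT_TABLES is None:
        _DEFAULT_TABLES = load_aa_class_tables()
    return _DEFAULT_TABLES


class AxisAgreement(NamedTuple):
    hydropathy: bool
    volume: bool
    chemistry: bool


class RuleMode(str, enum.Enum):
    STRICT = "strict"  # conservative iff all three axes conserved
    MAJORITY = "majority"  # conservative iff >= 2 axes conserved


@dataclass(frozen=True)
class ConservativenessRule:
    mode: RuleMode = RuleMode.STRICT

    def is_conservative(self, agreement: AxisAgreement) -> bool:
        n = sum(agreement)
        return n == 3 if self.mode == RuleMode.STRICT else n >= 2


class CodonConvention(str, enum.Enum):
    """How to translate a substitution when several share a codon.

    ``isolated`` applies the single base change to the germline codon (the
    default; keeps per-nucleotide counts additive).  ``joint`` compares the
    fully observed codon against germline.
    """

    ISOLATED = "isolated"
    JOINT = "joint"


@dataclass
class MutationTypeLabel:
    label: str  # "S" | "Rc" | "Rnc"
    axis_agreement: AxisAgreement | None = None
    to_stop: bool = False


def classify_aa_change(
    aa_from: str,
    aa_to: str,
    tables: AminoAcidClassTables | None = None,
    rule: ConservativenessRule | None = None,
) -> tuple[bool, AxisAgreement]:
    """Judge whether an amino-acid replacement is conservative."""
    if aa_from == aa_to:
        raise ValueError(f"{aa_from}->{aa_to}: not a replacement")
    tables = tables or default_tables()
    rule = rule or ConservativenessRule()
    for aa in (aa_from, aa_to):
        if aa not in tables.hydropathy:
            raise ValueError(f"{aa!r} is not a standard amino acid")
    agreement = AxisAgreement(
        hydropathy=tables.hydropathy[aa_from] == tables.hydropathy[aa_to],
        volume=tables.volume[aa_from] == tables.volume[aa_to],
        chemistry=tables.chemistry[aa_from] == tables.chemistry[aa_to],
    )
    return rule.is_conservative(agreement), agreement


def classify_nt_mutation(
    site: NtMutationSite,
    tables: AminoAcidClassTables | None = None,
    rule: ConservativenessRule | None = None,
    convention: CodonConvention = CodonConvention.ISOLATED,
) -> MutationTypeLabel | None:
    """Label one substitution S / Rc / Rnc, or ``None`` if unclassifiable.

    Unclassifiable sites (germline codon unavailable, contains N/gap, or is
    itself a stop) are excluded from type counts but still contribute to
    percent difference; callers count them separately.
    """
    codon = site.germline_codon
    if codon is None or any(b not in BASES for b in codon):
        return None
    aa_from = translate_codon(codon)
    if aa_from == STOP:
        return None
    if convention == CodonConvention.ISOLATED:
        mutated = (
            codon[: site.pos_in_codon]
            + site.observed_base
            + codon[site.pos_in_codon + 1 :]
        )
    else:
        if site.observed_codon is None:
            return None
        mutated = site.observed_codon
    aa_to = translate_codon(mutated)
    if aa_to == aa_from:
        return MutationTypeLabel(label="S")
    if aa_to == STOP:
        # a nonsense change maximally disrupts the receptor: non-conservative
        return MutationTypeLabel(label="Rnc", to_stop=True)
    conservative, agreement = classify_aa_change(aa_from, aa_to, tables, rule)
    return MutationTypeLabel(
        label="Rc" if conservative else "Rnc", axis_agreement=agreement
    )


@dataclass
class MutationProfile:
    """Per-sequence S/Rc/Rnc composition.

    ``n_total`` counts classified substitutions (= n_S + n_Rc + n_Rnc);
    ``n_unclassifiable`` is reported alongside so any discrepancy with the
    raw substitution count behind ``percent_diff`` stays visible.
    """

    patient_id: str
    n_S: int
    n_Rc: int
    n_Rnc: int
    percent_diff: float
    status: MutationStatus
    n_unclassifiable: int = 0
    n_total: int = field(init=False)

    def __post_init__(self) -> None:
        if min(self.n_S, self.n_Rc, self.n_Rnc, self.n_unclassifiable) < 0:
            raise ValueError("mutation counts must be non-negative")
        self.n_total = self.n_S + self.n_Rc + self.n_Rnc

    @property
    def category(self) -> str:
        """Cohort accounting category: 0 Mut / S only / R only / S+R."""
        if self.n_total == 0:
            return "0 Mut"
        if self.n_Rc + self.n_Rnc == 0:
            return "S only"
        if self.n_S == 0:
            return "R only"
        return "S+R"


def profile_sequence(
    patient_id: str,
    sites: list[NtMutationSite],
    pct: float,
    status: MutationStatus,
    tables: AminoAcidClassTables | None = None,
    rule: ConservativenessRule | None = None,
    convention: CodonConvention = CodonConvention.ISOLATED,
) -> MutationProfile:
    """Classify every called site and tally the S/Rc/Rnc composition."""
    counts = {"S": 0, "Rc": 0, "Rnc": 0}
    n_bad = 0
    for site in sites:
        lab = classify_nt_mutation(site, tables, rule, convention)
        if lab is None:
            n_bad += 1
        else:
            counts[lab.label] += 1
    return MutationProfile(
        patient_id=patient_id,
        n_S=counts["S"],
        n_Rc=counts["Rc"],
        n_Rnc=counts["Rnc"],
        percent_diff=pct,
        status=status,
        n_unclassifiable=n_bad,
    )
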