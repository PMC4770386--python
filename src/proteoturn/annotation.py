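"""Classification of protein N-termini into proteoform categories.

N-terminal peptides report where translation (or processing) produced a
protein start.  Peptides beginning at database position 1 or 2 point to the
annotated translation-initiation site (dbTIS); peptides starting beyond
position 2 that obey the co-translational rules — either retaining an
initiator Met, or immediately following a Met with a small-gyration-radius
residue exposed (initiator-Met excision) — point to alternative initiation
sites (aTIS).  Everything else is a candidate proteolytic product and is
excluded from turnover analyses.

The ruleset for initiator-Met excision: methionine aminopeptidases remove
the iMet when the second residue is one of A, V, S, T, C, G or P.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: residues with a small gyration radius: iMet excision expected
CLEAVABLE_RESIDUES = frozenset("AVSTCGP")
#: narrower alternative set (without Ser) offered for rule-sensitivity checks
CLEAVABLE_RESIDUES_NO_SER = frozenset("AVTCGP")

_CATEGORIES = ("dbTIS", "aTIS", "non-compliant")
_IMET = ("retained", "processed", "not-applicable")


@dataclass(frozen=True)
class ImetConfig:
    """Which second residues license initiator-Met excision."""

    cleavable_residues: frozenset[str] = CLEAVABLE_RESIDUES

    def __post_init__(self) -> None:
        bad = set(self.cleavable_residues) - AMINO_ACIDS
        if bad or not self.cleavable_residues:
            raise ValidationError(
                f"cleavable residue set invalid: {sorted(bad) or 'empty'}"
            )


@dataclass
class ProteoformRecord:
    """An N-terminal peptide with its proteoform-level classification."""

    peptide: str
    accession: str
    gene: str
    start: int  # 1-based position in the database sequence
    category: str = "non-compliant"
    imet_status: str = "not-applicable"
    acetylated: bool = False
    length: int = 0  # mature proteoform length (db length - start + 1)

    def __post_init__(self) -> None:
        if self.category not in _CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if self.imet_status not in _IMET:
            raise ValidationError(f"unknown iMet status {self.imet_status!r}")


@dataclass
class OriginEvidence:
    """Metadata flags used to assign the most likely origin of an aTIS."""

    riboseq_tis: bool = False
    swissprot_isoform: bool = False
    trembl: bool = False
    ensembl: bool = False
    transcript_support_level: int | None = None
    topfind_protease: bool = False
    acetylated: bool = False

    def __post_init__(self) -> None:
        tsl = self.transcript_support_level
        if tsl is not None and tsl < 1:
            raise ValidationError("transcript support level must be >= 1")

    @property
    def translation_support(self) -> bool:
        """Any metadata source pointing to translation (not proteolysis)."""
        return (
            self.acetylated
            or self.riboseq_tis
            or self.swissprot_isoform
            or self.trembl
            or self.ensembl
        )


def _check_residue(res: str) -> str:
    if len(res) != 1 or res.upper() not in AMINO_ACIDS:
        raise ValidationError(
            f"invalid amino-acid code {res!r}: expected one of the 20 "
            "standard one-letter codes"
        )
    return res.upper()


def imet_processing_expected(
    second_residue: str, config: ImetConfig | None = None
) -> bool:
    """True if the initiator Met is expected to be excised.

    Excision occurs when the second residue has a small gyration radius
    (A, V, S, T, C, G, P by default).
    """
    config = config or ImetConfig()
    return _check_residue(second_residue) in config.cleavable_residues


def classify_peptide_start(
    peptide: str,
    start: int,
    protein_seq: str,
    *,
    gene: str = "",
    accession: str = "",
    acetylated: bool = False,
    config: ImetConfig | None = None,
) -> ProteoformRecord:
    """Classify one N-terminal peptide against its database sequence.

    Rules (1-based ``start``):

    * start 1                          -> dbTIS, iMet retained
    * start 2, residue 2 cleavable     -> dbTIS, iMet processed
    * start 2, residue 2 not cleavable -> non-compliant
    * start > 2, peptide begins Met    -> aTIS, iMet retained
    * start > 2, preceding residue Met
      and first residue cleavable      -> aTIS, iMet processed
    * anything else                    -> non-compliant (likely proteolysis)
    """
    config = config or ImetConfig()
    peptide = peptide.upper()
    protein_seq = protein_seq.upper()
    for res in peptide:
        _check_residue(res)
    if start < 1 or start > len(protein_seq):
        raise ValidationError(
            f"start {start} outside sequence of length {len(protein_seq)}"
        )
    if not protein_seq[start - 1 :].startswith(peptide):
        raise ValidationError(
            f"peptide {peptide[:12]!r}... does not match {accession or 'sequence'}"
            f" at position {start}"
        )

    first = peptide[0]
    category, imet = "non-compliant", "not-applicable"
    if start == 1:
        category, imet = "dbTIS", "retained"
    elif start == 2:
        if first in config.cleavable_residues:
            category, imet = "dbTIS", "processed"
    else:
        if first == "M":
            category, imet = "aTIS", "retained"
        elif (
            protein_seq[start - 2] == "M"
            and first in config.cleavable_residues
        ):
            category, imet = "aTIS", "processed"

    return ProteoformRecord(
        peptide=peptide,
        accession=accession,
        gene=gene,
        start=start,
        category=category,
        imet_status=imet,
        acetylated=acetylated,
        length=len(protein_seq) - start + 1,
    )


@dataclass
class ProteoformPairs:
    """dbTIS/aTIS pairs and iMet-retained/processed pairs per gene."""

    tis_pairs: list[tuple[ProteoformRecord, ProteoformRecord]] = field(
        default_factory=list
    )
    multi_atis_flags: list[bool] = field(default_factory=list)
    imet_pairs: list[tuple[ProteoformRecord, ProteoformRecord]] = field(
        default_factory=list
    )


def _start_codon_position(rec: ProteoformRecord) -> int:
    """1-based position of the initiating Met codon this N-terminus uses."""
    if rec.imet_status == "processed":
        return rec.start - 1
    return rec.start


def pair_proteoforms(records: Iterable[ProteoformRecord]) -> ProteoformPairs:
    """Pair proteoforms of the same gene.

    Emits (i) every dbTIS x aTIS combination per gene, flagged when the
    gene carries more than one aTIS, and (ii) retained/processed pairs
    sharing an initiating Met codon (partial iMet processing).
    """
    by_gene: dict[str, list[ProteoformRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene, []).append(rec)

    pairs = ProteoformPairs()
    for gene in sorted(by_gene):
        recs = by_gene[gene]
        dbs = [r for r in recs if r.category == "dbTIS"]
        ats = [r for r in recs if r.category == "aTIS"]
        multi = len(ats) > 1
        for db, at in product(dbs, ats):
            pairs.tis_pairs.append((db, at))
            pairs.multi_atis_flags.append(multi)
        by_codon: dict[int, dict[str, ProteoformRecord]] = {}
        for r in recs:
            if r.imet_status in ("retained", "processed"):
                by_codon.setdefault(_start_codon_position(r), {})[
                    r.imet_status
                ] = r
        for codon in sorted(by_codon):
            forms = by_codon[codon]
            if "retained" in forms and "processed" in forms:
                pairs.imet_pairs.append(
                    (forms["retained"], forms["processed"])
                )
    return pairs


def select_mature_nterminus(
    pair: Sequence[ProteoformRecord], config: ImetConfig | None = None
) -> ProteoformRecord:
    """Pick the expected mature N-terminus from an iMet pair.

    Given a retained/processed pair sharing a start codon, returns the
    processed form when the post-Met residue is cleavable, the retained
    form otherwise.  A single record passes through unchanged.
    """
    config = config or ImetConfig()
    if len(pair) == 1:
        return pair[0]
    if len(pair) != 2:
        raise ValidationError("iMet pair must have one or two records")
    statuses = {r.imet_status for r in pair}
    if statuses != {"retained", "processed"}:
        raise ValidationError(
            f"malformed iMet pair: statuses {sorted(statuses)}"
        )
    codons = {_start_codon_position(r) for r in pair}
    if len(codons) != 1:
        raise ValidationError("iMet pair does not share a start codon")
    retained = next(r for r in pair if r.imet_status == "retained")
    processed = next(r for r in pair if r.imet_status == "processed")
    post_met = processed.peptide[0]
    if post_met in config.cleavable_residues:
        return processed
    return retained


def assign_origin(
    record: ProteoformRecord, evidence: OriginEvidence
) -> tuple[str, bool]:
    """Assign the most likely origin of an aTIS N-terminus.

    Returns ``(origin, highly_confident)``.  dbTIS records pass through
    as ``("annotated", True)``.  For aTIS records, a database match at an
    isoform position 1/2 with transcript support level <= 3 indicates a
    likely splice variant; the same match without that support is a poorly
    supported splicing event; a protease-product database match without
    any translation evidence marks a proteolysis candidate; otherwise the
    N-terminus is attributed to alternative translation initiation.
    Precedence when several rules fire: splicing-likely >
    alternative-initiation > splicing-poor > proteolysis-candidate.
    """
    if record.category == "dbTIS":
        return "annotated", True
    confident = evidence.translation_support

    db_match = evidence.swissprot_isoform or evidence.ensembl
    tsl = evidence.transcript_support_level
    splicing_likely = db_match and tsl is not None and tsl <= 3
    splicing_poor = db_match and not splicing_likely
    proteolysis = (
        evidence.topfind_protease
        and not evidence.acetylated
        and not evidence.riboseq_tis
    )

    if splicing_likely:
        return "splicing-likely", confident
    if evidence.riboseq_tis or evidence.acetylated or evidence.trembl:
        return "alternative-initiation", confident
    if splicing_poor:
        return "splicing-poor", confident
    if proteolysis:
        return "proteolysis-candidate", confident
    return "alternative-initiation", confident


def classify_table(
    peptides: "Mapping | Iterable",
    sequences: Mapping[str, str],
    config: ImetConfig | None = None,
) -> list[ProteoformRecord]:
    """Classify every row of a peptide table against a sequence map.

    ``peptides`` is an iterable of mappings with keys peptide, accession,
    gene, start and (optionally) acetylation_evidence.
    """
    import pandas as pd

    if isinstance(peptides, pd.DataFrame):
        rows = peptides.to_dict("records")
    else:
        rows = list(peptides)
    out = []
    for row in rows:
        acc = str(row["accession"])
        if acc not in sequences:
            raise ValidationError(f"accession {acc!r} not in FASTA")
        out.append(
            classify_peptide_start(
                str(row["peptide"]),
                int(row["start"]),
                sequences[acc],
                gene=str(row.get("gene", acc)),
                accession=acc,
                acetylated=bool(row.get("acetylation_evidence", False)),
                config=config,
            )
        )
    return out
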