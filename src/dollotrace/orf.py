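"""Coding-model integrity: lesion detection, NMD prediction, pseudogene calls.

A gene is classified PSEUDOGENE when its coding sequence carries an
inactivating lesion — a premature stop codon, a frameshifting indel, or
loss of the start codon.  Premature stops upstream of the last exon–exon
junction are additionally predicted to trigger nonsense-mediated decay
(NMD) of the transcript; even without NMD, a stop that truncates the
central intermediate-filament (rod) domain removes the part of the
protein required for filament assembly, so such genes are called
nonfunctional.

Frameshifts are detected against an intact reference ORF by global
pairwise alignment (match +1, mismatch -1, gap open -4, gap extend -1);
every gap run whose length is not a multiple of 3 shifts the reading
frame.  Lesion codon positions under other alignment schemes may shift
by ±1 codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Data import CodonTable

from typing import Mapping, Optional, Sequence

__all__ = [
    "CodingModel",
    "Lesion",
    "IntegrityReport",
    "splice_cds",
    "scan_orf",
    "compare_to_reference",
    "predict_nmd",
    "assess_functionality",
    "shared_lesion",
]

PREMATURE_STOP = "PREMATURE_STOP"
FRAMESHIFT_INDEL = "FRAMESHIFT_INDEL"
START_LOSS = "START_LOSS"
TERMINAL_STOP_LOSS = "TERMINAL_STOP_LOSS"

#: fraction of ambiguous bases above which a CDS is uninformative
MAX_N_FRACTION = 0.10


@dataclass(frozen=True)
class Lesion:
    """One inactivating lesion in a coding sequence.

    ``codon_position`` is the 1-based codon index in the reference frame
    (for frameshifts: the codon containing the first shifted base).
    """

    kind: str
    codon_position: int
    detail: str = ""

    def __post_init__(self) -> None:
        if self.codon_position < 1:
            raise ValueError("codon_position must be >= 1")


@dataclass
class CodingModel:
    """Exon structure and spliced CDS of one gene in one species."""

    gene_id: str
    species: str
    exons: list[tuple[int, int]]
    strand: str
    spliced_cds: str
    rod_domain: Optional[tuple[int, int]] = None
    genetic_code: int = 1

    def __post_init__(self) -> None:
        self.spliced_cds = self.spliced_cds.upper()
        last_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"exon ({s},{e}) has start > end")
            if s <= last_end:
                raise ValueError("exons overlap or are unordered")
            last_end = e
        total = sum(e - s + 1 for s, e in self.exons)
        if self.exons and total != len(self.spliced_cds):
            raise ValueError(
                f"spliced CDS length {len(self.spliced_cds)} != exon total {total}"
            )
        if self.rod_domain is not None:
            a, b = self.rod_domain
            if not (1 <= a <= b <= max(1, len(self.spliced_cds) // 3)):
                raise ValueError(f"rod_domain {self.rod_domain} outside CDS")

    @property
    def n_codons(self) -> int:
        return len(self.spliced_cds) // 3

    def last_junction_nt(self) -> Optional[int]:
        """Spliced-CDS position of the last exon–exon junction (nt after it
        belong to the last exon); None for single-exon models."""
        if len(self.exons) < 2:
            return None
        return sum(e - s + 1 for s, e in self.exons[:-1])


@dataclass
class IntegrityReport:
    """Lesion list and functional classification of one coding model."""

    gene_id: str
    species: str
    status: str
    lesions: list[Lesion] = field(default_factory=list)
    nmd_predicted: bool = False
    truncates_rod: bool = False
    ambiguous_codons: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.status == "INTACT") != (len(self.lesions) == 0):
            raise ValueError("status INTACT iff lesion list empty")
        if not self.lesions and self.nmd_predicted:
            raise ValueError("nmd_predicted requires a lesion")

    def premature_stops(self) -> list[Lesion]:
        return [l for l in self.lesions if l.kind == PREMATURE_STOP]


# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def splice_cds(
    exons: Sequence[tuple[int, int]], genome: str, strand: str
) -> str:
    """Concatenate coding exons into the spliced CDS.

    ``exons`` are 1-based inclusive intervals in ascending genomic order;
    for the minus strand the spliced CDS is the reverse complement of
    their concatenation, read 5'→3' along the transcript.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    parts = []
    for s, e in exons:
        if not (1 <= s <= e <= len(genome)):
            raise ValueError(f"exon ({s},{e}) outside sequence of length {len(genome)}")
        parts.append(genome[s - 1 : e])
    cds = "".join(parts)
    if strand == "-":
        cds = cds.translate(_COMPLEMENT)[::-1]
    return cds.upper()


def _stop_codons(code_id: int) -> set[str]:
    table = CodonTable.unambiguous_dna_by_id[code_id]
    return set(table.stop_codons)


def _start_codons(code_id: int) -> set[str]:
    # require canonical ATG; alternative starts in the table are not
    # treated as rescuing a lost ATG
    return {"ATG"}


def scan_orf(model: CodingModel, nmd_margin: int = 0) -> IntegrityReport:
    """Scan a spliced CDS for reading-frame-preserving lesions.

    Reports every internal stop codon as PREMATURE_STOP, a missing ATG as
    START_LOSS and a missing terminal stop as TERMINAL_STOP_LOSS.  Codons
    containing N are skipped and listed as ambiguous, never as lesions.
    NMD and functionality are assessed on the resulting report.
    """
    cds = model.spliced_cds
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    if len(cds) % 3 != 0:
        raise ValueError(
            "CDS length not a multiple of 3; if an indel is suspected, "
            "use compare_to_reference with an intact reference ORF"
        )
    stops = _stop_codons(model.genetic_code)
    n_codons = len(cds) // 3
    lesions: list[Lesion] = []
    ambiguous: list[int] = []
    first = cds[0:3]
    if "N" in first:
        ambiguous.append(1)
    elif first not in _start_codons(model.genetic_code):
        lesions.append(Lesion(START_LOSS, 1, detail=f"first codon {first}"))
    for i in range(n_codons - 1):
        codon = cds[3 * i : 3 * i + 3]
        if "N" in codon:
            if i > 0:
                ambiguous.append(i + 1)
            continue
        if codon in stops:
            lesions.append(Lesion(PREMATURE_STOP, i + 1, detail=codon))
    last = cds[-3:]
    if "N" in last:
        ambiguous.append(n_codons)
    elif last not in stops:
        lesions.append(Lesion(TERMINAL_STOP_LOSS, n_codons, detail=last))
    report = IntegrityReport(
        gene_id=model.gene_id,
        species=model.species,
        status="INTACT" if not lesions else "PSEUDOGENE",
        lesions=lesions,
        ambiguous_codons=ambiguous,
    )
    report.nmd_predicted = predict_nmd(report, model, margin=nmd_margin)
    assess_functionality(report, model)
    return report


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -4
    a.extend_gap_score = -1
    return a


def compare_to_reference(query_cds: str, reference_cds: str) -> list[Lesion]:
    """Detect frameshifting indels in a query CDS against an intact reference.

    The two sequences are globally aligned; every gap run whose length is
    not a multiple of 3 is reported as a FRAMESHIFT_INDEL at the codon
    containing its first aligned reference base.  The query is then
    re-scanned for stop codons in its own (shifted) frame; each internal
    stop is reported at the reference codon it aligns to.
    """
    query_cds = query_cds.upper()
    reference_cds = reference_cds.upper()
    if not query_cds or not reference_cds:
        raise ValueError("empty sequence")
    aln = _aligner().align(reference_cds, query_cds)[0]
    ref_aln, qry_aln = str(aln[0]), str(aln[1])

    lesions: list[Lesion] = []
    # gap runs
    i = 0
    ref_pos = 0  # 1-based count of consumed reference bases
    while i < len(ref_aln):
        if qry_aln[i] == "-" or ref_aln[i] == "-":
            in_query_gap = qry_aln[i] == "-"
            j = i
            run_ref_start = None
            while j < len(ref_aln) and (
                (qry_aln[j] == "-") if in_query_gap else (ref_aln[j] == "-")
            ):
                if in_query_gap and run_ref_start is None:
                    run_ref_start = ref_pos + 1
                if ref_aln[j] != "-":
                    ref_pos += 1
                j += 1
            run_len = j - i
            if run_len % 3 != 0:
                if run_ref_start is None:
                    # insertion in query: first aligned reference base after it
                    run_ref_start = min(ref_pos + 1, len(reference_cds))
                codon = (run_ref_start - 1) // 3 + 1
                kind = "deletion" if in_query_gap else "insertion"
                lesions.append(
                    Lesion(FRAMESHIFT_INDEL, codon, detail=f"{run_len}-nt {kind}")
                )
            i = j
        else:
            ref_pos += 1
            i += 1

    # stop re-scan in the query's own frame, mapped back to reference codons
    stops = _stop_codons(1)
    q_to_ref = _query_to_reference_map(ref_aln, qry_aln)
    nq = len(query_cds) // 3
    for k in range(nq - 1):  # internal codons only
        codon = query_cds[3 * k : 3 * k + 3]
        if "N" in codon:
            continue
        if codon in stops:
            ref_base = q_to_ref[3 * k]
            ref_codon = (ref_base - 1) // 3 + 1 if ref_base else k + 1
            if ref_codon < len(reference_cds) // 3:  # not the terminal stop
                lesions.append(Lesion(PREMATURE_STOP, ref_codon, detail=codon))
    lesions.sort(key=lambda l: (l.codon_position, l.kind))
    return lesions


def _query_to_reference_map(ref_aln: str, qry_aln: str) -> list[int]:
    """For each query base (0-based), the 1-based reference base it aligns
    to (or the last reference base consumed before it, for insertions)."""
    out = []
    ref_pos = 0
    for r, q in zip(ref_aln, qry_aln):
        if r != "-":
            ref_pos += 1
        if q != "-":
            out.append(ref_pos if ref_pos else 1)
    return out


def predict_nmd(
    report: IntegrityReport, model: CodingModel, margin: int = 0
) -> bool:
    """Predict nonsense-mediated decay from premature-stop position.

    True iff some premature stop ends at least ``margin`` nucleotides 5'
    of the last exon–exon junction in the spliced CDS.  The default
    margin 0 is the literal "stop before the last exon" rule; the
    canonical 50-nt boundary rule is ``margin=50``.  Single-exon models
    never predict NMD.
    """
    junction = model.last_junction_nt()
    if junction is None:
        return False
    for lesion in report.premature_stops():
        stop_end_nt = 3 * lesion.codon_position
        if junction - stop_end_nt >= margin:
            return True
    return False


def assess_functionality(report: IntegrityReport, model: CodingModel) -> str:
    """Classify the gene product as functional or nonfunctional.

    Nonfunctional iff NMD is predicted, or any frameshift is present, or
    a premature stop truncates the rod domain (with no rod annotation,
    any premature stop counts).  Updates ``report.truncates_rod`` and
    ``report.status`` in place and returns "functional"/"nonfunctional".
    """
    frameshift = any(l.kind == FRAMESHIFT_INDEL for l in report.lesions)
    rod_hit = False
    for lesion in report.premature_stops():
        if model.rod_domain is None or lesion.codon_position <= model.rod_domain[1]:
            rod_hit = True
    report.truncates_rod = rod_hit
    nonfunctional = report.nmd_predicted or frameshift or rod_hit
    if nonfunctional:
        report.status = "PSEUDOGENE"
    return "nonfunctional" if nonfunctional else "functional"


def shared_lesion(
    reports: Mapping[str, IntegrityReport],
    alignment: Mapping[str, str],
) -> list[set[str]]:
    """Group species whose premature stops fall in the same aligned column.

    ``alignment`` maps species to gapped CDS strings of equal length.
    Species sharing an aligned stop column are merged into one group
    (interpreted downstream as a single ancestral inactivation); species
    with no shared column form singletons.  Groups are returned sorted by
    their smallest member for determinism.
    """
    if not reports:
        raise ValueError("no reports")
    widths = {len(s) for s in alignment.values()}
    if len(widths) > 1:
        raise ValueError("alignment rows have unequal length")
    for sp in reports:
        if sp not in alignment:
            raise KeyError(f"species {sp!r} missing from alignment")

    def to_column(species: str, codon: int) -> int:
        """Aligned column of the first base of an ungapped codon."""
        target = 3 * (codon - 1)  # 0-based ungapped base index
        seen = 0
        for col, ch in enumerate(alignment[species]):
            if ch != "-":
                if seen == target:
                    return col
                seen += 1
        raise ValueError(f"codon {codon} beyond sequence of {species}")

    col_members: dict[int, set[str]] = {}
    for sp, rep in sorted(reports.items()):
        for lesion in rep.premature_stops():
            col_members.setdefault(to_column(sp, lesion.codon_position), set()).add(sp)

    # union-find over species via shared columns
    parent = {sp: sp for sp in reports}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for members in col_members.values():
        members = sorted(members)
        for other in members[1:]:
            parent[find(other)] = find(members[0])

    groups: dict[str, set[str]] = {}
    for sp in reports:
        groups.setdefault(find(sp), set()).add(sp)
    return sorted(groups.values(), key=lambda g: sorted(g)[0])
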