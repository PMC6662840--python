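"""Gene-order maps and synteny-anchored positional orthology.

A :class:`LocusMap` is the ordered list of gene features in one genomic
window of one species.  Positional orthology is called by finding the
conserved genes that flank a target in a reference map and asking whether
the same anchors, in the query species, still enclose a candidate gene.
This is the "manual alignment of gene maps" strategy of classical
comparative genomics, done programmatically.

Coordinates are 1-based inclusive throughout (GFF3 convention); BED input
is converted on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "GeneFeature",
    "LocusMap",
    "OrthologCall",
    "WindowIncomplete",
    "read_locus_map",
    "extract_window",
    "neighbors",
    "call_ortholog_by_synteny",
]

#: Ortholog-call status values.
ORTHOLOG = "ORTHOLOG"
HOMOLOG_UNRESOLVED = "HOMOLOG_UNRESOLVED"
ABSENT_FROM_WINDOW = "ABSENT_FROM_WINDOW"
WINDOW_INCOMPLETE = "WINDOW_INCOMPLETE"


@dataclass(frozen=True)
class GeneFeature:
    """One gene in a locus map.

    ``start``/``end`` are 1-based inclusive genomic coordinates;
    ``strand`` is ``"+"`` or ``"-"``.
    """

    gene_id: str
    symbol: str
    species: str
    sequence_region: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("symbol must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class LocusMap:
    """Ordered gene features of one genomic region in one species."""

    species: str
    sequence_region: str
    features: list[GeneFeature] = field(default_factory=list)
    orientation: str = "forward"

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        seen: set[str] = set()
        for f in self.features:
            if f.species != self.species or f.sequence_region != self.sequence_region:
                raise ValueError(
                    f"feature {f.gene_id} does not belong to "
                    f"{self.species}/{self.sequence_region}"
                )
            if f.gene_id in seen:
                raise ValueError(f"duplicate gene_id {f.gene_id!r}")
            seen.add(f.gene_id)

    def symbols(self) -> list[str]:
        return [f.symbol for f in self.features]

    def find(self, symbol: str) -> list[GeneFeature]:
        """All features whose symbol matches ``symbol`` case-insensitively."""
        s = symbol.upper()
        return [f for f in self.features if f.symbol.upper() == s]

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)


@dataclass(frozen=True)
class OrthologCall:
    """Outcome of a synteny-based positional-orthology test."""

    target_symbol: str
    query_species: str
    status: str
    left_anchor: str = ""
    right_anchor: str = ""
    evidence: int = 0
    candidates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.status == ORTHOLOG and self.evidence != 2:
            raise ValueError("ORTHOLOG status requires evidence == 2")


class WindowIncomplete:
    """Signal that a synteny window could not be bounded on both sides.

    Carried instead of a feature list when an anchor is missing (e.g. it
    fell off a scaffold end); downstream presence calling must treat this
    as UNKNOWN, never as gene absence.
    """

    def __init__(self, missing_anchor: str):
        self.missing_anchor = missing_anchor

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"WindowIncomplete(missing_anchor={self.missing_anchor!r})"


# ---------------------------------------------------------------------------
# reading

_GFF_ATTR = re.compile(r"(\w+)=([^;]+)")


def _parse_gff3(path: Path) -> list[dict]:
    """Minimal reader for the pinned GFF3 gene-record dialect.

    Only ``gene`` records are kept; the symbol comes from the
    ``gene_name`` or ``Name`` attribute, the id from ``ID``.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != "gene":
                continue
            ad = dict(_GFF_ATTR.findall(attrs))
            symbol = ad.get("gene_name") or ad.get("Name") or ad.get("ID", "")
            rows.append(
                dict(
                    gene_id=ad.get("ID", symbol),
                    symbol=symbol,
                    region=seqid,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                )
            )
    return rows


def read_locus_map(
    path: str | Path, format: str, species: Optional[str] = None
) -> LocusMap:
    """Read a per-species gene-coordinate map.

    Parameters
    ----------
    path
        Input file.
    format
        One of ``gff3``, ``bed`` (BED6, half-open 0-based; converted), or
        ``tsv`` (header ``species region symbol start end strand``).
    species
        Species identifier; required for gff3/bed (the formats do not
        carry one), ignored for tsv (taken from the column).
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "gff3":
        rows = _parse_gff3(path)
        sp = species or path.stem
    elif fmt == "bed":
        try:
            df = pd.read_csv(
                path,
                sep="\t",
                header=None,
                comment="#",
                names=["region", "start", "end", "symbol", "score", "strand"],
                dtype={"region": str, "symbol": str, "strand": str},
            )
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=["region", "start", "end", "symbol", "score", "strand"])
        sp = species or path.stem
        rows = [
            dict(
                gene_id=f"{r.symbol}@{int(r.start) + 1}",
                symbol=r.symbol,
                region=r.region,
                start=int(r.start) + 1,  # BED is 0-based half-open
                end=int(r.end),
                strand=r.strand,
            )
            for r in df.itertuples()
        ]
    elif fmt == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(
                columns=["species", "region", "symbol", "start", "end", "strand"]
            )
        expected = {"species", "region", "symbol", "start", "end", "strand"}
        if not expected.issubset(df.columns):
            raise ValueError(
                f"TSV locus map must have columns {sorted(expected)}; "
                f"got {list(df.columns)}"
            )
        species_seen = df["species"].unique()
        if len(species_seen) > 1:
            raise ValueError(
                f"locus map file mixes species {list(species_seen)}; one per file"
            )
        sp = species_seen[0] if len(species_seen) else (species or path.stem)
        # the TSV dialect carries no id column; synthesize a stable one
        rows = [
            dict(
                gene_id=f"{r.symbol}@{int(r.start)}",
                symbol=r.symbol,
                region=r.region,
                start=int(r.start),
                end=int(r.end),
                strand=r.strand,
            )
            for r in df.itertuples()
        ]
    else:
        raise ValueError(f"unknown locus-map format {format!r}")

    region = rows[0]["region"] if rows else "NA"
    feats = [
        GeneFeature(
            gene_id=r["gene_id"],
            symbol=r["symbol"],
            species=sp,
            sequence_region=r["region"],
            start=r["start"],
            end=r["end"],
            strand=r["strand"],
        )
        for r in rows
    ]
    ids = [f.gene_id for f in feats]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        raise ValueError(f"duplicate gene_id in {path}: {sorted(dup)}")
    return LocusMap(species=sp, sequence_region=region, features=feats)


# ---------------------------------------------------------------------------
# window extraction and neighborhood

def _flip(f: GeneFeature) -> GeneFeature:
    return replace(f, strand="+" if f.strand == "-" else "-")


def _locate_anchor(map: LocusMap, symbol: str) -> int:
    hits = [i for i, f in enumerate(map.features) if f.symbol.upper() == symbol.upper()]
    if len(hits) > 1:
        raise ValueError(f"anchor {symbol!r} occurs {len(hits)} times in map")
    if not hits:
        return -1
    return hits[0]


def extract_window(
    map: LocusMap, left_anchor: str, right_anchor: str
) -> list[GeneFeature] | WindowIncomplete:
    """Genes strictly between two anchor symbols, read left→right.

    If the anchors occur in flipped genomic order (the locus sits on the
    other strand in this assembly), the window is reversed and each
    feature's strand flipped so the result always reads
    ``left_anchor → right_anchor``.  A missing anchor yields a
    :class:`WindowIncomplete` signal rather than an exception.
    """
    li = _locate_anchor(map, left_anchor)
    ri = _locate_anchor(map, right_anchor)
    if li < 0:
        return WindowIncomplete(left_anchor)
    if ri < 0:
        return WindowIncomplete(right_anchor)
    if li < ri:
        return list(map.features[li + 1 : ri])
    window = list(map.features[ri + 1 : li])
    return [_flip(f) for f in reversed(window)]


def neighbors(
    map: LocusMap, symbol: str, sidedness: str = "transcriptional"
) -> tuple[Optional[str], Optional[str]]:
    """Immediate neighbor symbols of a gene.

    With ``sidedness="transcriptional"`` (default) the pair is read in the
    5'→3' direction of the focal gene: for a minus-strand gene the genomic
    right neighbor is its 5'-side neighbor.  ``sidedness="genomic"``
    returns plain (left, right) in ascending coordinates.
    """
    hits = [i for i, f in enumerate(map.features) if f.symbol.upper() == symbol.upper()]
    if not hits:
        raise KeyError(f"symbol {symbol!r} not in map")
    if len(hits) > 1:
        raise ValueError(f"symbol {symbol!r} occurs {len(hits)} times in map")
    i = hits[0]
    left = map.features[i - 1].symbol if i > 0 else None
    right = map.features[i + 1].symbol if i + 1 < len(map.features) else None
    if sidedness == "genomic":
        return left, right
    if sidedness != "transcriptional":
        raise ValueError(f"unknown sidedness {sidedness!r}")
    if map.features[i].strand == "-":
        return right, left
    return left, right


# ---------------------------------------------------------------------------
# orthology calling

def _reference_anchors(
    reference: LocusMap, target_symbol: str, anchor_set: Iterable[str]
) -> tuple[str, str]:
    """Nearest anchor-set members flanking the target in the reference."""
    anchors = {a.upper() for a in anchor_set}
    idx = [i for i, f in enumerate(reference.features)
           if f.symbol.upper() == target_symbol.upper()]
    if not idx:
        raise ValueError(f"target {target_symbol!r} absent from reference map")
    i = idx[0]
    left = next(
        (f.symbol for f in reversed(reference.features[:i])
         if f.symbol.upper() in anchors),
        "",
    )
    right = next(
        (f.symbol for f in reference.features[i + 1:]
         if f.symbol.upper() in anchors),
        "",
    )
    return left, right


def call_ortholog_by_synteny(
    query: LocusMap,
    reference: LocusMap,
    target_symbol: str,
    anchor_set: Iterable[str],
    homolog_pattern: Optional[str] = None,
) -> OrthologCall:
    """Call a positional ortholog of ``target_symbol`` in the query species.

    The nearest ``anchor_set`` members flanking the target in the
    reference are located in the query; a single candidate between them
    whose symbol matches exactly gives ORTHOLOG, a pattern match (default
    pattern ``<symbol>-like``, case-insensitive) or multiple candidates
    give HOMOLOG_UNRESOLVED, an empty window gives ABSENT_FROM_WINDOW and
    a missing anchor gives WINDOW_INCOMPLETE.
    """
    left, right = _reference_anchors(reference, target_symbol, anchor_set)
    if not left or not right:
        # reference itself cannot bound the target
        return OrthologCall(
            target_symbol=target_symbol,
            query_species=query.species,
            status=WINDOW_INCOMPLETE,
            left_anchor=left,
            right_anchor=right,
            evidence=int(bool(left)) + int(bool(right)),
        )
    window = extract_window(query, left, right)
    if isinstance(window, WindowIncomplete):
        present = 1 if _locate_anchor(query, left) >= 0 or _locate_anchor(query, right) >= 0 else 0
        return OrthologCall(
            target_symbol=target_symbol,
            query_species=query.species,
            status=WINDOW_INCOMPLETE,
            left_anchor=left,
            right_anchor=right,
            evidence=present,
        )
    pattern = homolog_pattern or rf"{re.escape(target_symbol)}-?like"
    rx = re.compile(pattern, re.IGNORECASE)
    exact = [f for f in window if f.symbol.upper() == target_symbol.upper()]
    like = [f for f in window if rx.fullmatch(f.symbol)]
    candidates = exact + [f for f in like if f not in exact]
    if len(exact) == 1 and len(candidates) == 1:
        status = ORTHOLOG
    elif candidates:
        status = HOMOLOG_UNRESOLVED
    else:
        status = ABSENT_FROM_WINDOW
    return OrthologCall(
        target_symbol=target_symbol,
        query_species=query.species,
        status=status,
        left_anchor=left,
        right_anchor=right,
        evidence=2,
        candidates=tuple(f.symbol for f in candidates),
    )
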